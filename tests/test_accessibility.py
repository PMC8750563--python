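"""Score matrices, quantile normalization, MPS/DPS, Poisson differential peaks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtchrom.accessibility import (
    build_score_matrix,
    classify_change,
    classify_change_table,
    correlation_matrix,
    differential_peaks,
    fc_vs_tss_table,
    quantile_normalize,
)
from emtchrom.intervals import RegionSet, TSSTable

from conftest import regions


# ---------------------------------------------------------------------------
# build_score_matrix


def test_score_matrix_log_transform_and_absence():
    a = regions(("chr1", 100, 200, 7.0), label="A")
    b = regions(("chr1", 5000, 5100, 3.0), label="B")
    m = build_score_matrix([a, b])
    assert m.shape == (2, 2)
    # raw score 7 -> log2(8) = 3; absent peak -> 0
    row_a = m.loc["chr1:0-300"] if "chr1:0-300" in m.index else m.iloc[0]
    assert row_a["A"] == pytest.approx(3.0)
    assert row_a["B"] == 0.0


def test_score_matrix_identical_inputs_identical_columns():
    a = regions(("chr1", 100, 200, 7.0), ("chr1", 5000, 5100, 2.0), label="A")
    b = regions(("chr1", 100, 200, 7.0), ("chr1", 5000, 5100, 2.0), label="B")
    m = build_score_matrix([a, b])
    assert (m["A"] == m["B"]).all()


def test_score_matrix_rows_are_fixed_width_bins():
    a = regions(("chr1", 1000, 2000, 1.0), label="A")
    b = regions(("chr1", 9000, 9500, 1.0), label="B")
    m = build_score_matrix([a, b], bin_size=300)
    for label in m.index:
        _, coords = label.split(":")
        lo, hi = map(int, coords.split("-"))
        assert hi - lo == 300


def test_score_matrix_rejects_unscored_regions():
    a = regions(("chr1", 100, 200), label="A")
    b = regions(("chr1", 400, 500, 1.0), label="B")
    with pytest.raises(ValueError, match="unscored"):
        build_score_matrix([a, b])


# ---------------------------------------------------------------------------
# quantile normalization


def test_quantile_normalize_hand_example():
    m = pd.DataFrame({"c1": [1.0, 2.0, 3.0], "c2": [6.0, 4.0, 5.0]})
    qn = quantile_normalize(m)
    assert qn["c1"].tolist() == [2.5, 3.5, 4.5]
    assert qn["c2"].tolist() == [4.5, 2.5, 3.5]


def test_quantile_normalize_fixed_point_on_identical_columns():
    m = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
    pd.testing.assert_frame_equal(quantile_normalize(m), m)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_quantile_normalize_idempotent_and_multisets_identical(seed):
    rng = np.random.default_rng(seed)
    m = pd.DataFrame(rng.integers(0, 20, size=(15, 4)).astype(float),
                     columns=list("abcd"))
    qn = quantile_normalize(m)
    cols = [np.sort(qn[c].to_numpy()) for c in qn.columns]
    for c in cols[1:]:
        np.testing.assert_array_equal(cols[0], c)
    pd.testing.assert_frame_equal(quantile_normalize(qn), qn)


# ---------------------------------------------------------------------------
# correlation


def test_correlation_matrix_properties_and_oracle(rng):
    m = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("xyz")).abs()
    corr = correlation_matrix(m)
    np.testing.assert_allclose(np.diag(corr), 1.0)
    np.testing.assert_allclose(corr, corr.T)
    # textbook Pearson oracle
    for a in "xyz":
        for b in "xyz":
            xa, xb = m[a] - m[a].mean(), m[b] - m[b].mean()
            expected = (xa * xb).sum() / math.sqrt((xa**2).sum() * (xb**2).sum())
            assert corr.loc[a, b] == pytest.approx(expected, abs=1e-12)


def test_correlation_negation_and_zero_variance():
    m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
    assert correlation_matrix(m).loc["a", "b"] == pytest.approx(-1.0)
    bad = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 2.0, 2.0]})
    with pytest.raises(ValueError, match="zero-variance"):
        correlation_matrix(bad)


# ---------------------------------------------------------------------------
# MPS / DPS classification


@pytest.mark.parametrize(
    "a,b,mps,dps,klass,major",
    [
        (4.0, 4.0, 4.0, 0.0, "moderate", False),
        (6.5, 3.9, 5.2, 2.6, "high", True),
        (1.0, 3.5, 2.25, -2.5, "low", True),
    ],
)
def test_classify_change_examples(a, b, mps, dps, klass, major):
    ch = classify_change(a, b)
    assert ch.mps == pytest.approx(mps)
    assert ch.dps == pytest.approx(dps)
    assert ch.accessibility_class == klass
    assert ch.major_change == major


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0, 10), st.floats(0, 10))
def test_classify_change_antisymmetric(a, b):
    ab, ba = classify_change(a, b), classify_change(b, a)
    assert ab.dps == pytest.approx(-ba.dps)
    assert ab.mps == pytest.approx(ba.mps)


def test_classify_change_table_matches_scalar():
    m = pd.DataFrame({"A": [4.0, 6.5, 1.0], "B": [4.0, 3.9, 3.5]})
    table = classify_change_table(m, "A", "B")
    for i in range(3):
        ch = classify_change(m["A"].iloc[i], m["B"].iloc[i])
        assert table["mps"].iloc[i] == pytest.approx(ch.mps)
        assert table["accessibility_class"].iloc[i] == ch.accessibility_class
        assert table["major_change"].iloc[i] == ch.major_change


# ---------------------------------------------------------------------------
# differential peaks


def _poisson_sf_oracle(k, lam):
    """P(X >= k) by explicit partial sums of the Poisson pmf."""
    p_le = 0.0
    term = math.exp(-lam)
    for i in range(int(k)):
        p_le += term
        term *= lam / (i + 1)
    return 1.0 - p_le


def test_differential_peaks_flagging_rules():
    dp = differential_peaks([40, 12, 0], [5, 4, 10], 1.0, 1.0)
    assert dp["flagged"].tolist() == [True, False, False]
    assert dp["fold"].iloc[0] == pytest.approx(8.0)
    assert dp["fold"].iloc[1] == pytest.approx(3.0)


def test_differential_peaks_p_matches_partial_sum_oracle():
    dp = differential_peaks([40, 12, 3, 100], [5, 4, 2, 30], 1.0, 1.0)
    for t, lam, p in zip(dp["tags_target"], dp["lambda"], dp["p_value"]):
        assert p == pytest.approx(_poisson_sf_oracle(t, lam), rel=1e-9)
    assert _poisson_sf_oracle(40, 5.0) < 1e-4


def test_differential_peaks_depth_normalization_and_zero_background():
    # background scaled to target depth: 10 tags at half depth -> lambda 20
    dp = differential_peaks([80, 80], [10, 0], 2.0, 1.0)
    assert dp["lambda"].iloc[0] == pytest.approx(20.0)
    assert dp["lambda"].iloc[1] == pytest.approx(1.0)  # 0.5 pseudocount * 2
    with pytest.raises(ValueError):
        differential_peaks([-1], [0], 1, 1)


def test_differential_peaks_directions_disjoint(rng):
    t = rng.poisson(50, size=200)
    b = rng.poisson(50, size=200)
    up = differential_peaks(t, b, 1.0, 1.0)["flagged"]
    down = differential_peaks(b, t, 1.0, 1.0)["flagged"]
    assert not (up & down).any()


def test_differential_peaks_planted_recovery(small_genome):
    """>= 95% sensitivity for planted 8-fold effects, <= 1% false positives."""
    from emtchrom.synthetic import simulate_region_set, simulate_tag_counts

    rs = simulate_region_set(small_genome, 400, 500, 50, seed=21)
    folds = np.ones(400)
    planted = np.arange(0, 400, 20)  # 20 planted regions
    folds[planted] = 8.0
    depth = 400 * 50  # expected background ~50 tags/region
    counts = simulate_tag_counts(rs, depth, depth, folds, seed=22)
    dp = differential_peaks(
        counts["tags_target"], counts["tags_background"], depth, depth
    )
    is_planted = np.zeros(400, dtype=bool)
    is_planted[planted] = True
    sensitivity = dp["flagged"][is_planted].mean()
    fp_rate = dp["flagged"][~is_planted].mean()
    assert sensitivity >= 0.95
    assert fp_rate <= 0.01


# ---------------------------------------------------------------------------
# fold-change vs TSS join


def test_fc_vs_tss_manual_join():
    tss = TSSTable(pd.DataFrame(
        [("G1", "chr1", 1000, "+"), ("G2", "chr1", 50_000, "+"),
         ("G3", "chr2", 5000, "-")],
        columns=["gene_id", "chrom", "tss", "strand"],
    ))
    peaks = regions(
        ("chr1", 900, 1100),      # center 1000 -> G1, distance 0
        ("chr1", 48_000, 48_400), # -> G2
        ("chr1", 10_000, 10_200), # -> G1
        ("chr2", 6000, 6200),     # -> G3 (minus strand)
        ("chr2", 100, 300),       # -> G3
    )
    expr = pd.DataFrame(
        {"s1": [9.0, 4.0, 1.0], "s2": [4.0, 4.0, 0.0]},
        index=["G1", "G2", "G3"],
    )
    out = fc_vs_tss_table(peaks, tss, expr, "s1", "s2", pseudocount=1.0)
    assert len(out) == 5
    assert out["gene_id"].tolist() == ["G1", "G1", "G2", "G3", "G3"]
    assert out["tss_distance"].iloc[0] == 0.0
    assert out["expression_fold_change"].iloc[0] == pytest.approx(2.0)  # (9+1)/(4+1)
    assert out["expression_fold_change"].iloc[2] == pytest.approx(1.0)
    # minus strand flips the sign: center 200 vs TSS 5000 -> -(-4800) = 4800,
    # center 6100 vs TSS 5000 -> -(1100) = -1100
    assert out["tss_distance"].iloc[3] == 4800.0
    assert out["tss_distance"].iloc[4] == -1100.0


def test_fc_vs_tss_missing_gene_flagged():
    tss = TSSTable(pd.DataFrame([("GX", "chr1", 100, "+")],
                                columns=["gene_id", "chrom", "tss", "strand"]))
    peaks = regions(("chr1", 0, 200))
    expr = pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["OTHER"])
    out = fc_vs_tss_table(peaks, tss, expr, "s1", "s2")
    assert out["missing_expression"].iloc[0]
    assert np.isnan(out["expression_fold_change"].iloc[0])


def test_fc_vs_tss_equal_samples_ratio_one():
    tss = TSSTable(pd.DataFrame([("GX", "chr1", 100, "+")],
                                columns=["gene_id", "chrom", "tss", "strand"]))
    peaks = regions(("chr1", 0, 200), ("chr1", 1000, 1200))
    expr = pd.DataFrame({"s1": [5.0], "s2": [5.0]}, index=["GX"])
    out = fc_vs_tss_table(peaks, tss, expr, "s1", "s2")
    assert (out["expression_fold_change"] == 1.0).all()
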