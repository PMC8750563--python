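"""Interval model: BED I/O, merging, gaps, deserts, TSS annotation, overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtchrom.intervals import (
    GenomeModel,
    GenomicRegion,
    RegionSet,
    TSSTable,
    basepair_overlap,
    count_peak_deserts,
    gap_lengths,
    median_gap,
    merge_region_sets,
    nearest_tss,
    read_bed,
    write_bed,
)

from conftest import regions


# ---------------------------------------------------------------------------
# GenomicRegion / RegionSet basics


@pytest.mark.parametrize("start,end", [(100, 50), (10, 10), (-1, 5)])
def test_invalid_region_coordinates_rejected(start, end):
    with pytest.raises(ValueError):
        GenomicRegion("chr1", start, end)


def test_regionset_sorts_on_construction():
    rs = regions(("chr2", 0, 10), ("chr1", 50, 60), ("chr1", 0, 10))
    assert [(r.chrom, r.start) for r in rs] == [("chr1", 0), ("chr1", 50), ("chr2", 0)]


def test_total_bp_collapses_internal_overlaps():
    rs = regions(("chr1", 0, 100), ("chr1", 50, 150))
    assert rs.total_bp() == 150


# ---------------------------------------------------------------------------
# BED I/O


def test_bed_round_trip_identity(tmp_path):
    rs = regions(
        ("chr1", 100, 200, 7.0), ("chr1", 450, 500, 3.5), ("chr2", 0, 50, 1.0)
    )
    path = tmp_path / "x.bed"
    write_bed(rs, path)
    back = read_bed(path)
    assert [(r.chrom, r.start, r.end, r.score) for r in back] == [
        (r.chrom, r.start, r.end, r.score) for r in rs
    ]


def test_read_bed_rejects_reversed_coordinates(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t100\t50\n")
    with pytest.raises(ValueError, match="start must be < end"):
        read_bed(path)


def test_read_bed_rejects_non_integer_and_unknown_chrom(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\tabc\t50\n")
    with pytest.raises(ValueError, match="non-integer"):
        read_bed(path)
    path.write_text("chrX\t0\t50\n")
    with pytest.raises(ValueError, match="unknown chromosome"):
        read_bed(path, genome=GenomeModel({"chr1": 1000}))


def test_read_bed_empty_file(tmp_path):
    path = tmp_path / "empty.bed"
    path.write_text("")
    assert len(read_bed(path)) == 0


# ---------------------------------------------------------------------------
# merge_region_sets (center-distance transitive closure)


def _brute_force_merge(sets, d):
    """Oracle: explicit transitive closure over all center-distance pairs."""
    pooled = [(r, s.condition_label) for s in sets for r in s]
    n = len(pooled)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        ri, rj = pooled[i][0], pooled[j][0]
        if ri.chrom == rj.chrom and abs(ri.center - rj.center) <= d:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(pooled[i])
    out = []
    for members in groups.values():
        chrom = members[0][0].chrom
        span = (min(r.start for r, _ in members), max(r.end for r, _ in members))
        labels = frozenset(l for _, l in members)
        out.append((chrom, span[0], span[1], labels))
    return sorted(out)


def test_merge_transitive_chain_hand_example():
    a = regions(("chr1", 100, 200), ("chr1", 450, 500), label="A")
    b = regions(("chr1", 180, 260), label="B")
    merged = merge_region_sets([a, b], 300)
    assert len(merged) == 1
    r = merged.regions[0]
    assert (r.chrom, r.start, r.end) == ("chr1", 100, 500)
    assert merged.membership.iloc[0].to_dict() == {"A": True, "B": True}


def test_merge_idempotent_on_single_set():
    a = regions(("chr1", 0, 100), ("chr1", 5000, 5100), ("chr2", 0, 50), label="A")
    merged = merge_region_sets([a], 300)
    assert [(r.chrom, r.start, r.end) for r in merged.regions] == [
        (r.chrom, r.start, r.end) for r in a
    ]
    assert merged.membership["A"].all()


def test_merge_with_empty_set_keeps_flags_false():
    a = regions(("chr1", 0, 100), label="A")
    b = RegionSet([], condition_label="B")
    merged = merge_region_sets([a, b], 300)
    assert len(merged) == 1
    assert not merged.membership["B"].any()


def test_merge_rejects_negative_distance():
    with pytest.raises(ValueError):
        merge_region_sets([regions(("chr1", 0, 10))], -1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_merge_matches_brute_force_closure(seed):
    rng = np.random.default_rng(seed)
    sets = []
    for label in "AB":
        regs = []
        for i in range(rng.integers(1, 30)):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, 20_000))
            regs.append(GenomicRegion(chrom, start, start + int(rng.integers(50, 800))))
        sets.append(RegionSet(regs, condition_label=label))
    d = int(rng.integers(0, 600))
    merged = merge_region_sets(sets, d)
    got = sorted(
        (r.chrom, r.start, r.end, frozenset(
            c for c in merged.membership.columns if merged.membership.iloc[i][c]))
        for i, r in enumerate(merged.regions)
    )
    assert got == _brute_force_merge(sets, d)


def test_merge_order_independent():
    a = regions(("chr1", 100, 200), ("chr1", 900, 1000), label="A")
    b = regions(("chr1", 180, 260), label="B")
    m1 = merge_region_sets([a, b], 300)
    m2 = merge_region_sets([b, a], 300)
    assert [(r.chrom, r.start, r.end) for r in m1.regions] == [
        (r.chrom, r.start, r.end) for r in m2.regions
    ]


# ---------------------------------------------------------------------------
# gaps and deserts


def test_gap_lengths_hand_example():
    rs = regions(("chr1", 0, 100), ("chr1", 300, 400), ("chr1", 1000, 1100))
    gaps = gap_lengths(rs)
    assert gaps == {"chr1": [200, 600]}
    assert median_gap(rs) == 400


def test_gap_lengths_single_peak_and_bookended():
    assert gap_lengths(regions(("chr1", 0, 100))) == {"chr1": []}
    assert gap_lengths(regions(("chr1", 0, 100), ("chr1", 100, 200))) == {"chr1": [0]}


def test_gap_lengths_rejects_overlapping():
    with pytest.raises(ValueError):
        gap_lengths(regions(("chr1", 0, 100), ("chr1", 50, 150)))


def test_gaps_plus_peaks_bounded_by_chromosome():
    rs = regions(("chr1", 10, 100), ("chr1", 300, 400), ("chr1", 900, 950))
    genome = GenomeModel({"chr1": 1000})
    total = sum(gap_lengths(rs)["chr1"]) + sum(r.length for r in rs)
    assert total <= genome.chrom_sizes["chr1"]


def test_peak_deserts_hand_arithmetic():
    genome = GenomeModel({"chr1": 5_000_000})
    rs = regions(("chr1", 0, 1000), ("chr1", 3_500_000, 3_501_000))
    assert count_peak_deserts(rs, genome) == 1  # effective gap 3,499,000

    masked = GenomeModel(
        {"chr1": 5_000_000},
        regions(("chr1", 200_000, 3_400_000), label="excluded"),
    )
    assert count_peak_deserts(rs, masked) == 0  # effective gap 299,000


def test_no_deserts_with_dense_peaks():
    rs = regions(*[("chr1", p, p + 1000) for p in range(0, 5_000_000, 500_000)])
    genome = GenomeModel({"chr1": 5_000_000})
    assert count_peak_deserts(rs, genome) == 0


# ---------------------------------------------------------------------------
# nearest TSS


def _tss(*rows):
    return TSSTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]))


def test_nearest_tss_sign_convention():
    tss = _tss(("GENE_A", "chr1", 10_000, "+"))
    peak = regions(("chr1", 11_200, 11_800))
    assert nearest_tss(peak, tss)["tss_distance"].iloc[0] == 1500.0
    tss_minus = _tss(("GENE_A", "chr1", 10_000, "-"))
    assert nearest_tss(peak, tss_minus)["tss_distance"].iloc[0] == -1500.0


def test_nearest_tss_zero_distance_and_tie_break():
    tss = _tss(("GENE_B", "chr1", 500, "+"), ("GENE_A", "chr1", 700, "+"))
    peak = regions(("chr1", 550, 650))  # center 600, equidistant
    out = nearest_tss(peak, tss)
    assert out["gene_id"].iloc[0] == "GENE_A"  # lexicographic tie-break
    on_tss = regions(("chr1", 450, 550))
    assert nearest_tss(on_tss, tss)["tss_distance"].iloc[0] == 0.0


def test_nearest_tss_rejects_empty_table():
    with pytest.raises(ValueError):
        nearest_tss(regions(("chr1", 0, 10)), _tss())


def test_nearest_tss_matches_all_pairs_scan():
    rng = np.random.default_rng(42)
    regs = regions(
        *[("chr1", int(s), int(s) + 200) for s in rng.integers(0, 1_000_000, 300)]
    )
    rows = [
        (f"G{i:03d}", "chr1", int(p), "+" if i % 2 else "-")
        for i, p in enumerate(rng.integers(0, 1_000_000, 80))
    ]
    table = _tss(*rows)
    got = nearest_tss(regs, table)
    for (_, row), r in zip(got.iterrows(), regs):
        best = min(
            rows,
            key=lambda t: (abs(r.center - t[2]), t[0]),
        )
        assert row["gene_id"] == best[0]
        expected = r.center - best[2]
        if best[3] == "-":
            expected = -expected
        assert row["tss_distance"] == expected


# ---------------------------------------------------------------------------
# base-pair overlap


def test_overlap_direct_cases():
    a = regions(("chr1", 0, 100))
    b = regions(("chr1", 50, 150))
    assert basepair_overlap(a, b) == 50
    assert basepair_overlap(a, regions(("chr2", 0, 100))) == 0
    assert basepair_overlap(a, a) == a.total_bp()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_overlap_symmetric_and_self_consistent(seed):
    rng = np.random.default_rng(seed)

    def random_set():
        regs = []
        for _ in range(rng.integers(1, 20)):
            start = int(rng.integers(0, 5000))
            regs.append(GenomicRegion(f"chr{rng.integers(1, 3)}", start,
                                      start + int(rng.integers(1, 300))))
        return RegionSet(regs)

    a, b = random_set(), random_set()
    assert basepair_overlap(a, b) == basepair_overlap(b, a)
    assert basepair_overlap(a, a) == a.total_bp()
    # brute force over covered base sets
    cover = lambda s: {(c, x) for c, lo, hi in s.merged_intervals() for x in range(lo, hi)}
    assert basepair_overlap(a, b) == len(cover(a) & cover(b))
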