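"""Peak-score matrices and differential-accessibility statistics.

Builds a merged-peak x condition matrix of log2 peak scores on fixed 300-bp
bins, quantile-normalizes it, and derives per-pair Pearson correlations,
mean/differential peak scores (MPS/DPS) with accessibility classes, Poisson
differential peaks (4-fold + cumulative Poisson p < 1e-4), and the join of
differential peaks to nearest-TSS distance and expression fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GenomicRegion,
    MergedPeaks,
    RegionSet,
    TSSTable,
    merge_region_sets,
    nearest_tss,
)

__all__ = [
    "AccessibilityChange",
    "build_score_matrix",
    "quantile_normalize",
    "correlation_matrix",
    "classify_change",
    "classify_change_table",
    "differential_peaks",
    "fc_vs_tss_table",
]

# MPS accessibility-class boundaries and the major-change DPS magnitude,
# on the log2(score + 1) scale.
MPS_LOW = 3.0
MPS_HIGH = 5.0
DPS_MAJOR = 2.0


@dataclass(frozen=True)
class AccessibilityChange:
    """Per-peak accessibility summary for a pair of conditions.

    mps: mean of the two log scores; dps: their difference (A - B);
    accessibility_class: low (MPS < 3), high (MPS > 5), else moderate;
    major_change: |DPS| > 2, with direction +1/-1/0.
    """

    mps: float
    dps: float
    accessibility_class: str
    major_change: bool
    direction: int


def classify_change(score_a: float, score_b: float) -> AccessibilityChange:
    """Classify a peak's accessibility change between two conditions."""
    mps = (score_a + score_b) / 2.0
    dps = score_a - score_b
    if mps < MPS_LOW:
        klass = "low"
    elif mps > MPS_HIGH:
        klass = "high"
    else:
        klass = "moderate"
    major = abs(dps) > DPS_MAJOR
    direction = 0 if not major else (1 if dps > 0 else -1)
    return AccessibilityChange(mps, dps, klass, major, direction)


def classify_change_table(
    matrix: pd.DataFrame, condition_a: str, condition_b: str
) -> pd.DataFrame:
    """Vectorized MPS/DPS classification for every row of a score matrix."""
    a = matrix[condition_a].to_numpy(dtype=float)
    b = matrix[condition_b].to_numpy(dtype=float)
    mps = (a + b) / 2.0
    dps = a - b
    klass = np.where(mps < MPS_LOW, "low", np.where(mps > MPS_HIGH, "high", "moderate"))
    major = np.abs(dps) > DPS_MAJOR
    return pd.DataFrame(
        {
            "mps": mps,
            "dps": dps,
            "accessibility_class": klass,
            "major_change": major,
            "direction": np.where(major, np.sign(dps).astype(int), 0),
        },
        index=matrix.index,
    )


def build_score_matrix(
    sets: Sequence[RegionSet], bin_size: int = 300, merge_distance: int = 300
) -> pd.DataFrame:
    """Merged-peak x condition matrix of log2(score + 1) values.

    Peaks from all conditions are merged by center distance, each merged peak
    is recentered to a fixed ``bin_size`` window (row labels are the window
    coordinates), and each cell holds log2(raw score + 1) of the condition's
    contributing peak — 0 where the condition called no peak there. Raises if
    any input region lacks a score.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 conditions")
    for s in sets:
        for r in s:
            if r.score is None:
                raise ValueError(f"unscored region {r} in {s.condition_label!r}")
    merged = merge_region_sets(sets, max_center_distance=merge_distance)
    half = bin_size // 2
    labels = []
    for r in merged.regions:
        c = int(r.center)
        labels.append(f"{r.chrom}:{max(0, c - half)}-{max(0, c - half) + bin_size}")
    raw = merged.scores.copy()
    raw.index = labels
    return np.log2(raw.fillna(0.0) + 1.0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns: rank r in every column maps to the mean of
    the rank-r values across the original columns.

    Ties are resolved by original row order, which makes the operation
    idempotent and leaves every column with the identical sorted multiset.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in matrix")
    sorted_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        order = np.argsort(values[:, j], kind="stable")
        out[order, j] = sorted_means
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between condition columns."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    stds = matrix.std(ddof=0)
    zero_var = stds[stds == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero-variance columns: {zero_var}")
    return matrix.corr(method="pearson")


def differential_peaks(
    tags_target: Sequence[int],
    tags_background: Sequence[int],
    depth_target: float,
    depth_background: float,
    min_fold: float = 4.0,
    max_p: float = 1e-4,
    index=None,
) -> pd.DataFrame:
    """Flag peaks with depth-independent fold and Poisson significance.

    The background count is scaled to the target depth to give the null rate
    lambda; a peak is flagged when tags_target / lambda >= ``min_fold`` and
    the upper Poisson tail P(X >= tags_target | lambda) < ``max_p``. A
    background of zero receives a 0.5 pseudocount before scaling.
    """
    t = np.asarray(tags_target, dtype=float)
    b = np.asarray(tags_background, dtype=float)
    if (t < 0).any() or (b < 0).any():
        raise ValueError("tag counts must be non-negative")
    if depth_target <= 0 or depth_background <= 0:
        raise ValueError("depths must be positive")
    b_eff = np.where(b == 0, 0.5, b)
    lam = b_eff * (depth_target / depth_background)
    fold = t / lam
    # cumulative Poisson upper tail P(X >= t)
    p = stats.poisson.sf(t - 1, lam)
    flagged = (fold >= min_fold) & (p < max_p)
    return pd.DataFrame(
        {
            "tags_target": t.astype(int),
            "tags_background": b.astype(int),
            "lambda": lam,
            "fold": fold,
            "p_value": p,
            "flagged": flagged,
        },
        index=index,
    )


def fc_vs_tss_table(
    diff_peaks: RegionSet,
    tss_table: TSSTable,
    expression: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Join differential peaks to nearest gene, TSS distance and expression FC.

    One row per differential peak; the fold change is the ratio of the two
    samples' expression for the peak's nearest gene, with a pseudocount for
    robustness to zeros. Genes absent from the expression table yield a row
    flagged missing with NaN fold change.
    """
    for s in (sample_a, sample_b):
        if s not in expression.columns:
            raise KeyError(f"sample {s!r} not in expression table")
    ann = nearest_tss(diff_peaks, tss_table)
    ratios = []
    missing = []
    for gene in ann["gene_id"]:
        if gene is None or gene not in expression.index:
            ratios.append(np.nan)
            missing.append(True)
        else:
            xa = expression.at[gene, sample_a]
            xb = expression.at[gene, sample_b]
            ratios.append((xa + pseudocount) / (xb + pseudocount))
            missing.append(False)
    ann = ann.copy()
    ann["expression_fold_change"] = ratios
    ann["missing_expression"] = missing
    return ann
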