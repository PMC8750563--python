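"""Permutation-based base-pair overlap enrichment.

Tests whether a query peak set overlaps a reference set (e.g. ChIP-seq
binding sites) more than expected by chance. The null model shuffles
length-matched regions uniformly over the unmasked genome; the empirical
p-value is the fraction of permutations whose overlap reaches the observed
value, floored at 1/n_permutations. Fold enrichment is observed over the
null mean.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .intervals import GenomeModel, GenomicRegion, RegionSet, basepair_overlap

__all__ = [
    "EnrichmentResult",
    "shuffle_length_matched",
    "permutation_overlap_test",
    "fold_enrichment",
    "bonferroni",
]


@dataclass
class EnrichmentResult:
    """Outcome of one permutation overlap test."""

    observed_bp: int
    null_mean_bp: float
    null_sd_bp: float
    fold_enrichment: float
    empirical_p: float
    n_permutations: int
    adjusted_p: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fold_enrichment(observed_bp: float, null_mean_bp: float) -> float:
    """Observed over expected overlap; infinite when nothing is expected."""
    if null_mean_bp == 0:
        warnings.warn("null mean overlap is 0; fold enrichment is infinite")
        return float("inf")
    return observed_bp / null_mean_bp


def _place_uniform(
    genome: GenomeModel, lengths: np.ndarray, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Sample one (chrom, start) per length, uniform over all valid starts.

    A start is valid when the whole region fits inside a single unmasked span.
    Sampling is exact: for each region length, spans are weighted by the
    number of start positions they admit.
    """
    spans = genome.unmasked_spans()
    if not spans:
        raise ValueError("genome is fully masked")
    span_chrom = [c for c, _, _ in spans]
    span_start = np.array([s for _, s, _ in spans], dtype=np.int64)
    span_len = np.array([e - s for _, s, e in spans], dtype=np.int64)
    out: list[tuple[str, int]] = []
    for length in lengths:
        capacity = span_len - int(length) + 1
        capacity = np.maximum(capacity, 0)
        total = capacity.sum()
        if total <= 0:
            raise ValueError(
                f"no unmasked span can host a region of length {int(length)}"
            )
        # uniform over all valid starts genome-wide
        k = int(rng.integers(0, total))
        idx = int(np.searchsorted(np.cumsum(capacity), k, side="right"))
        offset = k - (np.cumsum(capacity)[idx - 1] if idx > 0 else 0)
        out.append((span_chrom[idx], int(span_start[idx] + offset)))
    return out


def shuffle_length_matched(
    query: RegionSet, genome: GenomeModel, rng: np.random.Generator
) -> RegionSet:
    """Shuffle regions genome-wide, preserving the multiset of lengths.

    Each region is re-placed independently and uniformly over every start
    position at which it fits entirely within an unmasked span, so shuffled
    regions never intersect the excluded mask. Shuffled regions may overlap
    one another.
    """
    lengths = np.array([r.length for r in query], dtype=np.int64)
    placements = _place_uniform(genome, lengths, rng)
    regions = [
        GenomicRegion(chrom, start, start + int(length))
        for (chrom, start), length in zip(placements, lengths)
    ]
    return RegionSet(regions, condition_label="shuffled")


def permutation_overlap_test(
    query: RegionSet,
    reference: RegionSet,
    genome: GenomeModel,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test for base-pair overlap enrichment (one-sided).

    The observed overlap is compared against ``n_permutations`` overlaps of
    length-matched genome-wide shuffles of the query. The empirical p-value
    is ``max(1, #{null >= observed}) / n_permutations``, so the smallest
    reportable p at 1000 permutations is 0.001.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("query and reference must be non-empty")
    rng = np.random.default_rng(seed)
    observed = basepair_overlap(query, reference)
    null = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        shuffled = shuffle_length_matched(query, genome, rng)
        null[i] = basepair_overlap(shuffled, reference)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_permutations > 1 else 0.0
    count_ge = int((null >= observed).sum())
    empirical_p = max(1, count_ge) / n_permutations
    return EnrichmentResult(
        observed_bp=int(observed),
        null_mean_bp=null_mean,
        null_sd_bp=null_sd,
        fold_enrichment=fold_enrichment(observed, null_mean),
        empirical_p=empirical_p,
        n_permutations=n_permutations,
    )


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: min(1, m * p) for m tests."""
    m = len(p_values)
    for p in p_values:
        if not 0 < p <= 1:
            raise ValueError(f"p-value {p} outside (0, 1]")
    return [min(1.0, m * p) for p in p_values]
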