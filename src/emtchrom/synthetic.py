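"""Synthetic fixtures with planted ground truth.

Every input the analysis pipeline consumes can be generated here: a genome
with an excluded mask, per-condition peak sets, nested query regions (for
overlap-enrichment testing), per-region tag counts with planted fold effects,
50-bp window sequences with planted motif occurrences, and an expression
matrix with a built-in epithelial-mesenchymal axis anchored on CDH1. All
generators are seeded and byte-deterministic, and each emits the ground-truth
labels needed to score the downstream stage it feeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomeModel, GenomicRegion, RegionSet

__all__ = [
    "SimulationConfig",
    "make_genome",
    "simulate_region_set",
    "simulate_condition_peak_sets",
    "simulate_nested_query",
    "simulate_tag_counts",
    "simulate_window_sequences",
    "simulate_expression",
    "simulate_tss_table",
    "write_fasta",
    "child_seed",
]

_BASES = np.array(list("ACGT"))

# Region lengths are drawn from a normal truncated below at this floor, so
# every simulated peak can host a 50-bp motif window.
MIN_REGION_LENGTH = 50


def child_seed(seed: int, stream: str) -> int:
    """Derive a deterministic per-generator seed below 2**31 from one master seed."""
    # hash() is salted per-process for str; use a stable digest instead
    digest = sum(ord(c) * (31**i) for i, c in enumerate(stream)) % (2**31)
    ss = np.random.SeedSequence([seed, digest])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SimulationConfig:
    """Bundle of generator parameters for a full fixture.

    Defaults describe a desk-scale genome: two chromosomes totalling 15 Mb
    with 5% masked, a few hundred peaks per condition, sequencing depths deep
    enough that an 8-fold accessibility effect is unambiguous, a 17% motif
    plant rate, and a four-timepoint EMT axis.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 5_000_000}
    )
    excluded_fraction: float = 0.05
    n_regions: int = 400
    region_length_mean: float = 500.0
    region_length_sd: float = 120.0
    seed: int = 0
    depth_target: float = 2e4
    depth_background: float = 2e4
    fold_effects: Optional[Sequence[float]] = None
    motif_plant_rate: float = 0.17
    emt_axis: Sequence[float] = (0.0, 0.33, 1.0, 0.2)
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must not be empty")
        if any(v <= 0 for v in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be positive")
        if not 0 <= self.excluded_fraction < 1:
            raise ValueError("excluded_fraction must be in [0, 1)")
        if not 0 <= self.motif_plant_rate <= 1:
            raise ValueError("motif_plant_rate must be in [0, 1]")
        if any(not 0 <= a <= 1 for a in self.emt_axis):
            raise ValueError("emt_axis positions must be in [0, 1]")
        if self.region_length_mean <= 0:
            raise ValueError("region_length_mean must be positive")


# ---------------------------------------------------------------------------
# Genome and region placement


def make_genome(
    chrom_sizes: Mapping[str, int],
    excluded_fraction: float = 0.0,
    seed: int = 0,
    block_length: int = 50_000,
) -> GenomeModel:
    """Build a genome model with a random disjoint excluded mask.

    Per chromosome, non-overlapping blocks of ~``block_length`` bp are placed
    until the target excluded fraction is reached exactly (the final block is
    trimmed), emulating a blacklist/assembly-gap/centromere mask.
    """
    if not chrom_sizes:
        raise ValueError("chrom_sizes must not be empty")
    if not 0 <= excluded_fraction < 1:
        raise ValueError("excluded_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    excluded = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        target = int(round(excluded_fraction * size))
        if target == 0:
            continue
        blk = min(block_length, max(1, target))
        placed: list[tuple[int, int]] = []
        total = 0
        attempts = 0
        while total < target:
            attempts += 1
            if attempts > 100_000:
                raise RuntimeError(f"could not place mask blocks on {chrom}")
            length = min(blk, target - total)
            start = int(rng.integers(0, size - length + 1))
            end = start + length
            if any(start < e and s < end for s, e in placed):
                continue
            placed.append((start, end))
            total += length
        excluded.extend(
            GenomicRegion(chrom, s, e, name="excluded") for s, e in sorted(placed)
        )
    return GenomeModel(dict(chrom_sizes), RegionSet(excluded, "excluded"))


def _draw_lengths(rng, n: int, mean: float, sd: float) -> np.ndarray:
    lengths = rng.normal(mean, sd, size=n)
    return np.maximum(np.round(lengths), MIN_REGION_LENGTH).astype(int)


def simulate_region_set(
    genome: GenomeModel,
    n_regions: int,
    length_mean: float = 500.0,
    length_sd: float = 120.0,
    seed: int = 0,
    condition_label: str = "",
    max_attempts_per_region: int = 10_000,
) -> RegionSet:
    """Place ``n_regions`` mask-free, mutually non-overlapping regions.

    Lengths are truncated-normal (floor 50 bp); chromosomes are chosen in
    proportion to size; placement is rejection sampling against the excluded
    mask and already-placed regions.
    """
    if n_regions < 0:
        raise ValueError("n_regions must be >= 0")
    if length_mean <= 0:
        raise ValueError("length_mean must be positive")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    masked = {c: [] for c in chroms}
    for chrom, s, e in genome.excluded.merged_intervals():
        masked[chrom].append((s, e))
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    lengths = _draw_lengths(rng, n_regions, length_mean, length_sd)
    regions = []
    for i in range(n_regions):
        length = int(lengths[i])
        for attempt in range(max_attempts_per_region):
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            size = genome.chrom_sizes[chrom]
            if size < length:
                continue
            start = int(rng.integers(0, size - length + 1))
            end = start + length
            blocked = masked[chrom] + placed[chrom]
            if any(start < e and s < end for s, e in blocked):
                continue
            placed[chrom].append((start, end))
            regions.append(GenomicRegion(chrom, start, end, name=f"region{i:05d}"))
            break
        else:
            raise RuntimeError(
                f"failed to place region {i} of length {length} after "
                f"{max_attempts_per_region} attempts; genome too small or masked"
            )
    return RegionSet(regions, condition_label=condition_label)


def simulate_condition_peak_sets(
    genome: GenomeModel,
    conditions: Sequence[str],
    n_shared: int,
    n_unique: int,
    length_mean: float = 500.0,
    length_sd: float = 120.0,
    score_log_mean: float = 4.0,
    score_log_sd: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, RegionSet], pd.DataFrame]:
    """Multi-condition peak sets with controlled sharing and uniqueness.

    ``n_shared`` peaks appear in every condition (with condition-specific
    lognormal scores); each condition additionally receives ``n_unique``
    private peaks. Returns the per-condition sets plus a ground-truth table
    of peak name -> membership.
    """
    total = n_shared + n_unique * len(conditions)
    master = simulate_region_set(
        genome, total, length_mean, length_sd, seed=child_seed(seed, "peaks")
    )
    rng = np.random.default_rng(child_seed(seed, "peak_scores"))
    sets: dict[str, RegionSet] = {}
    truth_rows = []
    shared = master.regions[:n_shared]
    uniques = [
        master.regions[n_shared + i * n_unique : n_shared + (i + 1) * n_unique]
        for i in range(len(conditions))
    ]
    for r in shared:
        truth_rows.append({"name": r.name, "membership": ",".join(conditions)})
    for cond, regs in zip(conditions, uniques):
        for r in regs:
            truth_rows.append({"name": r.name, "membership": cond})
    for i, cond in enumerate(conditions):
        regs = []
        for r in shared + uniques[i]:
            score = float(rng.lognormal(score_log_mean, score_log_sd))
            regs.append(GenomicRegion(r.chrom, r.start, r.end, score=score, name=r.name))
        sets[cond] = RegionSet(regs, condition_label=cond)
    return sets, pd.DataFrame(truth_rows)


def simulate_nested_query(
    genome: GenomeModel,
    reference: RegionSet,
    n: int,
    query_length: int = 200,
    inside_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[RegionSet, pd.DataFrame]:
    """Query regions planted inside a reference set at a known rate.

    Exactly ``round(inside_fraction * n)`` queries are placed wholly inside
    randomly chosen reference regions (long enough to contain them); the rest
    are placed uniformly in the unmasked genome. Returns the query set and a
    ground-truth table flagging which queries were planted.
    """
    if len(reference) == 0:
        raise ValueError("reference must be non-empty")
    if not 0 <= inside_fraction <= 1:
        raise ValueError("inside_fraction must be in [0, 1]")
    hosts = [r for r in reference if r.length >= query_length]
    n_inside = int(round(inside_fraction * n))
    if n_inside > 0 and not hosts:
        raise ValueError("no reference region can contain a query of this length")
    rng = np.random.default_rng(seed)
    regions = []
    truth = []
    for i in range(n_inside):
        host = hosts[int(rng.integers(0, len(hosts)))]
        start = int(rng.integers(host.start, host.end - query_length + 1))
        regions.append(
            GenomicRegion(host.chrom, start, start + query_length, name=f"query{i:04d}")
        )
        truth.append({"name": f"query{i:04d}", "planted_inside": True})
    if n - n_inside > 0:
        from .enrichment import _place_uniform  # shared placement machinery

        outs = _place_uniform(
            genome, np.full(n - n_inside, query_length, dtype=int), rng
        )
        for j, (chrom, start) in enumerate(outs):
            name = f"query{n_inside + j:04d}"
            regions.append(
                GenomicRegion(chrom, int(start), int(start) + query_length, name=name)
            )
            truth.append({"name": name, "planted_inside": False})
    return RegionSet(regions, "query"), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Tag counts


def simulate_tag_counts(
    regions: RegionSet,
    depth_target: float,
    depth_background: float,
    fold_effects: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson tag counts per region for a target and a background condition.

    The per-region background rate is proportional to region length and sums
    to ``depth_background``; the target rate multiplies it by the region's
    fold effect and by ``depth_target / depth_background``, so the expected
    depth-normalized ratio equals the planted fold effect.
    """
    if depth_target <= 0 or depth_background <= 0:
        raise ValueError("depths must be positive")
    n = len(regions)
    if fold_effects is None:
        fold_effects = np.ones(n)
    fold_effects = np.asarray(fold_effects, dtype=float)
    if len(fold_effects) != n:
        raise ValueError("one fold effect per region required")
    if (fold_effects < 0).any():
        raise ValueError("fold effects must be non-negative")
    lengths = np.array([r.length for r in regions], dtype=float)
    rng = np.random.default_rng(seed)
    bg_rate = depth_background * lengths / lengths.sum()
    tg_rate = fold_effects * bg_rate * (depth_target / depth_background)
    return pd.DataFrame(
        {
            "name": [r.name or str(r) for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "tags_target": rng.poisson(tg_rate),
            "tags_background": rng.poisson(bg_rate),
            "fold_effect": fold_effects,
        }
    )


# ---------------------------------------------------------------------------
# Motif window sequences


def simulate_window_sequences(
    n_windows: int,
    window_size: int,
    pwm,
    plant_rate: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Fixed-width DNA windows with the PWM consensus planted at a known rate.

    Exactly ``round(plant_rate * n_windows)`` windows carry the consensus at a
    random offset on a random strand; the remainder are i.i.d. uniform DNA.
    Returns a table of (name, sequence, planted).
    """
    if not 0 <= plant_rate <= 1:
        raise ValueError("plant_rate must be in [0, 1]")
    consensus = pwm.consensus
    if window_size < len(consensus):
        raise ValueError("window_size must be >= motif length")
    rng = np.random.default_rng(seed)
    n_plant = int(round(plant_rate * n_windows))
    seqs = []
    planted_flags = []
    for i in range(n_windows):
        seq = list(_BASES[rng.integers(0, 4, size=window_size)])
        planted = i < n_plant
        if planted:
            motif = consensus
            if rng.integers(0, 2) == 1:
                motif = str(Seq(consensus).reverse_complement())
            offset = int(rng.integers(0, window_size - len(motif) + 1))
            seq[offset : offset + len(motif)] = list(motif)
        seqs.append("".join(seq))
        planted_flags.append(planted)
    return pd.DataFrame(
        {
            "name": [f"window{i:05d}" for i in range(n_windows)],
            "sequence": seqs,
            "planted": planted_flags,
        }
    )


def write_fasta(windows: pd.DataFrame, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(windows["name"], windows["sequence"])
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> pd.DataFrame:
    recs = list(SeqIO.parse(str(path), "fasta"))
    return pd.DataFrame(
        {"name": [r.id for r in recs], "sequence": [str(r.seq).upper() for r in recs]}
    )


# ---------------------------------------------------------------------------
# TSS table


def simulate_tss_table(genome: GenomeModel, n_genes: int, seed: int = 0):
    """Random gene TSS positions uniform over chromosomes (by size)."""
    from .intervals import TSSTable

    rng = np.random.default_rng(seed)
    chroms = sorted(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    rows = []
    for i in range(n_genes):
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        pos = int(rng.integers(0, genome.chrom_sizes[chrom]))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        rows.append({"gene_id": f"GENE{i:04d}", "chrom": chrom, "tss": pos, "strand": strand})
    return TSSTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Expression with a planted EMT axis


def simulate_expression(
    signature,
    emt_axis: Sequence[float],
    n_extra_genes: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 10.0,
    amplitude: float = 5.0,
) -> pd.DataFrame:
    """Expression matrix whose samples sit at known epithelial-mesenchymal positions.

    Signature genes with epithelial direction (+1, like the CDH1 anchor)
    decrease linearly from ``baseline + amplitude`` at axis 0 (epithelial) to
    ``baseline - amplitude`` at axis 1 (mesenchymal); mesenchymal-direction
    genes (-1) do the opposite. Extra genes carry no axis signal. Gaussian
    noise is added and the matrix floored at a small positive epsilon.
    """
    axis = np.asarray(emt_axis, dtype=float)
    if len(axis) < 3:
        raise ValueError("at least 3 samples required (correlation weights undefined)")
    if (axis < 0).any() or (axis > 1).any():
        raise ValueError("emt_axis positions must lie in [0, 1]")
    if signature.anchor_gene not in signature.genes:
        raise ValueError("signature must include its anchor gene")
    rng = np.random.default_rng(seed)
    samples = [f"sample{j:02d}" for j in range(len(axis))]
    rows = {}
    directions = signature.directions
    for gene in signature.genes:
        d = directions[gene]
        rows[gene] = baseline + amplitude * d * (1.0 - 2.0 * axis)
    for k in range(n_extra_genes):
        rows[f"NOISE{k:04d}"] = np.full(len(axis), baseline)
    df = pd.DataFrame(rows).T
    df.columns = samples
    if noise_sd > 0:
        df = df + rng.normal(0.0, noise_sd, size=df.shape)
    return df.clip(lower=0.01)
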