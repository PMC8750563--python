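"""Genomic-interval data model and peak-set operations.

Coordinates are 0-based, half-open (BED convention) throughout. The central
objects are :class:`GenomicRegion` (a single peak with an optional
accessibility score) and :class:`RegionSet` (a sorted per-condition peak set).
Peak merging follows the center-distance transitive-closure semantics of
HOMER's ``mergePeaks -d``: peaks whose centers lie within the given distance
are unified, and the unification is closed transitively so chains of nearby
peaks collapse into one region spanning their union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion",
    "RegionSet",
    "GenomeModel",
    "TSSTable",
    "MergedPeaks",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "merge_region_sets",
    "gap_lengths",
    "median_gap",
    "count_peak_deserts",
    "nearest_tss",
    "basepair_overlap",
]


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval with an optional score and name."""

    chrom: str
    start: int
    end: int
    score: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"negative score {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"


class RegionSet:
    """An ordered collection of regions, sorted by (chrom, start).

    Parameters
    ----------
    regions:
        Any iterable of :class:`GenomicRegion`; sorted on construction.
    condition_label:
        Free-text label, typically a treatment timepoint (e.g. ``"2d_tgfb"``).
    """

    def __init__(
        self,
        regions: Iterable[GenomicRegion] = (),
        condition_label: str = "",
    ) -> None:
        self.regions: list[GenomicRegion] = sorted(
            regions, key=lambda r: (r.chrom, r.start, r.end)
        )
        self.condition_label = condition_label

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> GenomicRegion:
        return self.regions[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.regions == other.regions

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegionSet({len(self)} regions, label={self.condition_label!r})"

    @property
    def chroms(self) -> list[str]:
        return sorted({r.chrom for r in self.regions})

    def by_chrom(self) -> dict[str, list[GenomicRegion]]:
        out: dict[str, list[GenomicRegion]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out

    def total_bp(self) -> int:
        """Total covered base pairs after collapsing internal overlaps."""
        return sum(e - s for _, s, e in self.merged_intervals())

    def merged_intervals(self) -> list[tuple[str, int, int]]:
        """Overlap-collapsed (chrom, start, end) triples, sorted."""
        out: list[tuple[str, int, int]] = []
        for chrom, regs in self.by_chrom().items():
            cur_s, cur_e = regs[0].start, regs[0].end
            for r in regs[1:]:
                if r.start <= cur_e:
                    cur_e = max(cur_e, r.end)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = r.start, r.end
            out.append((chrom, cur_s, cur_e))
        return sorted(out)

    def is_disjoint(self) -> bool:
        for regs in self.by_chrom().values():
            for a, b in zip(regs, regs[1:]):
                if b.start < a.end:
                    return False
        return True

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "name": [r.name for r in self.regions],
                "score": [r.score for r in self.regions],
            }
        )


@dataclass
class GenomeModel:
    """Chromosome sizes plus an excluded-region mask.

    The mask holds ENCODE-blacklist-style regions (artifact signal, assembly
    gaps, centromeres) that are removed from desert statistics and from the
    sampling space of every shuffle and simulation.
    """

    chrom_sizes: dict[str, int]
    excluded: RegionSet = field(default_factory=RegionSet)

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must contain at least one chromosome")
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {name} has non-positive size {size}")
        for r in self.excluded:
            if r.chrom not in self.chrom_sizes:
                raise ValueError(f"excluded region on unknown chromosome {r.chrom}")
            if r.end > self.chrom_sizes[r.chrom]:
                raise ValueError(f"excluded region {r} exceeds chromosome bounds")

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_sizes.values())

    def unmasked_spans(self) -> list[tuple[str, int, int]]:
        """Maximal (chrom, start, end) spans not covered by the mask."""
        masked = {c: [] for c in self.chrom_sizes}
        for chrom, s, e in self.excluded.merged_intervals():
            masked[chrom].append((s, e))
        spans: list[tuple[str, int, int]] = []
        for chrom, size in self.chrom_sizes.items():
            pos = 0
            for s, e in masked[chrom]:
                if s > pos:
                    spans.append((chrom, pos, s))
                pos = max(pos, e)
            if pos < size:
                spans.append((chrom, pos, size))
        return spans


class TSSTable:
    """Gene transcription start sites: (gene_id, chrom, tss position, strand)."""

    def __init__(self, df: pd.DataFrame) -> None:
        required = {"gene_id", "chrom", "tss", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"TSS table missing columns: {sorted(missing)}")
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in TSS table")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TSSTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED and chrom.sizes I/O


def read_bed(
    path: str | Path,
    genome: Optional[GenomeModel] = None,
    condition_label: str = "",
) -> RegionSet:
    """Read a BED3/BED5/BED6 file into a sorted :class:`RegionSet`.

    Column order is the BED standard: chrom, start, end[, name, score,
    strand]. Raises on non-integer coordinates, start >= end, and (when a
    genome is supplied) unknown chromosomes or out-of-bounds coordinates.
    """
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            if genome is not None:
                if chrom not in genome.chrom_sizes:
                    raise ValueError(f"{path}:{ln}: unknown chromosome {chrom}")
                if end > genome.chrom_sizes[chrom]:
                    raise ValueError(f"{path}:{ln}: region exceeds {chrom} bounds")
            try:
                regions.append(GenomicRegion(chrom, start, end, score=score, name=name))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return RegionSet(regions, condition_label=condition_label)


def write_bed(rs: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED (name/score columns only when present)."""
    with open(path, "w") as fh:
        for r in rs:
            fields = [r.chrom, str(r.start), str(r.end)]
            if r.name is not None or r.score is not None:
                fields.append(r.name if r.name is not None else ".")
            if r.score is not None:
                fields.append(f"{r.score:g}")
            fh.write("\t".join(fields) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    if not sizes:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


# ---------------------------------------------------------------------------
# Peak merging (HOMER mergePeaks -d semantics)


class MergedPeaks:
    """Result of a cross-set merge: regions plus per-set membership flags.

    ``membership`` is a boolean DataFrame (one row per merged region, one
    column per input condition label); ``scores`` holds, per condition, the
    maximum raw score among that condition's contributing peaks (NaN where the
    condition contributed none). Membership flags drive condition-sharing
    (Venn) counts.
    """

    def __init__(
        self, regions: RegionSet, membership: pd.DataFrame, scores: pd.DataFrame
    ) -> None:
        self.regions = regions
        self.membership = membership
        self.scores = scores

    def __len__(self) -> int:
        return len(self.regions)

    def membership_counts(self) -> dict[frozenset, int]:
        """Counts of merged regions per combination of contributing sets."""
        counts: dict[frozenset, int] = {}
        labels = list(self.membership.columns)
        for _, row in self.membership.iterrows():
            key = frozenset(l for l in labels if row[l])
            counts[key] = counts.get(key, 0) + 1
        return counts


def merge_region_sets(
    sets: Sequence[RegionSet], max_center_distance: int = 300
) -> MergedPeaks:
    """Merge peak sets by center distance with transitive closure.

    Peaks (from any input set) whose centers are within ``max_center_distance``
    of each other are unified; closure is transitive, so a chain of nearby
    peaks becomes one merged region spanning the union of its members. Because
    centers on one chromosome are totally ordered, linking consecutive
    center-sorted peaks is exact transitive closure.
    """
    if max_center_distance < 0:
        raise ValueError("max_center_distance must be non-negative")
    labels = []
    for i, s in enumerate(sets):
        label = s.condition_label or f"set{i}"
        if label in labels:
            raise ValueError(f"duplicate condition label {label!r}")
        labels.append(label)

    pooled: list[tuple[str, float, GenomicRegion, str]] = []
    for s, label in zip(sets, labels):
        for r in s:
            pooled.append((r.chrom, r.center, r, label))
    pooled.sort(key=lambda t: (t[0], t[1], t[2].start))

    out_regions: list[GenomicRegion] = []
    out_members: list[dict[str, bool]] = []
    out_scores: list[dict[str, float]] = []

    def flush(component: list[tuple[GenomicRegion, str]]) -> None:
        chrom = component[0][0].chrom
        start = min(r.start for r, _ in component)
        end = max(r.end for r, _ in component)
        members = {l: False for l in labels}
        scores: dict[str, float] = {l: np.nan for l in labels}
        for r, label in component:
            members[label] = True
            if r.score is not None:
                prev = scores[label]
                scores[label] = r.score if np.isnan(prev) else max(prev, r.score)
        out_regions.append(GenomicRegion(chrom, start, end))
        out_members.append(members)
        out_scores.append(scores)

    component: list[tuple[GenomicRegion, str]] = []
    prev_chrom, prev_center = None, None
    for chrom, center, r, label in pooled:
        if component and (
            chrom != prev_chrom or center - prev_center > max_center_distance
        ):
            flush(component)
            component = []
        component.append((r, label))
        prev_chrom, prev_center = chrom, center
    if component:
        flush(component)

    idx = sorted(range(len(out_regions)), key=lambda i: (out_regions[i].chrom, out_regions[i].start))
    regions = RegionSet([out_regions[i] for i in idx], condition_label="merged")
    names = [f"{r.chrom}:{r.start}-{r.end}" for r in regions]
    membership = pd.DataFrame([out_members[i] for i in idx], index=names)
    scores = pd.DataFrame([out_scores[i] for i in idx], index=names)
    return MergedPeaks(regions, membership, scores)


# ---------------------------------------------------------------------------
# Gap / desert statistics


def gap_lengths(rs: RegionSet) -> dict[str, list[int]]:
    """Inter-peak gap lengths per chromosome.

    A gap is ``next.start - previous.end`` for consecutive same-chromosome
    peaks of a merged (non-overlapping) set; distances to chromosome ends are
    not counted. Raises if the set contains overlapping regions.
    """
    if not rs.is_disjoint():
        raise ValueError("gap_lengths requires a merged (non-overlapping) set")
    gaps: dict[str, list[int]] = {}
    for chrom, regs in rs.by_chrom().items():
        gaps[chrom] = [b.start - a.end for a, b in zip(regs, regs[1:])]
    return gaps


def median_gap(rs: RegionSet) -> float:
    """Median inter-peak gap over all chromosomes (NaN if no gaps)."""
    all_gaps = [g for gs in gap_lengths(rs).values() for g in gs]
    return float(np.median(all_gaps)) if all_gaps else float("nan")


def _overlap_bp_with_intervals(
    start: int, end: int, intervals: Sequence[tuple[int, int]]
) -> int:
    total = 0
    for s, e in intervals:
        total += max(0, min(end, e) - max(start, s))
    return total


def count_peak_deserts(
    rs: RegionSet, genome: GenomeModel, min_gap: int = 1_000_000
) -> int:
    """Count inter-peak gaps whose masked-corrected length exceeds ``min_gap``.

    The effective gap length is the raw gap minus the base pairs it shares
    with the genome's excluded mask (blacklist, assembly gaps, centromeres),
    so deserts spanning unmappable sequence are not over-counted.
    """
    excluded_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in genome.excluded.merged_intervals():
        excluded_by_chrom.setdefault(chrom, []).append((s, e))
    n = 0
    for chrom, regs in rs.by_chrom().items():
        if chrom not in genome.chrom_sizes:
            raise ValueError(f"region chromosome {chrom} absent from genome")
        excl = excluded_by_chrom.get(chrom, [])
        for a, b in zip(regs, regs[1:]):
            if b.start < a.end:
                raise ValueError("count_peak_deserts requires a merged set")
            gap = b.start - a.end
            effective = gap - _overlap_bp_with_intervals(a.end, b.start, excl)
            if effective > min_gap:
                n += 1
    return n


# ---------------------------------------------------------------------------
# TSS annotation


def nearest_tss(rs: RegionSet, tss_table: TSSTable) -> pd.DataFrame:
    """Annotate each region with its nearest TSS and signed distance.

    Distance is peak center minus TSS position, with the sign flipped for
    minus-strand genes so positive always means downstream of the TSS.
    Nearest is by absolute distance among same-chromosome TSSs; ties break to
    the lexicographically smallest gene_id. Regions on chromosomes with no
    TSS get gene_id None and NaN distance.
    """
    if len(tss_table) == 0:
        raise ValueError("empty TSS table")
    by_chrom: dict[str, pd.DataFrame] = {
        chrom: sub.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for chrom, sub in tss_table.df.groupby("chrom")
    }
    rows = []
    for r in rs:
        sub = by_chrom.get(r.chrom)
        if sub is None:
            rows.append((str(r), None, np.nan))
            continue
        center = r.center
        absdist = (sub["tss"] - center).abs()
        best = absdist.min()
        cands = sub[absdist == best]
        # ties: smallest gene_id
        hit = cands.sort_values("gene_id").iloc[0]
        dist = center - hit["tss"]
        if hit["strand"] == "-":
            dist = -dist
        rows.append((str(r), hit["gene_id"], float(dist)))
    return pd.DataFrame(rows, columns=["region", "gene_id", "tss_distance"])


# ---------------------------------------------------------------------------
# Base-pair overlap


def basepair_overlap(a: RegionSet, b: RegionSet) -> int:
    """Total intersection length in bp between two region sets (symmetric).

    Internal overlaps within each set are collapsed first, so the result is
    the measure of the set intersection of covered bases.
    """
    a_iv = a.merged_intervals()
    b_iv = b.merged_intervals()
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in b_iv:
        by_chrom_b.setdefault(chrom, []).append((s, e))
    total = 0
    for chrom in {c for c, _, _ in a_iv} & set(by_chrom_b):
        xs = [(s, e) for c, s, e in a_iv if c == chrom]
        ys = by_chrom_b[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i][0], ys[j][0])
            e = min(xs[i][1], ys[j][1])
            if e > s:
                total += e - s
            if xs[i][1] < ys[j][1]:
                i += 1
            else:
                j += 1
    return total
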