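"""Known-motif scanning and enrichment on fixed 50-bp peak windows.

A PWM is scored by log2 odds against a background base composition; a window
is a hit when the best score over all offsets and both strands reaches the
PWM's detection threshold (default 80% of the maximum achievable score).
Enrichment of target vs background window hit counts uses the cumulative
hypergeometric tail; motifs with p above 1e-12 are conventionally discarded
from reported sets. Percentage-change dynamics compare each condition's
target percentage to an untreated control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeModel, GenomicRegion, RegionSet

__all__ = [
    "PWM",
    "MotifEnrichment",
    "extract_windows",
    "scan_window",
    "motif_target_percentage",
    "motif_enrichment_test",
    "percentage_change",
    "motif_enrichment_table",
    "MOTIF_P_CUTOFF",
]

MOTIF_P_CUTOFF = 1e-12
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PSEUDOCOUNT = 0.001


@dataclass
class PWM:
    """Position weight matrix with background model and detection threshold.

    ``matrix`` is 4 x L (rows A, C, G, T; columns sum to 1 before the
    pseudocount). ``log_odds_threshold`` defaults to 80% of the maximum
    achievable log2-odds score.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    log_odds_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A, C, G, T)")
        if self.matrix.shape[1] < 4:
            raise ValueError("PWM must be at least 4 columns long")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        if (self.matrix < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        probs = self.matrix + _PSEUDOCOUNT
        probs /= probs.sum(axis=0, keepdims=True)
        self._log_odds = np.log2(probs / self.background[:, None])
        if self.log_odds_threshold is None:
            self.log_odds_threshold = 0.8 * self.max_score

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self._log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        bases = "ACGT"
        return "".join(bases[i] for i in self.matrix.argmax(axis=0))

    @classmethod
    def from_consensus(
        cls, name: str, consensus: str, certainty: float = 0.97, **kwargs
    ) -> "PWM":
        """A near-deterministic PWM around a consensus string."""
        consensus = consensus.upper()
        L = len(consensus)
        m = np.full((4, L), (1 - certainty) / 3)
        for j, base in enumerate(consensus):
            if base not in _BASE_INDEX:
                raise ValueError(f"invalid consensus base {base!r}")
            m[_BASE_INDEX[base], j] = certainty
        return cls(name, m, **kwargs)

    @classmethod
    def from_jaspar(cls, path: str | Path, **kwargs) -> list["PWM"]:
        """Read JASPAR-style plain-text matrices (counts or probabilities).

        Format: a ``>name`` header followed by four lines ``A [ 1 2 ... ]``
        (brackets optional), in A/C/G/T order.
        """
        pwms = []
        name = None
        rows: list[list[float]] = []
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        for ln in lines:
            if ln.startswith(">"):
                if name is not None:
                    pwms.append(cls._finish_jaspar(name, rows, **kwargs))
                name = ln[1:].split()[0]
                rows = []
            else:
                body = ln
                if body[0] in "ACGT" and not body[0].isdigit():
                    body = body[1:]
                body = body.replace("[", " ").replace("]", " ")
                rows.append([float(x) for x in body.split()])
        if name is not None:
            pwms.append(cls._finish_jaspar(name, rows, **kwargs))
        if not pwms:
            raise ValueError(f"{path}: no PWM records found")
        return pwms

    @classmethod
    def _finish_jaspar(cls, name: str, rows: list[list[float]], **kwargs) -> "PWM":
        if len(rows) != 4:
            raise ValueError(f"PWM {name}: expected 4 base rows, got {len(rows)}")
        m = np.asarray(rows, dtype=float)
        m = m / m.sum(axis=0, keepdims=True)
        return cls(name, m, **kwargs)


@dataclass
class MotifEnrichment:
    """Per-motif enrichment summary mirroring known-motif report columns."""

    motif: str
    target_pct: float
    background_pct: float
    p_value: float
    percentage_change: Optional[float] = None


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp.get(b, "N") for b in reversed(seq))


def _best_score_one_strand(pwm: PWM, seq: str) -> float:
    L = pwm.length
    lo = pwm._log_odds
    best = -math.inf
    for off in range(len(seq) - L + 1):
        s = 0.0
        for j in range(L):
            idx = _BASE_INDEX.get(seq[off + j])
            if idx is not None:
                s += lo[idx, j]
            # N / masked lowercase bases contribute 0 (background odds)
        best = max(best, s)
    return best


def scan_window(pwm: PWM, sequence: str) -> tuple[bool, float]:
    """Best log2-odds score over all offsets and both strands, and hit call.

    Masked (lowercase) and N positions score as background (contribution 0).
    """
    if not sequence:
        raise ValueError("empty sequence")
    # lowercase input means repeat-masked: treat as N (background)
    seq = "".join(
        up if (orig.isupper() and up in "ACGT") else "N"
        for orig, up in zip(sequence, sequence.upper())
    )
    if len(seq) < pwm.length:
        raise ValueError("sequence shorter than motif")
    best = max(
        _best_score_one_strand(pwm, seq),
        _best_score_one_strand(pwm, _revcomp(seq)),
    )
    return best >= pwm.log_odds_threshold, best


def extract_windows(
    rs: RegionSet, size: int = 50, genome: Optional[GenomeModel] = None
) -> RegionSet:
    """Fixed-width windows centered on peak centers.

    The window for a peak is ``[c - size//2, c - size//2 + size)`` with
    ``c = (start + end) // 2`` (ties shift left). Windows extending past
    chromosome bounds, or intersecting the excluded mask when a genome is
    supplied, are dropped.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    half = size // 2
    masked: dict[str, list[tuple[int, int]]] = {}
    if genome is not None:
        for chrom, s, e in genome.excluded.merged_intervals():
            masked.setdefault(chrom, []).append((s, e))
    out = []
    n_dropped = 0
    for r in rs:
        c = (r.start + r.end) // 2
        start = c - half
        end = start + size
        if start < 0:
            n_dropped += 1
            continue
        if genome is not None:
            if r.chrom in genome.chrom_sizes and end > genome.chrom_sizes[r.chrom]:
                n_dropped += 1
                continue
            if any(start < e2 and s2 < end for s2, e2 in masked.get(r.chrom, [])):
                n_dropped += 1
                continue
        out.append(GenomicRegion(r.chrom, start, end, name=r.name))
    result = RegionSet(out, condition_label=rs.condition_label)
    result.n_dropped = n_dropped  # type: ignore[attr-defined]
    return result


def motif_target_percentage(sequences: Sequence[str], pwm: PWM) -> float:
    """Percentage of windows containing at least one motif hit."""
    if len(sequences) == 0:
        raise ValueError("no windows supplied")
    hits = sum(1 for s in sequences if scan_window(pwm, s)[0])
    return 100.0 * hits / len(sequences)


def motif_enrichment_test(
    target_hits: int, target_total: int, background_hits: int, background_total: int
) -> float:
    """Cumulative hypergeometric p for target vs background hit counts.

    Population = all windows, successes = all hit windows, draws = target
    windows; p = P(X >= target_hits).
    """
    for v in (target_hits, target_total, background_hits, background_total):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if target_hits > target_total or background_hits > background_total:
        raise ValueError("hits cannot exceed totals")
    M = target_total + background_total
    K = target_hits + background_hits
    return float(stats.hypergeom.sf(target_hits - 1, M, K, target_total))


def percentage_change(condition_pct: float, control_pct: float) -> float:
    """Signed percentage-point difference vs the untreated control."""
    for v in (condition_pct, control_pct):
        if not 0 <= v <= 100:
            raise ValueError("percentages must lie in [0, 100]")
    return condition_pct - control_pct


def motif_enrichment_table(
    target_seqs: Sequence[str],
    background_seqs: Sequence[str],
    pwms: Sequence[PWM],
    control_pcts: Optional[dict[str, float]] = None,
    p_cutoff: float = MOTIF_P_CUTOFF,
) -> pd.DataFrame:
    """Score a panel of motifs and filter by the significance cutoff.

    Returns one row per motif with target/background percentages, the
    hypergeometric p, the percentage change vs a control percentage when
    supplied, and a ``reported`` flag (p <= cutoff).
    """
    rows = []
    nt, nb = len(target_seqs), len(background_seqs)
    for pwm in pwms:
        th = sum(1 for s in target_seqs if scan_window(pwm, s)[0])
        bh = sum(1 for s in background_seqs if scan_window(pwm, s)[0])
        p = motif_enrichment_test(th, nt, bh, nb)
        tp = 100.0 * th / nt
        bp = 100.0 * bh / nb
        change = (
            percentage_change(tp, control_pcts[pwm.name])
            if control_pcts and pwm.name in control_pcts
            else np.nan
        )
        rows.append(
            {
                "motif": pwm.name,
                "target_pct": tp,
                "background_pct": bp,
                "p_value": p,
                "percentage_change": change,
                "reported": p <= p_cutoff,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
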