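"""Transcriptomic EMT-state scoring.

The 76-gene EMT score (76GS) is a weighted sum of signature-gene expression
where each gene's weight is its Pearson correlation with CDH1 (the anchor)
across samples; scores are mean-centered so the cohort average is zero.
Positive scores read as epithelial, negative as mesenchymal. The module also
provides EMT-Up/EMT-Down signature z-score summaries, simple expression fold
changes, and the hypergeometric gene-set overlap test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EMTSignature",
    "EMTScoreResult",
    "make_default_signature",
    "gs76_score",
    "signature_summary",
    "expression_fold_change",
    "hypergeometric_overlap",
    "read_expression",
    "write_expression",
]


@dataclass
class EMTSignature:
    """A CDH1-anchored EMT gene signature.

    ``genes`` nominally holds 76 genes including the anchor. ``directions``
    (+1 epithelial-like, -1 mesenchymal-like) are ground-truth simulation
    directions only; scoring weights are always recomputed from the data as
    correlations with the anchor.
    """

    genes: list[str]
    anchor_gene: str = "CDH1"
    directions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.anchor_gene not in self.genes:
            raise ValueError("anchor gene must be part of the signature")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        if not self.directions:
            # default: half epithelial-like, half mesenchymal-like
            self.directions = {
                g: (1 if i % 2 == 0 else -1) for i, g in enumerate(self.genes)
            }
        self.directions[self.anchor_gene] = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "EMTSignature":
        """Plain gene-list text; a line ``#anchor <gene>`` sets the anchor."""
        genes = []
        anchor = "CDH1"
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#anchor"):
                    anchor = line.split()[1]
                elif not line.startswith("#"):
                    genes.append(line)
        return cls(genes, anchor_gene=anchor, directions={})

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#anchor {self.anchor_gene}\n")
            for g in self.genes:
                fh.write(g + "\n")


def make_default_signature(n_genes: int = 76) -> EMTSignature:
    """A synthetic 76-gene signature (CDH1 anchor plus placeholder genes).

    The published gene list is configuration data; this stand-in exists so
    simulation and tests run without external gene lists.
    """
    genes = ["CDH1"] + [f"SIG{i:03d}" for i in range(1, n_genes)]
    return EMTSignature(genes, anchor_gene="CDH1")


@dataclass
class EMTScoreResult:
    """Per-sample EMT scores with phenotype calls."""

    scores: pd.Series
    weights: pd.Series
    coverage: float  # fraction of signature genes found in the matrix

    @property
    def calls(self) -> pd.Series:
        return pd.Series(
            np.where(self.scores >= 0, "epithelial", "mesenchymal"),
            index=self.scores.index,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "call": self.calls})


def _check_expression(expr: pd.DataFrame) -> None:
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")


def gs76_score(expr: pd.DataFrame, signature: EMTSignature) -> EMTScoreResult:
    """Weighted-sum EMT score with CDH1-correlation weights, mean-centered.

    Weight of gene i is its Pearson correlation with the anchor across
    samples (the anchor's own weight is 1); the raw per-sample score is the
    weighted sum over signature genes found in the matrix; final scores are
    centered so their mean is zero. Positive = epithelial.
    """
    _check_expression(expr)
    if expr.shape[1] < 3:
        raise ValueError("at least 3 samples required for correlation weights")
    if signature.anchor_gene not in expr.index:
        raise ValueError(f"anchor gene {signature.anchor_gene!r} absent from matrix")
    anchor = expr.loc[signature.anchor_gene].to_numpy(dtype=float)
    if np.std(anchor) == 0:
        raise ValueError("anchor gene has zero variance")
    found = [g for g in signature.genes if g in expr.index]
    if len(found) < 2:
        raise ValueError("fewer than 2 signature genes found in matrix")
    if len(found) < len(signature.genes):
        warnings.warn(
            f"{len(signature.genes) - len(found)} signature genes missing; "
            f"scoring over the {len(found)}-gene intersection"
        )
    weights = {}
    for g in found:
        if g == signature.anchor_gene:
            weights[g] = 1.0
            continue
        x = expr.loc[g].to_numpy(dtype=float)
        if np.std(x) == 0:
            weights[g] = 0.0
        else:
            weights[g] = float(stats.pearsonr(x, anchor)[0])
    w = pd.Series(weights)
    raw = w @ expr.loc[w.index]
    scores = raw - raw.mean()
    return EMTScoreResult(
        scores=scores, weights=w, coverage=len(found) / len(signature.genes)
    )


def _zscore_rows(sub: pd.DataFrame) -> pd.DataFrame:
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    z = sub.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
    return z.fillna(0.0)  # constant genes contribute z = 0


def signature_summary(
    expr: pd.DataFrame, up_genes: Sequence[str], down_genes: Sequence[str]
) -> dict[str, pd.DataFrame | pd.Series]:
    """Per-sample mean z-scores for EMT-Up and EMT-Down gene sets.

    Each gene is z-scored across samples; the per-sample summary is the mean
    z over the set's genes present in the matrix. Per-gene z rows are also
    returned for heatmap-style output.
    """
    _check_expression(expr)
    out: dict[str, pd.DataFrame | pd.Series] = {}
    for label, genes in (("up", up_genes), ("down", down_genes)):
        found = [g for g in genes if g in expr.index]
        if not found:
            raise ValueError(f"no {label}-set genes found in expression matrix")
        z = _zscore_rows(expr.loc[found])
        out[f"{label}_z"] = z
        out[f"{label}_summary"] = z.mean(axis=0)
    return out


def expression_fold_change(
    expr: pd.DataFrame, sample_a: str, sample_b: str, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene expression ratio (a + eps) / (b + eps)."""
    for s in (sample_a, sample_b):
        if s not in expr.columns:
            raise KeyError(f"unknown sample label {s!r}")
    return (expr[sample_a] + pseudocount) / (expr[sample_b] + pseudocount)


def hypergeometric_overlap(
    set_a: set, set_b: set, universe: set
) -> tuple[int, float]:
    """Overlap size and hypergeometric tail p for two gene sets.

    p = P(X >= |a n b|) with X ~ Hypergeometric(N=|universe|, K=|a|, n=|b|).
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))
    return k, min(p, 1.0)


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")
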