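"""End-to-end orchestration: fixture generation and the full analysis run.

``run_simulate`` writes a complete synthetic study to disk (genome, four
condition peak sets on an EMT time course, tag counts with planted fold
effects, motif windows with planted consensus occurrences, query/reference
region pairs, TSS table, expression matrix with a planted EMT axis) together
with ground truth and a checksum manifest. ``run_all`` consumes such a
fixture (or equivalent user files) and emits every analysis table: peak
counts and TSS annotation, gap/desert statistics, the quantile-normalized
score matrix and its correlation, MPS/DPS classifications, Poisson
differential peaks joined to expression fold change, motif percentages and
dynamics, permutation overlap enrichment, and 76GS scores.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import accessibility, enrichment, expression, intervals, motifs, synthetic

__all__ = ["PipelineConfig", "run_simulate", "run_all"]

DEFAULT_CONDITIONS = ("untreated", "tgfb_2d", "tgfb_10d", "withdrawn")


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the analysis' canonical values.

    merge_distance 300 bp, motif window 50 bp, desert threshold 1 Mb, MPS
    class bounds 3/5, major-change DPS magnitude 2, differential-peak fold 4
    with Poisson p < 1e-4, 1000 permutations, motif significance cutoff 1e-12.
    """

    seed: int = 0
    out_dir: str = "emtchrom_out"
    # simulation shape
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 5_000_000}
    )
    excluded_fraction: float = 0.05
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_shared_peaks: int = 250
    n_unique_peaks: int = 60
    region_length_mean: float = 500.0
    region_length_sd: float = 120.0
    n_genes: int = 300
    depth_target: float = 2e4
    depth_background: float = 2e4
    planted_fold: float = 8.0
    planted_fraction: float = 0.05
    n_windows: int = 200
    window_size: int = 50
    motif_plant_rates: dict[str, float] = field(
        default_factory=lambda: {
            "untreated": 0.171,
            "tgfb_2d": 0.189,
            "tgfb_10d": 0.188,
            "withdrawn": 0.171,
        }
    )
    motif_consensus: str = "TGACTCAT"
    n_reference_regions: int = 100
    reference_length: int = 1000
    n_query_regions: int = 50
    query_length: int = 200
    query_inside_fraction: float = 1.0
    emt_axis: tuple[float, ...] = (0.0, 0.33, 1.0, 0.2)
    expression_noise_sd: float = 0.5
    n_extra_genes: int = 100
    # analysis thresholds
    merge_distance: int = 300
    bin_size: int = 300
    desert_min_gap: int = 1_000_000
    mps_low: float = 3.0
    mps_high: float = 5.0
    dps_major: float = 2.0
    diff_min_fold: float = 4.0
    diff_max_p: float = 1e-4
    n_permutations: int = 1000
    motif_p_cutoff: float = 1e-12

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        if "emt_axis" in data:
            data["emt_axis"] = tuple(data["emt_axis"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["emt_axis"] = list(self.emt_axis)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_simulate(config: PipelineConfig, out_dir: Optional[str | Path] = None) -> dict:
    """Generate the full synthetic fixture; returns the manifest dict."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    cs = synthetic.child_seed

    genome = synthetic.make_genome(
        config.chrom_sizes, config.excluded_fraction, seed=cs(seed, "genome")
    )
    intervals.write_chrom_sizes(genome.chrom_sizes, out / "chrom.sizes")
    intervals.write_bed(genome.excluded, out / "exclude.bed")

    peak_sets, membership_truth = synthetic.simulate_condition_peak_sets(
        genome,
        list(config.conditions),
        config.n_shared_peaks,
        config.n_unique_peaks,
        config.region_length_mean,
        config.region_length_sd,
        seed=cs(seed, "condition_peaks"),
    )
    for cond, rs in peak_sets.items():
        intervals.write_bed(rs, out / f"peaks_{cond}.bed")
    membership_truth.to_csv(out / "truth_peak_membership.tsv", sep="\t", index=False)

    tss = synthetic.simulate_tss_table(genome, config.n_genes, seed=cs(seed, "tss"))
    tss.to_tsv(out / "tss.tsv")

    # tag counts with planted fold effects on the first condition's peaks
    base_rs = peak_sets[config.conditions[0]]
    rng = np.random.default_rng(cs(seed, "fold_assignment"))
    n = len(base_rs)
    n_planted = int(round(config.planted_fraction * n))
    folds = np.ones(n)
    planted_idx = rng.choice(n, size=n_planted, replace=False)
    folds[planted_idx] = config.planted_fold
    counts = synthetic.simulate_tag_counts(
        base_rs,
        config.depth_target,
        config.depth_background,
        folds,
        seed=cs(seed, "tag_counts"),
    )
    counts.to_csv(out / "tag_counts.tsv", sep="\t", index=False)

    pwm = motifs.PWM.from_consensus("AP1_like", config.motif_consensus)
    with open(out / "motif.jaspar", "w") as fh:
        fh.write(f">{pwm.name}\n")
        for base, row in zip("ACGT", pwm.matrix):
            fh.write(base + "  [ " + "  ".join(f"{v:.4f}" for v in row) + " ]\n")
    window_truth = {}
    for cond in config.conditions:
        rate = config.motif_plant_rates.get(cond, 0.17)
        win = synthetic.simulate_window_sequences(
            config.n_windows,
            config.window_size,
            pwm,
            rate,
            seed=cs(seed, f"windows_{cond}"),
        )
        synthetic.write_fasta(win, out / f"windows_{cond}.fasta")
        window_truth[cond] = {
            "plant_rate": rate,
            "planted": win["planted"].tolist(),
        }
    bg = synthetic.simulate_window_sequences(
        config.n_windows, config.window_size, pwm, 0.0, seed=cs(seed, "windows_bg")
    )
    synthetic.write_fasta(bg, out / "windows_background.fasta")

    reference = synthetic.simulate_region_set(
        genome,
        config.n_reference_regions,
        config.reference_length,
        0.0,
        seed=cs(seed, "reference"),
        condition_label="reference",
    )
    intervals.write_bed(reference, out / "reference.bed")
    query, query_truth = synthetic.simulate_nested_query(
        genome,
        reference,
        config.n_query_regions,
        config.query_length,
        config.query_inside_fraction,
        seed=cs(seed, "query"),
    )
    intervals.write_bed(query, out / "query.bed")
    query_truth.to_csv(out / "truth_query.tsv", sep="\t", index=False)

    signature = expression.make_default_signature()
    signature.to_file(out / "signature.txt")
    expr = synthetic.simulate_expression(
        signature,
        list(config.emt_axis),
        n_extra_genes=config.n_extra_genes,
        noise_sd=config.expression_noise_sd,
        seed=cs(seed, "expression"),
    )
    if len(config.conditions) == expr.shape[1]:
        expr.columns = list(config.conditions)
    expression.write_expression(expr, out / "expression.tsv")

    truth = {
        "seed": seed,
        "planted_fold_regions": sorted(int(i) for i in planted_idx),
        "planted_fold": config.planted_fold,
        "motif_windows": window_truth,
        "emt_axis": list(config.emt_axis),
        "query_inside_fraction": config.query_inside_fraction,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)

    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "config": config.to_dict(),
        "files": {p.name: _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_all(
    config: PipelineConfig,
    fixture_dir: str | Path,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Run every analysis stage on a fixture directory; returns a report dict."""
    fx = Path(fixture_dir)
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name):
        def deco(fn):
            try:
                report["stages"][name] = fn()
            except Exception as exc:  # noqa: BLE001 - stage-named abort
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return fn

        return deco

    genome = intervals.GenomeModel(
        intervals.read_chrom_sizes(fx / "chrom.sizes"),
        intervals.read_bed(fx / "exclude.bed"),
    )
    peak_sets = {
        cond: intervals.read_bed(fx / f"peaks_{cond}.bed", genome, cond)
        for cond in config.conditions
    }
    tss = intervals.TSSTable.from_tsv(fx / "tss.tsv")

    @stage("peaks")
    def _peaks():
        rows = []
        for cond, rs in peak_sets.items():
            merged = intervals.merge_region_sets([rs], config.merge_distance)
            ann = intervals.nearest_tss(merged.regions, tss)
            ann.to_csv(out / f"annotation_{cond}.tsv", sep="\t", index=False)
            rows.append(
                {
                    "condition": cond,
                    "n_peaks": len(rs),
                    "n_merged": len(merged),
                    "median_abs_tss_distance": float(
                        ann["tss_distance"].abs().median()
                    ),
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "peak_counts.tsv", sep="\t", index=False)
        return df.to_dict(orient="records")

    @stage("venn")
    def _venn():
        merged = intervals.merge_region_sets(
            list(peak_sets.values()), config.merge_distance
        )
        counts = {
            "+".join(sorted(k)) if k else "none": v
            for k, v in merged.membership_counts().items()
        }
        with open(out / "venn_counts.json", "w") as fh:
            json.dump(counts, fh, indent=2, sort_keys=True)
        return counts

    @stage("deserts")
    def _deserts():
        rows = []
        for cond, rs in peak_sets.items():
            merged = intervals.merge_region_sets([rs], config.merge_distance)
            rows.append(
                {
                    "condition": cond,
                    "median_gap_bp": intervals.median_gap(merged.regions),
                    "n_deserts": intervals.count_peak_deserts(
                        merged.regions, genome, config.desert_min_gap
                    ),
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "gap_desert_stats.tsv", sep="\t", index=False)
        return df.to_dict(orient="records")

    @stage("matrix")
    def _matrix():
        m = accessibility.build_score_matrix(
            list(peak_sets.values()), config.bin_size, config.merge_distance
        )
        m.to_csv(out / "score_matrix.tsv", sep="\t", index_label="region")
        qn = accessibility.quantile_normalize(m)
        qn.to_csv(out / "score_matrix_qn.tsv", sep="\t", index_label="region")
        corr = accessibility.correlation_matrix(qn)
        corr.to_csv(out / "correlation.tsv", sep="\t", index_label="condition")
        return {"n_bins": int(m.shape[0]), "r2_min": float((corr.values**2).min())}

    @stage("mpsdps")
    def _mpsdps():
        qn = pd.read_csv(out / "score_matrix_qn.tsv", sep="\t", index_col="region")
        a, b = config.conditions[0], config.conditions[2 % len(config.conditions)]
        table = accessibility.classify_change_table(qn, a, b)
        table.to_csv(out / f"mps_dps_{a}_vs_{b}.tsv", sep="\t", index_label="region")
        return {
            "pair": [a, b],
            "n_major_change": int(table["major_change"].sum()),
            "class_counts": table["accessibility_class"].value_counts().to_dict(),
        }

    @stage("diffpeaks")
    def _diffpeaks():
        counts = pd.read_csv(fx / "tag_counts.tsv", sep="\t")
        dp = accessibility.differential_peaks(
            counts["tags_target"],
            counts["tags_background"],
            config.depth_target,
            config.depth_background,
            config.diff_min_fold,
            config.diff_max_p,
            index=counts["name"],
        )
        dp = pd.concat([counts[["chrom", "start", "end"]].set_index(counts["name"]), dp], axis=1)
        dp.to_csv(out / "differential_peaks.tsv", sep="\t", index_label="name")
        flagged = dp[dp["flagged"]]
        flagged_rs = intervals.RegionSet(
            [
                intervals.GenomicRegion(r.chrom, r.start, r.end, name=name)
                for name, r in flagged.iterrows()
            ],
            "diff_peaks",
        )
        expr = expression.read_expression(fx / "expression.tsv")
        sa, sb = expr.columns[0], expr.columns[min(2, expr.shape[1] - 1)]
        if len(flagged_rs) > 0:
            fc = accessibility.fc_vs_tss_table(flagged_rs, tss, expr, sa, sb)
            fc.to_csv(out / "fc_vs_tss.tsv", sep="\t", index=False)
        return {"n_flagged": int(dp["flagged"].sum()), "n_total": int(len(dp))}

    @stage("motifs")
    def _motifs():
        pwms = motifs.PWM.from_jaspar(fx / "motif.jaspar")
        bg = synthetic.read_fasta(fx / "windows_background.fasta")
        control_pcts: dict[str, float] = {}
        tables = []
        control = config.conditions[0]
        for cond in config.conditions:
            win = synthetic.read_fasta(fx / f"windows_{cond}.fasta")
            table = motifs.motif_enrichment_table(
                list(win["sequence"]),
                list(bg["sequence"]),
                pwms,
                control_pcts=control_pcts if cond != control else None,
                p_cutoff=config.motif_p_cutoff,
            )
            table.insert(0, "condition", cond)
            tables.append(table)
            if cond == control:
                control_pcts = dict(zip(table["motif"], table["target_pct"]))
        df = pd.concat(tables, ignore_index=True)
        df.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
        return df[["condition", "motif", "target_pct", "percentage_change"]].to_dict(
            orient="records"
        )

    @stage("enrich")
    def _enrich():
        query = intervals.read_bed(fx / "query.bed", genome, "query")
        reference = intervals.read_bed(fx / "reference.bed", genome, "reference")
        result = enrichment.permutation_overlap_test(
            query,
            reference,
            genome,
            n_permutations=config.n_permutations,
            seed=synthetic.child_seed(config.seed, "permutation"),
        )
        result.to_json(out / "overlap_enrichment.json")
        return result.to_dict()

    @stage("emtscore")
    def _emtscore():
        expr = expression.read_expression(fx / "expression.tsv")
        signature = expression.EMTSignature.from_file(fx / "signature.txt")
        result = expression.gs76_score(expr, signature)
        result.to_frame().to_csv(out / "emt_scores.tsv", sep="\t", index_label="sample")
        return {
            "scores": result.scores.round(6).to_dict(),
            "coverage": result.coverage,
        }

    log = {
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages_completed": list(report["stages"]),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
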