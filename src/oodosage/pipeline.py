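"""Pipeline orchestration: generate -> demux -> normalize -> de -> dosage.

One YAML-serializable config drives every stage with explicit per-stage
seeds; artifacts are plain TSV/JSON written deterministically, so a
rerun with the same config is byte-identical. Each stage can also be
driven independently from the command line (see :mod:`oodosage.cli`).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import dosage as dosage_mod
from . import norm as norm_mod
from . import qpcr as qpcr_mod
from . import synthdata, umi

log = logging.getLogger("oodosage")

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """All tunables of the pipeline, with per-stage seeds."""

    outdir: str = "oodosage_run"
    # gene universe
    n_autosomal: int = 2000
    n_x: int = 200
    n_y: int = 40
    n_par: int = 8
    n_spikes: int = 92
    n_replicates: int = 3
    n_batches: int = 1
    # truth model
    truth: dict = field(default_factory=lambda: asdict(synthdata.TruthParams()))
    # read-level simulation runs the FASTQ -> demux path; off by default
    # for large universes, where the generator's molecule matrix is used
    # directly (read-level runs are intended for small universes)
    simulate_reads: bool = False
    error_rate: float = 0.0
    untagged_fraction: float = 0.5
    tag: dict = field(default_factory=lambda: asdict(synthdata.TagPattern()))
    # normalization / QC
    pseudocount_log: float = 1.0
    top_n_variable: int = 500
    # differential expression
    k_surrogates: int = 0
    alpha: float = 0.05
    lfc_min: float = 0.0
    # dosage statistics
    pseudocount_ratio: float = 0.5
    n_bins: int = 6
    resample_size: int = 100
    bootstrap_reps: int = 5000
    # qPCR demo stage
    run_qpcr: bool = True
    # seeds per stochastic stage
    seed_annotation: int = 11
    seed_truth: int = 12
    seed_counts: int = 13
    seed_reads: int = 14
    seed_bootstrap: int = 15
    seed_qpcr: int = 16

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if self.n_spikes < norm_mod.MIN_SPIKES:
            raise ValueError(
                f"n_spikes={self.n_spikes} < {norm_mod.MIN_SPIKES} needed "
                "for size-factor estimation")
        for name in ("n_autosomal", "n_x", "n_y", "n_par"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        synthdata.TruthParams(**self.truth)
        synthdata.TagPattern(**self.tag)

    def digest(self) -> str:
        """Hash of the analysis parameters (the output path is excluded,
        so the same analysis written elsewhere keeps the same identity)."""
        data = asdict(self)
        data.pop("outdir")
        blob = yaml.safe_dump(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, set):
        return sorted(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def spike_design_from_truth(truth: synthdata.TruthTable) -> pd.DataFrame:
    """Nominal spike amounts implied by the generator's spike means.

    In the synthetic world the nominal input amounts are known exactly
    (they are the truth-table spike means); attomoles are back-computed
    so the design round-trips through :func:`oodosage.norm.size_factors`.
    """
    spikes = truth.means.index[truth.means.index.str.startswith("ERCC-")]
    molecules = truth.means.loc[spikes, "XX"].to_numpy()
    return pd.DataFrame({
        "spike_id": spikes,
        "attomoles": molecules / (1e-18 * norm_mod.AVOGADRO),
        "expected_molecules": molecules,
    })


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order; return the report index."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.digest(), "stages": {}}
    config.to_yaml(out / "config.yaml")

    def stage(name):
        log.info("stage %s ...", name)
        return time.time()

    def done(name, t0):
        log.info("stage %s finished in %.2f s", name, time.time() - t0)

    # --- simulate -----------------------------------------------------
    t0 = stage("simulate")
    annot = synthdata.make_annotation(
        config.n_autosomal, config.n_x, config.n_y, config.n_par,
        config.n_spikes, seed=config.seed_annotation)
    samples = synthdata.make_samples(config.n_replicates, config.n_batches)
    truth = synthdata.simulate_truth(
        annot, synthdata.TruthParams(**config.truth), seed=config.seed_truth)
    counts_true, factors = synthdata.simulate_counts(
        truth, samples, seed=config.seed_counts)
    spikes = spike_design_from_truth(truth)
    _write_tsv(annot, out / "annotation.tsv", index=False)
    _write_tsv(samples, out / "samples.tsv", index=False)
    _write_tsv(counts_true, out / "counts_true.tsv")
    _write_tsv(spikes, out / "spikes.tsv", index=False)
    _write_tsv(truth.means, out / "truth_means.tsv")
    report["stages"]["simulate"] = {
        "n_features": len(annot), "n_samples": len(samples),
        "seed": config.seed_counts,
    }

    done("simulate", t0)

    # --- demux (reads -> UMI counts) ---------------------------------
    t0 = stage("demux")
    tag = synthdata.TagPattern(**config.tag)
    if config.simulate_reads:
        with open(out / "reads.fastq", "w") as fh:
            _, truth_map = synthdata.simulate_reads(
                counts_true, tag, error_rate=config.error_rate,
                untagged_fraction=config.untagged_fraction,
                seed=config.seed_reads, out=fh)
        _write_tsv(truth_map, out / "truth_map.tsv", index=False)
        with open(out / "reads.fastq") as fh:
            counts, qc = umi.count_umis(
                umi.parse_fastq(fh), truth_map, samples, tag,
                features=counts_true.index)
    else:
        counts, qc = counts_true, {"reads_in": None,
                                   "note": "molecule matrix used directly"}
    _write_tsv(counts, out / "counts.tsv")
    _write_json(qc, out / "demux_qc.json")
    report["stages"]["demux"] = {"qc": qc,
                                 "seed": config.seed_reads}

    done("demux", t0)

    # --- normalize + QC ----------------------------------------------
    t0 = stage("normalize")
    factors_est = norm_mod.size_factors(counts, spikes)
    nm = norm_mod.normalize(counts, factors_est,
                            pseudocount=config.pseudocount_log)
    gene_rows = annot.loc[annot["feature_class"] != "spike", "feature_id"]
    detected_rows = counts.loc[gene_rows].sum(axis=1) > 0
    log_genes = nm.log_matrix.loc[gene_rows[detected_rows.to_numpy()]]
    top = norm_mod.top_variable_genes(
        log_genes, min(config.top_n_variable, len(log_genes)))
    dist = norm_mod.spearman_distance(log_genes, top)
    pca = norm_mod.pca_qc(log_genes)
    _write_tsv(nm.normalized, out / "normalized.tsv")
    _write_tsv(nm.log_matrix, out / "log_matrix.tsv")
    _write_tsv(factors_est.to_frame(), out / "size_factors.tsv")
    _write_tsv(dist, out / "spearman_distance.tsv")
    _write_tsv(pca.scores, out / "pca_scores.tsv")
    report["stages"]["normalize"] = {
        "variance_explained_pc1": float(pca.variance_explained[0]),
    }

    done("normalize", t0)

    # --- differential expression -------------------------------------
    t0 = stage("de")
    sv = de_mod.estimate_surrogates(log_genes, samples, config.k_surrogates)
    design = de_mod.design_matrix(samples, sv)
    fit = de_mod.fit_models(log_genes, design)
    result = de_mod.moderate(fit)
    _write_tsv(result.table, out / "de_results.tsv", index=False)
    ann_idx = annot.set_index("feature_id")
    x_genes = set(ann_idx.index[ann_idx["feature_class"].isin(
        ["x_linked", "par_x"])])
    a_genes = set(ann_idx.index[ann_idx["feature_class"] == "autosomal"])
    venns = {}
    for name, universe in [("x_linked", x_genes), ("autosomal", a_genes)]:
        vp = de_mod.dosage_venn(result, universe, config.alpha, config.lfc_min)
        venns[name] = vp
        _write_json({"counts": vp.counts,
                     "categories": {k: sorted(v)
                                    for k, v in vp.categories.items()}},
                    out / f"venn_{name}.json")
    report["stages"]["de"] = {
        "d0": result.d0, "s02": result.s02,
        "red_x_genes": len(venns["x_linked"].categories["red"]),
    }

    done("de", t0)

    # --- dosage statistics -------------------------------------------
    t0 = stage("dosage")
    non_y = ann_idx.index[~ann_idx["feature_class"].isin(
        ["y_linked", "par_y", "spike"])]
    detected = nm.normalized.loc[non_y].sum(axis=1) > 0
    universe = nm.normalized.loc[non_y[detected]]
    bins = dosage_mod.assign_bins(universe.mean(axis=1), config.n_bins)
    boots = dosage_mod.xa_bootstrap(
        universe, samples, annot, bins,
        resample_size=config.resample_size, reps=config.bootstrap_reps,
        seed=config.seed_bootstrap, pseudocount=config.pseudocount_ratio)
    boot_stats = [dict(bin=b.bin_id, genotype=b.genotype, **b.boxplot_stats)
                  for b in boots]
    bin6 = dosage_mod.bin6_genotype_ratio_bootstrap(
        universe, samples, annot, bins,
        resample_size=config.resample_size, reps=config.bootstrap_reps,
        seed=config.seed_bootstrap, pseudocount=config.pseudocount_ratio)
    bin6_stats = {k: v.boxplot_stats for k, v in bin6.items()}
    red = venns["x_linked"].categories["red"]
    ratio_profile = None
    fit_summary = None
    if red:
        rf, profile = dosage_mod.ratio_fit(
            nm.normalized, samples, red, annot,
            pseudocount=config.pseudocount_ratio)
        fit_summary = asdict(rf)
        ratio_profile = profile
        _write_tsv(profile, out / "ratio_profile.tsv", index=False)
        _write_json(fit_summary, out / "ratio_fit.json")
    y_classes = dosage_mod.classify_y_genes(
        nm.normalized, samples, annot, result,
        pseudocount=config.pseudocount_ratio)
    _write_tsv(y_classes, out / "y_gene_classes.tsv", index=False)
    homologs = dosage_mod.homolog_sum(
        nm.normalized, samples, annot, pseudocount=config.pseudocount_ratio)
    _write_tsv(homologs, out / "homolog_summary.tsv", index=False)
    _write_json({"xa": boot_stats, "bin6": bin6_stats},
                out / "bootstrap_stats.json")
    bins.to_frame().to_csv(out / "bins.tsv", sep="\t")
    report["stages"]["dosage"] = {
        "ratio_fit": fit_summary,
        "bin6": bin6_stats,
        "n_y_high": int((y_classes["de_class"] == "high").sum()),
        "seed": config.seed_bootstrap,
    }

    done("dosage", t0)

    # --- qPCR demo ----------------------------------------------------
    if config.run_qpcr:
        t0 = stage("qpcr")
        levels = qpcr_mod.relative_table(qpcr_mod.simulate_qpcr(
            ["GeneX", "GeneA"], ["20-30um", "FG"],
            true_levels={("GeneX", "XO", "FG"): 0.5,
                         ("GeneX", "XY", "FG"): 0.5},
            seed=config.seed_qpcr))
        summary = qpcr_mod.summarize_groups(levels)
        comps = []
        for (gene, sb), sub in levels.groupby(["gene", "size_bin"]):
            grp = {g: s["level"].to_numpy()
                   for g, s in sub.groupby("genotype")}
            tab = qpcr_mod.compare_groups(grp, method="anova_tukey")
            tab.insert(0, "gene", gene)
            tab.insert(1, "size_bin", sb)
            comps.append(tab)
        _write_tsv(summary, out / "qpcr_summary.tsv", index=False)
        _write_tsv(pd.concat(comps, ignore_index=True),
                   out / "qpcr_comparisons.tsv", index=False)
        report["stages"]["qpcr"] = {"n_records": len(levels),
                                    "seed": config.seed_qpcr}

        done("qpcr", t0)

    _write_json(report, out / "report.json")
    return report
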