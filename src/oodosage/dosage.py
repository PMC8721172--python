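"""X-dosage statistics: lognormal ratio fits, binned X:A bootstrap,
Y-gene expression classes, and X/Y homolog sums.

All statistics run on the ERCC-normalized expression matrix. Ratios and
homolog summaries use geometric means over replicates (the natural
summary under a lognormal model); the bootstrap X:A statistic uses
arithmetic per-genotype means of the replicates, matching the wording
of each procedure. A pseudocount (default 0.5 normalized units) guards
ratios against true zeros, which Y-linked genes have in XX and XO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import DEResult, bh_fdr

GENOTYPES = ("XX", "XO", "XY")

DEFAULT_PSEUDOCOUNT = 0.5


def _genotype_columns(meta: pd.DataFrame, genotype: str) -> list[str]:
    cols = list(meta.loc[meta["genotype"] == genotype, "sample_id"])
    if not cols:
        raise ValueError(f"no samples with genotype {genotype}")
    return cols


def genotype_means(normalized: pd.DataFrame, meta: pd.DataFrame,
                   how: str = "arithmetic") -> pd.DataFrame:
    """Per-genotype summary of replicate expression (arithmetic or geometric)."""
    out = {}
    for g in GENOTYPES:
        cols = _genotype_columns(meta, g)
        block = normalized[cols]
        if how == "arithmetic":
            out[g] = block.mean(axis=1)
        elif how == "geometric":
            out[g] = np.exp(np.log(block + DEFAULT_PSEUDOCOUNT).mean(axis=1)) \
                - DEFAULT_PSEUDOCOUNT
        else:
            raise ValueError(f"unknown summary {how!r}")
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Lognormal ratio fit (dosage-dependent DEG profile along the X)

@dataclass
class RatioFit:
    """Lognormal summary of a set of expression ratios.

    geometric_mean = exp(mean log ratio); sdlog is the SD of the log
    ratios; the multiplicative-SD interval is (gm/exp(sdlog),
    gm*exp(sdlog)); ci_mean is a 95 % t-interval for the geometric mean.
    """

    n: int
    geometric_mean: float
    sdlog: float
    multiplicative_sd_interval: tuple[float, float]
    ci_mean: tuple[float, float]


def fit_lognormal_ratios(ratios: np.ndarray, conf: float = 0.95) -> RatioFit:
    """Fit the lognormal summary to a vector of positive ratios."""
    r = np.asarray(ratios, float)
    if r.size == 0:
        raise ValueError("empty ratio vector")
    if (r <= 0).any():
        raise ValueError("ratios must be > 0")
    logs = np.log(r)
    mu = float(logs.mean())
    sd = float(logs.std(ddof=1)) if r.size > 1 else 0.0
    gm = float(np.exp(mu))
    if r.size > 1 and sd > 0:
        half = stats.t.ppf(0.5 + conf / 2, r.size - 1) * sd / np.sqrt(r.size)
    else:
        half = 0.0
    return RatioFit(
        n=int(r.size), geometric_mean=gm, sdlog=sd,
        multiplicative_sd_interval=(gm / np.exp(sd), gm * np.exp(sd)),
        ci_mean=(float(np.exp(mu - half)), float(np.exp(mu + half))),
    )


def ratio_fit(
    normalized: pd.DataFrame,
    meta: pd.DataFrame,
    genes: set[str],
    annotation: pd.DataFrame,
    numerator: tuple[str, ...] = ("XO", "XY"),
    denominator: str = "XX",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[RatioFit, pd.DataFrame]:
    """Per-gene transcript-level ratios vs XX, with a lognormal fit.

    For each gene the ratio is the geometric mean over the numerator
    genotype's replicates divided by the geometric mean over XX
    replicates (pseudocount added before logs). With both XO and XY in
    the numerator the per-genotype log-ratio vectors are concatenated,
    so the pooled fit equals the fit on the combined vectors. The
    per-gene table is ordered by X-chromosome position for plotting the
    ratio profile along the chromosome.
    """
    if not genes:
        raise ValueError("empty gene set")
    genes_l = [g for g in normalized.index if g in genes]
    logx = np.log(normalized.loc[genes_l] + pseudocount)
    den_cols = _genotype_columns(meta, denominator)
    log_den = logx[den_cols].mean(axis=1)
    rows = []
    for g_geno in numerator:
        num_cols = _genotype_columns(meta, g_geno)
        log_num = logx[num_cols].mean(axis=1)
        ratio = np.exp(log_num - log_den)
        for gene, r in ratio.items():
            rows.append({"gene": gene, "numerator": g_geno, "ratio": float(r)})
    table = pd.DataFrame(rows)
    pos = annotation.set_index("feature_id")["start_bp"]
    table["start_bp"] = table["gene"].map(pos)
    table = table.sort_values(["start_bp", "gene", "numerator"],
                              kind="mergesort").reset_index(drop=True)
    fit = fit_lognormal_ratios(table["ratio"].to_numpy())
    return fit, table


# ---------------------------------------------------------------------------
# Expression bins and the bootstrap X:A statistic

def assign_bins(mean_expression: pd.Series, n_bins: int = 6) -> pd.Series:
    """Split genes into n_bins contiguous, equally sized expression bins.

    Genes are sorted by mean expression (ties broken by feature_id) and
    cut into contiguous groups whose sizes differ by at most one; bin 1
    is the lowest-expression group, bin n_bins the highest.
    """
    if len(mean_expression) < n_bins:
        raise ValueError(f"need >= {n_bins} genes, got {len(mean_expression)}")
    # stable two-key sort: expression then feature_id
    lex = np.lexsort((np.asarray(mean_expression.index),
                      mean_expression.to_numpy()))
    key = mean_expression.index[lex]
    labels = np.zeros(len(key), dtype=int)
    splits = np.array_split(np.arange(len(key)), n_bins)
    for b, idx in enumerate(splits, start=1):
        labels[idx] = b
    return pd.Series(labels, index=pd.Index(key), name="bin").reindex(
        mean_expression.index)


@dataclass
class BinBootstrapResult:
    """Bootstrap distribution of X:A median ratios for one (bin, genotype)."""

    bin_id: int
    genotype: str
    draws: np.ndarray
    resample_size: int
    reps: int
    seed: int

    @property
    def boxplot_stats(self) -> dict:
        q1, med, q3 = np.percentile(self.draws, [25, 50, 75])
        iqr = q3 - q1
        lo = self.draws[self.draws >= q1 - 1.5 * iqr].min()
        hi = self.draws[self.draws <= q3 + 1.5 * iqr].max()
        return {"median": float(med), "q1": float(q1), "q3": float(q3),
                "whisker_lo": float(lo), "whisker_hi": float(hi)}


def _bootstrap_medians(rng: np.random.Generator, values: np.ndarray,
                       size: int, reps: int) -> np.ndarray:
    idx = rng.integers(0, len(values), size=(reps, size))
    return np.median(values[idx], axis=1)


def xa_bootstrap(
    normalized: pd.DataFrame,
    meta: pd.DataFrame,
    annotation: pd.DataFrame,
    bins: pd.Series,
    resample_size: int = 100,
    reps: int = 5000,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[BinBootstrapResult]:
    """Bootstrap X:A expression ratios per expression bin and genotype.

    Per replicate draw: ``resample_size`` X-linked genes and the same
    number of autosomal genes are sampled with replacement within the
    bin; the median per-genotype mean expression of each draw is taken
    and their ratio median_X / median_A emitted. Y-linked genes are
    excluded from the universe upstream (when bins are built).
    """
    ann = annotation.set_index("feature_id")
    gm = genotype_means(normalized, meta, how="arithmetic") + pseudocount
    feats = bins.index
    is_x = ann.loc[feats, "feature_class"].isin(["x_linked", "par_x"]).to_numpy()
    is_a = (ann.loc[feats, "feature_class"] == "autosomal").to_numpy()
    results = []
    for b in sorted(bins.dropna().unique()):
        in_bin = (bins == b).to_numpy()
        x_genes = feats[in_bin & is_x]
        a_genes = feats[in_bin & is_a]
        for stratum, members in [("X-linked", x_genes), ("autosomal", a_genes)]:
            if len(members) == 0:
                raise ValueError(f"bin {b}: empty {stratum} stratum")
        for g_geno in GENOTYPES:
            rng = np.random.default_rng([seed, int(b), GENOTYPES.index(g_geno)])
            xv = gm.loc[x_genes, g_geno].to_numpy()
            av = gm.loc[a_genes, g_geno].to_numpy()
            med_x = _bootstrap_medians(rng, xv, resample_size, reps)
            med_a = _bootstrap_medians(rng, av, resample_size, reps)
            results.append(BinBootstrapResult(
                bin_id=int(b), genotype=g_geno, draws=med_x / med_a,
                resample_size=resample_size, reps=reps, seed=seed))
    return results


def bin6_genotype_ratio_bootstrap(
    normalized: pd.DataFrame,
    meta: pd.DataFrame,
    annotation: pd.DataFrame,
    bins: pd.Series,
    resample_size: int = 100,
    reps: int = 5000,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    bin_id: int | None = None,
) -> dict[str, BinBootstrapResult]:
    """Bootstrap XO:XX and XY:XX mean-level ratios among bin-6 X genes.

    The same resampling scheme as the X:A bootstrap, but each draw
    resamples highly expressed (top-bin) X-linked genes once and the
    statistic is the median of the drawn genes' XO (or XY) means over
    the median of the same genes' XX means.
    """
    if bin_id is None:
        bin_id = int(bins.max())
    ann = annotation.set_index("feature_id")
    feats = bins.index
    is_x = ann.loc[feats, "feature_class"].isin(["x_linked", "par_x"]).to_numpy()
    x_genes = feats[(bins == bin_id).to_numpy() & is_x]
    if len(x_genes) == 0:
        raise ValueError(f"bin {bin_id}: empty X-linked stratum")
    gm = genotype_means(normalized, meta, how="arithmetic") + pseudocount
    out = {}
    for i, g_geno in enumerate(("XO", "XY")):
        rng = np.random.default_rng([seed, 100 + i])
        idx = rng.integers(0, len(x_genes), size=(reps, resample_size))
        num = np.median(gm.loc[x_genes, g_geno].to_numpy()[idx], axis=1)
        den = np.median(gm.loc[x_genes, "XX"].to_numpy()[idx], axis=1)
        out[f"{g_geno}:XX"] = BinBootstrapResult(
            bin_id=bin_id, genotype=g_geno, draws=num / den,
            resample_size=resample_size, reps=reps, seed=seed)
    return out


# ---------------------------------------------------------------------------
# Y-linked / PAR gene expression classes

def classify_y_genes(
    normalized: pd.DataFrame,
    meta: pd.DataFrame,
    annotation: pd.DataFrame,
    de_result: DEResult | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Class Y-chromosome genes by their XY-vs-XX log2 fold change.

    Log2FC = log2((XY mean + pc) / (XX mean + pc)); classes: ``high``
    for Log2FC >= 3, ``medium`` for 1 < Log2FC < 3, ``none`` otherwise.
    If a DEResult is given, BH-adjusted p values of the XX-XY contrast
    (recomputed within the Y-gene subset) are attached.
    """
    ann = annotation.set_index("feature_id")
    y_feats = ann.index[ann["feature_class"].isin(["y_linked", "par_y"])]
    y_feats = y_feats.intersection(normalized.index)
    if len(y_feats) == 0:
        raise ValueError("annotation contains no y_linked/par_y features "
                         "present in the matrix")
    gm = genotype_means(normalized.loc[y_feats], meta, how="arithmetic")
    lfc = np.log2((gm["XY"] + pseudocount) / (gm["XX"] + pseudocount))
    cls = pd.Series("none", index=y_feats, name="de_class")
    cls[lfc >= 3] = "high"
    cls[(lfc > 1) & (lfc < 3)] = "medium"
    out = pd.DataFrame({
        "gene": y_feats,
        "start_bp": ann.loc[y_feats, "start_bp"].to_numpy(),
        "log2FC": lfc.to_numpy(),
        "de_class": cls.to_numpy(),
    })
    if de_result is not None:
        sub = de_result.for_contrast("XX-XY").reindex(y_feats)
        valid = sub["p"].notna()
        fdr = pd.Series(np.nan, index=y_feats)
        if valid.any():
            fdr[valid] = bh_fdr(sub.loc[valid, "p"].to_numpy())
        out["fdr"] = fdr.to_numpy()
    return out.sort_values("start_bp").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Homolog sums (X + Y gametolog pairs)

def homolog_sum(
    normalized: pd.DataFrame,
    meta: pd.DataFrame,
    annotation: pd.DataFrame,
    groups: list[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per homolog group and genotype: member geometric means and X+Y sum.

    Member summaries are geometric means over replicates with lognormal
    multiplicative-SD intervals; the group "sum" adds member geometric
    means per genotype, so Y members contribute (near) zero in XX/XO and
    raise the XY sum toward the XX level when X and Y homologs share
    function.
    """
    ann = annotation.set_index("feature_id")
    have = ann["homolog_group"].dropna()
    if groups is None:
        groups = sorted(have.unique())
    rows = []
    for grp in groups:
        members = have.index[have == grp]
        if len(members) == 0:
            raise ValueError(f"unknown homolog group {grp!r}")
        missing = [m for m in members if m not in normalized.index]
        if missing:
            raise ValueError(f"group {grp!r}: members missing from matrix: "
                             f"{missing}")
        for g_geno in GENOTYPES:
            cols = _genotype_columns(meta, g_geno)
            gms = {}
            for m in members:
                logs = np.log(normalized.loc[m, cols].to_numpy(float)
                              + pseudocount)
                gm = float(np.exp(logs.mean())) - pseudocount
                sd = float(logs.std(ddof=1)) if len(cols) > 1 else 0.0
                gms[m] = max(gm, 0.0)
                rows.append({
                    "group": grp, "genotype": g_geno, "member": m,
                    "feature_class": ann.loc[m, "feature_class"],
                    "geometric_mean": gms[m],
                    "sd_interval_lo": max(gm, 0.0) / np.exp(sd),
                    "sd_interval_hi": max(gm, 0.0) * np.exp(sd),
                })
            rows.append({
                "group": grp, "genotype": g_geno, "member": "sum",
                "feature_class": "sum",
                "geometric_mean": sum(gms.values()),
                "sd_interval_lo": np.nan, "sd_interval_hi": np.nan,
            })
    return pd.DataFrame(rows)
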