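"""qRT-PCR relative quantification normalized to a reference gene.

Relative transcript level per sample is efficiency^(-dCq) with
dCq = Cq(gene) - Cq(reference); the study normalizes every cDNA sample
to endogenous *Ppia*. Group comparisons across genotypes within an
oocyte size bin use Welch's t-test (two groups), one-way ANOVA followed
by Tukey's HSD, or Kruskal-Wallis followed by Dunn's rank-sum test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

CQ_RANGE = (0.0, 45.0)


def relative_expression(cq_gene: float, cq_reference: float,
                        efficiency: float = 2.0) -> float:
    """efficiency^(-(cq_gene - cq_reference)).

    With perfect doubling per cycle (efficiency 2) this is the standard
    2^(-dCq) relative level against the reference gene.
    """
    if not 1 < efficiency <= 2:
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    for name, cq in [("cq_gene", cq_gene), ("cq_reference", cq_reference)]:
        if not CQ_RANGE[0] < cq < CQ_RANGE[1]:
            raise ValueError(f"{name}={cq} outside {CQ_RANGE}")
    return float(efficiency ** (-(cq_gene - cq_reference)))


def relative_table(records: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Add a relative-level column and mean +/- SEM group summaries.

    ``records`` columns: gene, genotype, size_bin, replicate, cq_gene,
    cq_reference. Returns the per-record table with ``level``; group
    summaries are available via :func:`summarize_groups`.
    """
    out = records.copy()
    out["level"] = [
        relative_expression(r.cq_gene, r.cq_reference, efficiency)
        for r in records.itertuples(index=False)
    ]
    return out


def summarize_groups(levels: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM per (gene, genotype, size_bin)."""
    g = levels.groupby(["gene", "genotype", "size_bin"])["level"]
    return g.agg(mean="mean", sem="sem", n="count").reset_index()


def compare_groups(groups: dict[str, np.ndarray],
                   method: str = "welch_t") -> pd.DataFrame:
    """Pairwise p values among genotype groups of relative levels.

    ``method``: ``welch_t`` (unequal-variance t per pair),
    ``anova_tukey`` (one-way ANOVA then Tukey HSD, studentized range),
    or ``kruskal_dunn`` (Kruskal-Wallis then Dunn's z test on rank sums
    with Bonferroni adjustment over pairs).
    """
    names = sorted(groups)
    arrays = {k: np.asarray(groups[k], float) for k in names}
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    min_n = 1 if method == "kruskal_dunn" else 2
    for k, v in arrays.items():
        if len(v) < min_n:
            raise ValueError(f"group {k!r} has {len(v)} observations "
                             f"(need >= {min_n} for {method})")
    pairs = list(combinations(names, 2))
    if method == "welch_t":
        rows = []
        for a, b in pairs:
            if np.array_equal(arrays[a], arrays[b]):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(arrays[a], arrays[b], equal_var=False)
            rows.append({"group1": a, "group2": b, "stat": float(t),
                         "p": float(p)})
        return pd.DataFrame(rows)
    if method == "anova_tukey":
        res = stats.tukey_hsd(*[arrays[k] for k in names])
        rows = []
        for (a, b) in pairs:
            i, j = names.index(a), names.index(b)
            rows.append({"group1": a, "group2": b,
                         "stat": float(res.statistic[i, j]),
                         "p": float(res.pvalue[i, j])})
        return pd.DataFrame(rows)
    if method == "kruskal_dunn":
        return _dunn(arrays, pairs)
    raise ValueError(f"unknown method {method!r}")


def _dunn(arrays: dict[str, np.ndarray],
          pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Dunn's post-hoc z tests on rank sums, Bonferroni over pairs.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with the tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    pooled = np.concatenate([arrays[k] for k in arrays])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_rank, sizes, pos = {}, {}, 0
    for k, v in arrays.items():
        mean_rank[k] = float(ranks[pos:pos + len(v)].mean())
        sizes[k] = len(v)
        pos += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())
                     / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    m = len(pairs)
    for a, b in pairs:
        se = np.sqrt(var_unit * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = min(1.0, 2 * stats.norm.sf(abs(z)) * m)
        rows.append({"group1": a, "group2": b, "stat": float(z), "p": float(p)})
    return pd.DataFrame(rows)


def simulate_qpcr(
    genes: list[str],
    size_bins: list[str],
    n_replicates: int = 3,
    true_levels: dict[tuple[str, str, str], float] | None = None,
    cq_reference: float = 20.0,
    cq_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Tiny fixture generator for qPCR records.

    ``true_levels`` maps (gene, genotype, size_bin) to relative level vs
    the reference (default 1.0 everywhere); Cq values get Normal noise
    of SD ``cq_sd`` cycles.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        for geno in ("XX", "XO", "XY"):
            for sb in size_bins:
                level = 1.0
                if true_levels:
                    level = true_levels.get((gene, geno, sb), 1.0)
                for rep in range(1, n_replicates + 1):
                    ref = cq_reference + rng.normal(0, cq_sd)
                    cq = ref - np.log2(level) + rng.normal(0, cq_sd)
                    rows.append({"gene": gene, "genotype": geno,
                                 "size_bin": sb, "replicate": rep,
                                 "cq_gene": float(cq),
                                 "cq_reference": float(ref)})
    return pd.DataFrame(rows)
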