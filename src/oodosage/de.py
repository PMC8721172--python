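"""Three-way differential expression with empirical-Bayes moderation.

Per-gene ordinary least squares on log2 expression against genotype
(plus optional surrogate covariates for batch structure), empirical-
Bayes shrinkage of the residual variances toward a pooled prior
(moderated t), Benjamini-Hochberg FDR, directional DEG selection per
pairwise contrast, and the 4-set Venn partition that defines the
sex-chromosome-dosage gene categories:

* ``red``            higher in XX than both XO and XY, XO ~ XY
                     (X-dosage dependent)
* ``purple_solid``   higher in XX and XY than XO, XX ~ XY
* ``purple_broken``  ordered XX > XY > XO
* ``brown``          lower in XY than both XX and XO

The variance moderation follows the standard empirical-Bayes treatment
for gene-wise linear models: gene variances s_g^2 with d residual df
are assumed scaled-inverse-chi-square around a prior (d0, s0^2); the
hyperparameters are estimated by method of moments on log s_g^2
(digamma/trigamma matching, trigamma inverted by bisection) and the
posterior variance (d0 s0^2 + d s_g^2) / (d0 + d) feeds a t statistic
with d0 + d degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

CONTRASTS = ("XX-XO", "XX-XY", "XO-XY")

#: bisection tolerance for the trigamma inversion
_TRIGAMMA_TOL = 1e-10


# ---------------------------------------------------------------------------
# Design and surrogate covariates

def design_matrix(samples: pd.DataFrame,
                  surrogates: np.ndarray | None = None) -> pd.DataFrame:
    """Cell-means genotype design (one column per genotype) + surrogates."""
    X = pd.get_dummies(samples["genotype"], dtype=float)
    X = X[[g for g in ("XX", "XO", "XY") if g in X.columns]]
    X.index = samples["sample_id"].to_numpy()
    for g in X.columns:
        if X[g].sum() < 2:
            raise ValueError(f"genotype {g} has < 2 samples")
    if surrogates is not None and surrogates.size:
        for k in range(surrogates.shape[1]):
            X[f"SV{k + 1}"] = surrogates[:, k]
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def estimate_surrogates(log_matrix: pd.DataFrame, samples: pd.DataFrame,
                        k: int) -> np.ndarray:
    """Surrogate covariates as top-k PCs of the genotype-residual matrix.

    Regresses the genotype design out of each gene, then takes the k
    leading right-singular vectors of the residual matrix. By
    construction the surrogates are orthogonal to the fitted genotype
    means. Deterministic up to sign; sign fixed as in PCA.
    """
    X = design_matrix(samples).to_numpy()
    n, p = X.shape
    if k == 0:
        return np.empty((n, 0))
    if k >= n - p:
        raise ValueError(f"k={k} must be < residual df {n - p}")
    Y = log_matrix.to_numpy(float)
    H = X @ np.linalg.pinv(X)
    R = Y - Y @ H.T
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    sv = Vt[:k, :].T
    for i in range(k):
        j = int(np.argmax(np.abs(sv[:, i])))
        if sv[j, i] < 0:
            sv[:, i] *= -1
    return sv


# ---------------------------------------------------------------------------
# Per-gene linear model

@dataclass
class FitResult:
    coef: pd.DataFrame          # genes x design columns
    s2: pd.Series               # residual variance per gene
    df_residual: float
    stderr_unit: pd.DataFrame   # per-contrast sqrt(c' (X'X)^-1 c)
    contrasts: pd.DataFrame     # genes x contrasts, log2FC


def fit_models(log_matrix: pd.DataFrame, design: pd.DataFrame) -> FitResult:
    """Ordinary least squares per gene; pairwise genotype contrasts."""
    X = design.to_numpy(float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if n <= p:
        raise ValueError("no residual degrees of freedom")
    Y = log_matrix.to_numpy(float)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv.T                      # genes x p
    resid = Y - B @ X.T
    df = n - p
    s2 = (resid ** 2).sum(axis=1) / df

    cols = list(design.columns)
    cvecs, units, names = [], [], []
    for name in CONTRASTS:
        a, b = name.split("-")
        c = np.zeros(p)
        c[cols.index(a)] = 1.0
        c[cols.index(b)] = -1.0
        cvecs.append(c)
        units.append(float(np.sqrt(c @ XtX_inv @ c)))
        names.append(name)
    C = np.stack(cvecs, axis=1)
    contrasts = pd.DataFrame(B @ C, index=log_matrix.index, columns=names)
    return FitResult(
        coef=pd.DataFrame(B, index=log_matrix.index, columns=cols),
        s2=pd.Series(s2, index=log_matrix.index, name="s2"),
        df_residual=float(df),
        stderr_unit=pd.DataFrame([units], columns=names),
        contrasts=contrasts,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection."""
    if y <= 0:
        return np.inf
    lo, hi = 1e-8, 1e8
    while special.polygamma(1, lo) < y:
        lo /= 10
        if lo < 1e-300:
            return lo
    while special.polygamma(1, hi) > y:
        hi *= 10
    while hi - lo > _TRIGAMMA_TOL * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments (d0, s0^2) from gene residual variances.

    Matches the mean and variance of log s_g^2 to the scaled-F model:
    z = log s^2 has variance trigamma(d/2) + trigamma(d0/2) and mean
    log s0^2 + digamma(d/2) - digamma(d0/2) + log(d0/d). Zero excess
    variance (all s^2 essentially equal) gives d0 = inf and the pooled
    variance.
    """
    s2 = np.asarray(s2, float)
    s2 = s2[s2 > 0]  # exactly-zero variances (undetected genes) carry no
    # information about the prior scale and would blow up the log moments
    if len(s2) < 10:
        raise ValueError("need >= 10 genes with positive residual variance "
                         "to estimate the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    ebar = float(e.mean())
    excess = float(((e - ebar) ** 2).sum() / (len(e) - 1)
                   - special.polygamma(1, df / 2))
    if excess <= 0:
        return np.inf, float(np.exp(ebar))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2 * half_d0
    s02 = float(np.exp(ebar + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s02


@dataclass
class DEResult:
    table: pd.DataFrame         # gene, contrast, log2FC, t, p, fdr
    d0: float
    s02: float
    df_residual: float

    def for_contrast(self, contrast: str) -> pd.DataFrame:
        sub = self.table[self.table["contrast"] == contrast]
        return sub.set_index("gene")


def moderate(fit: FitResult, d0: float | None = None,
             s02: float | None = None) -> DEResult:
    """Moderated t statistics and BH-adjusted p values for all contrasts.

    s~^2 = (d0 s0^2 + d s^2) / (d0 + d); t~ = log2FC / (u * s~) with
    d0 + d degrees of freedom (u the contrast standard-error unit).
    d0 = 0 reduces to the ordinary t test; d0 = inf pools all genes.
    Pass d0/s02 to override the method-of-moments estimates.
    """
    d = fit.df_residual
    if d0 is None or s02 is None:
        e_d0, e_s02 = estimate_prior(fit.s2.to_numpy(), d)
        d0 = e_d0 if d0 is None else d0
        s02 = e_s02 if s02 is None else s02
    s2 = fit.s2.to_numpy()
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    rows = []
    for name in CONTRASTS:
        lfc = fit.contrasts[name].to_numpy()
        u = float(fit.stderr_unit[name].iloc[0])
        se = u * np.sqrt(s2_post)
        t = np.divide(lfc, se, out=np.zeros_like(lfc), where=se > 0)
        if np.isinf(df_total):
            p = 2 * stats.norm.sf(np.abs(t))
        else:
            p = 2 * stats.t.sf(np.abs(t), df_total)
        p = np.clip(p, np.nextafter(0, 1), 1.0)
        fdr = bh_fdr(p)
        rows.append(pd.DataFrame({
            "gene": fit.contrasts.index, "contrast": name,
            "log2FC": lfc, "t": t, "p": p, "fdr": fdr,
        }))
    table = pd.concat(rows, ignore_index=True)
    return DEResult(table=table, d0=float(d0), s02=float(s02),
                    df_residual=d)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(p, float)
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in (0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DEG lists and Venn partition

def select_degs(result: DEResult, contrast: str, direction: str,
                alpha: float = 0.05, lfc_min: float = 0.0) -> set[str]:
    """Directional DEG list for one pairwise contrast.

    ``direction`` "over" keeps genes with positive log2FC (first
    genotype higher), "under" negative; selection is p < alpha and
    |log2FC| > lfc_min.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    if direction not in ("over", "under"):
        raise ValueError(f"direction must be 'over' or 'under'")
    sub = result.for_contrast(contrast)
    sig = sub["p"] < alpha
    if direction == "over":
        keep = sig & (sub["log2FC"] > lfc_min)
    else:
        keep = sig & (sub["log2FC"] < -lfc_min)
    return set(sub.index[keep])


@dataclass
class VennPartition:
    """All 2^4 membership cells of four named gene sets, plus categories."""

    sets: dict[str, set[str]]
    cells: dict[tuple[bool, bool, bool, bool], set[str]]
    categories: dict[str, set[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {"".join("1" if b else "0" for b in key): len(v)
               for key, v in self.cells.items()}
        out.update({f"category:{k}": len(v) for k, v in self.categories.items()})
        return out


#: canonical set names: first genotype of the pair is the higher one
SET_NAMES = ("XX>XO", "XX>XY", "XY>XO", "XY<XO")


def venn_partition(sets: dict[str, set[str]]) -> VennPartition:
    """Partition the union of 4 directional DEG lists into 16 cells.

    Expects the four canonical comparison groups (``XX>XO``, ``XX>XY``,
    ``XY>XO``, ``XY<XO``). Dosage categories are computed from the
    cells:

    red           = (XX>XO) & (XX>XY) - (XY>XO) - (XY<XO)
    purple_solid  = (XX>XO) & (XY>XO) - (XX>XY)
    purple_broken = (XX>XY) & (XY>XO)
    brown         = (XX>XY) & (XY<XO)
    """
    unknown = set(sets) - set(SET_NAMES)
    if unknown:
        raise ValueError(f"unknown set name(s): {sorted(unknown)}")
    missing = set(SET_NAMES) - set(sets)
    if missing:
        raise ValueError(f"missing set(s): {sorted(missing)}")
    universe = set().union(*sets.values())
    cells: dict[tuple[bool, bool, bool, bool], set[str]] = {
        key: set() for key in product((False, True), repeat=4)}
    for g in universe:
        key = tuple(g in sets[name] for name in SET_NAMES)
        cells[key].add(g)

    s = {name: sets[name] for name in SET_NAMES}
    categories = {
        "red": (s["XX>XO"] & s["XX>XY"]) - s["XY>XO"] - s["XY<XO"],
        "purple_solid": (s["XX>XO"] & s["XY>XO"]) - s["XX>XY"],
        "purple_broken": s["XX>XY"] & s["XY>XO"],
        "brown": s["XX>XY"] & s["XY<XO"],
    }
    return VennPartition(sets=s, cells=cells, categories=categories)


def dosage_venn(result: DEResult, genes: set[str] | None = None,
                alpha: float = 0.05, lfc_min: float = 0.0) -> VennPartition:
    """The study's 4-list Venn on (a subset of) the tested genes.

    The four comparison groups come from the directional DEG lists:
    XX>XO and XX>XY (over in the XX-* contrasts), XY>XO (under in
    XO-XY) and XY<XO (over in XO-XY).
    """
    pick = {
        "XX>XO": select_degs(result, "XX-XO", "over", alpha, lfc_min),
        "XX>XY": select_degs(result, "XX-XY", "over", alpha, lfc_min),
        "XY>XO": select_degs(result, "XO-XY", "under", alpha, lfc_min),
        "XY<XO": select_degs(result, "XO-XY", "over", alpha, lfc_min),
    }
    if genes is not None:
        pick = {k: v & genes for k, v in pick.items()}
    return venn_partition(pick)
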