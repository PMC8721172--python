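"""ERCC spike-in normalization, log transform, and expression QC.

Size factors anchor each sample's counts to the known number of spike-in
molecules added per sample: factor_s is the median, over detected
spikes, of observed count / expected molecules, rescaled so the
geometric mean of the factors is 1. Normalized expression is
count / factor; log expression is log2(normalized + pseudocount).

QC mirrors the study: PCA on centered log expression and a Spearman
correlation distance matrix over the top 500 highly expressed, most
variable genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23

#: minimum detected spikes per sample for a stable median ratio
MIN_SPIKES = 8


def expected_molecules(attomoles: float) -> float:
    """Molecule number for a given attomole amount (attomoles * 1e-18 * N_A)."""
    if attomoles < 0:
        raise ValueError(f"attomoles must be >= 0, got {attomoles}")
    return attomoles * 1e-18 * AVOGADRO


def make_spike_design(spike_ids: list[str],
                      total_attomoles: float = 4.7) -> pd.DataFrame:
    """Nominal per-spike amounts for a Mix-1-like ladder.

    The study adds 4.7 attomoles of ERCC Mix 1 (after a 220,000-fold
    dilution) per sample; individual spikes span a wide concentration
    ladder. Amounts here follow a geometric ladder over ~3.5 decades,
    scaled to the stated total.
    """
    n = len(spike_ids)
    ladder = np.exp(np.linspace(np.log(1.0), np.log(3000.0), n))
    amounts = ladder / ladder.sum() * total_attomoles
    df = pd.DataFrame({"spike_id": spike_ids, "attomoles": amounts})
    df["expected_molecules"] = [expected_molecules(a) for a in df["attomoles"]]
    return df


def size_factors(counts: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Per-sample size factors from spike counts vs expected molecules.

    factor_s = median over detected spikes of count(spike, s) /
    expected_molecules(spike), rescaled to geometric mean 1. Requires at
    least MIN_SPIKES detected (count > 0) spikes per sample.
    """
    design = design.set_index("spike_id") if "spike_id" in design.columns else design
    spikes = design.index.intersection(counts.index)
    expected = design.loc[spikes, "expected_molecules"].to_numpy(float)
    usable = expected > 0
    spikes, expected = spikes[usable], expected[usable]
    raw = {}
    for s in counts.columns:
        obs = counts.loc[spikes, s].to_numpy(float)
        det = obs > 0
        if det.sum() < MIN_SPIKES:
            raise ValueError(
                f"sample {s}: only {int(det.sum())} detected spikes "
                f"(need >= {MIN_SPIKES}) for size-factor estimation")
        raw[s] = float(np.median(obs[det] / expected[det]))
    f = pd.Series(raw, name="size_factor")
    return f / np.exp(np.mean(np.log(f)))


@dataclass
class NormalizedMatrix:
    normalized: pd.DataFrame
    log_matrix: pd.DataFrame
    size_factors: pd.Series
    pseudocount: float = 1.0


def normalize(counts: pd.DataFrame, factors: pd.Series,
              pseudocount: float = 1.0) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor; log2(x + pc)."""
    if (factors <= 0).any():
        raise ValueError("size factors must be > 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    normalized = counts / factors.reindex(counts.columns)
    log_matrix = np.log2(normalized + pseudocount)
    return NormalizedMatrix(normalized=normalized, log_matrix=log_matrix,
                            size_factors=factors, pseudocount=pseudocount)


def top_variable_genes(log_matrix: pd.DataFrame, n: int = 500) -> list[str]:
    """The n most variable genes among those with above-median mean.

    "Highly and differentially expressed" is operationalized as a
    high-mean filter (mean log expression above the across-gene median)
    followed by ranking on across-sample variance; ties break on
    feature_id for determinism.
    """
    if n > len(log_matrix):
        raise ValueError(f"n={n} exceeds {len(log_matrix)} features")
    mean = log_matrix.mean(axis=1)
    high = log_matrix.loc[mean > mean.median()]
    if len(high) < n:
        high = log_matrix
    var = high.var(axis=1, ddof=1)
    order = sorted(high.index, key=lambda g: (-var[g], g))
    return order[:n]


def spearman_distance(log_matrix: pd.DataFrame,
                      features: list[str] | None = None) -> pd.DataFrame:
    """Sample-sample distance 1 - Spearman rho over the given features."""
    sub = log_matrix.loc[features] if features is not None else log_matrix
    if len(sub) < 3:
        raise ValueError("need >= 3 features for a rank correlation")
    if (sub.std(axis=0) == 0).any():
        warnings.warn("constant sample column(s); distance set to 1",
                      RuntimeWarning, stacklevel=2)
    rho = sub.corr(method="spearman")  # average-rank ties; NaN if constant
    d = 1.0 - rho.to_numpy()
    d[np.isnan(d)] = 1.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=sub.columns, columns=sub.columns)


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x components
    variance_explained: np.ndarray


def pca_qc(log_matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """Per-feature-centered SVD of the samples.

    Scores are deterministic up to sign; the sign is fixed so each
    component's largest-magnitude loading is positive.
    """
    if log_matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    X = log_matrix.to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(len(S), n_components or len(S))
    # sign convention: largest-|loading| entry of each left vector positive
    for i in range(k):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] *= -1
            Vt[i, :] *= -1
    total = float((S ** 2).sum())
    ve = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    scores = pd.DataFrame(
        (Vt[:k, :] * S[:k, None]).T, index=log_matrix.columns,
        columns=[f"PC{i + 1}" for i in range(k)])
    return PcaResult(scores=scores, variance_explained=ve)
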