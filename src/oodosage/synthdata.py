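"""Synthetic data generator for the XX / XO / XY oocyte dosage pipeline.

Emulates the study design end to end so every downstream stage can be
tested without downloading real sequencing data: a gene universe spread
over autosomes, the X and Y chromosomes, the pseudoautosomal region (PAR)
and ERCC spike-ins; genotype-specific true mean expression encoding
X-dosage-dependent, dosage-compensated, Y-expressed and PAR classes;
UMI count matrices with multiplicative (lognormal) biological noise,
Poisson molecule sampling and per-sample library factors; and tagged
5' reads (anchor + 12-nt UMI + fixed bases + G-stretch + cDNA) in FASTQ
with a ground-truth read map.

The per-allele transcription model sets the true dosage ratio: a gene
whose expression follows X-chromosome copy number has XO and XY means
equal to ``rho`` times the XX mean (default ``rho = 0.5``, one active
X allele instead of two), while dosage-compensated genes are equal
across genotypes. Y-linked classes are zero in XX and XO.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

GENOTYPES = ("XX", "XO", "XY")

AUTOSOMES = tuple(str(i) for i in range(1, 20))

#: truth classes by feature class; fractions are deterministic (largest-
#: remainder rounding), so e.g. a 0.5 dosage fraction over 20 X genes
#: yields exactly 10 dosage_dependent labels.
DEFAULT_CLASS_FRACTIONS: dict[str, dict[str, float]] = {
    "autosomal": {"neutral": 1.0},
    "x_linked": {"dosage_dependent": 0.5, "compensated": 0.5},
    "y_linked": {"y_high": 0.25, "y_medium": 0.5, "y_silent": 0.25},
    "par": {"par_xy_up": 1.0},
    "spike": {"spike": 1.0},
}


@dataclass
class TruthParams:
    """Global parameters of the true-expression model.

    dosage_ratio
        rho: XO (= XY) over XX mean for dosage-dependent genes; per-allele
        transcription gives 0.5.
    base_gm, base_sdlog
        lognormal baseline for per-gene mean molecules per sample; the
        default sdlog spans >4 orders of magnitude so 6 expression bins
        are non-degenerate.
    bio_sdlog
        multiplicative biological noise (lognormal sdlog) on true means,
        per gene x sample; spike-ins get 0 (technical noise only).
    lib_sdlog
        per-sample library/capture factor spread (lognormal sdlog).
    batch_effect
        multiplicative log2 shift applied to a random subset of genes in
        the second batch (0 disables batching).
    batch_gene_fraction
        fraction of genes affected by the batch shift.
    spike_fraction
        target fraction of total molecules contributed by spike-ins;
        the study's dilution aims at 3-6 % of reads.
    y_high_floor
        minimum XY mean for y_high genes (molecules), keeping their
        XY-vs-XX log2 fold change above the "high" boundary.
    """

    dosage_ratio: float = 0.5
    base_gm: float = 20.0
    base_sdlog: float = 2.4
    bio_sdlog: float = 0.2
    lib_sdlog: float = 0.15
    batch_effect: float = 0.0
    batch_gene_fraction: float = 0.3
    spike_fraction: float = 0.045
    y_high_floor: float = 64.0
    par_xy_gain: float = 2.0


@dataclass
class TruthTable:
    """Per-feature true mean molecules per genotype plus global params."""

    means: pd.DataFrame  # index feature_id, columns XX, XO, XY
    params: TruthParams


@dataclass
class TagPattern:
    """Layout of the modified Smart-seq3 5' tag.

    A tagged read begins with the template-switching-oligo anchor, a
    12-nt random UMI, the fixed post-UMI bases, then >=2 template-switch
    G's, followed by cDNA.
    """

    anchor: str = "AGATGTGTATAAGAGACAG"
    umi_length: int = 12
    post_umi: str = "ACG"
    min_g_stretch: int = 2
    max_start_offset: int = 5
    allowed_mismatches_in_anchor: int = 1

    def __post_init__(self) -> None:
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if not self.anchor:
            raise ValueError("anchor must be non-empty")
        if self.max_start_offset < 0:
            raise ValueError("max_start_offset must be >= 0")

    def min_read_length(self) -> int:
        return (len(self.anchor) + self.umi_length + len(self.post_umi)
                + self.min_g_stretch)


def _largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Deterministically convert fractions into integer counts summing to n."""
    items = sorted(fractions.items())
    total = sum(f for _, f in items)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions sum to {total}, expected 1")
    raw = [(name, f * n) for name, f in items]
    counts = {name: int(np.floor(x)) for name, x in raw}
    short = n - sum(counts.values())
    # hand out the remainder by largest fractional part, ties by name
    order = sorted(raw, key=lambda t: (-(t[1] - np.floor(t[1])), t[0]))
    for name, _ in order[:short]:
        counts[name] += 1
    return counts


def _positions(rng: np.random.Generator, n: int, lo: int = 1) -> np.ndarray:
    """Strictly increasing 1-based positions via cumulative random gaps."""
    gaps = rng.integers(1_000, 500_000, size=n)
    return lo + np.cumsum(gaps)


def make_annotation(
    n_autosomal: int,
    n_x: int,
    n_y: int,
    n_par: int,
    n_spikes: int,
    class_fractions: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    n_homolog_groups: int | None = None,
) -> pd.DataFrame:
    """Build a synthetic gene annotation table.

    Returns a DataFrame with columns feature_id, chromosome, start_bp,
    feature_class, truth_class, homolog_group. PAR features are split
    between the X (``par_x``) and Y (``par_y``) copies; ``par_y`` rows
    are placed distal to every ``y_linked`` position. Homolog groups
    pair an X-linked gene with a Y-linked gene (and their autosomal
    paralogs are allowed but not generated by default).
    """
    for name, n in [("n_autosomal", n_autosomal), ("n_x", n_x), ("n_y", n_y),
                    ("n_par", n_par), ("n_spikes", n_spikes)]:
        if n < 0:
            raise ValueError(f"{name} must be >= 0, got {n}")
    fr = dict(DEFAULT_CLASS_FRACTIONS)
    if class_fractions:
        fr.update(class_fractions)
    rng = np.random.default_rng(seed)

    rows: list[dict] = []

    def add_features(prefix, n, chromosome_of, feature_class_of, truth_classes):
        classes = []
        for cls, k in sorted(_largest_remainder_counts(truth_classes, n).items()):
            classes += [cls] * k
        classes = list(rng.permutation(classes))
        for i in range(n):
            rows.append({
                "feature_id": f"{prefix}{i:05d}",
                "chromosome": chromosome_of(i),
                "feature_class": feature_class_of(i),
                "truth_class": classes[i],
            })

    # autosomes: round-robin over chromosomes 1..19
    add_features("gA", n_autosomal, lambda i: AUTOSOMES[i % len(AUTOSOMES)],
                 lambda i: "autosomal", fr["autosomal"])
    add_features("gX", n_x, lambda i: "X", lambda i: "x_linked", fr["x_linked"])
    add_features("gY", n_y, lambda i: "Y", lambda i: "y_linked", fr["y_linked"])
    n_par_x = (n_par + 1) // 2
    add_features("gP", n_par, lambda i: "X" if i < n_par_x else "Y",
                 lambda i: "par_x" if i < n_par_x else "par_y", fr["par"])
    add_features("ERCC-", n_spikes, lambda i: "ERCC", lambda i: "spike",
                 fr["spike"])

    annot = pd.DataFrame(rows)
    if annot.empty:
        annot = pd.DataFrame(columns=["feature_id", "chromosome", "start_bp",
                                      "feature_class", "truth_class",
                                      "homolog_group"])
        return annot

    # positions: strictly increasing within each chromosome; par_y distal
    # to all y_linked positions.
    annot["start_bp"] = 0
    for chrom, idx in annot.groupby("chromosome").groups.items():
        sub = annot.loc[idx]
        if chrom == "Y":
            y_idx = sub.index[sub["feature_class"] == "y_linked"]
            p_idx = sub.index[sub["feature_class"] == "par_y"]
            pos = _positions(rng, len(y_idx))
            annot.loc[y_idx, "start_bp"] = pos
            lo = int(pos[-1]) if len(pos) else 1
            annot.loc[p_idx, "start_bp"] = _positions(rng, len(p_idx), lo=lo + 1)
        else:
            annot.loc[idx, "start_bp"] = _positions(rng, len(idx))
    annot["start_bp"] = annot["start_bp"].astype(int)

    # homolog groups: pair X-linked genes with expressed Y-linked genes
    annot["homolog_group"] = pd.NA
    x_ids = annot.index[annot["feature_class"] == "x_linked"]
    y_ids = annot.index[(annot["feature_class"] == "y_linked")
                        & (annot["truth_class"] != "y_silent")]
    k = min(len(x_ids), len(y_ids))
    if n_homolog_groups is not None:
        k = min(k, n_homolog_groups)
    for g in range(k):
        annot.loc[x_ids[g], "homolog_group"] = f"hg{g:03d}"
        annot.loc[y_ids[g], "homolog_group"] = f"hg{g:03d}"

    annot = annot[["feature_id", "chromosome", "start_bp", "feature_class",
                   "truth_class", "homolog_group"]].reset_index(drop=True)
    if annot["feature_id"].duplicated().any():
        raise AssertionError("duplicate feature_ids generated")
    return annot


def simulate_truth(annotation: pd.DataFrame,
                   params: TruthParams | None = None,
                   seed: int = 0) -> TruthTable:
    """Draw genotype-specific true mean molecule numbers per feature.

    Class rules hold exactly: y_* and par_y classes are zero in XX and XO;
    dosage_dependent genes have XO = XY = rho * XX; compensated, neutral
    and spike genes are equal across genotypes; par genes gain expression
    in XY (extra Y copy plus boundary up-regulation).
    """
    params = params or TruthParams()
    if not 0 < params.dosage_ratio <= 1:
        raise ValueError(f"dosage_ratio must be in (0, 1], got {params.dosage_ratio}")
    rng = np.random.default_rng(seed)
    n = len(annotation)
    base = rng.lognormal(mean=np.log(params.base_gm), sigma=params.base_sdlog,
                         size=n)
    means = pd.DataFrame(0.0, index=annotation["feature_id"].to_numpy(),
                         columns=list(GENOTYPES))
    cls = annotation["truth_class"].to_numpy()

    def set_means(mask, xx, xo, xy):
        means.iloc[mask, 0] = xx
        means.iloc[mask, 1] = xo
        means.iloc[mask, 2] = xy

    rho = params.dosage_ratio
    m = cls == "dosage_dependent"
    set_means(m, base[m], rho * base[m], rho * base[m])
    for c in ("compensated", "neutral"):
        m = cls == c
        set_means(m, base[m], base[m], base[m])
    m = cls == "y_high"
    hi = np.maximum(base[m], params.y_high_floor)
    set_means(m, 0.0, 0.0, hi)
    m = cls == "y_medium"
    set_means(m, 0.0, 0.0, rng.uniform(1.0, 3.0, size=m.sum()))
    # y_silent stays all-zero
    m = (cls == "par_xy_up") & (annotation["feature_class"] == "par_x").to_numpy()
    set_means(m, base[m], base[m], params.par_xy_gain * base[m])
    m = (cls == "par_xy_up") & (annotation["feature_class"] == "par_y").to_numpy()
    set_means(m, 0.0, 0.0, base[m])

    # spikes: equal across genotypes and samples; a fixed ladder scaled so
    # spike molecules hit the target fraction of the genotype-average total.
    m = cls == "spike"
    n_spk = int(m.sum())
    if n_spk:
        ladder = np.exp(np.linspace(np.log(1.0), np.log(3000.0), n_spk))
        gene_total = float(means.loc[:, list(GENOTYPES)].to_numpy()[~m].sum()
                           / len(GENOTYPES))
        f = params.spike_fraction
        scale = f / (1 - f) * gene_total / ladder.sum() if gene_total > 0 else 1.0
        spk = ladder * scale
        set_means(m, spk, spk, spk)

    return TruthTable(means=means, params=params)


@dataclass
class SampleFactors:
    """Ground-truth per-sample technical factors, for recovery tests."""

    lib_factor: pd.Series
    batch: pd.Series
    batch_genes: pd.Index


def make_samples(n_replicates: int = 3, n_batches: int = 1) -> pd.DataFrame:
    """Default sample sheet: biological triplicate per genotype.

    Batches follow replicate sets (each batch processes one replicate of
    every genotype), so batch composition is identical across genotypes.
    """
    rows = []
    for g in GENOTYPES:
        for r in range(1, n_replicates + 1):
            rows.append({"sample_id": f"{g}{r}", "genotype": g,
                         "replicate": r,
                         "batch": f"b{(r - 1) % n_batches + 1}"})
    return pd.DataFrame(rows)


def simulate_counts(
    truth: TruthTable,
    samples: pd.DataFrame,
    seed: int = 0,
    poisson: bool = True,
) -> tuple[pd.DataFrame, SampleFactors]:
    """Sample a UMI count matrix from the truth table.

    count(g, s) ~ Poisson(mean_{g,genotype(s)} * lib_s * exp(eps)),
    eps ~ Normal(0, bio_sdlog^2) per gene x sample; spikes use sdlog 0,
    so their variation is purely technical. ``poisson=False`` is a debug
    switch that returns rounded noiseless expectations.
    Returns the counts (features x samples) and the true sample factors.
    """
    p = truth.params
    for g in GENOTYPES:
        if not (samples["genotype"] == g).any():
            raise ValueError(f"no sample with genotype {g}")
    rng = np.random.default_rng(seed)
    feats = truth.means.index
    is_spike = np.asarray(feats.str.startswith("ERCC-"))

    lib = pd.Series(
        rng.lognormal(mean=0.0, sigma=p.lib_sdlog, size=len(samples)),
        index=samples["sample_id"].to_numpy(), name="lib_factor")
    batches = sorted(samples["batch"].unique())
    batch_genes = pd.Index([])
    if p.batch_effect != 0 and len(batches) > 1:
        gene_pool = feats[~is_spike]
        k = int(round(p.batch_gene_fraction * len(gene_pool)))
        batch_genes = pd.Index(rng.choice(gene_pool, size=k, replace=False))

    counts = np.zeros((len(feats), len(samples)), dtype=np.int64)
    for j, row in enumerate(samples.itertuples(index=False)):
        mu = truth.means[row.genotype].to_numpy().copy()
        lam = mu * lib.iloc[j]
        if p.bio_sdlog > 0:
            eps = rng.normal(0.0, p.bio_sdlog, size=len(feats))
            eps[is_spike] = 0.0
            lam = lam * np.exp(eps)
        if len(batch_genes) and row.batch != batches[0]:
            shift = np.isin(feats, batch_genes)
            lam = lam * np.where(shift, 2.0 ** p.batch_effect, 1.0)
        counts[:, j] = rng.poisson(lam) if poisson else np.round(lam)

    mat = pd.DataFrame(counts, index=feats,
                       columns=samples["sample_id"].to_numpy())
    factors = SampleFactors(lib_factor=lib,
                            batch=pd.Series(samples["batch"].to_numpy(),
                                            index=lib.index, name="batch"),
                            batch_genes=batch_genes)
    return mat, factors


# ---------------------------------------------------------------------------
# Tagged-read (FASTQ) simulation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


def _apply_errors(rng: np.random.Generator, seq: np.ndarray,
                  error_rate: float) -> np.ndarray:
    """Substitution errors at error_rate per base on a uint8 sequence array."""
    if error_rate <= 0:
        return seq
    hit = rng.random(seq.shape) < error_rate
    # shift each hit base by 1..3 in the ACGT alphabet (never identity)
    idx = np.searchsorted(_BASES, seq[hit])
    seq = seq.copy()
    seq[hit] = _BASES[(idx + rng.integers(1, 4, size=int(hit.sum()))) % 4]
    return seq


def simulate_reads(
    counts: pd.DataFrame,
    tag: TagPattern | None = None,
    error_rate: float = 0.0,
    untagged_fraction: float = 0.5,
    seed: int = 0,
    cdna_length: int = 60,
    out: io.TextIOBase | None = None,
) -> tuple[io.TextIOBase, pd.DataFrame]:
    """Emit one tagged 5' read per counted molecule, plus untagged reads.

    Each molecule gets a UMI drawn uniformly from the 4^12 12-mers
    (collisions allowed) and one read laid out as
    anchor + UMI + post_umi + GGG + cDNA. Untagged internal reads are
    added as a Poisson(u/(1-u)) count per molecule so that the expected
    untagged fraction of all reads equals ``untagged_fraction``.
    Substitution errors are applied at ``error_rate`` per base.

    Returns (FASTQ text stream, truth map) where the truth map has
    columns read_id, sample_id, truth_gene, truth_umi (umi empty for
    untagged reads). Pass a writable text handle as ``out`` to stream
    records to disk instead of an in-memory buffer; the handle is
    returned as given (in-memory buffers are rewound).
    """
    tag = tag or TagPattern()
    if not (0 <= error_rate < 1) or not (0 <= untagged_fraction < 1):
        raise ValueError("error_rate and untagged_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    fastq = out if out is not None else io.StringIO()
    truth_rows: list[tuple[str, str, str, str]] = []
    prefix = (tag.anchor + "{umi}" + tag.post_umi + "G" * 3)
    # deterministic per-gene cDNA 5' sequence
    gene_cdna = {g: _random_dna(rng, cdna_length) for g in counts.index}
    u = untagged_fraction
    lam_untag = u / (1 - u)
    serial = 0
    for sample in counts.columns:
        col = counts[sample]
        nz = col[col > 0]
        for gene, n_mol in nz.items():
            n_mol = int(n_mol)
            umis_int = rng.integers(0, 4 ** tag.umi_length, size=n_mol)
            n_untag = rng.poisson(lam_untag, size=n_mol) if lam_untag > 0 else \
                np.zeros(n_mol, dtype=int)
            for i in range(n_mol):
                umi = _int_to_umi(int(umis_int[i]), tag.umi_length)
                seq = prefix.format(umi=umi) + gene_cdna[gene]
                arr = _apply_errors(
                    rng, np.frombuffer(seq.encode(), dtype=np.uint8),
                    error_rate)
                rid = f"r{serial:08d}"
                serial += 1
                _write_fastq(fastq, rid, bytes(arr).decode())
                truth_rows.append((rid, sample, gene, umi))
                for _ in range(int(n_untag[i])):
                    iseq = _random_dna(rng, len(seq))
                    rid = f"r{serial:08d}"
                    serial += 1
                    _write_fastq(fastq, rid, iseq)
                    truth_rows.append((rid, sample, gene, ""))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "sample_id",
                                              "truth_gene", "truth_umi"])
    if out is None:
        fastq.seek(0)
    return fastq, truth


def _int_to_umi(x: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = _BASES[x & 3]
        x >>= 2
    return out.decode()


def _write_fastq(buf: io.StringIO, rid: str, seq: str) -> None:
    buf.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def truth_params_to_dict(p: TruthParams) -> dict:
    return asdict(p)
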