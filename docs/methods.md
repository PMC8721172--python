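# Methods

## The scientific setting

XX, XO and XY mouse oocytes differ in X-chromosome copy number (2, 1, 1)
and in Y presence. Because growing oocytes reactivate the X, transcript
levels of an X-linked gene can either track copy number (XO and XY at
half the XX level) or be compensated (equal across genotypes). The
pipeline quantifies this from 5'-UMI RNA-seq: each cDNA molecule carries
a 12-nt unique molecular identifier in its 5' tag, so PCR duplicates
collapse to single molecule counts, and ERCC spike-ins added at a known
amount per sample anchor absolute normalization. The package implements
the full computational chain and a generator that emulates the study
design closely enough for every stage to be validated against planted
ground truth.

## Synthetic-data model

Per-gene baseline means are lognormal, `exp(N(log 20, 2.4²))` molecules
per sample, spanning more than four orders of magnitude so that six
expression bins are non-degenerate. Genotype rules are exact by
construction: dosage-dependent genes have XO = XY = ρ·XX with ρ = 0.5
(one active allele instead of two); compensated, neutral and spike
features are equal across genotypes; Y-linked classes are zero in XX and
XO; PAR features gain expression in XY (the Y copy plus boundary
up-regulation, default 2× on the X copy). Default truth-class mixture:
X-linked genes split 50/50 dosage-dependent/compensated; Y-linked genes
25 % high, 50 % medium, 25 % silent, echoing the observed pattern of a
few strongly expressed short-arm genes, many medium repetitive genes,
and silenced classics.

Counts are Poisson–lognormal:
`count(g, s) ~ Poisson(mean · lib_s · exp(ε))`, ε ~ N(0, sdlog²) with
sdlog = 0.2 biological noise per gene × sample, and lognormal per-sample
library factors (sdlog 0.15). Spike-ins receive no biological noise, so
technical and biological variance are separable — this is why the noise
model is Poisson-lognormal rather than a negative binomial with a single
dispersion: the spike rows must be Poisson-only for size-factor recovery
tests to have an exact target. Spike amounts follow a fixed geometric
ladder scaled so spike molecules are ~4.5 % of the total, inside the
3–6 % window the protocol aims for. An optional batch effect multiplies
a random 30 % of genes in the non-reference batch; batches follow
replicate sets (each batch contains one replicate of every genotype), so
batch is balanced across genotypes — an unbalanced batch would be
partially confounded with the genotype contrasts and uncorrectable by
any residual-space surrogate.

Reads: one tagged 5' read per molecule
(`anchor + UMI + ACG + GGG + cDNA`), UMIs uniform over 4¹² (collisions
allowed and uncorrected — negligible at the scales used), untagged
internal reads added as Poisson(u/(1−u)) per molecule so the expected
untagged fraction is u (default 0.5, a guess exposed in config; the
protocol does not report it), substitution errors at a per-base rate.
Reads are single-end: only the tagged 5' read carries quantification
signal in this design, so the mate contributes nothing and is omitted.

What the generator does **not** emulate: genome sequence, alignment
ambiguity or multimapping (gene assignment is ground truth, standing in
for an external aligner), gene length and GC effects, amplification
bias, cell-to-cell heterogeneity within the 30-oocyte pools, and any
expression-dependence of the compensated/dosage-dependent split.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under a faithful noise model, not robustness
to alignment or library-prep artifacts.

## Tag extraction and UMI counting

The anchor may start at offsets 0–5 with at most one substitution
(lowest qualifying offset wins); the UMI must be 12 N-free bases; the
post-UMI `ACG` is exact; at least two template-switch G's are required
and consumed greedily, so the reported cDNA start never begins with a
G of the tag. The mismatch tolerance and offset window are decisions —
the original regular expressions are not recoverable — and are
configurable in `TagPattern`. An N in the UMI is a no-match, avoiding
dedup ambiguity. Counting is by exact (gene, sample, UMI) identity;
a directional Hamming-1 collapse is provided but off by default since
no UMI error correction is described for the original analysis.

## Normalization

Size factor per sample: median over detected spikes of
observed count / expected molecules, rescaled to geometric mean 1.
The median ratio is robust, uses the only stated anchor (spike-ins with
known input), and avoids inventing regression weights. Whether the
original analysis normalized to per-spike expectations or spike totals
is unknowable from the text; with ≥ 8 detected spikes required per
sample the median-ratio choice is stable either way. The stated
"4.7 attomoles of Mix 1" is read as the total spike input per sample,
distributed over spikes by a concentration ladder (config input).
`log2(x + 1)` stands in for the original (unpublished) log-voom-variant
transform; the pseudocount is configurable. The "top 500 highly and
differentially expressed genes" rule is operationalized as: restrict to
genes with above-median mean log expression, rank by variance, ties by
feature id.

## Differential expression

Per-gene OLS on a cell-means genotype design; contrasts XX−XO, XX−XY,
XO−XY. Surrogate covariates (a simplified stand-in for full surrogate
variable analysis, which iterates reweighted estimation) are the top-k
right-singular vectors of the residual matrix after projecting out
genotype: the original usage only requires covariates to include in the
linear model, and this version is directly testable against planted
batches. k defaults to 0; a parallel-analysis style choice (compare
residual singular values against permuted data) is sensible when batch
structure is suspected, and the planted-batch tests show k = 1 restores
type-I calibration that a batch effect destroys.

Moderation follows the standard empirical-Bayes treatment of gene-wise
variances: s²_g ~ s̃² χ²_d/d with a scaled-inverse-χ² prior (d₀, s₀²).
Hyperparameters come from method of moments on log s²: with
e_g = log s²_g − ψ(d/2) + log(d/2), the excess of Var(e) over ψ′(d/2)
equals ψ′(d₀/2), inverted by bisection to 10⁻¹⁰; zero or negative
excess takes the d₀ = ∞ branch (all genes share the pooled variance,
normal reference distribution). Genes with exactly zero residual
variance (undetected rows) are excluded from the moment estimation —
their log-variances are −∞ and would destroy the prior — but still
receive moderated statistics. The moderated t has d₀ + d degrees of
freedom; d₀ = 0 reproduces the ordinary t exactly (a tested identity).

DEG lists are directional at p < α (α = 0.05), with an optional
|log₂FC| > 1 gate used for the Y-focused comparisons. The Venn
partition takes the four comparison groups XX>XO, XX>XY, XY>XO, XY<XO
over one gene universe (X-linked and autosomal genes are partitioned
separately), computes all 16 membership cells, and derives the named
categories: red (XX above both single-X genotypes, XO ~ XY — the
X-dosage-dependent set), purple solid (XX and XY above XO), purple
broken (XX > XY > XO), brown (XY below both).

## Dosage statistics

Ratios use a 0.5-normalized-unit pseudocount on both numerator and
denominator; Y-linked genes have true zeros in XX/XO, and the original
handling is unstated. Genotype summaries are arithmetic means of
replicates for the bootstrap statistics ("mean transcript levels") and
geometric means for the ratio fit and homolog summaries ("geometric
mean of the replicate data") — each quoted procedure names its own
summary. The lognormal ratio fit reports exp(mean log ratio)
(geometric mean), the SD of log ratios, the multiplicative-SD interval
(gm/e^sd, gm·e^sd) and a 95 % t-interval on the mean log.

Bins: genes sorted by pooled-genotype mean normalized expression
(ties by feature id) and cut into six contiguous groups whose sizes
differ by at most one; binning on pooled rather than per-genotype
expression keeps gene membership constant across genotypes. The
bootstrap draws 100 X-linked and 100 autosomal genes with replacement
within a bin — independently, since the strata share no genes — takes
the median of each draw per genotype, and emits the X:A ratio; 5,000
reps, seeded per (bin, genotype) from one stage seed. The bin-6
genotype bootstrap resamples top-bin X genes once per rep and divides
the median XO (or XY) mean by the median XX mean of the same draw.
The Y-gene classes apply the quoted boundaries exactly (≥ 3 high,
1 < · < 3 medium, ≤ 1 none) to log₂((XY+pc)/(XX+pc)); BH-adjusted
p values from the XX−XY contrast are attached within the Y-gene subset.
Homolog sums add member geometric means per genotype, so a Y gametolog
contributes only in XY and can raise the X+Y sum to the XX level.

## qPCR

Relative level is efficiency^(−ΔCq) with ΔCq = Cq(gene) − Cq(reference)
and efficiency fixed at 2 (no standard curves are reported;
configurable in (1, 2]). Group comparisons: Welch t, one-way ANOVA with
Tukey's HSD (studentized range, via scipy), or Kruskal–Wallis followed
by Dunn's rank-sum z tests with the tie-corrected variance and
Bonferroni adjustment over pairs (the multiplicity adjustment is not
named in the source of the procedure; Bonferroni is the conservative
default).

## Numerical and reproducibility choices

All randomness flows through numpy Generators seeded per stage;
bootstrap draws additionally fold the (bin, genotype) index into the
seed so adding bins never perturbs existing cells. TSV artifacts are
written with a fixed `%.10g` float format and JSON with sorted keys, so
a rerun with the same config is byte-identical; the config hash
excludes the output path. PCA and surrogate signs are fixed by making
each component's largest-magnitude loading positive. Spearman distances
treat a constant sample profile as correlation 0 (distance 1) with a
warning. Degenerate inputs fail fast with named errors (sample with
< 8 detected spikes, empty bootstrap stratum naming bin and stratum,
rank-deficient designs).

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the suite
completes in about a minute: full pipeline runs use ~1,300–5,000 genes,
9 samples and up to 5,000 bootstrap reps; read-level (FASTQ → demux)
runs use shallower libraries (base geometric mean 10, sdlog 1.5), which
also keeps every (gene, sample) molecule group far below the 4¹² UMI
space so truth-matrix recovery from error-free reads is exact rather
than approximate. Null-calibration checks use 10,000 genes; the
planted-dosage recovery benchmark uses 2,000 X genes (600 planted) at
a well-expressed panel (counts ≈ 250–4,000), mirroring the fact that
dosage-dependent DEG sets are composed of robustly detected genes —
at low counts the single variance prior under-serves Poisson-dominated
genes (precision weights are deliberately out of scope) and recovery
drops a few points.

## Known limitations

- Gene assignment is an input; no aligner is bundled, so misassignment
  and multimapping effects are untested.
- The log2(x+1) transform and median-ratio size factors are reasonable
  stand-ins for the original (unrecoverable) transform and an
  unstated normalization detail; absolute molecule estimates inherit
  whatever bias the spike capture efficiency has.
- The moderated test assumes homoskedastic log expression within a
  gene; for very low counts it is mildly miscalibrated (no voom-style
  weights by design).
- The bootstrap X:A ratio quantifies resampling noise, not gene-
  sampling noise: with few genes per stratum the per-bin median can sit
  several percent from its population value, which is why low-bin
  calibration statements pool bins 1–3.
- Selection by p < α biases fitted effect sizes of the selected set
  (the red-category ratio fit lands slightly below the true ρ).
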