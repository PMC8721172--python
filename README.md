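# oodosage

Sex-chromosome dosage analysis of mouse oocyte transcriptomes.

Growing mouse oocytes violate the usual rules of X-chromosome dosage
compensation: with the X reactivated before meiosis, XX oocytes carry two
active X chromosomes while XO and XY oocytes carry one. Comparing bulk
5'-UMI RNA-seq of XX, XO and XY oocytes (three biological replicates per
genotype, ERCC spike-ins as an absolute anchor) lets one ask, gene by gene,
whether transcript levels follow X copy number or are compensated, what the
ectopic Y chromosome expresses, and whether X/Y gametolog pairs sum to the
XX level.

`oodosage` packages that analysis as a reusable, fully tested pipeline with
a synthetic-data generator, so every stage runs and is verified without any
external download:

- **synthdata** — gene universe over autosomes / X / Y / PAR / ERCC spikes;
  genotype-specific true means encoding dosage-dependent (XO = XY = ρ·XX,
  ρ = 0.5 for per-allele transcription), compensated, Y-expressed and PAR
  classes; Poisson-lognormal UMI counts with per-sample library factors;
  tagged 5' reads in FASTQ with a ground-truth read map.
- **umi** — 5' tag detection (anchor `AGATGTGTATAAGAGACAG`, 12-nt UMI,
  `ACG`, G-stretch), UMI extraction, and deduplicated per-gene counting.
- **norm** — ERCC size factors (median ratio of observed counts to expected
  molecules, `attomoles × 10⁻¹⁸ × N_A`), log₂(x+1) expression, PCA QC and a
  top-500 Spearman-distance matrix.
- **de** — per-gene OLS on genotype (plus optional residual-PCA surrogate
  covariates for batch), empirical-Bayes moderated t
  (s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d), hyperparameters by method of moments
  on log s²), BH FDR, directional DEG lists at p < α, and the 4-list Venn
  partition into dosage categories (red = XX > XO and XX > XY with XO ~ XY,
  purple solid/broken, brown).
- **dosage** — lognormal ratio fits (geometric mean, multiplicative SD,
  95 % CI) of XO/XY : XX ratios along the X; six equal-size expression bins
  and the bootstrap X:A statistic (resample 100 genes with replacement from
  the X and autosomal strata, 5,000 reps, ratio of median expressions);
  bin-6 XO:XX / XY:XX bootstrap; Y-gene expression classes
  (high: log₂FC ≥ 3, medium: 1 < log₂FC < 3, none otherwise); homolog sums.
- **qpcr** — relative quantification `efficiency^(−ΔCq)` against a
  reference gene (*Ppia*-style), with Welch t, ANOVA + Tukey HSD, or
  Kruskal–Wallis + Dunn group comparisons.
- **pipeline / cli** — one YAML config, per-stage seeds, deterministic
  TSV/JSON artifacts (`oodosage run`, `simulate`, `demux`, `normalize`,
  `de`, `dosage`, `qpcr`).

## Worked example

```python
import oodosage as oo

config = oo.RunConfig(outdir="demo", n_autosomal=2000, n_x=200, n_y=40,
                      n_par=8, n_spikes=92, bootstrap_reps=5000)
report = oo.run_pipeline(config)

print(report["stages"]["de"]["red_x_genes"])
print(report["stages"]["dosage"]["ratio_fit"])
```

With the default generator (half of X genes dosage-dependent at ρ = 0.5,
biological noise sdlog 0.2, expression spanning four decades) this prints:

```
47
{'n': 94, 'geometric_mean': 0.4439..., 'sdlog': 0.2290...,
 'multiplicative_sd_interval': (0.3529..., 0.5583...),
 'ci_mean': (0.4238..., 0.4650...)}
```

47 X-linked genes land in the red (X-dosage-dependent) Venn category —
the well-expressed planted genes; detection of weakly expressed ones is
power-limited at n = 3. Their fitted XO/XY : XX geometric-mean ratio is
0.44 (95 % CI 0.42–0.47), recovering the planted per-allele ratio 0.5
with the mild downward selection bias that p-value-filtered effect sizes
carry. The same run writes, under `demo/`, the normalized matrix and size
factors, DE tables, Venn cells/categories as JSON, the bootstrap X:A
box-plot statistics per (bin, genotype), Y-gene classes and homolog
summaries; bin-6 bootstrap medians land at XO:XX ≈ 0.59 and XY:XX ≈ 0.67,
reflecting the dosage-dependent half of the X genes, while identical reruns
are byte-identical.

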