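# gausspower

Classification of gene-expression noise profiles along a Gaussian →
power-law spectrum, from replicated RNA-seq expression matrices.

## The problem

With 20+ biological replicates per condition, the distribution of a
gene's expression level across genetically identical individuals becomes
observable gene by gene. Those empirical distributions are not all
negative-binomial-shaped: some are Gaussian, some have long power-law-like
tails, and many sit in between. This package implements an analysis
pipeline that explains that spectrum with a single three-parameter family
— the **Gauss-power (G-P) mixing density** — derived as the stationary law
of a stochastic feedback model of transcription,

    dx/dt = G + R(t) + F·x/(K + x)·η(t) − C·x,

whose stationary density (for D/C → 0, with g = G/C, f = F/C) is

    P(x) = A·(K+x)/(f·x) · x^{(2gK−K²)/f²}
           · exp(−(1/f²)·[gK²/x + (2K−g)x + x²/2]),  x > 0.

`K` and `F` act like a Michaelis constant and maximum velocity of
feedback noise. For K ≪ g the density is a truncated Gaussian; for
K ≫ g (with f co-scaled) it develops a power-law-like tail. The fitted
ratio r = log₁₀(K/g) classifies a profile as **Gaussian** (K = 0 or
r < −1.3), **intermediate** (−0.6 < r < 0.1) or **power law-like**
(r > 0.4). A continuous gamma-function generalization of the negative
binomial serves as the competing fit.

The pipeline: per-condition harvest-bias filtering (early-vs-late t-test,
P > 0.2 retained) → standardized eCDF profiles → k-means clustering with
BIC-selected k → cluster-average ePDF by numerical differentiation →
branch-ruled least-squares fits of both families → classification and
summary tables. A synthetic-cohort generator simulates the Langevin model
so the whole pipeline is testable end to end without any data download.

Intended users: computational biologists studying expression noise in
highly replicated bulk or single-cell RNA-seq designs, and anyone needing
a tested reference implementation of the G-P density, its sampler, or the
Stratonovich-Heun integrator of the feedback SDE.

## Worked example

```bash
# 1. generate a synthetic cohort: 300 genes, one condition of 24
#    replicates, 10% of genes with a harvest-order drift
gausspower simulate --n-genes 300 --drift-fraction 0.1 --seed 42 --outdir cohort

# 2. write a config and run the full pipeline
cat > config.yaml <<EOF
matrix: cohort/matrix.tsv
metadata: cohort/metadata.tsv
annotation: cohort/annotation.tsv
outdir: results
k_range: [2, 12]
seed: 7
EOF
gausspower run-all --config config.yaml
```

Output of the `run-all` step (as printed by the command; ~5 min on one
CPU):

```json
{
  "clusters_by_condition": {
    "22-1": 12, "22-13": 11, "22-19": 12, "22-7": 11,
    "7-1": 11, "7-13": 12, "7-19": 12, "7-7": 12
  },
  "gp_preferred_fraction": 0.7849462365591398,
  "n_genes_by_condition": {
    "22-1": 219, "22-13": 206, "22-19": 204, "22-7": 219,
    "7-1": 209, "7-13": 220, "7-19": 208, "7-7": 226
  },
  "pooled_label_ratios": {
    "Gaussian": 0.42696629213483145,
    "Intermediate": 0.21348314606741572,
    "PowerLawLike": 0.3595505617977528
  },
  "unclassified_fraction": 0.16773816481589712
}
```

Reading: per condition, ~210 of 300 genes pass the stationarity filter
(the ~30 drifted genes are removed, plus the ~20% of stationary genes a
calibrated P > 0.2 test sacrifices); their eCDF profiles group into
11-12 clusters; the G-P fit beats the generalized NB on 78% of cluster
ePDFs; and the pooled label ratios recover the generator's
0.44/0.26/0.30 Gaussian/intermediate/power mix within a few points.
Stage outputs (`filtered.tsv`,
`assignments.tsv`, `fits.tsv`, `gene_classes.tsv`,
`summary_by_condition.tsv`, ...) are TSVs in `results/`.

The same stages are available as library calls (`gausspower.run_pipeline`,
`gausspower.fit_family`, `gausspower.gp_sample`, ...) and as individual
CLI subcommands (`filter`, `cluster`, `fit`, `classify`, `report`).

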