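# mlrdecon

Cell-type deconvolution of bulk tissue gene expression with
outcome-interaction coefficients, and the companion analyses needed to
characterize outcome-linked, cell-type-specific genes: a seed-gene
correlation screen, Monte-Carlo enrichment tests with closed-form oracles,
an EGR-response-element (ERE) motif scanner, and positive-pixel-count
quantification of immunohistochemistry (IHC) images. A synthetic-data
generator produces cohorts, expression matrices, promoter sequences and
IHC-like images with known ground truth, so every stage of the pipeline is
verifiable without any external data.

The package is aimed at computational biologists analyzing bulk expression
from histologically mixed tissue (the motivating application is prostate
cancer, where each sample is a mixture of tumor epithelium, stroma and
benign hyperplastic epithelium) who want to know **which cell type** drives
an expression change and whether that change is linked to clinical outcome.

## The model

For gene *g*, the observed log2 expression of sample *i* is modeled by a
multiple linear regression on the pathologist-estimated cell composition:

```
y_i = β₀ + Σⱼ βⱼ·P_ij + Σⱼ γⱼ·P_ij·RS_i + ε_i,     ε_i ~ N(0, σ²)
```

where `P_ij` is the fraction of cell type *j* in sample *i* (tumor, stroma,
BPH; the residual "other" compartment is left out to keep the design full
rank) and `RS_i` is the binary relapse indicator. `βⱼ` is the
cell-type-specific expression in non-relapse samples and
`γⱼ = βⱼ(relapse) − βⱼ(non-relapse)` the relapse differential for that cell
type; each coefficient gets a two-sided t-test on the residual degrees of
freedom. A strongly negative, significant `γ_tumor` marks a gene whose
tumor-cell expression is specifically reduced in patients who later relapse.
The design matrix is shared by all genes of an array, so a genome-scale fit
is a single factorization applied to every probe row at once.

Around the regression sit the rest of the pipeline stages:

* **Correlation screen** — Pearson R of every probe against a seed probe,
  p from `t = R·√((n−2)/(1−R²))`, OLS slope; candidates need `R ≥ 0.45` and
  `p ≤ 0.001`, and lists from different platforms are intersected at the
  unique-gene-symbol level.
* **Enrichment simulations** — three 10,000-draw resampling tests
  (motif-positive fraction, list overlap, significant-γ count), each paired
  with its exact binomial/hypergeometric tail as an independent oracle.
* **Motif scan** — ERE position-frequency matrix from the consensus
  `GCG(G/T)GGGCG`, conservation-weighted matrix similarity in [0, 1],
  both-strand window scan at threshold 0.80.
* **IHC quantification** — pixel classification at intensity thresholds
  220/175/100 into negative/weak/medium/strong, NSR (strong / all positive
  pixels), weighted score `(1·weak + 2·medium + 3·strong) / all pixels`,
  pseudocoloring, and Welch t-tests between region groups.

## Worked example

```python
import mlrdecon as m
from mlrdecon import presets

# a study-scale synthetic cohort: 108 samples, Dirichlet compositions,
# relapse fraction 38/101, expression from the built-in EGR presets
spec = presets.default_cohort_spec(seed=3)
comps = m.generate_compositions(spec)
relapse = m.generate_relapse_labels(spec)
expr = m.simulate_expression(comps, relapse,
                             list(presets.table2_models().values()), seed=4)

fits = m.fit_all(expr, comps, relapse)
print(fits.loc["Egr3", ["beta_tumor", "gamma_tumor", "p_tumor:relapse"]])
```

```
beta_tumor         0.443962
gamma_tumor       -1.871808
p_tumor:relapse    0.027172
Name: Egr3, dtype: float64
```

The generating truth for this gene was `β_tumor = 1.125`,
`γ_tumor = −1.921` (simulated residual SD 0.635): the fit recovers the
coefficients within their standard errors, and the negative, significant
`γ_tumor` (p ≈ 0.027 here) flags tumor-cell expression as reduced in
relapsing disease — exactly the signature the pipeline is designed to
detect. Averaged over 100 independent cohorts the estimate is unbiased
(see `mlrdecon.pipeline.gamma_recovery`).

The full pipeline — simulate, deconvolve, screen, enrich, scan, quantify —
runs from the shell:

```
mlrdecon replicate --seed 0 --outdir out/
mlrdecon enrich --test significant-fraction --seed 1 --out enrich.json
```

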