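# mprabayes

Bayesian analysis of massively parallel reporter assays (MPRA) from
barcode-level sequencing counts.

MPRA libraries tag each allele of each candidate regulatory variant
with multiple inert DNA barcodes, transfect the pooled plasmids into
cells, and sequence both the plasmid DNA and the transcribed RNA.
Comparing RNA output between the reference and alternate alleles of a
variant measures its **transcription shift (TS)** — the quantity that
separates functional regulatory variants from inert ones.  The counts
are overdispersed, depth-dependent, and confounded by unknown per-
barcode DNA input, which makes the classical log-ratio-plus-t-test
("activity") analysis fragile.

`mprabayes` models the counts directly.  For a variant with barcodes
*bc* and sequencing samples *s*:

```
mu_dna[bc]   ~ Gamma(alpha_muDNA, beta_muDNA)
mu_allele    ~ Gamma(alpha_muRNA, beta_muRNA)      (one per allele)
phi_dna      ~ Gamma(alpha_phiDNA, beta_phiDNA)
phi_allele   ~ Gamma(alpha_phiRNA, beta_phiRNA)    (one per allele)
DNA[s, bc]   ~ NB(mean = d_s * mu_dna[bc],              dispersion = phi_dna)
RNA[s, bc]   ~ NB(mean = d_s * mu_dna[bc] * mu_allele,  dispersion = phi_allele)
```

with the mean–dispersion negative binomial (`Var = mu + mu^2/phi`) and
per-sample depth factors `d_s`.  TS is the generated quantity
`log(mu_alt) − log(mu_ref)`.  The gamma hyperparameters are estimated
**empirically** from the population of per-variant maximum-likelihood
fits — equally weighted (marginal prior), within annotation groups
(grouped prior), or with adaptive t-kernel weights in continuous
annotation space (conditional prior).  A variant is called
**functional** when the 95% highest-density interval (HDI) of its TS
posterior excludes zero (optionally a region of practical equivalence).
Ranking uses a pseudo-significance score: one minus the smallest HDI
mass that still contains zero.

Each variant is fit in two stages: a fast Laplace approximation at the
posterior mode screens out variants whose 80% TS interval already
contains zero; survivors get an exact Hamiltonian Monte Carlo fit
(4 chains × 200 warmup + 500 draws, preconditioned with the Laplace
curvature), with chains lengthened automatically when an HDI edge falls
near zero.

The package also ships the assay simulator used for validation, the
classical activity t-test baseline, ROC/PR evaluation utilities, and
exact-match barcode counting from FASTQ.

## Worked example

```python
from mprabayes import SimConfig, simulate_assay, fit_assay, FitConfig
from mprabayes.evaluate import activity_ttest, bayes_method_result, evaluate

table, truth = simulate_assay(SimConfig(n_variants=300, frac_functional=0.05,
                                        barcodes_per_allele=10, seed=1))
assay = fit_assay(table, priors="marginal", cfg=FitConfig(seed=1))
print(assay.results.head(3)[["variant_id", "ts_mean", "hdi_lower",
                             "hdi_upper", "functional_call"]])
print("bayes :", evaluate(bayes_method_result(assay), truth))
print("ttest :", evaluate(activity_ttest(table), truth))
```

prints (seed 1):

```
  variant_id   ts_mean  hdi_lower  hdi_upper  functional_call
0   var00000 -0.021713  -0.245372   0.201946            False
1   var00001  0.053332  -0.144199   0.250864            False
2   var00002  0.017086  -0.231926   0.266098            False
bayes : EvalReport(method='nb-bayes', auc=0.8467..., aupr=0.5432...,
                   spread_at_zero=0.1154..., cor_functional=0.9909...)
ttest : EvalReport(method='ttest', auc=0.8117..., aupr=0.5648...,
                   spread_at_zero=0.1350..., cor_functional=0.9908...)
```

The Bayesian fit ranks functional variants better (higher AUC), its
effect estimates for truly null variants are tighter around zero
(smaller spread at zero — the empirical-prior shrinkage), and its
estimates for functional variants track the truth closely.

The same pipeline is available from the shell:

```bash
mprabayes simulate --out-dir sim --n-variants 300 --seed 1
mprabayes fit --counts sim/counts.tsv --sample-types sim/sample_types.tsv \
              --out-dir fit --seed 1
mprabayes evaluate --results fit/results.tsv --truth sim/truth.tsv \
              --out metrics.tsv
```

Subcommands: `simulate`, `fit` (marginal / grouped / conditional
priors), `evaluate`, `compare`, `count-barcodes`.

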