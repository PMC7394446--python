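# Methods

## The count model

One variant's data are the integer barcode counts from the DNA
(plasmid) and RNA (transcript) sequencing samples of the assay.  Each
count is modelled with the mean–dispersion negative binomial,
`Var = mu + mu^2 / phi`, so larger `phi` means closer to Poisson.  The
mean of every count is proportional to its sample's depth factor `d_s`;
DNA means carry the unknown per-barcode library concentration
`mu_dna[bc]`, and RNA means additionally carry the allele's
transcription multiplier `mu_allele`.  The transcription shift
`TS = log(mu_alt) − log(mu_ref)` is the target of inference.  All five
parameter families (`mu_dna`, `mu_ref`, `mu_alt`, `phi_dna`,
`phi_rna`) carry gamma priors.

Assumptions worth stating explicitly:

* one `phi_dna` per variant, shared across that variant's barcodes (the
  model names a single DNA dispersion per variant);
* `phi_rna` is allele-specific in the likelihood but both alleles share
  one gamma prior;
* depth factors are treated as known once computed from column totals
  (their estimation error is ignored — with library-scale totals it is
  negligible);
* barcodes absent from the table are treated as failed in library
  preparation; observed zeros are data and enter the likelihood.

## Depth factors

The model only requires that NB means scale with sequencing depth.  We
define `d_s = (column total of s) / geomean(column totals of the same
sample type)`, separately for DNA and RNA.  Geometric-mean
normalization makes `d` scale-free (multiplying all same-type columns
by a constant changes nothing) and puts `mu` parameters on the scale of
the "average sample".  Because DNA and RNA are normalized separately,
the global DNA→RNA scale is absorbed into `mu_allele`; this offsets
both alleles equally, so TS is unaffected.  The totals-based definition
is a convention, not a claim about the data: any depth proxy
proportional to it yields identical inference.

## Empirical priors

Each variant is first fit by maximum likelihood (L-BFGS on
log-parameters, analytic gradients, three starts seeded from a
method-of-moments point).  Fits that do not converge or that end on the
parameter box (for example `phi → ∞` when replicates happen to look
Poisson) are excluded from the prior population but still receive
posterior fits.  Gamma priors are then fit to the MLE populations by
(weighted) maximum likelihood — Newton iteration on the shape after
profiling out the rate.

* **Marginal**: all usable variants weighted equally.  `mu_dna` is fit
  to barcode-level MLEs pooled across variants; `mu_ref` and `mu_alt`
  populations are fit separately (a pooled option exists); `phi_rna`
  pools ref and alt dispersions.
* **Grouped**: an independent prior per categorical annotation label;
  groups below 10 usable variants fall back to the marginal prior with
  a warning.
* **Conditional**: per-variant weights from a Student-t kernel centred
  on the variant's (standardized) annotation vector.  The kernel scale
  starts at the median annotation distance and moves along a geometric
  grid (factor 1.1) to the smallest scale at which the 100th-largest
  weight is at least 1% of the largest, so the prior reflects a
  neighborhood rather than the nearest neighbor.  Defaults: `n_top` =
  100, floor ratio 0.01, 3 degrees of freedom (heavy tails keep distant
  variants from being zeroed out); multi-annotation distance is
  Euclidean after per-dimension z-scoring.  The target variant's own
  MLE stays in the weighted population — it is one observation among
  roughly a hundred, so its influence on its own prior is small.

Fitting priors to raw MLE populations overstates the population spread
(estimation noise is not deconvolved) and small-replicate dispersion
MLEs are biased upward; both effects are inherited from the estimation
procedure and are visible as slightly conservative shrinkage in the
calibration runs below.

## Posterior inference

Sampling works on log-parameters (all positive quantities, so the
posterior is smooth and unconstrained).  For each variant:

1. **Screen.** A Laplace approximation at the posterior mode (found by
   L-BFGS warm-started from the MLE) yields a Gaussian TS marginal.  If
   the 80% interval contains zero the variant is finalized as
   non-functional without MCMC; its HDI and pseudo-significance score
   are computed in closed form from the Gaussian.  Approximation
   failures promote the variant to MCMC (fail-open), so the screen can
   only add, never remove, exact fits.
2. **MCMC.** Hamiltonian Monte Carlo with a diagonal mass matrix taken
   from the Laplace curvature, step size tuned by dual averaging
   (target acceptance 0.8) over 200 warmup iterations, trajectory
   length ≈ 2 in preconditioned space with jittered leapfrog counts.
   4 chains × 500 kept draws by default.  Convergence gate: split-Rhat
   ≤ 1.05 and ESS ≥ 100 on TS-relevant parameters, with one automatic
   retry at 4× lengths.  The inner loops (likelihood gradients and the
   full HMC sweep) are numba-compiled; the plain-numpy implementations
   remain in the code base as the reference the kernels are tested
   against, and an ensemble sampler (emcee) serves as an independent
   cross-check in the test suite.
3. **Refine.** If either 95% HDI edge lies within 10% of the HDI width
   from zero, sampling is repeated with 4× draws, escalating once more
   (total ≤ 25× base length).  "Close to zero" has no canonical
   definition; the 10% margin is configurable.

Determinism: per-variant seeds are derived by hashing the global seed
with the variant id, so results are identical across reruns and worker
counts.

## Decision rules and ranking

* **HDI**: narrowest contiguous interval containing ⌈mass·n⌉ sorted
  draws; ties break toward the lowest start.
* **Call**: functional iff the 95% HDI excludes zero, or — when a
  region of practical equivalence (ROPE) is supplied — iff the HDI and
  ROPE are disjoint.
* **Score**: one minus the smallest mass on a 0.001-step grid whose HDI
  contains zero; lower = stronger evidence.  Two properties of this
  estimator matter in practice: (i) it saturates at 0.001 for variants
  whose draws all fall on one side of zero, creating ties among the
  strongest variants; (ii) at small masses the empirical HDI tracks
  density clumps near the mode, so exactly-null posteriors score high
  (≈ 0.85–0.95) but not exactly 1.  For screen-stage (Gaussian) fits
  the score is computed analytically, which removes Monte-Carlo jitter
  from the bulk of the ranking.

## The simulator

`simulate_assay` draws from the same generative model the inference
assumes, plus two nuisance processes: per-sample depth factors
(log-normal, sd 0.3) and per-barcode dropout (Bernoulli 0.05, removing
the barcode from every sample — library-preparation failure).
Defaults: 3000 variants, 5% functional, 10 barcodes/allele, 3 DNA and
5 RNA samples; hyperpriors `mu_dna ~ Gamma(5, 0.1)` (≈50 counts at
depth 1), `mu_allele ~ Gamma(4, 4)`, dispersions `~ Gamma(10, 1)`
(φ ≈ 5–20).  Functional effects are `±|N(0, 0.5²)|` truncated below at
0.1 with random sign.  Column totals emerge from the concentration
scale and depth factors rather than being set directly; this keeps the
generator minimal while preserving the depth-proportionality the model
cares about.

What the simulator does **not** emulate: sequencing error in barcodes,
PCR jackpotting, batch structure across replicates, allele-specific
barcode biases, or correlated dispersions.  Passing tests therefore
demonstrate correctness of the inference under the stated model and
robustness to depth variation and dropout — not robustness to every
artifact of real libraries.

## Calibration and comparison results (computed by the test suite)

Desk-scale study sizes were chosen so the full suite runs on one CPU in
minutes: 300-variant assays, 10–20 replicates, 100–200 replicate
single-variant fits.  Under these conditions the suite verifies: MLE
recovery of a twofold shift within ±0.15 in ≥90% of replicates; 95% HDI
coverage of the true shift within [0.89, 0.99]; posterior-mean
shrinkage of the most extreme null MLE; lower spread-at-zero than the
activity t-test; conditional/marginal TS agreement (r > 0.95) under
uninformative annotations; and detection gains from truth-correlated
annotations.  The ranking comparison against the t-test favors the
count model on AUC, spread at zero, and truth correlation; AUPR at this
assay size is dominated by score-floor ties among the strongest
variants (see above) and is not reliably ordered between the two
methods under the default simulation conditions.

## Known limitations

* The score's grid floor (0.001) cannot discriminate among very strong
  variants; p-value-based baselines can.
* Empirical priors are treated as fixed — their estimation uncertainty
  is not propagated (a fully joint hierarchical fit over all variants
  is out of scope).
* Two alleles per variant, one cell type, no multi-condition designs.
* Barcode counting is exact-match only; error-tolerant decoding is out
  of scope.
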