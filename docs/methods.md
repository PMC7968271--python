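# Methods

## Mixed-model kernel learning

The kernel engine fits `y = Xb + Σ_k u_k + e` with `u_k ~ N(0, K_k σ²_k)`
and `e ~ N(0, I σ²_e)` by Gibbs sampling. Each kernel is eigendecomposed
once (`K = U D U′`, modes below `1e-10 × max eigenvalue` dropped; a
minimum eigenvalue below `−1e-8 × max` is an error), and the random vector
is sampled as an independent Gaussian regression on the eigenvectors with
prior variances `d_i σ²_k` — one vectorised draw per term per iteration.
Fixed effects get a flat prior and a joint Gaussian draw through the
Cholesky factor of `X′X` (ridge `1e-10 × trace` for safety); variances get
scaled-inverse-χ² full conditionals with `df = 5`.

Prior scales follow the common default partition rule: the prior *mode* of
`σ²_k · mean(diag K_k)` equals an equal share of `var(y) · R²` with
`R² = 0.5`, and the residual mode equals `var(y) · (1 − R²)`. Both `df`
and `R²` are arguments.

Test-set prediction is the conditional expectation
`X_tst b̂ + Σ_k K_tst,trn K_trn,trn⁻¹ û_k` (the spectra-only model M1 omits
the fixed-effect term; the top-3 marker covariates of M5/M6 travel inside
`X`). Training-block solves use a Cholesky factorisation with a single
logged `1e-8` diagonal-jitter retry — relationship matrices built from
centered columns are singular by construction, and the fitted `û` lies in
the kernel's column space, so the jittered solve is accurate to O(jitter).

Marker effects are recovered from a genomic-kernel fit by the standard
GBLUP back-solution `â = Z′G⁻¹û_g / (2 Σ p_j(1−p_j))`, which requires the
allele frequencies the kernel was built with (passing any others is an
error, because the scaling would be unknown).

### Relationship matrices

* **S** (spectral): `W W′ / m` on the column-standardized wavenumber
  matrix; standardization statistics come from the training rows of a fold
  by default (a `standardize_scope` switch selects full-data statistics).
  Dividing by the retained column count makes `trace(S) = n − 1`.
* **G** (genomic): VanRaden method 1, `Z Z′ / (2 Σ p_j(1−p_j))`,
  `Z = dosages − 2p`, frequencies from the construction set (full data by
  default; the M6 variant rebuilds G excluding the fold's top-3 markers
  *before* forming Z and the denominator). Monomorphic SNPs are an error —
  QC removes them.
* **A** (pedigree): recursive tabular method over a topological ordering
  of the full pedigree, restricted to the study cows only afterwards so
  ancestral paths are never lost. Diagonals are `1 + F` (inbreeding).

## Multilayer BayesB

Each predictor layer (wavenumbers; SNP dosages) gets its own
point-mass-plus-scaled-t mixture prior, implemented hierarchically: a
per-effect normal whose variance has a scaled-inverse-χ² prior
(`df = 5`). The per-effect update integrates the effect out of the
inclusion decision (Bernoulli draw from the marginal likelihood ratio),
then draws the effect when included; excluded effects refresh their latent
variance from the prior. The layer inclusion probability π has a Beta
hyper-prior parameterised by mean `probin = 0.5` and concentration
`counts = 10` (prior variance `probin(1−probin)/(counts+1) = 0.023`),
updated from its Beta full conditional; a fixed π is available per layer.
Fixed effects get a Gaussian prior with variance 1e8. Layer t-scales
follow the default rule: π · (sum of column variances) · `df·S/(df−2)`
equals the layer's equal share of `var(y) · R²`; the residual
scaled-inverse-χ² mode equals `var(y)(1 − R²)`.

The per-effect sweep is numba-compiled; the whole chain is deterministic
given the seed. Thinning applies only to stored chains — posterior means
use every post-burn-in draw. Because the sweep visits predictors in column
order, permuting columns permutes posterior summaries up to Monte-Carlo
error (not bitwise), which is how the permutation property is tested.

Predictions follow the catalogue: `W_IR,tst â_IR` (M1), plus `X_tst b̂`
(M2/M3), plus `W_SNP,tst â_SNP` (M4), with test designs standardized by
training statistics.

## PLS baseline

Predictors are column-concatenated, standardized (zero-variance columns
dropped with a warning), and decomposed by NIPALS (scikit-learn
`PLSRegression`). The latent-variable count minimises 10-fold inner-CV
RMSE over `1..min(50, n−1, p)`; one decomposition per inner fold scores
all truncation ranks. Genomic/pedigree blocks enter as kernel principal
components (eigenvectors × √eigenvalues, smallest count strictly exceeding
80% cumulative eigenvalue share); categorical on-farm terms enter one-hot
and are standardized like any other column.

## Model catalogue and cross-validation

Only the catalogue combinations construct: kernel M1–M7, BayesB M1–M4,
PLS M1–M4 + M7. Fixed effects are intercept + herd and parity (one-hot,
first level reference) + linear DIM (centered on the training mean). Test
levels unseen in training map to the reference-mean (zero) effect, with a
logged count.

Random sub-sampling CV draws seeded permutations of the *sorted* cow ids
(fold assignment is invariant to row order); the full-scale defaults give
the 716/250 partition at n = 966. Herd CV samples herds without
replacement (defaults 65 train / 20 test at 85 herds), strips the herd
effect from every model, and refuses M2. Top-3 markers for M5/M6 are
selected inside each training fold from the fold's kernel M4 fit by
largest `|â|` (back-solution; ties broken by SNP order and logged). A
single-marker-regression alternative was considered for top-marker
selection and rejected in favour of the back-solution, which uses the same
fit the models already produce. Metrics are aggregated as the mean over
repeats of per-repeat R² and slope (never pooled predictions), with SDs
reported alongside.

One master seed drives everything: it spawns per-repeat streams, which
spawn per-entry fit seeds, so any subset of the catalogue reruns
identically.

## Synthetic data generator

The generator emulates a cohort of dairy cows in commercial herds:
defaults are 966 cows in 85 herds (sizes ~ round N(11.4, 2.4²), min 3,
adjusted to sum exactly), DIM ~ N(169.8, 101.8²) truncated at 0, parity ~
round N(2.4, 1.2²) ≥ 1, 1060 wavenumbers spanning 5011–925 cm⁻¹, 2,000
SNPs (scalable), and nine milk-protein traits rescaled to their catalogue
means/SDs. The test suite uses a desk-scale profile (300 cows, 26 herds,
200 channels, 500 SNPs) so the whole suite runs in about a minute.

Structure, per seed:

* **Pedigree/genotypes**: `max(40, n/2)` founders (half sires), one
  offspring generation by random mating; founder haplotypes at frequencies
  U(0.05, 0.5) are gene-dropped with independent segregation per SNP, so
  linkage disequilibrium is family-induced only (no map).
* **Genetics**: 3 planted QTL with equal-magnitude, random-sign effects on
  standardized dosages carrying 60% of the genetic variance (each QTL is
  then unambiguously "large"), plus a polygenic tail over the remaining
  markers; the shared genetic factor is scaled to each trait's h²
  (default 0.5).
* **Trait**: mean + SD × (genetic + herd + DIM/parity + residual), with
  herd share 0.25 and covariate share 0.05 by default; components are
  centered and scaled to exact realized shares, so the configured mean is
  the cohort mean and realized h² sits within sampling error of the
  target.
* **Spectra**: smooth baseline + a per-herd independent smooth signature
  curve + a smooth loading of a noisy copy of the genetic value
  (`spectra_genetic_fidelity = 0.5` is the squared correlation between the
  genetic value and the genetic signal the spectra carry) + AR(1)
  channel-correlated noise (ρ = 0.9).

Two spectra choices deserve their rationale. *Per-herd signatures*: herd
management shifts many absorbance bands idiosyncratically, so each herd
gets its own signature (one degree of freedom per herd). This is exactly
what makes cow-level random CV optimistic — the spectral kernel clusters
herdmates and borrows their phenotypes, herd by herd — while carrying no
herd-to-trait mapping that could transfer to unseen herds; a global
"herd-effect times loading curve" construction would generalise perfectly
across herds and erase the random-vs-herd CV gap that herd blocking is
designed to expose. *Genetic fidelity < 1*: if the spectra encoded the
genetic value noiselessly, markers would be redundant; partial fidelity is
what makes adding genomics to spectra worthwhile, which is the phenomenon
the toolkit exists to measure.

What the generator does **not** emulate: map-based recombination and
population LD, mechanistic milk-chemistry spectra, trait-specific genetic
architectures (the nine traits share one genetic factor and one herd
factor, differing in h² scaling and independent residuals), herd-by-trait
interactions, or repeated records per cow. Passing tests therefore show
the machinery is correct and the designs behave as intended under the
assumed structure — not that any particular accuracy level will be
attained on real cohorts.

## Numerical choices

* QC thresholds are strict-less-than removals (call rate < 0.95,
  MAF < 0.05); boundary values are kept. QC is idempotent.
* Missing genotypes: Binomial(2, p_ref) draws from observed-call
  frequencies, computed once on the full data before CV (imputation
  precedes resampling in the intended workflow).
* Mahalanobis screening flags cows above a χ² quantile in PC space and
  never removes them.
* Zero-variance columns are dropped (with a warning) before
  standardization, kernels, and PLS.
* MCMC defaults are 50,000 burn-in + 50,000 kept, thin 10; the test suite
  and the acceptance script use scaled-down chains (around 1–4 thousand
  kept draws) and the desk-scale generator profile, which keep every
  Monte-Carlo check inside its tolerance at interactive runtimes.
* Monte-Carlo standard errors use batch means (25 batches); sampler-vs-
  oracle checks require ≥ 90% of elements within 2 SE and all within 4 SE,
  the vector-level rendering of "agrees within Monte-Carlo error" (the
  maximum of 30 pivotal deviations routinely exceeds 2).
* Effective sample size below 30 on a variance chain logs a warning, never
  an error.

## Known limitations

* The kernel sampler supports at most two kernel terms (all catalogue
  models need at most two).
* BayesB supports exactly the catalogue's M1–M4; there is no BayesA/C or
  Bayesian LASSO.
* PLS is the standard dense NIPALS; no sparse or kernel variants.
* HDF5 containers are not implemented; all interfaces are delimited text.
* Herd CV leaves cows of unassigned herds out of a repeat when the herd
  count exceeds train + test.
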