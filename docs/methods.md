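# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices and the known limitations of `twincort`.

## Twin model

### Likelihood

For p traits (fixed analysis order: perceived stress, depressive symptoms,
neuroticism, HCC last — so the final Cholesky factor isolates genetic variance
in HCC not shared with the psychological traits), the model is the Cholesky
parameterization Σ = XX′ + YY′ + ZZ′ with lower-triangular X (additive
genetic, A), Y (shared environment, C) and Z (unique environment plus
measurement error, E). Cross-relative covariance is r·A + C with r = 1 (MZ
co-twins) or 0.5 (DZ co-twins, full siblings). Each family contributes

    k·ln(2π) + ln|Σ_obs| + (y − μ)′ Σ_obs⁻¹ (y − μ)

over its observed entries, where μ stacks per-person mean predictions from
the covariate model (intercept, sex, centered age, age², sex×age, sex×age²;
age is centered at the sample mean for conditioning). This is
full-information ML: singletons enter as single-person blocks and partially
missing trait vectors as marginal densities. Families are grouped by
(relatedness pattern, missingness pattern) so the per-evaluation cost is a
handful of small Cholesky factorizations plus vectorized quadratic forms.

Non-twin family members are treated, by default, as independent single-person
families; an optional mode (`singleton_mode="family"`) keeps them in their
family block with 0.5 A-sharing to every member, which matches the generating
truth of the synthetic cohort. The default mirrors the convention of using
singletons only to improve mean/variance estimation; the two modes give
nearly identical estimates on the synthetic data and the choice is surfaced
rather than hidden.

### Estimation

`fit_model` minimizes the −2 lnL by L-BFGS-B with numerical gradients,
bounds constraining Cholesky diagonals to be non-negative (resolving the sign
indeterminacy of ±X), and a multi-start scheme (default 5 starts) seeding the
path diagonals at fractions of the observed per-trait residual SDs and the
mean model at per-trait OLS. Convergence tolerances: `ftol 1e−10`,
`gtol 1e−6`, 2000 iterations; every start's outcome is kept in the fit log.
A numerically singular block covariance returns a large penalty inside
optimization and raises outside it.

### Inference

* **LRT**: Δ(−2 lnL) between nested fits against χ² with df = the difference
  in free-parameter counts (the dropped 4×4 lower-triangular C factor costs
  10 df). Variance components sit on a boundary under the null, so the plain
  χ² is conservative; it is nevertheless what is implemented because it is
  the convention the analysis emulates and reproduces its printed p-value.
* **Standardization**: component table entry (j,k) is
  100·path²_jk/Σ_jj; rows sum to 100 over components before rounding.
  Heritability is A_jj/Σ_jj; rA/rC/rE are component correlation matrices,
  with NaN where a trait has zero variance in a component.
* **Confidence intervals**: profile likelihood (bound where −2 lnL rises by
  the χ²₁ quantile with all other parameters re-optimized) for free
  parameters and, via the (h², total-variance) reparameterization, for
  univariate heritability; a bound that runs into the parameter-space edge is
  flagged one-sided. Derived multivariate quantities fall back to a
  family-resampling percentile bootstrap; the method used is recorded in the
  result object.
* **Twin correlations**: ML under an exchangeable bivariate normal (shared
  mean coefficients, equal variances across twin order — the double-entry
  intraclass convention, and numerically identical to it). The mean model is
  profiled by GLS and the common variance in closed form, so only r is
  profiled numerically; CIs by profile likelihood. A plain double-entry
  Pearson estimator is available for comparison. The ML/double-entry
  estimator carries the usual small negative finite-sample bias
  (≈ −0.006 at 115 pairs, r = 0.66), well inside the recovery tolerance.
* **Median split**: whole families are assigned to the younger/older half by
  family mean age relative to the person-level median, so no family
  straddles the split; the AE model is refitted per half.
* **Stability**: Pearson correlation between time points on the retest
  subsample, reported descriptively.

## Phenotype preparation

* log10(HCC + offset) with offset 0.1 pg/mg — the smallest positive value the
  emulated assay reports; configurable.
* Winsorization at mean ± 3 SD on the log scale, moments computed on
  time-point-1 data *including* the outliers; the same bounds are applied to
  time-point-2 values. The operation is idempotent.
* Experimental covariates (batch, storage group, month, study phase) are
  screened by drop-one comparison against the full joint OLS model. The
  variance-increase convention is (Var_reduced − Var_full)/Var_full × 100
  with Var = SSR/n; partial F-tests give p-values. Residualization is a
  single pooled OLS on drop-first dummy-coded factors whose coefficients are
  shared across time points; residuals are exactly orthogonal to the design
  and invariant to the choice of reference level.
* IRT: Samejima's logistic graded response model — the standard choice for
  ordered polytomous symptom items. Calibration by marginal ML (EM), E-step
  on a fixed 61-node Gauss–Hermite quadrature of the standard-normal latent
  density, M-step per item on expected count tables with thresholds
  parameterized as (b₁, log-gaps) to enforce ordering. EM stops when the
  marginal log-likelihood moves < 1e−5 (tests and the pipeline use 1e−4 for
  speed, which changes estimates at the third decimal). The latent scale is
  identified by the fixed N(0,1) prior, so calibrating both stress scales
  together with overlap respondents places them on one liability metric; a
  disconnected instrument graph is an error. Scoring is EAP under the same
  prior; all-missing response vectors score as missing. Items with empty
  categories are collapsed with a warning and the category map retained for
  scoring.
* Neuroticism: prorated sum scores per instrument (≥ 50 % of items answered),
  z-standardized within instrument and concatenated — matching the practice
  of combining two age-specific questionnaires.

## Polygenic-score pipeline

* QC order: person call rate, then variant call rate, MAF and exact HWE
  (full enumeration of heterozygote counts conditional on allele counts; the
  test is computed on one member per family to avoid relatedness inflating
  it). Each exclusion is reported with its reason.
* Harmonization counts the target ALT allele, sign-flips β when the effect
  allele is REF, resolves strand flips by complement, and drops
  strand-ambiguous (A/T, C/G) and irreconcilable variants.
* Clumping: greedy by ascending p (deterministic tie-break p → chrom → pos →
  id), keeping a variant only if r² ≤ 0.1 with every kept variant within
  500 kb, LD computed from target dosages (mean-imputed). The r²/window
  defaults are the conventional ones and configurable; kept sets are nested
  as r² loosens.
* Scoring: Σ β·dosage at eight nested thresholds (5e−8, 1e−5, 0.001, 0.01,
  0.05, 0.1, 0.5, 1.0); missing dosages imputed to twice the counted-allele
  frequency; scores z-standardized per threshold before association (so β is
  per SD of score).
* Ancestry PCs: SVD of column-standardized dosages on one randomly chosen
  (seeded) member per family, all persons projected; deterministic
  orientation (largest-magnitude loading positive).
* Mixed model: y = Wγ + s·β + g + ε with g ~ N(0, σ²_g K) on the pedigree
  relatedness matrix (MZ co-twins 1, other family members 0.5). REML via a
  single eigendecomposition of K and a bounded 1-D search over
  log(σ²_g/σ²_e) — exact and cheap at cohort scale; an average-information
  scheme would only matter for much larger K. Wald z for β with one-sided
  upper-tail p (alternative: positive association); two-sided p =
  2·min(p₁, 1−p₁) by construction. Signed incremental R² =
  sign(β)·(R²_full − R²_null) computed from the fixed-effect predictions on
  the raw scale, so a negative value encodes a negative association
  direction. Constraining σ²_g = 0 reproduces OLS exactly, which is used as
  an oracle check.

## Synthetic-data generator

The generator's defaults are the study conditions it emulates:

* **Families**: 116 MZ + 187 DZ pairs (`n_dz_pairs` counts all DZ pairs; the
  first 14 correspond to triplet sets and carry one extra co-aged singleton)
  plus 51 extra singleton siblings attached to random twin families — 671
  persons. Ages truncated-normal (14.5, 2.4) on [10.1, 31.1], co-twins share
  age; sexes assigned stratified-exactly at the 419/671 female fraction, MZ
  co-twins share sex. A seeded fraction (146/671) gets a second time point
  two years later.
* **Latent traits**: factor scores with the quantitative-genetic sharing
  rules (A: MZ identical, DZ/siblings 0.5-shared via a shared+specific
  construction; C: family-shared; E: individual), mapped through the default
  AE paths — the square roots of the reference standardized AE decomposition
  of the four traits, all loadings taken positive, which reproduces its
  genetic correlations (0.77, 0.74, 0.14, 0.12, 0.19) exactly. Time-2 latents
  regress toward time 1 at per-trait stabilities (0.61, 0.51, 0.58, 0.32).
  Mean effects: small female shifts (+0.15 dep, +0.20 neuro, −0.03 HCC,
  +0.05 stress on the latent scale) and mild age trends — sized to echo the
  observed sex differences, since only observed means, not generating
  coefficients, are available to copy.
* **HCC**: log10 HCC = 0.55 + 0.35·latent + batch + month + storage + study
  effects; raw = 10^log10 − 0.1, floored at 0. Batch (35 levels) and study
  phase (6) effects are i.i.d. normal (SD 0.08 each); storage-group (5)
  effects are sorted-descending normals (SD 0.05), so HCC falls with storage
  time; month effects are a sinusoid of amplitude 0.10 peaking in March and
  bottoming in September. These magnitudes were fixed once from the reported
  relative contributions of the four covariates (batch/study largest,
  storage smallest, month seasonal and clearly detectable at n = 671).
* **Items**: under-16s answer a 30-item 4-category stress scale and a 20-item
  binary neuroticism scale; 16-and-overs a 10-item 5-category stress scale
  and a 12-item 5-category neuroticism scale; everyone a 34-item 3-category
  depressive-symptom scale; a configurable fraction of 16–19-year-olds
  (default all, ≈ 160 persons) also answers the younger stress scale,
  providing the linking overlap. Item truth: discriminations
  log-normal(0, 0.3), equally spaced thresholds with small item jitter.
  Whole-instrument missingness at rates 1/671 (stress), 51/671 (neuroticism),
  55/671 (depressive symptoms).
* **Genotypes**: biallelic variants at frequencies U(0.05, 0.5); two parental
  haplotype pairs per family, children receive one haplotype per parent (MZ
  co-twins share the transmission), giving exact MZ identity and expected
  0.5 DZ/sibling sharing. Disjoint causal sets per discovery trait with
  normal effects; discovery summary statistics from per-variant OLS in an
  independent unrelated population (default n = 5000, SNP-h² 0.3). When a
  study is simulated with genotypes, each causal trait's standardized genetic
  value is blended into its latent trait (weight 0.25, variance re-normalized)
  so PRS associations have a known positive truth.
* **Seeding**: one global seed, split into named substreams
  (cohort/latent/effects/items/genotypes) via `SeedSequence.spawn`; identical
  seeds give byte-identical outputs.

What the generator does **not** emulate — and what passing tests therefore do
not establish about real data: realistic LD beyond the block-copy option (so
clumping behaves more aggressively on real panels), genotyping/imputation
error and dosage uncertainty, assay error beyond log-normal noise,
item-level differential functioning or age drift in item parameters,
assortative mating, D (dominance) variance, and selection/attrition. The
recovery results say the estimators are consistent and approximately unbiased
under the stated model, not that the model is true of any particular cohort.

## Problem sizes used in the checks

Recovery and calibration checks are sized to the study: 200 simulated
cohorts of 115 MZ + 183 DZ pairs for heritability recovery; 1000–1500
replicates for the pair-correlation estimator at 115/183 pairs; the
multivariate recovery check uses ten times the family counts, noise-free
traits and an intercept-only mean model; CI coverage uses 120 replicates;
the one-sided type-I check uses 1000 replicates of 40 two-child families.
These sizes are the package's chosen trade-off between Monte-Carlo error and
default-suite turnaround.

## Known limitations

* Numerical gradients make high-dimensional fits (4-trait ACE with saturated
  means: 54 parameters) take tens of seconds; analytic gradients would be the
  next optimization.
* The LRT p-value ignores the boundary problem for variance components
  (conservative); a 50:50 χ̄² mixture would be less so.
* Profile CIs for derived multivariate quantities are delegated to the
  bootstrap rather than constrained reparameterization.
* The exact HWE test uses one member per family rather than a
  relatedness-corrected test statistic.
* `hcc_resid` keeps residual covariate-estimation noise (≈ 54 fitted
  deviations at n = 671), which slightly attenuates twin correlations
  relative to the latent truth — visible in the README example.
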