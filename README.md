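# twincort

Twin-cohort simulation and analysis of hair cortisol concentration (HCC).

Hair cortisol integrates roughly three months of hypothalamus–pituitary–adrenal
(HPA) axis activity into a single retrospective measurement, which makes it an
attractive biomarker for chronic-stress research. A central open question is
how much of its variation is heritable and whether the genes influencing it
overlap with those behind self-reported stress, depressive symptoms and
neuroticism. `twincort` implements, as a tested pipeline, the classical
twin-study answer to that question for an adolescent/young-adult cohort of
116 MZ and 187 DZ twin pairs plus 65 singletons (671 subjects), together with
a synthetic-cohort generator so that every stage runs — and is verified —
without access to any restricted human data.

The package is aimed at biostatisticians and behavioral geneticists who want a
transparent, scriptable re-implementation of the standard Mx/GCTA-style
analysis chain: phenotype harmonization, biometric variance decomposition and
polygenic-score association under family structure.

## The models

**Cholesky ACE/AE/CE twin model (FIML).** For p traits the phenotypic
covariance is decomposed as

    Σ = A + C + E,   A = XX′,  C = YY′,  E = ZZ′,

with X, Y, Z lower-triangular path matrices (so each component is positive
semidefinite by construction). Expected cross-relative covariance is
`r·A + C`, with A-sharing r = 1 for MZ co-twins and r = ½ for DZ co-twins and
siblings. Every family contributes the multivariate-normal density of its
*observed* entries (full-information maximum likelihood), so singletons and
partially missing trait vectors stay in the likelihood. Trait means carry sex,
age, age², sex×age and sex×age² fixed effects. Nested models are compared by
likelihood-ratio χ² tests; reported quantities are standardized variance
components (percent of trait variance per squared standardized loading),
heritabilities h² = A_jj/Σ_jj, genetic/environmental correlations
rA = A_jk/√(A_jj A_kk), and profile-likelihood confidence intervals.

**Phenotype preparation.** Raw HCC (pg/mg) is mapped to log10(HCC + 0.1),
winsorized at mean ± 3 SD, and residualized on dummy-coded experimental
covariates (assay batch, storage time, month of sampling, study phase).
Questionnaire items go through Samejima's graded response model, fitted by
marginal ML (EM over Gauss–Hermite quadrature); the two perceived-stress
scales are calibrated concurrently, with respondents who completed both
anchoring a single liability metric, and persons are scored by EAP.
Neuroticism scores are z-standardized within instrument and concatenated.

**Polygenic scores and mixed-model association.** Target genotypes pass call
rate (≥ 0.95), MAF (≥ 0.01) and exact Hardy–Weinberg (p ≥ 1e−6) filters; GWAS
summary statistics are harmonized onto the target counted allele (strand flips
resolved, A/T–C/G variants dropped); greedy LD clumping (r² ≤ 0.1 within
500 kb) precedes scoring at eight nested p-value thresholds (5e−8 … 1.0).
Association uses a two-variance-component linear mixed model,
y = Wγ + s·β + g + ε with g ~ N(0, σ²_g K) on the pedigree relatedness matrix
K, fitted by REML on the spectrum of K, reporting one-sided p-values (upper
tail, positive-association alternative) and signed incremental R².

**Synthetic cohort.** The generator reproduces the study's structure — family
composition, truncated-normal ages (mean 14.5, SD 2.4, range 10.1–31.1),
two-instrument stress assessment with an overlap subgroup, log-normal HCC with
additive batch/month/storage/study effects on the log10 scale, Mendelian
family genotypes and a simulated discovery GWAS — from known Cholesky ground
truth, so recovery is checkable end to end.

## Worked example

```python
import numpy as np
from twincort.cohort import simulate_study
from twincort.phenotypes import prepare_phenotypes
from twincort import twin_model as tm

study = simulate_study(seed=7)   # 671 persons: 116 MZ + 187 DZ pairs + 65 singletons
prep = prepare_phenotypes(study.phenotypes)
ped = study.cohort.pedigree()

for zyg in ("MZ", "DZ"):
    res = tm.twin_correlations(prep.table, ped, "hcc_resid", zyg)
    print(f"r{zyg} = {res['r']:.2f} (95% CI {res['ci'][0]:.2f}-{res['ci'][1]:.2f}, "
          f"{res['n_pairs']} pairs)")

traits = ("stress", "dep", "neuro", "hcc_resid")
data = tm.build_twin_data(prep.table, ped, traits=traits)
ae = tm.fit_model(data, tm.ModelSpec("AE", traits), n_starts=2)
ace = tm.fit_model(data, tm.ModelSpec("ACE", traits), n_starts=2)
delta, df, p = tm.compare_lrt(ace, ae)
print(f"ACE vs AE: delta chi2 = {delta:.2f}, df = {df}, p = {p:.2f}")
dec = tm.decompose(ae)
print("h2:", {t: round(float(h), 2) for t, h in zip(traits, dec.h2)})
```

Output:

```
rMZ = 0.63 (95% CI 0.50-0.72, 116 pairs)
rDZ = 0.29 (95% CI 0.16-0.42, 187 pairs)
ACE vs AE: delta chi2 = 2.28, df = 10, p = 0.99
h2: {'stress': 0.46, 'dep': 0.56, 'neuro': 0.43, 'hcc_resid': 0.66}
```

The MZ correlation roughly doubles the DZ correlation and the shared-
environment factor can be dropped without worsening fit (p ≫ 0.05), so the AE
model is retained; the HCC heritability estimate (here 0.66 at one simulated
cohort of this size; the generating value is 0.72) is the A share of the
trait's variance under that model. One such cohort carries sampling error of
several points — the recovery tests average over hundreds of replicates.

The same stages are scriptable from the shell:

```bash
twincort run-all --config config.yaml --out runs/demo --seed 7
```

which chains `simulate → prepare → twinfit → prs → report` and leaves TSV
tables (descriptives, twin correlations, decomposition, PRS sweep), a PRS
figure and a `study_report.json` with provenance (seed, config hash, version)
in the output directory.

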