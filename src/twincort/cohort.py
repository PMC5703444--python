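"""Synthetic twin-family cohorts with known ground truth.

The generator emulates an adolescent/young-adult twin cohort assessed
for hair cortisol concentration (HCC) and three psychological traits.
Its defaults reproduce the study design it is modelled on: 116 MZ and
187 DZ twin pairs (14 of the DZ pairs come from triplet sets and carry
one extra singleton each), 51 additional singleton siblings, ages
truncated-normal with mean 14.5 y and SD 2.4 y on [10.1, 31.1], and a
female fraction of 419/671.

Trait structure is a p-variate Cholesky factor model: a person's latent
trait vector is ``X a + Y c + Z e`` plus a fixed-effect mean
contribution, where ``a``/``c``/``e`` are standard-normal factor scores
shared within a family according to quantitative-genetic rules (MZ
co-twins share ``a`` fully, DZ co-twins and siblings at 0.5; ``c`` is
shared by everyone in a family; ``e`` is individual) and X, Y, Z are
lower-triangular path matrices.  The default truth is the AE solution
reported for stress, depressive symptoms, neuroticism and HCC (trait
order fixed), reconstructed from its standardized variance components
with positive loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TRAITS = ["stress", "dep", "neuro", "hcc"]

#: Standardized AE variance components (%) of the published 4-variate
#: Cholesky solution, trait order stress, dep, neuro, HCC.  Loadings are
#: the square roots (all taken positive, which reproduces the published
#: genetic correlations exactly).
TABLE_A_PCT = np.array(
    [
        [53.89, 0.0, 0.0, 0.0],
        [32.95, 22.10, 0.0, 0.0],
        [33.78, 2.79, 19.81, 0.0],
        [1.33, 0.03, 1.20, 69.37],
    ]
)
TABLE_E_PCT = np.array(
    [
        [46.12, 0.0, 0.0, 0.0],
        [6.65, 38.30, 0.0, 0.0],
        [12.15, 5.00, 26.48, 0.0],
        [0.68, 0.07, 0.21, 27.02],
    ]
)

#: Two-year stability of the four traits (test–retest correlation of the
#: latent values), trait order as above.
DEFAULT_STABILITY = np.array([0.61, 0.51, 0.58, 0.32])


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class CohortDesign:
    """Family-structure and assessment design of a simulated cohort."""

    n_mz_pairs: int = 116
    n_dz_pairs: int = 187
    n_triplet_sets: int = 14
    n_extra_siblings: int = 51
    female_fraction: float = 419 / 671
    age_mean: float = 14.5
    age_sd: float = 2.4
    age_range: tuple[float, float] = (10.1, 31.1)
    overlap_fraction: float = 1.0  # of 16-19-year-olds taking both stress scales
    retest_fraction: float = 146 / 671
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_triplet_sets", "n_extra_siblings"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("female_fraction", "overlap_fraction", "retest_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be an increasing pair")
        # n_dz_pairs counts ALL DZ pairs, including the triplet-derived
        # ones; a design specifying only triplet sets still yields one DZ
        # pair per set.
        if self.n_mz_pairs + max(self.n_dz_pairs, self.n_triplet_sets) == 0:
            raise ValueError("design produces an empty cohort (no families)")


def _cholesky_from_pct(pct: np.ndarray) -> np.ndarray:
    return np.sqrt(np.asarray(pct, float) / 100.0)


@dataclass
class TrueModel:
    """Generating parameters for latent traits, means and HCC scale.

    X/Y/Z are p x p lower-triangular path matrices for A/C/E.
    ``mean_betas`` is (6, p): coefficients for intercept, sex (1 =
    female), centered age, age^2, sex*age and sex*age^2 on the latent
    scale.  Experimental effects act additively on log10(HCC):
    batch/storage/study effects are i.i.d. normal per level with the
    given SDs, month effects follow a sinusoid peaking in ``month_peak``
    (March, end of the Australian summer, by default).
    """

    X: np.ndarray = field(default_factory=lambda: _cholesky_from_pct(TABLE_A_PCT))
    Y: np.ndarray | None = None
    Z: np.ndarray = field(default_factory=lambda: _cholesky_from_pct(TABLE_E_PCT))
    mean_betas: np.ndarray | None = None
    stability: np.ndarray = field(default_factory=lambda: DEFAULT_STABILITY.copy())
    hcc_log_mean: float = 0.55
    hcc_log_sd: float = 0.35
    hcc_offset: float = 0.1
    n_batches: int = 35
    n_storage_groups: int = 5
    n_study_phases: int = 6
    n_waves: int = 2
    batch_sd: float = 0.08
    storage_sd: float = 0.05
    study_sd: float = 0.08
    month_amplitude: float = 0.10
    month_peak: int = 3

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        p = self.X.shape[0]
        if self.Y is None:
            self.Y = np.zeros((p, p))
        self.Y = np.asarray(self.Y, float)
        self.Z = np.asarray(self.Z, float)
        for m in (self.X, self.Y, self.Z):
            if m.shape != (p, p) or not np.allclose(m, np.tril(m)):
                raise ValueError("path matrices must be p x p lower-triangular")
        if self.mean_betas is None:
            self.mean_betas = np.zeros((6, p))
        self.mean_betas = np.asarray(self.mean_betas, float)
        eig = np.linalg.eigvalsh(self.sigma())
        if eig.min() <= 1e-10:
            raise ValueError("implied trait covariance is not positive definite")

    @property
    def p(self) -> int:
        return self.X.shape[0]

    def sigma(self) -> np.ndarray:
        return self.X @ self.X.T + self.Y @ self.Y.T + self.Z @ self.Z.T


def default_true_model() -> TrueModel:
    """Published-solution AE truth with mild sex/age mean effects.

    Female (sex = 1) raises depressive symptoms and neuroticism and
    slightly lowers HCC on the latent scale; stress and neuroticism
    drift up mildly with age.  Magnitudes are generator choices sized
    to echo the observed sex differences of the source cohort.
    """
    betas = np.zeros((6, 4))
    betas[1] = [0.05, 0.15, 0.20, -0.03]  # sex (female)
    betas[2] = [0.02, 0.00, 0.015, 0.0]  # centered age
    return TrueModel(mean_betas=betas)


@dataclass
class TwinCohort:
    """Individuals table plus the design that produced it."""

    individuals: pd.DataFrame
    design: CohortDesign

    @property
    def n(self) -> int:
        return len(self.individuals)

    def pairs(self, zygosity: str) -> pd.DataFrame:
        """Wide table of co-twin person_ids for the given zygosity."""
        twins = self.individuals[
            (self.individuals.zygosity == zygosity)
            & self.individuals.role.isin(["twin1", "twin2"])
        ]
        wide = twins.pivot(index="family_id", columns="role", values="person_id")
        return wide.dropna()

    def pedigree(self) -> pd.DataFrame:
        cols = ["family_id", "person_id", "zygosity", "role", "sex", "age_t1", "age_t2"]
        return self.individuals[cols].copy()


def build_cohort(design: CohortDesign, rng=None) -> TwinCohort:
    """Realize the family structure, ages, sexes and experimental labels.

    Triplet sets are represented as a DZ pair plus one singleton in the
    same family; extra siblings are singletons attached to existing
    families.  Co-twins share age (and, for MZ, sex); the triplet
    singleton shares the pair's age.  Experimental labels (batch, month,
    storage group, study phase, genotyping wave) are assigned uniformly
    at random per person, irrespective of family.
    """
    rng = _rng(design.seed if rng is None else rng)
    lo, hi = design.age_range
    a, b = (lo - design.age_mean) / design.age_sd, (hi - design.age_mean) / design.age_sd

    def draw_age(size):
        return stats.truncnorm.rvs(
            a, b, loc=design.age_mean, scale=design.age_sd, size=size, random_state=rng
        )

    n_mz, n_trip = design.n_mz_pairs, design.n_triplet_sets
    n_dz = max(design.n_dz_pairs, n_trip)
    n_fam = n_mz + n_dz
    mz_ages = draw_age(n_mz)
    dz_ages = draw_age(n_dz)
    sib_ages = draw_age(design.n_extra_siblings)
    frac = design.female_fraction

    def exact_sexes(size):
        # stratified-exact assignment: the realized female count matches
        # the configured fraction up to rounding, not just in expectation
        n_f = int(round(frac * size))
        out = np.zeros(size, bool)
        out[:n_f] = True
        return rng.permutation(out)

    mz_sex = exact_sexes(n_mz)
    dz_sex = exact_sexes(2 * n_dz).reshape(-1, 2) if n_dz else np.zeros((0, 2), bool)
    trip_sex = exact_sexes(n_trip)
    sib_sex = exact_sexes(design.n_extra_siblings)
    sib_host = rng.integers(0, n_fam, design.n_extra_siblings) if n_fam else np.array([], int)

    rows: list[tuple] = []
    pid = 0

    def add(fid, zyg, role, sex, age):
        nonlocal pid
        rows.append((f"F{fid:04d}", f"P{pid:05d}", zyg, role, int(sex), float(age)))
        pid += 1

    for i in range(n_mz):
        add(i, "MZ", "twin1", mz_sex[i], mz_ages[i])
        add(i, "MZ", "twin2", mz_sex[i], mz_ages[i])
    for i in range(n_dz):
        fid = n_mz + i
        add(fid, "DZ", "twin1", dz_sex[i, 0], dz_ages[i])
        add(fid, "DZ", "twin2", dz_sex[i, 1], dz_ages[i])
        if i < n_trip:  # triplet set: DZ pair + co-aged singleton
            add(fid, "singleton", "singleton", trip_sex[i], dz_ages[i])
    for j in range(design.n_extra_siblings):
        add(int(sib_host[j]), "singleton", "singleton", sib_sex[j], sib_ages[j])

    ind = pd.DataFrame(
        rows, columns=["family_id", "person_id", "zygosity", "role", "sex", "age_t1"]
    )
    ind = ind.sort_values(["family_id", "person_id"], kind="stable").reset_index(drop=True)
    n = len(ind)
    ind["batch"] = [f"B{int(x):02d}" for x in rng.integers(0, 35, n)]
    ind["month"] = rng.integers(1, 13, n)
    ind["storage_group"] = [f"S{int(x)}" for x in rng.integers(0, 5, n)]
    ind["study_phase"] = [f"PH{int(x)}" for x in rng.integers(0, 6, n)]
    ind["genotyping_wave"] = [f"W{int(x)}" for x in rng.integers(0, 2, n)]
    retest = rng.random(n) < design.retest_fraction
    ind["age_t2"] = np.where(retest, ind["age_t1"] + 2.0, np.nan)
    return TwinCohort(individuals=ind, design=design)


def _factor_scores(cohort: TwinCohort, p: int, kind: str, rng) -> np.ndarray:
    """Standard-normal factor scores with the family sharing rule of `kind`.

    kind 'A': MZ co-twins identical; DZ co-twins and singleton siblings
    correlate 0.5 with every other family member (shared + specific
    construction).  kind 'C': identical within family.  kind 'E':
    independent.
    """
    ind = cohort.individuals
    n = len(ind)
    if kind == "E":
        return rng.standard_normal((n, p))
    fam_codes, _ = pd.factorize(ind["family_id"], sort=False)
    n_fam = int(fam_codes.max()) + 1 if n else 0
    shared = rng.standard_normal((n_fam, p))
    if kind == "C":
        return shared[fam_codes]
    spec = rng.standard_normal((n, p))
    # MZ co-twins share their person-specific part (hence identical A
    # scores) while remaining 0.5-correlated with any sibling.
    is_mz = (ind["zygosity"] == "MZ").to_numpy()
    role = ind["role"].to_numpy()
    twin1_row = {fam_codes[i]: i for i in np.nonzero(is_mz & (role == "twin1"))[0]}
    for i in np.nonzero(is_mz & (role == "twin2"))[0]:
        spec[i] = spec[twin1_row[fam_codes[i]]]
    return np.sqrt(0.5) * shared[fam_codes] + np.sqrt(0.5) * spec


def mean_design(ind: pd.DataFrame, age_col: str = "age_t1", age_center: float | None = None) -> np.ndarray:
    """Fixed-effect design: intercept, sex, age_c, age_c^2, sex*age_c, sex*age_c^2."""
    age = ind[age_col].to_numpy(float)
    if age_center is None:
        age_center = float(np.nanmean(age))
    ac = age - age_center
    sex = ind["sex"].to_numpy(float)
    return np.column_stack([np.ones_like(ac), sex, ac, ac**2, sex * ac, sex * ac**2])


def draw_latent_traits(
    cohort: TwinCohort,
    truth: TrueModel,
    seed=None,
    include_retest: bool = True,
) -> dict[int, np.ndarray]:
    """Draw per-person latent trait matrices for each time point.

    Returns ``{1: (n, p), 2: (n, p)}``; time-2 rows are NaN for persons
    without a retest.  Time-2 latents regress toward time 1 at the
    per-trait stability coefficients (same A/C/E sharing in the
    innovation), so Pearson r between time points equals the configured
    stability.  The fixed-effect mean contribution uses time-1 age.
    """
    rng = _rng(seed)
    p = truth.p
    a = _factor_scores(cohort, p, "A", rng)
    c = _factor_scores(cohort, p, "C", rng)
    e = _factor_scores(cohort, p, "E", rng)
    core1 = a @ truth.X.T + c @ truth.Y.T + e @ truth.Z.T
    mu = mean_design(cohort.individuals) @ truth.mean_betas
    out = {1: core1 + mu}
    if include_retest:
        rho = np.asarray(truth.stability, float)
        a2 = _factor_scores(cohort, p, "A", rng)
        c2 = _factor_scores(cohort, p, "C", rng)
        e2 = _factor_scores(cohort, p, "E", rng)
        innov = a2 @ truth.X.T + c2 @ truth.Y.T + e2 @ truth.Z.T
        core2 = core1 * rho + innov * np.sqrt(1.0 - rho**2)
        t2 = core2 + mu
        no_retest = cohort.individuals["age_t2"].isna().to_numpy()
        t2[no_retest] = np.nan
        out[2] = t2
    return out


def realize_experimental_effects(truth: TrueModel, seed=None) -> dict[str, dict]:
    """Draw the per-level additive log10-scale effects for HCC.

    Batch/storage/study effects are i.i.d. N(0, sd); storage effects are
    then sorted descending so HCC falls with storage time; month effects
    are ``amplitude * cos(2*pi*(month - peak)/12)``.
    """
    rng = _rng(seed)
    storage = np.sort(rng.normal(0.0, truth.storage_sd, truth.n_storage_groups))[::-1]
    months = {
        m: truth.month_amplitude * np.cos(2 * np.pi * (m - truth.month_peak) / 12.0)
        for m in range(1, 13)
    }
    return {
        "batch": {f"B{i:02d}": v for i, v in enumerate(rng.normal(0, truth.batch_sd, truth.n_batches))},
        "storage_group": {f"S{i}": v for i, v in enumerate(storage)},
        "study_phase": {f"PH{i}": v for i, v in enumerate(rng.normal(0, truth.study_sd, truth.n_study_phases))},
        "month": months,
    }


def emit_hcc_raw(
    latent_hcc: np.ndarray,
    individuals: pd.DataFrame,
    truth: TrueModel,
    effects: dict[str, dict] | None = None,
    seed=None,
) -> np.ndarray:
    """Map latent HCC to raw pg/mg via the log10 scale model.

    raw = 10**(log_mean + log_sd*latent + batch + month + storage +
    study) - offset, floored at 0 (concentrations cannot be negative).
    Inverts the downstream log10(x + offset) transform at zero effects.
    """
    if effects is None:
        effects = realize_experimental_effects(truth, seed)
    log10 = truth.hcc_log_mean + truth.hcc_log_sd * np.asarray(latent_hcc, float)
    log10 = log10 + individuals["batch"].map(effects["batch"]).to_numpy(float)
    log10 = log10 + individuals["month"].map(effects["month"]).to_numpy(float)
    log10 = log10 + individuals["storage_group"].map(effects["storage_group"]).to_numpy(float)
    log10 = log10 + individuals["study_phase"].map(effects["study_phase"]).to_numpy(float)
    return np.maximum(10.0**log10 - truth.hcc_offset, 0.0)


# ---------------------------------------------------------------------------
# questionnaire items
# ---------------------------------------------------------------------------

#: instrument -> (trait, n_items, n_categories, age rule)
INSTRUMENTS = {
    "DLSS": ("stress", 30, 4, "young"),
    "PSS": ("stress", 10, 5, "old"),
    "JEPQ": ("neuro", 20, 2, "young"),
    "NEO": ("neuro", 12, 5, "old"),
    "SPHERE": ("dep", 34, 3, "all"),
}

#: default whole-instrument missingness, echoing the observed 1/51/55
#: missing out of 671 for stress/neuroticism/depressive symptoms.
DEFAULT_MISSING_RATES = {"stress": 1 / 671, "neuro": 51 / 671, "dep": 55 / 671}


@dataclass
class IrtTruth:
    """Generating item parameters for every instrument."""

    items: dict[str, dict]  # instrument -> {"a": (k,), "b": (k, K-1)}

    @classmethod
    def default(cls, seed=0, disc_sigma: float = 0.3, threshold_span: float = 3.0) -> "IrtTruth":
        """Discriminations log-normal(0, sigma); thresholds equally spaced
        over ±span/2 with a small item-location jitter."""
        rng = _rng(seed)
        items = {}
        for inst, (_, k, ncat, _) in INSTRUMENTS.items():
            a = rng.lognormal(0.0, disc_sigma, k)
            base = np.linspace(-threshold_span / 2, threshold_span / 2, ncat - 1)
            shift = rng.normal(0.0, 0.3, k)
            b = base[None, :] + shift[:, None]
            items[inst] = {"a": a, "b": b}
        return cls(items=items)

    def __post_init__(self) -> None:
        for inst, pars in self.items.items():
            b = np.atleast_2d(np.asarray(pars["b"], float))
            if b.shape[1] > 1 and not np.all(np.diff(b, axis=1) > 0):
                raise ValueError(f"{inst}: item thresholds must be strictly increasing")


def grm_category_probs(theta: np.ndarray, a: float, b: np.ndarray) -> np.ndarray:
    """Graded-response category probabilities at abilities `theta`.

    P(Y >= k) = logistic(a * (theta - b_k)); columns are the K category
    probabilities.
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    b = np.asarray(b, float)
    cum = 1.0 / (1.0 + np.exp(-a * (theta[:, None] - b[None, :])))
    upper = np.column_stack([np.ones(len(theta)), cum])
    lower = np.column_stack([cum, np.zeros(len(theta))])
    return upper - lower


def _sample_items(theta, a_vec, b_mat, rng) -> np.ndarray:
    n, k = len(theta), len(a_vec)
    out = np.empty((n, k), dtype=float)
    for j in range(k):
        probs = grm_category_probs(theta, a_vec[j], b_mat[j])
        u = rng.random(n)
        out[:, j] = (u[:, None] > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1)
    return out


def emit_items(
    latent: dict[str, np.ndarray],
    cohort: TwinCohort,
    irt_truth: IrtTruth,
    seed=None,
    missing_rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Sample ordinal questionnaire responses for every person.

    Instrument assignment follows age at time 1: under-16s answer the
    DLSS (stress) and JEPQ (neuroticism); 16-and-overs the PSS and NEO;
    everyone the SPHERE (depressive symptoms).  A configurable fraction
    of 16-19-year-olds additionally completes the DLSS so the two stress
    scales overlap.  Missingness knocks out whole instruments per person
    at the configured per-trait rates.  Returns a wide table of
    ``<instrument>_i<j>`` columns (NaN where not administered).
    """
    rng = _rng(seed)
    if missing_rates is None:
        missing_rates = DEFAULT_MISSING_RATES
    ind = cohort.individuals
    n = len(ind)
    age = ind["age_t1"].to_numpy(float)
    young = age < 16
    overlap = (~young) & (age < 19) & (rng.random(n) < cohort.design.overlap_fraction)
    administered = {
        "DLSS": young | overlap,
        "PSS": ~young,
        "JEPQ": young,
        "NEO": ~young,
        "SPHERE": np.ones(n, bool),
    }
    drop = {t: rng.random(n) < missing_rates.get(t, 0.0) for t in ("stress", "dep", "neuro")}
    cols = {}
    for inst, (trait, k, _, _) in INSTRUMENTS.items():
        pars = irt_truth.items[inst]
        resp = np.full((n, k), np.nan)
        mask = administered[inst] & ~drop[trait] & ~np.isnan(latent[trait])
        if mask.any():
            resp[mask] = _sample_items(latent[trait][mask], pars["a"], pars["b"], rng)
        for j in range(k):
            cols[f"{inst}_i{j + 1}"] = resp[:, j]
    out = pd.DataFrame(cols)
    out.insert(0, "person_id", ind["person_id"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# genotypes and discovery GWAS
# ---------------------------------------------------------------------------


def _draw_family_genotypes(cohort: TwinCohort, freqs: np.ndarray, rng) -> np.ndarray:
    """Mendelian transmission within families; (n_persons, m) dosages.

    Each family gets two parents with haplotypes drawn at the variant
    frequencies; every child receives one haplotype from each parent
    (MZ co-twins share the same transmission, DZ co-twins and siblings
    draw independently, giving expected genotype correlation 0.5).
    """
    ind = cohort.individuals
    m = len(freqs)
    out = np.empty((len(ind), m), dtype=np.int8)
    for _, idx in ind.groupby("family_id", sort=False).indices.items():
        parents = rng.random((4, m)) < freqs  # maternal x2, paternal x2
        mz_transmission = None
        for row_pos in idx:
            zyg = ind.iat[row_pos, ind.columns.get_loc("zygosity")]
            if zyg == "MZ":
                if mz_transmission is None:
                    mz_transmission = (rng.integers(0, 2), rng.integers(0, 2))
                mi, pi = mz_transmission
            else:
                mi, pi = rng.integers(0, 2), rng.integers(0, 2)
            out[row_pos] = parents[mi].astype(np.int8) + parents[2 + pi].astype(np.int8)
    return out


def emit_genotypes_and_gwas(
    cohort: TwinCohort,
    m_variants: int = 2000,
    n_causal: int = 50,
    discovery_n: int = 5000,
    seed=None,
    causal_traits: tuple[str, ...] = ("hcc", "dep", "neuro"),
    snp_h2: float = 0.3,
    freq_range: tuple[float, float] = (0.05, 0.5),
):
    """Generate target-cohort genotypes plus per-trait discovery GWAS.

    Each trait in ``causal_traits`` gets its own disjoint set of
    ``n_causal`` causal variants with N(0, 1)-drawn standardized
    effects.  Discovery summary statistics come from per-variant OLS in
    an independent unrelated population of ``discovery_n`` people whose
    phenotype carries ``snp_h2`` of its variance from the causal set.

    Returns ``(VariantTable, {trait: sumstats DataFrame},
    {trait: standardized genetic value per cohort person})``.
    """
    from .io import VariantTable

    rng = _rng(seed)
    if not 0 < freq_range[0] < freq_range[1] < 1:
        raise ValueError("allele frequencies must lie strictly inside (0, 1)")
    if n_causal * len(causal_traits) > m_variants:
        raise ValueError("need m_variants >= n_causal per causal trait")
    freqs = rng.uniform(*freq_range, m_variants)
    meta = pd.DataFrame(
        {
            "id": [f"rs{i + 1}" for i in range(m_variants)],
            "chrom": (np.arange(m_variants) % 22 + 1).astype(str),
            "pos": (np.arange(m_variants) // 22 + 1) * 5000,
            "ref": "A",
            "alt": "G",
        }
    )
    target = _draw_family_genotypes(cohort, freqs, rng).astype(float)

    causal_idx: dict[str, np.ndarray] = {}
    betas: dict[str, np.ndarray] = {}
    perm = rng.permutation(m_variants)
    for t, trait in enumerate(causal_traits):
        idx = np.sort(perm[t * n_causal : (t + 1) * n_causal])
        causal_idx[trait] = idx
        betas[trait] = rng.standard_normal(n_causal)

    sd = np.sqrt(2 * freqs * (1 - freqs))

    def genetic_value(geno: np.ndarray, trait: str) -> np.ndarray:
        idx = causal_idx[trait]
        if len(idx) == 0:  # null GWAS: no causal variants
            return np.zeros(len(geno))
        gstd = (geno[:, idx] - 2 * freqs[idx]) / sd[idx]
        gv = gstd @ betas[trait]
        return gv / np.sqrt(len(idx))  # unit-ish variance

    sumstats: dict[str, pd.DataFrame] = {}
    # one shared discovery genotype pool per trait, chunked over variants
    for trait in causal_traits:
        geno = (rng.random((discovery_n, m_variants)) < freqs).astype(np.int8) + (
            rng.random((discovery_n, m_variants)) < freqs
        ).astype(np.int8)
        geno = geno.astype(np.float32)
        gv = genetic_value(geno, trait)
        if gv.std() > 0:
            gv = np.sqrt(snp_h2) * gv / gv.std()
        y = gv + np.sqrt(1 - snp_h2) * rng.standard_normal(discovery_n)
        gc = geno - geno.mean(axis=0)
        yc = y - y.mean()
        ssx = (gc**2).sum(axis=0)
        beta = (gc * yc[:, None]).sum(axis=0) / ssx
        resid_var = ((yc**2).sum() - beta**2 * ssx) / (discovery_n - 2)
        se = np.sqrt(resid_var / ssx)
        tstat = beta / se
        pval = 2 * stats.t.sf(np.abs(tstat), discovery_n - 2)
        pval = np.clip(pval, np.finfo(float).tiny, 1.0)
        sumstats[trait] = pd.DataFrame(
            {
                "SNP": meta["id"],
                "CHR": meta["chrom"],
                "BP": meta["pos"],
                "A1": meta["alt"],
                "A2": meta["ref"],
                "FREQ": freqs,
                "BETA": beta.astype(float),
                "SE": se.astype(float),
                "P": pval,
            }
        )
    def _standardized(g: np.ndarray) -> np.ndarray:
        return (g - g.mean()) / g.std() if g.std() > 0 else g

    gvalues = {trait: _standardized(genetic_value(target, trait)) for trait in causal_traits}
    table = VariantTable(
        variants=meta,
        dosages=target.T,
        persons=list(cohort.individuals["person_id"]),
    )
    return table, sumstats, gvalues


# ---------------------------------------------------------------------------
# one-call simulation of the full study inputs
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    cohort: TwinCohort
    truth: TrueModel
    irt_truth: IrtTruth
    latent: dict[int, np.ndarray]
    phenotypes: pd.DataFrame  # long: person x time point, hcc_raw + items + labels
    genotypes: object | None
    sumstats: dict[str, pd.DataFrame]
    experimental_effects: dict[str, dict]


def simulate_study(
    design: CohortDesign | None = None,
    truth: TrueModel | None = None,
    seed: int = 0,
    with_genotypes: bool = True,
    gwas_kwargs: dict | None = None,
    prs_effect: float = 0.25,
) -> SimulatedStudy:
    """Generate every input table of the study from a single seed.

    Seeds are split into per-component substreams
    (cohort/latents/effects/items/genotypes) via ``SeedSequence.spawn``
    so components are independently reproducible.  When genotypes are
    generated, each causal trait's standardized genetic value is blended
    into its latent trait at weight ``prs_effect`` (trait rescaled to
    keep unit-ish variance) so polygenic-score associations have truth.
    """
    design = design or CohortDesign(seed=seed)
    truth = truth or default_true_model()
    ss = np.random.SeedSequence(seed)
    sub = {k: np.random.default_rng(s) for k, s in zip(
        ("cohort", "latent", "effects", "items", "geno"), ss.spawn(5))}
    cohort = build_cohort(design, rng=sub["cohort"])
    latent = draw_latent_traits(cohort, truth, seed=sub["latent"])

    genotypes, sumstats, gvalues = None, {}, {}
    if with_genotypes:
        genotypes, sumstats, gvalues = emit_genotypes_and_gwas(
            cohort, seed=sub["geno"], **(gwas_kwargs or {})
        )
        w = float(prs_effect)
        for trait, gv in gvalues.items():
            j = TRAITS.index(trait)
            for t in latent:
                latent[t][:, j] = (latent[t][:, j] + w * gv) / np.sqrt(1 + w**2)

    irt_truth = IrtTruth.default(seed=seed)
    effects = realize_experimental_effects(truth, seed=sub["effects"])
    ind = cohort.individuals
    frames = []
    for t, lat in latent.items():
        present = ~np.isnan(lat).all(axis=1)
        items = emit_items(
            {k: lat[:, i] for i, k in enumerate(TRAITS)}, cohort, irt_truth, seed=sub["items"]
        )
        hcc_raw = emit_hcc_raw(lat[:, TRAITS.index("hcc")], ind, truth, effects=effects)
        frame = pd.concat(
            [
                ind[["person_id", "sex", "batch", "month", "storage_group",
                     "study_phase", "genotyping_wave"]].reset_index(drop=True),
                items.drop(columns="person_id"),
            ],
            axis=1,
        )
        frame.insert(1, "time_point", t)
        frame.insert(2, "age", ind[f"age_t{t}"].to_numpy(float))
        frame.insert(3, "hcc_raw", hcc_raw)
        frames.append(frame[present])
    phenotypes = pd.concat(frames, ignore_index=True)
    return SimulatedStudy(
        cohort=cohort,
        truth=truth,
        irt_truth=irt_truth,
        latent=latent,
        phenotypes=phenotypes,
        genotypes=genotypes,
        sumstats=sumstats,
        experimental_effects=effects,
    )


def truth_payload(study: SimulatedStudy) -> dict:
    """JSON-serializable record of all generating parameters."""
    t = study.truth
    return {
        "traits": TRAITS[: t.p],
        "X": t.X,
        "Y": t.Y,
        "Z": t.Z,
        "mean_betas": t.mean_betas,
        "stability": t.stability,
        "hcc": {"log_mean": t.hcc_log_mean, "log_sd": t.hcc_log_sd, "offset": t.hcc_offset},
        "experimental_effects": study.experimental_effects,
        "design": vars(study.cohort.design),
    }
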