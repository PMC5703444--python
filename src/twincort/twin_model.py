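"""Multivariate Cholesky ACE/AE/CE twin models by FIML.

The phenotypic covariance of p traits is decomposed as
``Sigma = A + C + E`` with ``A = X X'``, ``C = Y Y'``, ``E = Z Z'`` and
X, Y, Z lower-triangular path matrices (Cholesky parameterization, so
each component matrix is positive semidefinite by construction).  The
expected cross-relative covariance is ``r A + C`` with A-sharing
coefficient r = 1 for MZ co-twins and r = 0.5 for DZ co-twins and full
siblings.  Every family contributes the multivariate-normal density of
its *observed* trait entries (full-information maximum likelihood), so
unpaired twins, singleton siblings and partially missing trait vectors
all enter the likelihood.  Trait means are modelled inside the
likelihood as sex, centered age, age^2, sex*age and sex*age^2 fixed
effects per trait.

Model selection uses likelihood-ratio chi-square tests between nested
models (ACE vs AE/CE); reported quantities are standardized variance
components, per-trait heritabilities, genetic/environmental
correlations and profile-likelihood confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

LN2PI = float(np.log(2.0 * np.pi))

#: analysis trait order: HCC enters last so its final Cholesky factor
#: captures genetic variance independent of the psychological traits
DEFAULT_TRAITS = ["stress", "dep", "neuro", "hcc"]

_PENALTY = 1e12


# ---------------------------------------------------------------------------
# model specification and parameter packing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Which variance components are free; E is always present."""

    components: str = "ACE"  # "ACE", "AE" or "CE"
    traits: tuple[str, ...] = tuple(DEFAULT_TRAITS)
    covariates: str = "saturated"  # "saturated" (sex/age polynomial) or "intercept"

    def __post_init__(self) -> None:
        if self.components not in ("ACE", "AE", "CE", "E"):
            raise ValueError("components must be one of ACE, AE, CE, E")

    @property
    def p(self) -> int:
        return len(self.traits)

    @property
    def has_a(self) -> bool:
        return "A" in self.components

    @property
    def has_c(self) -> bool:
        return "C" in self.components

    def n_path_params(self) -> int:
        ntri = self.p * (self.p + 1) // 2
        return ntri * (1 + self.has_a + self.has_c)


def _tril_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(p)


def _vec_to_tril(vec: np.ndarray, p: int) -> np.ndarray:
    m = np.zeros((p, p))
    m[np.tril_indices(p)] = vec
    return m


def _tril_to_vec(m: np.ndarray) -> np.ndarray:
    return np.asarray(m)[np.tril_indices(m.shape[0])]


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class _Group:
    """Families sharing one relatedness matrix and missingness pattern."""

    relatedness: np.ndarray  # (k, k) A-sharing coefficients, unit diagonal
    mask: np.ndarray  # (k*p,) bool, member-major stacking
    y: np.ndarray  # (n_fam, n_obs)
    W: np.ndarray  # (n_fam, k, q) member covariate designs

    @property
    def n_members(self) -> int:
        return self.relatedness.shape[0]


@dataclass
class TwinData:
    """FIML-ready family blocks for one trait set."""

    traits: tuple[str, ...]
    groups: list[_Group]
    q: int
    n_families: int
    n_persons: int
    age_center: float
    trait_sd: np.ndarray
    beta_start: np.ndarray  # (q, p) OLS per-trait start values

    @property
    def p(self) -> int:
        return len(self.traits)


def _covariate_design(sex: np.ndarray, age: np.ndarray, mode: str, center: float) -> np.ndarray:
    if mode == "intercept":
        return np.ones((len(sex), 1))
    ac = age - center
    return np.column_stack([np.ones_like(ac), sex, ac, ac**2, sex * ac, sex * ac**2])


def build_twin_data(
    prepared: pd.DataFrame,
    pedigree: pd.DataFrame,
    traits=DEFAULT_TRAITS,
    covariates: str = "saturated",
    time_point: int = 1,
    singleton_mode: str = "independent",
) -> TwinData:
    """Assemble family likelihood blocks from prepared phenotypes.

    ``singleton_mode='independent'`` treats non-twin family members as
    their own single-person families (the default analysis convention);
    ``'family'`` keeps them in the family block with DZ-like 0.5
    A-sharing to every other member.
    """
    traits = tuple(traits)
    df = prepared[prepared["time_point"] == time_point].merge(
        pedigree[["person_id", "family_id", "zygosity", "role"]], on="person_id", how="inner"
    )
    tmat = df[list(traits)].to_numpy(float)
    keep = ~np.isnan(tmat).all(axis=1)
    df, tmat = df[keep].reset_index(drop=True), tmat[keep]
    center = float(np.nanmean(df["age"]))
    W_all = _covariate_design(df["sex"].to_numpy(float), df["age"].to_numpy(float), covariates, center)
    q, p = W_all.shape[1], len(traits)

    # starting values: per-trait OLS betas and residual SDs
    beta_start = np.zeros((q, p))
    trait_sd = np.ones(p)
    for j in range(p):
        obs = ~np.isnan(tmat[:, j])
        if obs.sum() > q:
            b, *_ = np.linalg.lstsq(W_all[obs], tmat[obs, j], rcond=None)
            beta_start[:, j] = b
            trait_sd[j] = np.std(tmat[obs, j] - W_all[obs] @ b, ddof=q)

    units: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []  # (R, y_stack, W_stack)
    n_persons = 0
    for _, idx in df.groupby("family_id", sort=False).indices.items():
        idx = np.asarray(idx)
        roles = df["role"].to_numpy()[idx]
        is_twin = np.isin(roles, ["twin1", "twin2"])
        order = np.concatenate([idx[is_twin][np.argsort(roles[is_twin])], idx[~is_twin]])
        members = list(order)
        n_persons += len(members)
        if singleton_mode == "independent":
            twin_rows = [i for i in members if df["role"].iat[i] in ("twin1", "twin2")]
            single_rows = [i for i in members if i not in twin_rows]
            if len(twin_rows) == 2:
                r = 1.0 if df["zygosity"].iat[twin_rows[0]] == "MZ" else 0.5
                R = np.array([[1.0, r], [r, 1.0]])
                units.append((R, tmat[twin_rows], W_all[twin_rows]))
            else:
                single_rows = twin_rows + single_rows
            for i in single_rows:
                units.append((np.ones((1, 1)), tmat[[i]], W_all[[i]]))
        else:
            k = len(members)
            R = np.full((k, k), 0.5)
            np.fill_diagonal(R, 1.0)
            mz_twins = [
                m
                for m in range(k)
                if df["zygosity"].iat[members[m]] == "MZ"
                and df["role"].iat[members[m]] in ("twin1", "twin2")
            ]
            for a_i in mz_twins:
                for b_i in mz_twins:
                    R[a_i, b_i] = 1.0
            units.append((R, tmat[members], W_all[members]))

    # group units by (relatedness, missingness) pattern for vectorization
    buckets: dict[bytes, list] = {}
    for R, y, W in units:
        mask = ~np.isnan(y.ravel())
        if not mask.any():
            continue
        key = R.tobytes() + b"|" + mask.tobytes()
        buckets.setdefault(key, []).append((R, mask, y.ravel()[mask], W))
    groups = []
    for entries in buckets.values():
        R, mask = entries[0][0], entries[0][1]
        groups.append(
            _Group(
                relatedness=R,
                mask=mask,
                y=np.vstack([e[2] for e in entries]),
                W=np.stack([e[3] for e in entries]),
            )
        )
    return TwinData(
        traits=traits,
        groups=groups,
        q=q,
        n_families=len(units),
        n_persons=n_persons,
        age_center=center,
        trait_sd=trait_sd,
        beta_start=beta_start,
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def expected_pair_cov(X, Y, Z, zygosity: str) -> np.ndarray:
    """Expected 2p x 2p twin-pair covariance under the Cholesky model.

    Within-person blocks are A + C + E; the cross-twin block is A + C
    for MZ and 0.5 A + C for DZ pairs.
    """
    X = np.asarray(X, float)
    Y = np.zeros_like(X) if Y is None else np.asarray(Y, float)
    Z = np.asarray(Z, float)
    A, C, E = X @ X.T, Y @ Y.T, Z @ Z.T
    if zygosity == "MZ":
        r = 1.0
    elif zygosity == "DZ":
        r = 0.5
    else:
        raise ValueError(f"unknown zygosity: {zygosity!r}")
    within = A + C + E
    cross = r * A + C
    return np.block([[within, cross], [cross, within]])


def neg2ll_fiml(X, Y, Z, betas, data: TwinData, on_singular: str = "penalty") -> float:
    """-2 log likelihood summed over family blocks.

    Each block contributes ``k ln(2 pi) + ln|Sigma_obs| +
    (y - mu)' Sigma_obs^-1 (y - mu)`` over its observed entries.  A
    numerically singular block covariance returns a large penalty when
    ``on_singular='penalty'`` (optimizer-safe) and raises otherwise.
    """
    X = np.asarray(X, float)
    p = X.shape[0]
    Yc = np.zeros((p, p)) if Y is None else np.asarray(Y, float)
    Z = np.asarray(Z, float)
    A, C, E = X @ X.T, Yc @ Yc.T, Z @ Z.T
    B = np.asarray(betas, float)
    total = 0.0
    for g in data.groups:
        k = g.n_members
        J = np.ones((k, k))
        sigma = np.kron(g.relatedness, A) + np.kron(J, C) + np.kron(np.eye(k), E)
        sig = sigma[np.ix_(g.mask, g.mask)]
        try:
            cf = cho_factor(sig, lower=True)
        except np.linalg.LinAlgError:
            if on_singular == "penalty":
                return _PENALTY
            raise
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        mu = (g.W @ B).reshape(len(g.y), -1)[:, g.mask]
        resid = g.y - mu
        quad = float((resid * cho_solve(cf, resid.T).T).sum())
        total += len(g.y) * (g.mask.sum() * LN2PI + logdet) + quad
    return total


@dataclass
class CholeskyModelFit:
    spec: ModelSpec
    X: np.ndarray
    Y: np.ndarray | None
    Z: np.ndarray
    betas: np.ndarray
    minus2ll: float
    n_free_params: int
    converged: bool
    n_families: int
    age_center: float = float("nan")
    start_log: list = field(default_factory=list)

    @property
    def A(self) -> np.ndarray:
        return self.X @ self.X.T

    @property
    def C(self) -> np.ndarray | None:
        return None if self.Y is None else self.Y @ self.Y.T

    @property
    def E(self) -> np.ndarray:
        return self.Z @ self.Z.T

    def sigma(self) -> np.ndarray:
        out = self.A + self.E
        if self.Y is not None:
            out = out + self.C
        return out


def _pack(spec: ModelSpec, X, Y, Z, B) -> np.ndarray:
    parts = []
    if spec.has_a:
        parts.append(_tril_to_vec(X))
    if spec.has_c:
        parts.append(_tril_to_vec(Y))
    parts.append(_tril_to_vec(Z))
    parts.append(np.asarray(B).ravel())
    return np.concatenate(parts)


def _unpack(spec: ModelSpec, q: int, theta: np.ndarray):
    p = spec.p
    ntri = p * (p + 1) // 2
    pos = 0
    X = np.zeros((p, p))
    Y = None
    if spec.has_a:
        X = _vec_to_tril(theta[pos : pos + ntri], p)
        pos += ntri
    if spec.has_c:
        Y = _vec_to_tril(theta[pos : pos + ntri], p)
        pos += ntri
    Z = _vec_to_tril(theta[pos : pos + ntri], p)
    pos += ntri
    B = theta[pos : pos + q * p].reshape(q, p)
    return X, Y, Z, B


def _bounds(spec: ModelSpec, q: int) -> list[tuple]:
    # Cholesky diagonals >= 0 resolve the sign indeterminacy
    p = spec.p
    tri = [(0.0, None) if i == j else (None, None) for i, j in zip(*np.tril_indices(p))]
    nblocks = 1 + spec.has_a + spec.has_c
    return tri * nblocks + [(None, None)] * (q * p)


_START_FRACS = {
    # fractions of the observed residual SD assigned to each component's
    # diagonal start, per multi-start attempt
    "ACE": [(0.6, 0.4, 0.7), (0.4, 0.6, 0.7), (0.7, 0.2, 0.7), (0.2, 0.7, 0.7), (0.55, 0.55, 0.65)],
    "AE": [(0.7, 0.7), (0.85, 0.5), (0.5, 0.85), (0.95, 0.3), (0.3, 0.95)],
    "CE": [(0.7, 0.7), (0.85, 0.5), (0.5, 0.85), (0.95, 0.3), (0.3, 0.95)],
    "E": [(1.0,), (0.8,), (1.2,), (0.5,), (1.5,)],
}


def fit_model(
    data: TwinData,
    spec: ModelSpec,
    n_starts: int = 5,
    ftol: float = 1e-10,
    gtol: float = 1e-6,
    maxiter: int = 2000,
) -> CholeskyModelFit:
    """Minimize the FIML -2 lnL over free paths and mean coefficients.

    Multi-start quasi-Newton (L-BFGS-B, numerical gradients): diagonal
    path starts at fractions of the observed per-trait residual SDs,
    mean model started at per-trait OLS.  The best converged start wins;
    no start converging is an error carrying the per-start log.
    """
    q, p = data.q, spec.p
    if tuple(data.traits) != tuple(spec.traits):
        raise ValueError("data traits do not match spec traits")
    bounds = _bounds(spec, q)

    def objective(theta):
        X, Y, Z, B = _unpack(spec, q, theta)
        return neg2ll_fiml(X, Y, Z, B, data)

    log = []
    best = None
    for s, fracs in enumerate(_START_FRACS[spec.components][:n_starts]):
        blocks = []
        comps = (["A"] if spec.has_a else []) + (["C"] if spec.has_c else []) + ["E"]
        for frac, _comp in zip(fracs, comps):
            blocks.append(_tril_to_vec(np.diag(frac * data.trait_sd)))
        theta0 = np.concatenate(blocks + [data.beta_start.ravel()])
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": ftol, "gtol": gtol, "maxiter": maxiter, "maxfun": 10**6},
        )
        log.append({"start": s, "fun": float(res.fun), "converged": bool(res.success), "message": str(res.message)})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"no start converged; log: {log}")
    X, Y, Z, B = _unpack(spec, q, best.x)
    return CholeskyModelFit(
        spec=spec,
        X=X,
        Y=Y if spec.has_c else None,
        Z=Z,
        betas=B,
        minus2ll=float(best.fun),
        n_free_params=spec.n_path_params() + q * p,
        converged=True,
        n_families=data.n_families,
        age_center=data.age_center,
        start_log=log,
    )


# ---------------------------------------------------------------------------
# inference on fitted models
# ---------------------------------------------------------------------------


def chisq_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("statistic must be >= 0")
    return float(stats.chi2.sf(x, df))


def compare_lrt(full: CholeskyModelFit, nested: CholeskyModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a full Cholesky model."""
    free_full = set("ACE" if full.spec.components == "ACE" else full.spec.components)
    free_nested = set(nested.spec.components)
    if not free_nested < free_full:
        raise ValueError(
            f"{nested.spec.components} is not nested in {full.spec.components}"
        )
    delta = nested.minus2ll - full.minus2ll
    if delta < -1e-6:
        raise ValueError("nested model fits better than full; check convergence")
    delta = max(delta, 0.0)
    df = nested_df = full.n_free_params - nested.n_free_params
    if nested_df <= 0:
        raise ValueError("models have identical free-parameter counts")
    return delta, df, chisq_sf(delta, df)


@dataclass
class Decomposition:
    """Standardized variance components and component correlations."""

    traits: tuple[str, ...]
    standardized: dict[str, np.ndarray]  # component -> (p, p) percent table
    h2: np.ndarray
    correlations: dict[str, np.ndarray]  # rA/(rC)/rE/rP


def standardize(fit: CholeskyModelFit) -> dict[str, np.ndarray]:
    """Percent of total trait variance per squared standardized loading.

    Entry (j, k) of a component table is ``100 * path_jk^2 / Sigma_jj``;
    rows sum to 100 over all components.
    """
    sigma_jj = np.diag(fit.sigma())
    if np.any(sigma_jj <= 0):
        raise ValueError("zero total variance for a trait")
    out = {}
    pieces = [("A", fit.X)] + ([("C", fit.Y)] if fit.Y is not None else []) + [("E", fit.Z)]
    for name, path in pieces:
        out[name] = 100.0 * path**2 / sigma_jj[:, None]
    return out


def component_correlations(fit: CholeskyModelFit) -> dict[str, np.ndarray]:
    """rA/(rC)/rE from the component covariance matrices, rP from Sigma.

    A trait with zero variance in a component gets NaN correlations with
    every other trait (undefined, reported missing).
    """

    def corr(M):
        d = np.sqrt(np.diag(M))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = M / np.outer(d, d)
        r[np.diag_indices_from(r)] = np.where(np.diag(M) > 0, 1.0, np.nan)
        return r

    out = {"rA": corr(fit.A), "rE": corr(fit.E), "rP": corr(fit.sigma())}
    if fit.Y is not None:
        out["rC"] = corr(fit.C)
    return out


def decompose(fit: CholeskyModelFit) -> Decomposition:
    std = standardize(fit)
    h2 = np.diag(fit.A) / np.diag(fit.sigma())
    return Decomposition(
        traits=fit.spec.traits, standardized=std, h2=h2, correlations=component_correlations(fit)
    )


def paths_from_standardized(pct: np.ndarray, total_var: np.ndarray | None = None) -> np.ndarray:
    """Rebuild (positive-loading) paths from a standardized percent table."""
    pct = np.asarray(pct, float)
    paths = np.sqrt(pct / 100.0)
    if total_var is not None:
        paths = paths * np.sqrt(np.asarray(total_var, float))[:, None]
    return np.tril(paths)


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------


@dataclass
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    method: str
    lower_at_bound: bool = False
    upper_at_bound: bool = False


def _profiled_dev(data, spec, fit, fix_fn, grid_value) -> float:
    """-2 lnL re-optimized over all parameters except the constraint."""
    q = data.q
    theta0 = _pack(spec, fit.X, fit.Y if fit.Y is not None else np.zeros_like(fit.X), fit.Z, fit.betas)
    free_idx, fixed = fix_fn(grid_value, theta0)

    def obj(sub):
        theta = fixed.copy()
        theta[free_idx] = sub
        X, Y, Z, B = _unpack(spec, q, theta)
        return neg2ll_fiml(X, Y, Z, B, data)

    bounds_all = _bounds(spec, q)
    res = optimize.minimize(
        obj,
        fixed[free_idx],
        method="L-BFGS-B",
        bounds=[bounds_all[i] for i in free_idx],
        options={"ftol": 1e-10, "maxiter": 1000},
    )
    return float(res.fun)


def profile_ci(
    data: TwinData,
    spec: ModelSpec,
    fit: CholeskyModelFit,
    param_index: int,
    level: float = 0.95,
    lower_limit: float | None = None,
) -> ConfidenceInterval:
    """Profile-likelihood CI for one free packed parameter.

    Bounds are where -2 lnL rises by the chi-square(1) quantile above
    its minimum while all other parameters are re-optimized.  A bound
    running into the parameter-space edge (e.g. a non-negative Cholesky
    diagonal pinned at 0) yields a one-sided interval with a flag.
    """
    crit = stats.chi2.ppf(level, 1)
    theta_hat = _pack(spec, fit.X, fit.Y if fit.Y is not None else np.zeros_like(fit.X), fit.Z, fit.betas)
    v_hat = theta_hat[param_index]
    base = fit.minus2ll
    bounds_all = _bounds(spec, data.q)
    lo_edge = bounds_all[param_index][0] if lower_limit is None else lower_limit

    def fix_fn(v, theta0):
        fixed = theta0.copy()
        fixed[param_index] = v
        free = [i for i in range(len(theta0)) if i != param_index]
        return free, fixed

    def excess(v):
        return _profiled_dev(data, spec, fit, fix_fn, v) - base - crit

    step = max(0.25 * abs(v_hat), 0.1 * data.trait_sd.mean())

    def search(direction):
        v = v_hat
        prev = v
        for _ in range(40):
            v = v + direction * step
            if lo_edge is not None and v < lo_edge:
                if excess(lo_edge) < 0:
                    return float(lo_edge), True
                v = lo_edge + 1e-9
                break
            if excess(v) > 0:
                break
            prev = v
        else:
            return float(v), True
        lo, hi = (prev, v) if direction > 0 else (v, prev)
        root = optimize.brentq(excess, lo, hi, xtol=1e-5)
        return float(root), False

    upper, ub_flag = search(+1)
    lower, lb_flag = search(-1)
    return ConfidenceInterval(lower, upper, level, "profile", lb_flag, ub_flag)


def bootstrap_ci(
    data: TwinData,
    spec: ModelSpec,
    statistic,
    level: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
    n_starts: int = 2,
) -> ConfidenceInterval:
    """Family-resampling percentile bootstrap for derived quantities.

    ``statistic(fit) -> float``; the fallback CI method when profiling a
    derived multivariate quantity is impractical.
    """
    rng = np.random.default_rng(seed)
    units = []
    for g in data.groups:
        for i in range(len(g.y)):
            units.append((g.relatedness, g.mask, g.y[i], g.W[i]))
    vals = []
    for _ in range(n_boot):
        take = rng.integers(0, len(units), len(units))
        buckets: dict[bytes, list] = {}
        for t in take:
            R, mask, y, W = units[t]
            key = R.tobytes() + b"|" + mask.tobytes()
            buckets.setdefault(key, []).append((R, mask, y, W))
        groups = [
            _Group(
                relatedness=entries[0][0],
                mask=entries[0][1],
                y=np.vstack([e[2] for e in entries]),
                W=np.stack([e[3] for e in entries]),
            )
            for entries in buckets.values()
        ]
        bdata = TwinData(
            traits=data.traits,
            groups=groups,
            q=data.q,
            n_families=len(units),
            n_persons=data.n_persons,
            age_center=data.age_center,
            trait_sd=data.trait_sd,
            beta_start=data.beta_start,
        )
        try:
            vals.append(statistic(fit_model(bdata, spec, n_starts=n_starts)))
        except RuntimeError:
            continue
    alpha = 1.0 - level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return ConfidenceInterval(float(lo), float(hi), level, "bootstrap")


def h2_profile_ci(
    data: TwinData,
    fit: CholeskyModelFit,
    level: float = 0.95,
) -> ConfidenceInterval:
    """Profile-likelihood CI for h^2 of a univariate AE model.

    Reparameterizes (a, e) as (h2, total variance): a = sqrt(h2 * s2),
    e = sqrt((1 - h2) * s2), and profiles over h2 re-optimizing s2 and
    the mean coefficients.
    """
    if fit.spec.p != 1 or fit.spec.components != "AE":
        raise ValueError("h2 profiling implemented for univariate AE fits")
    crit = stats.chi2.ppf(level, 1)
    base = fit.minus2ll
    q = data.q

    def dev(h2):
        def obj(x):
            s2 = np.exp(x[0])
            X = np.array([[np.sqrt(h2 * s2)]])
            Z = np.array([[np.sqrt((1 - h2) * s2)]])
            return neg2ll_fiml(X, None, Z, x[1:].reshape(q, 1), data)

        x0 = np.concatenate([[np.log(fit.sigma()[0, 0])], fit.betas.ravel()])
        res = optimize.minimize(obj, x0, method="L-BFGS-B", options={"ftol": 1e-10})
        return float(res.fun)

    h2_hat = float(np.clip(fit.A[0, 0] / fit.sigma()[0, 0], 1e-9, 1 - 1e-9))

    def excess(v):
        return dev(v) - base - crit

    def edge_search(direction, edge):
        v, prev = h2_hat, h2_hat
        step = 0.05
        for _ in range(40):
            v = np.clip(v + direction * step, 0.0, 1.0)
            if excess(v) > 0:
                break
            prev = v
            if v == edge:
                return float(edge), True
        else:
            return float(v), True
        lo, hi = (prev, v) if direction > 0 else (v, prev)
        return float(optimize.brentq(excess, lo, hi, xtol=1e-4)), False

    upper, ub = edge_search(+1, 1.0)
    lower, lb = edge_search(-1, 0.0)
    return ConfidenceInterval(lower, upper, level, "profile", lb, ub)


# ---------------------------------------------------------------------------
# twin correlations, stability, median split
# ---------------------------------------------------------------------------


def _pair_arrays(prepared, pedigree, trait, zygosity, covariates="saturated", time_point=1):
    df = prepared[prepared["time_point"] == time_point].merge(
        pedigree[["person_id", "family_id", "zygosity", "role"]], on="person_id", how="inner"
    )
    twins = df[(df["zygosity"] == zygosity) & df["role"].isin(["twin1", "twin2"])]
    twins = twins.dropna(subset=[trait])
    counts = twins.groupby("family_id")["person_id"].count()
    complete = counts[counts == 2].index
    twins = twins[twins["family_id"].isin(complete)].sort_values(["family_id", "role"])
    y = twins[trait].to_numpy(float).reshape(-1, 2)
    center = float(np.nanmean(df["age"]))
    W = _covariate_design(
        twins["sex"].to_numpy(float), twins["age"].to_numpy(float), covariates, center
    ).reshape(len(y), 2, -1)
    return y, W


def _pair_corr_dev(r: float, y: np.ndarray, W: np.ndarray) -> float:
    """Profile -2 lnL of the equal-variance bivariate normal at fixed r.

    Mean coefficients enter by GLS and the common variance has a closed
    form, so only r needs numerical profiling.
    """
    n, _, q = W.shape
    cinv = np.array([[1.0, -r], [-r, 1.0]]) / (1.0 - r * r)
    A = np.einsum("nik,ij,njl->kl", W, cinv, W)
    b = np.einsum("nik,ij,nj->k", W, cinv, y)
    beta = np.linalg.solve(A, b)
    resid = y - W @ beta
    rss = float(np.einsum("ni,ij,nj->", resid, cinv, resid))
    s2 = rss / (2 * n)
    return 2 * n * (LN2PI + np.log(s2)) + n * np.log(1 - r * r) + 2 * n


def pair_correlation_ml(
    y: np.ndarray, W: np.ndarray | None = None, level: float = 0.95, ci: bool = True
) -> dict:
    """ML within-pair correlation of an (n, 2) pair matrix.

    Bivariate normal with equal variances across twin order and shared
    mean coefficients (W is (n, 2, q); default intercept only); CI by
    profile likelihood on r.
    """
    y = np.asarray(y, float)
    n = len(y)
    if W is None:
        W = np.ones((n, 2, 1))
    res = optimize.minimize_scalar(
        _pair_corr_dev, args=(y, W), bounds=(-0.999, 0.999), method="bounded",
        options={"xatol": 1e-6},
    )
    r_hat, dev_min = float(res.x), float(res.fun)
    out = {"r": r_hat, "n_pairs": n, "method": "ml"}
    if ci:
        crit = stats.chi2.ppf(level, 1)

        def excess(r):
            return _pair_corr_dev(r, y, W) - dev_min - crit

        lo = optimize.brentq(excess, -0.999, r_hat) if excess(-0.999) > 0 else -1.0
        hi = optimize.brentq(excess, r_hat, 0.999) if excess(0.999) > 0 else 1.0
        out["ci"] = (float(lo), float(hi))
        out["level"] = level
    return out


def twin_correlations(
    prepared: pd.DataFrame,
    pedigree: pd.DataFrame,
    trait: str,
    zygosity: str,
    covariates: str = "saturated",
    level: float = 0.95,
    method: str = "ml",
) -> dict:
    """Within-pair correlation with covariate-adjusted means.

    ``method='ml'`` fits a bivariate normal with shared mean
    coefficients and equal variances across twin order (the
    double-entry/intraclass convention) and profiles r for the CI;
    ``'pearson'`` reports the double-entry Pearson correlation of the
    mean-model residuals for comparison.
    """
    y, W = _pair_arrays(prepared, pedigree, trait, zygosity, covariates)
    n = len(y)
    if n < 3:
        raise ValueError(f"need >= 3 complete {zygosity} pairs for {trait}")
    if method == "pearson":
        q = W.shape[2]
        beta, *_ = np.linalg.lstsq(W.reshape(-1, q), y.ravel(), rcond=None)
        resid = (y.ravel() - W.reshape(-1, q) @ beta).reshape(-1, 2)
        de = np.vstack([resid, resid[:, ::-1]])
        r = float(np.corrcoef(de[:, 0], de[:, 1])[0, 1])
        return {"r": r, "n_pairs": n, "method": "pearson"}

    return pair_correlation_ml(y, W, level=level)


def stability_correlation(prepared: pd.DataFrame, trait: str) -> dict:
    """Pearson correlation between time points on the retest subsample."""
    wide = prepared.pivot_table(index="person_id", columns="time_point", values=trait)
    if 2 not in wide.columns:
        raise ValueError("no second time point in prepared data")
    both = wide.dropna(subset=[1, 2])
    if len(both) < 3:
        raise ValueError("fewer than 3 complete retest records")
    r = float(np.corrcoef(both[1], both[2])[0, 1])
    return {"r": r, "n": int(len(both))}


def median_split_fit(
    prepared: pd.DataFrame,
    pedigree: pd.DataFrame,
    spec: ModelSpec,
    min_families: int = 20,
    **fit_kwargs,
):
    """Refit the model separately in the younger and older half.

    Whole families are assigned by their mean age relative to the
    person-level median, so no family straddles the split.
    Returns ``(median, younger fit, older fit)``.
    """
    t1 = prepared[prepared["time_point"] == 1].merge(
        pedigree[["person_id", "family_id"]], on="person_id"
    )
    median = float(t1["age"].median())
    fam_age = t1.groupby("family_id")["age"].mean()
    young_fams = set(fam_age[fam_age <= median].index)
    fits = []
    for younger in (True, False):
        fams = young_fams if younger else set(fam_age.index) - young_fams
        persons = t1[t1["family_id"].isin(fams)]["person_id"]
        sub = prepared[prepared["person_id"].isin(persons)]
        data = build_twin_data(sub, pedigree, traits=spec.traits, covariates=spec.covariates)
        if data.n_families < min_families:
            raise ValueError("too few families in one half of the median split")
        fits.append(fit_model(data, spec, **fit_kwargs))
    return median, fits[0], fits[1]
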