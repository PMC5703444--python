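"""Graded response model (GRM): marginal-ML calibration and EAP scoring.

Samejima's logistic graded model for ordered polytomous items:
``P(Y_ij >= k | theta_i) = logistic(a_j * (theta_i - b_jk))`` with
discrimination ``a_j > 0`` and strictly increasing thresholds ``b_jk``.
Item parameters are estimated by marginal maximum likelihood via an EM
algorithm over a fixed Gauss-Hermite quadrature of the standard-normal
latent distribution; the latent scale is identified by fixing that
distribution, so instruments calibrated concurrently through overlap
persons land on one common liability metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp


def gauss_hermite_normal(n_quad: int = 61) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for E[f(theta)], theta ~ N(0,1)."""
    x, w = np.polynomial.hermite.hermgauss(n_quad)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _category_logprobs(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """(n_theta, K) log category probabilities of one item."""
    cum = expit(a * (theta[:, None] - b[None, :]))
    upper = np.column_stack([np.ones(len(theta)), cum])
    lower = np.column_stack([cum, np.zeros(len(theta))])
    return np.log(np.maximum(upper - lower, 1e-300))


@dataclass
class IRTCalibration:
    """Estimated item parameters on one common latent scale."""

    discriminations: dict[str, float]
    thresholds: dict[str, np.ndarray]
    category_maps: dict[str, dict[int, int]]  # observed code -> fitted category
    instruments: dict[str, str] = field(default_factory=dict)  # item -> instrument
    log_likelihood: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    n_quad: int = 61

    def __post_init__(self) -> None:
        for item, a in self.discriminations.items():
            if a <= 0:
                raise ValueError(f"{item}: discrimination must be positive")
            b = np.asarray(self.thresholds[item], float)
            if len(b) > 1 and not np.all(np.diff(b) > 0):
                raise ValueError(f"{item}: thresholds must be strictly increasing")

    @property
    def items(self) -> list[str]:
        return list(self.discriminations)


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    if len(b) == 1:
        return np.array([np.log(a), b[0]])
    return np.concatenate([[np.log(a), b[0]], np.log(np.diff(b))])


def _unpack(x: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(np.clip(x[0], -10, 10)))
    if len(x) == 2:
        return a, np.array([x[1]])
    return a, x[1] + np.concatenate([[0.0], np.cumsum(np.exp(np.clip(x[2:], -10, 10)))])


def fit_graded_model(
    responses: pd.DataFrame,
    n_quad: int = 61,
    max_iter: int = 1000,
    tol: float = 1e-5,
    instruments: dict[str, str] | None = None,
    on_nonconvergence: str = "error",
) -> IRTCalibration:
    """Calibrate all items of `responses` (persons x items, NaN missing).

    Codes need not start at 0; observed categories are ranked and empty
    intermediate categories are collapsed with a warning.  EM stops when
    the marginal log-likelihood improves by less than ``tol``; failure
    to converge within ``max_iter`` raises (with the likelihood trace
    attached) unless ``on_nonconvergence='warn'``.
    """
    theta, wq = gauss_hermite_normal(n_quad)
    items = list(responses.columns)
    X = responses.to_numpy(float)
    n, _ = X.shape
    if n == 0 or not items:
        raise ValueError("empty response table")

    codes: list[np.ndarray] = []
    cat_maps: dict[str, dict[int, int]] = {}
    n_cats: list[int] = []
    for j, item in enumerate(items):
        col = X[:, j]
        observed = np.unique(col[~np.isnan(col)]).astype(int)
        if len(observed) < 2:
            raise ValueError(f"{item}: needs at least two observed categories")
        full = np.arange(observed.min(), observed.max() + 1)
        if len(observed) < len(full):
            warnings.warn(f"{item}: empty categories collapsed", stacklevel=2)
        cat_maps[item] = {int(c): k for k, c in enumerate(observed)}
        coded = np.full(n, -1, dtype=int)
        m = ~np.isnan(col)
        coded[m] = np.searchsorted(observed, col[m].astype(int))
        codes.append(coded)
        n_cats.append(len(observed))

    # starting values: a = 1, thresholds at observed cumulative quantiles
    a_hat = np.ones(len(items))
    b_hat: list[np.ndarray] = []
    for j, item in enumerate(items):
        m = codes[j] >= 0
        props = np.bincount(codes[j][m], minlength=n_cats[j]) / m.sum()
        cum = np.clip(np.cumsum(props)[:-1], 0.01, 0.99)
        b0 = np.log(cum / (1 - cum))  # logit of P(Y < k)
        b_hat.append(np.maximum.accumulate(b0) + 1e-6 * np.arange(len(b0)))

    trace: list[float] = []
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        logL = np.zeros((n, n_quad))
        logP = []
        for j in range(len(items)):
            lp = _category_logprobs(a_hat[j], b_hat[j], theta)  # (Q, K)
            logP.append(lp)
            m = codes[j] >= 0
            logL[m] += lp[:, codes[j][m]].T
        logw = logL + np.log(wq)[None, :]
        ll = float(logsumexp(logw, axis=1).sum())
        trace.append(ll)
        post = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        # M-step: per-item weighted multinomial fit on expected counts
        for j in range(len(items)):
            m = codes[j] >= 0
            onehot = np.zeros((m.sum(), n_cats[j]))
            onehot[np.arange(m.sum()), codes[j][m]] = 1.0
            r = post[m].T @ onehot  # (Q, K)

            def nll(x, r=r):
                a, b = _unpack(x)
                return -(r * _category_logprobs(a, b, theta)).sum()

            res = optimize.minimize(nll, _pack(a_hat[j], b_hat[j]), method="L-BFGS-B")
            a_hat[j], b_hat[j] = _unpack(res.x)

    if not converged:
        msg = f"GRM EM did not converge in {max_iter} iterations (trace: {trace[-5:]})"
        if on_nonconvergence == "error":
            err = RuntimeError(msg)
            err.trace = trace  # type: ignore[attr-defined]
            raise err
        warnings.warn(msg, stacklevel=2)

    return IRTCalibration(
        discriminations={item: float(a_hat[j]) for j, item in enumerate(items)},
        thresholds={item: b_hat[j].copy() for j, item in enumerate(items)},
        category_maps=cat_maps,
        instruments=dict(instruments or {}),
        log_likelihood=trace[-1],
        n_iter=it,
        converged=converged,
        n_quad=n_quad,
    )


def check_linking(responses: pd.DataFrame, instruments: dict[str, str]) -> None:
    """Require every pair of instruments to be linked via overlap persons.

    Concurrent calibration only identifies one common scale if the
    instrument co-response graph is connected.
    """
    insts = sorted(set(instruments.values()))
    if len(insts) < 2:
        return
    answered = {
        inst: responses[[c for c in responses.columns if instruments.get(c) == inst]]
        .notna()
        .any(axis=1)
        for inst in insts
    }
    parent = {i: i for i in insts}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(insts):
        for b in insts[i + 1 :]:
            if (answered[a] & answered[b]).any():
                parent[find(a)] = find(b)
    if len({find(i) for i in insts}) > 1:
        raise ValueError(
            "no overlap persons link all instruments; concurrent calibration "
            "cannot put them on one scale"
        )


def irt_calibrate(
    responses: pd.DataFrame,
    instruments: dict[str, str] | None = None,
    **fit_kwargs,
) -> IRTCalibration:
    """Concurrently calibrate one or more instruments on one scale.

    `instruments` maps item columns to instrument names; when two or
    more instruments are present, persons who answered both anchor the
    common metric and their absence is an error.
    """
    instruments = instruments or {}
    cols = [c for c in responses.columns if not instruments or c in instruments]
    sub = responses[cols]
    keep = sub.notna().any(axis=1)
    check_linking(sub[keep], instruments)
    return fit_graded_model(sub[keep], instruments=instruments, **fit_kwargs)


def eap_score(responses: pd.DataFrame, calibration: IRTCalibration) -> pd.Series:
    """Expected a-posteriori liability under the standard-normal prior.

    Persons with no scored responses get NaN; a response code outside
    the calibrated categories of an item is an error.
    """
    theta, wq = gauss_hermite_normal(calibration.n_quad)
    items = [c for c in responses.columns if c in calibration.discriminations]
    if not items:
        raise ValueError("no calibrated items among response columns")
    n = len(responses)
    logw = np.tile(np.log(wq), (n, 1))
    any_obs = np.zeros(n, bool)
    for item in items:
        col = responses[item].to_numpy(float)
        m = ~np.isnan(col)
        if not m.any():
            continue
        cmap = calibration.category_maps[item]
        try:
            coded = np.array([cmap[int(v)] for v in col[m]])
        except KeyError as exc:
            raise ValueError(f"{item}: response outside calibrated categories: {exc}") from exc
        lp = _category_logprobs(
            calibration.discriminations[item], calibration.thresholds[item], theta
        )
        logw[m] += lp[:, coded].T
        any_obs |= m
    post = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    scores = post @ theta
    scores[~any_obs] = np.nan
    return pd.Series(scores, index=responses.index, name="eap")
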