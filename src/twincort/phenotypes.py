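"""Phenotype preparation: HCC transforms and questionnaire harmonization.

Turns the raw long-format phenotype table into the four analysis
phenotypes (trait order fixed throughout the package):

1. ``stress`` — IRT liability from two perceived-stress scales (DLSS
   for under-16s, PSS from 16), concurrently calibrated so overlap
   respondents anchor one common scale;
2. ``dep``    — IRT liability from the 34 depressive-symptom items;
3. ``neuro``  — neuroticism sum scores, z-standardized within
   instrument (JEPQ / NEO) and concatenated;
4. ``hcc_resid`` — log10(HCC + offset), winsorized at mean ± 3 SD, with
   experimental covariates (batch, storage, month, study phase)
   regressed out by dummy-coded OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import irt
from .cohort import INSTRUMENTS

#: screening/report order of the experimental covariates
COVARIATE_ORDER = ["batch", "storage_group", "month", "study_phase"]


def log10_offset_transform(values, offset: float = 0.1) -> np.ndarray:
    """log10(x + offset); the offset is the smallest positive measured
    value (0.1 pg/mg for the instrument emulated here).  Missing values
    propagate; negatives are an error."""
    v = np.asarray(values, float)
    neg = np.nonzero(v < 0)[0]
    if neg.size:
        raise ValueError(f"negative HCC at record index {neg[0]} (value {v[neg[0]]})")
    return np.log10(v + offset)


def winsorize_3sd(values, n_sd: float = 3.0) -> tuple[np.ndarray, int]:
    """Clip to mean ± n_sd * SD (moments computed on the input itself,
    outliers included).  Returns (clipped, n_clipped); idempotent."""
    v = np.asarray(values, float)
    obs = v[~np.isnan(v)]
    if len(obs) < 2:
        raise ValueError("winsorization needs at least two non-missing values")
    lo = obs.mean() - n_sd * obs.std(ddof=1)
    hi = obs.mean() + n_sd * obs.std(ddof=1)
    clipped = np.clip(v, lo, hi)
    n = int(np.nansum((v < lo) | (v > hi)))
    return clipped, n


def _dummy_design(factors: pd.DataFrame) -> pd.DataFrame:
    """Intercept + drop-first dummy coding of every categorical factor."""
    design = pd.DataFrame({"const": np.ones(len(factors))}, index=factors.index)
    for col in factors.columns:
        dummies = pd.get_dummies(factors[col].astype("category"), prefix=col, drop_first=True)
        design = pd.concat([design, dummies.astype(float)], axis=1)
    return design


def residualize_fixed_effects(values, factors: pd.DataFrame) -> np.ndarray:
    """OLS residuals of `values` on dummy-coded experimental factors.

    Residuals are exactly orthogonal to every design column; missing
    responses propagate.  Rank deficiency (aliased factor levels) is an
    error naming the offending columns.
    """
    v = np.asarray(values, float)
    design = _dummy_design(factors)
    X = design.to_numpy(float)
    obs = ~np.isnan(v)
    rank = np.linalg.matrix_rank(X[obs])
    if rank < X.shape[1]:
        # identify aliased columns by incremental rank
        aliased, cols = [], []
        base = np.empty((obs.sum(), 0))
        for j, name in enumerate(design.columns):
            cand = np.column_stack([base, X[obs][:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                aliased.append(name)
            else:
                base = cand
        raise ValueError(f"design is rank deficient; aliased levels: {aliased}")
    resid = np.full_like(v, np.nan)
    beta, *_ = np.linalg.lstsq(X[obs], v[obs], rcond=None)
    resid[obs] = v[obs] - X[obs] @ beta
    return resid


def covariate_screen(log_hcc, factors: pd.DataFrame) -> pd.DataFrame:
    """Drop-one assessment of each experimental covariate.

    For every factor: the percent increase in residual variance when it
    is dropped from the joint model of all factors —
    ``(Var_reduced - Var_full) / Var_full * 100`` with Var = SSR/n —
    plus the partial F-test p-value.  Report rows follow
    :data:`COVARIATE_ORDER`; single-level factors are excluded with a
    warning.
    """
    v = np.asarray(log_hcc, float)
    obs = ~np.isnan(v)
    usable = []
    for col in [c for c in COVARIATE_ORDER if c in factors.columns] + [
        c for c in factors.columns if c not in COVARIATE_ORDER
    ]:
        if factors.loc[obs, col].nunique() < 2:
            warnings.warn(f"{col}: single level, excluded from screen", stacklevel=2)
        else:
            usable.append(col)
    if not usable:
        raise ValueError("no usable factors")
    y = v[obs]

    def fit(cols):
        X = _dummy_design(factors.loc[obs, cols]).to_numpy(float)
        return sm.OLS(y, X).fit()

    full = fit(usable)
    var_full = full.ssr / full.nobs
    rows = []
    for col in usable:
        red = fit([c for c in usable if c != col])
        var_red = red.ssr / red.nobs
        df_num = full.df_model - red.df_model
        f = ((red.ssr - full.ssr) / df_num) / (full.ssr / full.df_resid)
        from scipy import stats as sps

        p = float(sps.f.sf(f, df_num, full.df_resid))
        rows.append(
            {
                "factor": col,
                "n_levels": int(factors.loc[obs, col].nunique()),
                "variance_increase_pct": 100.0 * (var_red - var_full) / var_full,
                "F": float(f),
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def z_combine(scores: pd.Series, instrument: pd.Series) -> pd.Series:
    """Z-standardize within instrument and concatenate onto one column.

    Each instrument's respondents get mean 0 / SD 1 within themselves;
    fewer than two scored persons or zero variance is an error.
    """
    out = pd.Series(np.nan, index=scores.index, dtype=float)
    for inst in instrument.dropna().unique():
        m = (instrument == inst) & scores.notna()
        if m.sum() < 2:
            raise ValueError(f"{inst}: needs at least two scored persons")
        sd = scores[m].std(ddof=1)
        if sd == 0:
            raise ValueError(f"{inst}: zero within-instrument variance")
        out[m] = (scores[m] - scores[m].mean()) / sd
    return out


def _instrument_items(instrument: str) -> list[str]:
    n = INSTRUMENTS[instrument][1]
    return [f"{instrument}_i{j + 1}" for j in range(n)]


def _sum_score(table: pd.DataFrame, instrument: str, min_prop: float = 0.5) -> pd.Series:
    """Instrument sum score, prorated mean*k when >= min_prop items answered."""
    cols = [c for c in _instrument_items(instrument) if c in table.columns]
    sub = table[cols]
    prop = sub.notna().mean(axis=1)
    score = sub.mean(axis=1) * len(cols)
    score[prop < min_prop] = np.nan
    return score


@dataclass
class PreparedPhenotypes:
    """Analysis phenotypes plus the calibrations that produced them."""

    table: pd.DataFrame  # person_id, time_point, stress, dep, neuro, hcc_resid
    stress_calibration: irt.IRTCalibration
    dep_calibration: irt.IRTCalibration
    covariate_report: pd.DataFrame
    n_winsorized: int
    hcc_offset: float


def prepare_phenotypes(
    phenotypes: pd.DataFrame,
    hcc_offset: float = 0.1,
    irt_kwargs: dict | None = None,
) -> PreparedPhenotypes:
    """Run the full preparation pipeline on a long-format raw table.

    IRT calibrations are estimated on time-point-1 responses and reused
    to score time point 2; winsorization bounds come from time-point-1
    log-HCC; the covariate residualization is a single pooled OLS whose
    coefficients are shared across time points.
    """
    irt_kwargs = {"tol": 1e-4, "max_iter": 300, **(irt_kwargs or {})}
    df = phenotypes.reset_index(drop=True)
    t1 = df["time_point"] == 1

    stress_items = [c for c in _instrument_items("DLSS") + _instrument_items("PSS") if c in df.columns]
    stress_instr = {c: c.split("_")[0] for c in stress_items}
    stress_cal = irt.irt_calibrate(df.loc[t1, stress_items], stress_instr, **irt_kwargs)
    dep_items = [c for c in _instrument_items("SPHERE") if c in df.columns]
    dep_cal = irt.irt_calibrate(df.loc[t1, dep_items], {c: "SPHERE" for c in dep_items}, **irt_kwargs)

    stress = irt.eap_score(df[stress_items], stress_cal)
    dep = irt.eap_score(df[dep_items], dep_cal)

    jepq = _sum_score(df, "JEPQ")
    neo = _sum_score(df, "NEO")
    neuro_raw = jepq.fillna(neo)
    neuro_inst = pd.Series(
        np.where(jepq.notna(), "JEPQ", np.where(neo.notna(), "NEO", None)), index=df.index
    )
    neuro = z_combine(neuro_raw, neuro_inst)

    log_hcc = log10_offset_transform(df["hcc_raw"], offset=hcc_offset)
    obs1 = log_hcc[t1.to_numpy()]
    _, n_clip = winsorize_3sd(obs1)
    m1 = np.nanmean(obs1)
    s1 = np.nanstd(obs1[~np.isnan(obs1)], ddof=1)
    log_hcc = np.clip(log_hcc, m1 - 3 * s1, m1 + 3 * s1)

    screen = covariate_screen(log_hcc, df[COVARIATE_ORDER])
    hcc_resid = residualize_fixed_effects(log_hcc, df[COVARIATE_ORDER])

    table = pd.DataFrame(
        {
            "person_id": df["person_id"],
            "time_point": df["time_point"],
            "sex": df["sex"],
            "age": df["age"],
            "stress": stress,
            "dep": dep,
            "neuro": neuro,
            "hcc_resid": hcc_resid,
        }
    )
    if "genotyping_wave" in df.columns:
        table["genotyping_wave"] = df["genotyping_wave"]
    return PreparedPhenotypes(
        table=table,
        stress_calibration=stress_cal,
        dep_calibration=dep_cal,
        covariate_report=screen,
        n_winsorized=n_clip,
        hcc_offset=hcc_offset,
    )
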