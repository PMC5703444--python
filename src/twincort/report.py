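"""Descriptive tables, study-style summaries and pipeline orchestration.

Produces the study's table analogs — descriptives by sex, the twin
correlation/heritability/stability table, the standardized Cholesky
decomposition, and the PRS threshold-sweep figure — and chains the
stages simulate -> prepare -> twinfit -> prs -> report from one config
and seed.  Every table is written as TSV with a JSON sidecar of
unrounded values; rounding (2 d.p.) happens only at render time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io, phenotypes, prs, twin_model
from .cohort import TRAITS, CohortDesign, SimulatedStudy, simulate_study, truth_payload

log = logging.getLogger("twincort")

PRETTY = {
    "stress": "Perceived stress",
    "dep": "Depressive symptoms",
    "neuro": "Neuroticism",
    "hcc": "Hair cortisol",
    "hcc_resid": "Hair cortisol",
}


def descriptives(prepared: pd.DataFrame, raw: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of age and the analysis phenotypes, total and by sex."""
    t1 = prepared[prepared["time_point"] == 1].copy()
    t1 = t1.merge(
        raw.loc[raw["time_point"] == 1, ["person_id", "hcc_raw"]], on="person_id", how="left"
    )
    strata = {"total": t1, "male": t1[t1["sex"] == 0], "female": t1[t1["sex"] == 1]}
    rows = []
    for var, label in [
        ("age", "Age (years)"),
        ("stress", PRETTY["stress"]),
        ("dep", PRETTY["dep"]),
        ("neuro", PRETTY["neuro"]),
        ("hcc_raw", "Hair cortisol (pg/mg)"),
    ]:
        row = {"variable": label}
        for name, df in strata.items():
            if len(df) == 0:
                raise ValueError(f"empty stratum: {name}")
            v = df[var].astype(float)
            row[f"{name}_n"] = int(v.notna().sum())
            row[f"{name}_mean"] = float(v.mean())
            row[f"{name}_sd"] = float(v.std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def twin_correlation_table(
    prepared: pd.DataFrame,
    pedigree: pd.DataFrame,
    h2: dict[str, float] | None = None,
    traits=("stress", "dep", "neuro", "hcc_resid"),
) -> pd.DataFrame:
    """MZ/DZ within-pair correlations (95% CI), heritability, stability."""
    rows = []
    for trait in traits:
        row = {"trait": PRETTY.get(trait, trait)}
        for zyg in ("MZ", "DZ"):
            res = twin_model.twin_correlations(prepared, pedigree, trait, zyg)
            row[f"r{zyg}"] = res["r"]
            row[f"r{zyg}_lo"], row[f"r{zyg}_hi"] = res["ci"]
            row[f"n_{zyg}_pairs"] = res["n_pairs"]
        if h2 is not None:
            row["h2"] = h2.get(trait, np.nan)
        try:
            stab = twin_model.stability_correlation(prepared, trait)
            row["stability"], row["n_retest"] = stab["r"], stab["n"]
        except ValueError:
            row["stability"], row["n_retest"] = np.nan, 0
        rows.append(row)
    return pd.DataFrame(rows)


def decomposition_table(decomp: twin_model.Decomposition) -> pd.DataFrame:
    """Standardized components (%) and component correlations, long form."""
    rows = []
    for comp, table in decomp.standardized.items():
        for j, tj in enumerate(decomp.traits):
            for k in range(j + 1):
                rows.append(
                    {
                        "block": f"standardized_{comp}",
                        "row": PRETTY.get(tj, tj),
                        "col": PRETTY.get(decomp.traits[k], decomp.traits[k]),
                        "value": float(table[j, k]),
                    }
                )
    for name, mat in decomp.correlations.items():
        for j, tj in enumerate(decomp.traits):
            for k in range(j):
                rows.append(
                    {
                        "block": name,
                        "row": PRETTY.get(tj, tj),
                        "col": PRETTY.get(decomp.traits[k], decomp.traits[k]),
                        "value": float(mat[j, k]),
                    }
                )
    return pd.DataFrame(rows)


def plot_prs_sweep(sweep: pd.DataFrame, path) -> None:
    """Signed incremental R^2 vs threshold, one panel per phenotype."""
    phenos = list(dict.fromkeys(sweep["phenotype"]))
    discs = list(dict.fromkeys(sweep["discovery"]))
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), squeeze=False)
    width = 0.8 / max(len(discs), 1)
    for ax, pheno in zip(axes.ravel(), phenos):
        sub = sweep[sweep["phenotype"] == pheno]
        thresholds = sorted(sub["threshold"].unique())
        xs = np.arange(len(thresholds))
        for d_i, disc in enumerate(discs):
            ss = sub[sub["discovery"] == disc].set_index("threshold").loc[thresholds]
            bars = ax.bar(xs + d_i * width, 100 * ss["r2_signed"], width, label=f"PRS {disc}")
            for x, (_, row) in zip(bars, ss.iterrows()):
                if row["sig"]:
                    ax.annotate(
                        row["sig"], (x.get_x() + x.get_width() / 2, x.get_height()),
                        ha="center", fontsize=8,
                    )
        ax.set_xticks(xs + width)
        ax.set_xticklabels([f"{t:g}" for t in thresholds], rotation=45, fontsize=7)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(PRETTY.get(pheno, pheno))
        ax.set_ylabel("signed incremental R² (%)")
        ax.set_xlabel("p-value threshold")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate_stage(config: dict, seed: int, out: Path) -> SimulatedStudy:
    design = CohortDesign(seed=seed, **config.get("design", {}))
    study = simulate_study(
        design=design,
        seed=seed,
        with_genotypes=config.get("with_genotypes", True),
        gwas_kwargs=config.get("gwas", None),
    )
    out.mkdir(parents=True, exist_ok=True)
    io.write_pedigree(out / "pedigree.tsv", study.cohort.pedigree())
    io.write_phenotypes(out / "phenotypes_raw.tsv", study.phenotypes)
    io.write_json(out / "truth.json", truth_payload(study))
    if study.genotypes is not None:
        io.write_vcf(out / "genotypes.vcf", study.genotypes)
        for trait, ss in study.sumstats.items():
            io.write_sumstats(out / f"sumstats_{trait}.tsv", ss)
    return study


def prepare_stage(config: dict, out: Path) -> phenotypes.PreparedPhenotypes:
    raw = io.read_phenotypes(out / "phenotypes_raw.tsv")
    prepared = phenotypes.prepare_phenotypes(raw, **config.get("prepare", {}))
    io.write_phenotypes(out / "phenotypes_prepared.tsv", prepared.table)
    prepared.covariate_report.to_csv(out / "covariate_screen.tsv", sep="\t", index=False)
    io.write_json(
        out / "irt_calibration.json",
        {
            "stress": {
                "a": prepared.stress_calibration.discriminations,
                "b": {k: v for k, v in prepared.stress_calibration.thresholds.items()},
            },
            "dep": {
                "a": prepared.dep_calibration.discriminations,
                "b": {k: v for k, v in prepared.dep_calibration.thresholds.items()},
            },
            "n_winsorized": prepared.n_winsorized,
        },
    )
    return prepared


def twinfit_stage(config: dict, out: Path) -> dict:
    prepared = io.read_phenotypes(out / "phenotypes_prepared.tsv")
    pedigree = io.read_pedigree(out / "pedigree.tsv")
    traits = ("stress", "dep", "neuro", "hcc_resid")
    fit_cfg = config.get("fit", {})
    n_starts = fit_cfg.get("n_starts", 5)
    covariates = fit_cfg.get("covariates", "saturated")
    data = twin_model.build_twin_data(prepared, pedigree, traits=traits, covariates=covariates)
    fits = {}
    for comps in ("ACE", "AE", "CE"):
        spec = twin_model.ModelSpec(components=comps, traits=traits, covariates=covariates)
        fits[comps] = twin_model.fit_model(data, spec, n_starts=n_starts)
    lrt = {}
    for sub in ("AE", "CE"):
        delta, df, p = twin_model.compare_lrt(fits["ACE"], fits[sub])
        lrt[sub] = {"delta_chi2": delta, "df": df, "p": p}
    decomp = twin_model.decompose(fits["AE"])
    h2 = {t: float(h) for t, h in zip(traits, decomp.h2)}
    corr_table = twin_correlation_table(prepared, pedigree, h2=h2, traits=traits)
    corr_table.to_csv(out / "twin_correlations.tsv", sep="\t", index=False)
    decomposition_table(decomp).to_csv(out / "decomposition.tsv", sep="\t", index=False)
    payload = {
        "fits": {
            c: {
                "minus2ll": f.minus2ll,
                "n_free_params": f.n_free_params,
                "converged": f.converged,
                "X": f.X,
                "Y": f.Y,
                "Z": f.Z,
                "betas": f.betas,
            }
            for c, f in fits.items()
        },
        "lrt": lrt,
        "h2": h2,
        "rA": decomp.correlations["rA"],
        "rE": decomp.correlations["rE"],
        "rP": decomp.correlations["rP"],
    }
    if config.get("median_split", True):
        spec = twin_model.ModelSpec(components="AE", traits=traits, covariates=covariates)
        median, fy, fo = twin_model.median_split_fit(
            prepared, pedigree, spec, n_starts=fit_cfg.get("split_starts", 2)
        )
        payload["median_split"] = {
            "median_age": median,
            "h2_younger": np.diag(fy.A) / np.diag(fy.sigma()),
            "h2_older": np.diag(fo.A) / np.diag(fo.sigma()),
        }
    io.write_json(out / "twinfit.json", payload)
    return payload


def prs_stage(config: dict, out: Path) -> pd.DataFrame:
    table = io.read_vcf(out / "genotypes.vcf")
    pedigree = io.read_pedigree(out / "pedigree.tsv")
    prepared = io.read_phenotypes(out / "phenotypes_prepared.tsv")
    cfg = config.get("prs", {})
    qced, report = prs.qc_filter(table, pedigree)
    report.to_csv(out / "qc_exclusions.tsv", sep="\t", index=False)
    pcs = prs.pca_ancestry(qced, pedigree, n_pcs=cfg.get("n_pcs", 5), seed=config.get("seed", 0))
    K = prs.pedigree_kinship(pedigree, persons=qced.persons)

    profiles = {}
    for f in sorted(Path(out).glob("sumstats_*.tsv")):
        disc = f.stem.replace("sumstats_", "")
        stats_df = io.read_sumstats(f)
        aligned, _ = prs.harmonize_alleles(stats_df, qced)
        clumped = prs.clump(
            aligned, qced, r2_max=cfg.get("r2_max", 0.1), window_kb=cfg.get("window_kb", 500)
        )
        profiles[disc] = prs.score_at_thresholds(qced, clumped)
        profiles[disc].frame().to_csv(out / f"scores_{disc}.tsv", sep="\t", index=False)

    t1 = prepared[prepared["time_point"] == 1].set_index("person_id")
    t1 = t1.loc[[p for p in qced.persons if p in t1.index]]
    age_c = t1["age"] - t1["age"].mean()
    W = pd.DataFrame(
        {
            "const": 1.0,
            "sex": t1["sex"].astype(float),
            "age": age_c,
            "age2": age_c**2,
            "sex_age": t1["sex"] * age_c,
            "sex_age2": t1["sex"] * age_c**2,
        },
        index=t1.index,
    )
    W = pd.concat([W, pcs.loc[t1.index]], axis=1)
    if "genotyping_wave" in t1.columns:
        W = pd.concat(
            [W, pd.get_dummies(t1["genotyping_wave"], prefix="wave", drop_first=True).astype(float)],
            axis=1,
        )
    pheno = t1.reset_index()
    sweep = prs.threshold_sweep(pheno, profiles, W, K)
    sweep.to_csv(out / "prs_sweep.tsv", sep="\t", index=False)
    plot_prs_sweep(sweep, out / "prs_sweep.png")
    return sweep


def assemble_report(out: Path, config: dict | None = None, seed: int | None = None) -> dict:
    """Collect stage outputs into one StudyReport JSON.

    Missing stage outputs raise, naming the stage to rerun; a missing
    PRS stage yields a partial report with an explicit gap entry.
    """
    out = Path(out)
    required = {
        "simulate": ["pedigree.tsv", "phenotypes_raw.tsv"],
        "prepare": ["phenotypes_prepared.tsv", "covariate_screen.tsv"],
        "twinfit": ["twinfit.json", "twin_correlations.tsv", "decomposition.tsv"],
    }
    for stage, files in required.items():
        for f in files:
            if not (out / f).exists():
                raise FileNotFoundError(f"missing {f}; rerun stage '{stage}'")
    prepared = io.read_phenotypes(out / "phenotypes_prepared.tsv")
    raw = io.read_phenotypes(out / "phenotypes_raw.tsv")
    desc = descriptives(prepared, raw)
    desc.to_csv(out / "descriptives.tsv", sep="\t", index=False)
    report = {
        "descriptives": desc.to_dict(orient="records"),
        "twin": io.read_json(out / "twinfit.json"),
        "covariate_screen": pd.read_csv(out / "covariate_screen.tsv", sep="\t").to_dict(
            orient="records"
        ),
        "provenance": {
            "seed": seed,
            "config_hash": config_hash(config or {}),
            "version": __import__("twincort").__version__,
        },
    }
    if (out / "prs_sweep.tsv").exists():
        report["prs_sweep"] = pd.read_csv(out / "prs_sweep.tsv", sep="\t").to_dict(orient="records")
    else:
        report["prs_sweep"] = None
        report["gaps"] = ["prs stage not run"]
    io.write_json(out / "study_report.json", report)
    return report


def run_all(config: dict, seed: int, out) -> dict:
    """simulate -> prepare -> twinfit -> prs -> report, with timings."""
    out = Path(out)
    timings = {}
    stages = [
        ("simulate", lambda: simulate_stage(config, seed, out)),
        ("prepare", lambda: prepare_stage(config, out)),
        ("twinfit", lambda: twinfit_stage(config, out)),
    ]
    if config.get("with_genotypes", True):
        stages.append(("prs", lambda: prs_stage(config, out)))
    for name, fn in stages:
        t0 = time.time()
        log.info("stage %s starting (seed=%s)", name, seed)
        fn()
        timings[name] = time.time() - t0
        log.info("stage %s done in %.1fs", name, timings[name])
    report = assemble_report(out, config=config, seed=seed)
    report["provenance"]["timings_s"] = timings
    io.write_json(out / "study_report.json", report)
    return report
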