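"""Polygenic risk scores and family-aware association.

Genotype QC (call rate, MAF, Hardy-Weinberg exact test), harmonization
of GWAS summary statistics onto the target counted alleles, greedy LD
clumping, sum-of-weighted-dosages scoring at nested p-value thresholds,
ancestry principal components, pedigree relatedness and a two-variance-
component linear mixed model (REML via eigendecomposition of the
relatedness matrix) testing each score against each phenotype with a
one-sided alternative of positive association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import VariantTable

#: the eight nested inclusion thresholds used for scoring
PRS_THRESHOLDS = (5e-8, 1e-5, 0.001, 0.01, 0.05, 0.1, 0.5, 1.0)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def hwe_exact_p(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value (full enumeration).

    Two-sided mid-less convention: the probability mass of all
    heterozygote counts no more likely than the observed one, under the
    exact conditional distribution given allele counts.
    """
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    # enumerate heterozygote counts with the same parity as n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logprob = np.zeros(len(hets))
    from scipy.special import gammaln

    n_common = 2 * n - n_rare
    for i, h in enumerate(hets):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logprob[i] = (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(rare_hom + 1)
            - gammaln(common_hom + 1)
            + gammaln(n_rare + 1)
            + gammaln(n_common + 1)
            - gammaln(2 * n + 1)
        )
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    obs = prob[hets == n_het][0]
    return float(prob[prob <= obs + 1e-12].sum())


def qc_filter(
    table: VariantTable,
    pedigree: pd.DataFrame | None = None,
    call_rate: float = 0.95,
    maf: float = 0.01,
    hwe_p: float = 1e-6,
) -> tuple[VariantTable, pd.DataFrame]:
    """Person call-rate, variant call-rate, MAF and HWE filters.

    HWE is computed on one person per family (the lexicographically
    first) to avoid relatedness inflating the test.  Returns the
    filtered table plus a per-exclusion report (id, reason).
    """
    report = []
    person_cr = table.person_call_rate()
    keep_person = person_cr >= call_rate
    for pid, ok, cr in zip(table.persons, keep_person, person_cr):
        if not ok:
            report.append({"id": pid, "kind": "person", "reason": "call_rate", "value": cr})
    table = table.subset(person_mask=keep_person)

    if pedigree is not None:
        fam = pedigree.set_index("person_id")["family_id"]
        seen: dict[str, str] = {}
        founder_mask = np.zeros(table.n_persons, bool)
        for i, pid in enumerate(table.persons):
            f = fam.get(pid, pid)
            if f not in seen:
                seen[f] = pid
                founder_mask[i] = True
    else:
        founder_mask = np.ones(table.n_persons, bool)

    cr = table.variant_call_rate()
    freq = table.alt_frequency()
    minor = np.minimum(freq, 1 - freq)
    hwe = np.ones(table.n_variants)
    founders = table.dosages[:, founder_mask]
    for i in range(table.n_variants):
        d = founders[i][~np.isnan(founders[i])]
        hwe[i] = hwe_exact_p(
            int((d == 1).sum()), int((d == 0).sum()), int((d == 2).sum())
        )
    keep = np.ones(table.n_variants, bool)
    for i, vid in enumerate(table.variants["id"]):
        if cr[i] < call_rate:
            keep[i] = False
            report.append({"id": vid, "kind": "variant", "reason": "call_rate", "value": cr[i]})
        elif minor[i] < maf:
            keep[i] = False
            report.append({"id": vid, "kind": "variant", "reason": "maf", "value": minor[i]})
        elif hwe[i] < hwe_p:
            keep[i] = False
            report.append({"id": vid, "kind": "variant", "reason": "hwe", "value": hwe[i]})
    out = table.subset(variant_mask=keep)
    if out.n_variants == 0:
        raise ValueError("no variants left after QC")
    return out, pd.DataFrame(report, columns=["id", "kind", "reason", "value"])


# ---------------------------------------------------------------------------
# harmonization and clumping
# ---------------------------------------------------------------------------


def harmonize_alleles(stats_df: pd.DataFrame, table: VariantTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align summary-statistic effects onto the target ALT dosage.

    The counted allele is the target ALT.  BETA is sign-flipped when the
    effect allele matches REF; strand flips are resolved via base
    complement; strand-ambiguous (A/T, C/G) variants and irreconcilable
    allele pairs are dropped with reasons.
    """
    tv = table.variants.set_index("id")
    rows, report = [], []
    for rec in stats_df.itertuples(index=False):
        vid = rec.SNP
        if vid not in tv.index:
            report.append({"id": vid, "reason": "not_in_target"})
            continue
        ref, alt = tv.at[vid, "ref"], tv.at[vid, "alt"]
        a1, a2 = str(rec.A1), str(rec.A2)
        if a1 == _COMPLEMENT.get(a2):
            report.append({"id": vid, "reason": "strand_ambiguous"})
            continue
        if {a1, a2} == {ref, alt}:
            pass
        elif {_COMPLEMENT.get(a1), _COMPLEMENT.get(a2)} == {ref, alt}:
            a1, a2 = _COMPLEMENT[a1], _COMPLEMENT[a2]
        else:
            report.append({"id": vid, "reason": "allele_mismatch"})
            continue
        beta = float(rec.BETA) if a1 == alt else -float(rec.BETA)
        rows.append(
            {
                "id": vid,
                "chrom": tv.at[vid, "chrom"],
                "pos": int(tv.at[vid, "pos"]),
                "beta": beta,
                "p": float(rec.P),
            }
        )
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "beta", "p"]), pd.DataFrame(
        report, columns=["id", "reason"]
    )


def clump(
    aligned: pd.DataFrame,
    ld_source: VariantTable,
    r2_max: float = 0.1,
    window_kb: float = 500.0,
) -> pd.DataFrame:
    """Greedy LD clumping on the target genotypes.

    Variants are visited by ascending p (ties broken by chrom, pos, id)
    and kept only if their squared dosage correlation with every
    already-kept variant within the window is <= r2_max.
    """
    idx_of = {vid: i for i, vid in enumerate(ld_source.variants["id"])}
    work = aligned[aligned["id"].isin(idx_of)].copy()
    work = work.sort_values(["p", "chrom", "pos", "id"], kind="mergesort")
    D = ld_source.dosages
    col_mean = np.nanmean(D, axis=1)
    filled = np.where(np.isnan(D), col_mean[:, None], D)
    centered = filled - filled.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    kept: list[dict] = []
    for rec in work.itertuples(index=False):
        gi = idx_of[rec.id]
        ok = True
        for k in kept:
            if k["chrom"] != rec.chrom or abs(k["pos"] - rec.pos) > window_kb * 1000:
                continue
            denom = norms[gi] * norms[k["gi"]]
            r2 = 0.0 if denom == 0 else (centered[gi] @ centered[k["gi"]] / denom) ** 2
            if r2 > r2_max:
                ok = False
                break
        if ok:
            kept.append({"id": rec.id, "chrom": rec.chrom, "pos": rec.pos, "gi": gi, "p": rec.p, "beta": rec.beta})
    out = pd.DataFrame(kept, columns=["id", "chrom", "pos", "gi", "p", "beta"]).drop(columns="gi")
    return out


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


@dataclass
class ScoreProfile:
    persons: list[str]
    thresholds: tuple[float, ...]
    scores: np.ndarray  # (n_persons, n_thresholds)
    n_variants: dict[float, int]

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=[f"p<{t:g}" for t in self.thresholds])
        df.insert(0, "person_id", self.persons)
        return df


def score_at_thresholds(
    table: VariantTable,
    aligned: pd.DataFrame,
    thresholds=PRS_THRESHOLDS,
    standardize: bool = True,
) -> ScoreProfile:
    """Beta-weighted dosage sums at nested p-value thresholds.

    Missing dosages are imputed to twice the counted-allele frequency
    (the mean dosage); scores are z-standardized per threshold by
    default before association.
    """
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
    idx_of = {vid: i for i, vid in enumerate(table.variants["id"])}
    use = aligned[aligned["id"].isin(idx_of)]
    gi = np.array([idx_of[v] for v in use["id"]], dtype=int)
    D = table.dosages[gi]
    freq = np.nanmean(D, axis=1) / 2.0
    filled = np.where(np.isnan(D), (2 * freq)[:, None], D)
    betas = use["beta"].to_numpy(float)
    pvals = use["p"].to_numpy(float)
    scores = np.empty((table.n_persons, len(thresholds)))
    n_used = {}
    for j, t in enumerate(thresholds):
        m = pvals <= t
        n_used[t] = int(m.sum())
        scores[:, j] = betas[m] @ filled[m]
    if standardize:
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        scores = (scores - scores.mean(axis=0)) / sd
    return ScoreProfile(
        persons=list(table.persons),
        thresholds=tuple(thresholds),
        scores=scores,
        n_variants=n_used,
    )


# ---------------------------------------------------------------------------
# kinship and ancestry
# ---------------------------------------------------------------------------


def pedigree_kinship(pedigree: pd.DataFrame, persons: list[str] | None = None) -> pd.DataFrame:
    """Expected relatedness: MZ co-twins 1, other family members 0.5.

    Returns a symmetric PSD matrix indexed by person id (values are
    twice the kinship coefficient, i.e. the expected additive genetic
    correlation).
    """
    ped = pedigree if persons is None else pedigree[pedigree["person_id"].isin(persons)]
    ids = list(ped["person_id"])
    n = len(ids)
    K = np.zeros((n, n))
    pos = {pid: i for i, pid in enumerate(ids)}
    for _, fam in ped.groupby("family_id"):
        rows = list(fam.itertuples(index=False))
        for a in rows:
            for b in rows:
                i, j = pos[a.person_id], pos[b.person_id]
                if i == j:
                    K[i, j] = 1.0
                elif (
                    a.zygosity == "MZ"
                    and b.zygosity == "MZ"
                    and a.role in ("twin1", "twin2")
                    and b.role in ("twin1", "twin2")
                ):
                    K[i, j] = 1.0
                else:
                    K[i, j] = 0.5
    out = pd.DataFrame(K, index=ids, columns=ids)
    if persons is not None:
        out = out.loc[persons, persons]
    return out


def genomic_kinship(table: VariantTable) -> pd.DataFrame:
    """Empirical relatedness from standardized dosages (GRM)."""
    freq = table.alt_frequency()
    sd = np.sqrt(2 * freq * (1 - freq))
    ok = sd > 0
    D = table.dosages[ok]
    filled = np.where(np.isnan(D), (2 * freq[ok])[:, None], D)
    Zs = (filled - 2 * freq[ok][:, None]) / sd[ok][:, None]
    K = Zs.T @ Zs / ok.sum()
    return pd.DataFrame(K, index=table.persons, columns=table.persons)


def pca_ancestry(
    table: VariantTable,
    pedigree: pd.DataFrame | None = None,
    n_pcs: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Ancestry PCs of the column-standardized dosage matrix.

    Axes are estimated on one randomly chosen member per family (seeded)
    so relatedness does not drive them, then all persons are projected.
    Each PC is oriented so its largest-magnitude loading is positive.
    """
    if n_pcs == 0:
        return pd.DataFrame(index=table.persons)
    if n_pcs > table.n_variants:
        raise ValueError("fewer variants than requested PCs")
    rng = np.random.default_rng(seed)
    if pedigree is not None:
        fam = pedigree.set_index("person_id")["family_id"]
        groups: dict[str, list[int]] = {}
        for i, pid in enumerate(table.persons):
            groups.setdefault(fam.get(pid, pid), []).append(i)
        founders = np.array(sorted(int(rng.choice(v)) for v in groups.values()))
    else:
        founders = np.arange(table.n_persons)
    freq = table.alt_frequency()
    sd = np.sqrt(2 * freq * (1 - freq))
    ok = sd > 0
    D = table.dosages[ok]
    filled = np.where(np.isnan(D), (2 * freq[ok])[:, None], D)
    Zs = ((filled - 2 * freq[ok][:, None]) / sd[ok][:, None]).T  # persons x variants
    sub = Zs[founders] - Zs[founders].mean(axis=0)
    _, _, vt = np.linalg.svd(sub, full_matrices=False)
    load = vt[:n_pcs].T  # variants x n_pcs
    flip = np.sign(load[np.abs(load).argmax(axis=0), np.arange(n_pcs)])
    flip[flip == 0] = 1.0
    load = load * flip
    proj = (Zs - Zs[founders].mean(axis=0)) @ load
    return pd.DataFrame(
        proj, index=table.persons, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )


# ---------------------------------------------------------------------------
# mixed-model association
# ---------------------------------------------------------------------------


@dataclass
class MixedAssocResult:
    beta: float
    se: float
    z: float
    p_one_sided: float
    p_two_sided: float
    r2_signed: float
    sigma2_g: float
    sigma2_e: float
    n: int
    converged: bool = True


def _reml_neg2ll(log_lambda, d, yr, Wr):
    lam = np.exp(log_lambda)
    v = lam * d + 1.0
    Wv = Wr / v[:, None]
    A = Wr.T @ Wv
    b = Wv.T @ yr
    beta = np.linalg.solve(A, b)
    resid = yr - Wr @ beta
    n, q = Wr.shape
    rss = float(resid @ (resid / v))
    s2 = rss / (n - q)
    sign, logdetA = np.linalg.slogdet(A)
    return (
        (n - q) * np.log(s2) + np.log(v).sum() + logdetA + (n - q),
        beta,
        s2,
    )


def mixed_assoc(
    y: np.ndarray,
    score: np.ndarray,
    covariates: np.ndarray,
    K: np.ndarray,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    constrain_sigma_g: float | None = None,
) -> MixedAssocResult:
    """One score vs one phenotype under ``y = W g + s b + u + e``.

    ``u ~ N(0, sg^2 K)``, ``e ~ N(0, se^2 I)`` with K the family
    relatedness matrix; variance components by REML on the spectrum of
    K (pass ``eig`` to reuse the eigendecomposition).  The association
    test is a Wald z for b with one-sided upper-tail p (alternative:
    positive association).  ``r2_signed`` is sign(b) times the
    incremental fixed-effect R^2 of the score over the covariate-only
    model on the raw scale.
    """
    y = np.asarray(y, float)
    keep = ~np.isnan(y) & ~np.isnan(score) & ~np.isnan(covariates).any(axis=1)
    y, s, W0 = y[keep], np.asarray(score, float)[keep], np.asarray(covariates, float)[keep]
    K = np.asarray(K, float)[np.ix_(keep, keep)]
    n = len(y)
    W = np.column_stack([W0, s])
    if eig is None or not keep.all():
        dvals, U = np.linalg.eigh(K)
        if dvals.min() < -1e-8:
            raise ValueError("relatedness matrix is not PSD")
        dvals = np.maximum(dvals, 0.0)
    else:
        dvals, U = eig
    yr, Wr = U.T @ y, U.T @ W

    if constrain_sigma_g is not None:
        if constrain_sigma_g != 0:
            raise ValueError("only sigma_g = 0 can be constrained")
        lam = 0.0
        _, beta, s2e = _reml_neg2ll(-np.inf, dvals, yr, Wr)
    else:
        res = optimize.minimize_scalar(
            lambda x: _reml_neg2ll(x, dvals, yr, Wr)[0],
            bounds=(-12.0, 12.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success:
            raise RuntimeError(f"REML did not converge: {res}")
        lam = float(np.exp(res.x))
        _, beta, s2e = _reml_neg2ll(res.x, dvals, yr, Wr)
    v = lam * dvals + 1.0
    A = Wr.T @ (Wr / v[:, None])
    cov = s2e * np.linalg.inv(A)
    b = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    z = b / se
    p_one = float(stats.norm.sf(z))
    # incremental fixed-effect R^2 on the raw scale
    tss = float(((y - y.mean()) ** 2).sum())

    def fixed_r2(cols):
        bet = np.linalg.solve(cols.T @ (U @ ((U.T @ cols) / v[:, None])), cols.T @ (U @ (yr / v)))
        resid = y - cols @ bet
        return 1.0 - float((resid**2).sum()) / tss

    r2 = fixed_r2(W) - fixed_r2(W0)
    return MixedAssocResult(
        beta=b,
        se=se,
        z=float(z),
        p_one_sided=p_one,
        p_two_sided=float(2 * stats.norm.sf(abs(z))),
        r2_signed=float(np.sign(b) * abs(r2)),
        sigma2_g=lam * s2e,
        sigma2_e=s2e,
        n=n,
    )


def threshold_sweep(
    phenotypes: pd.DataFrame,
    profiles: dict[str, ScoreProfile],
    covariates: pd.DataFrame,
    K: pd.DataFrame,
    traits=("stress", "dep", "neuro", "hcc_resid"),
) -> pd.DataFrame:
    """Full association grid: phenotype x threshold x discovery trait.

    All inputs are aligned on ``phenotypes['person_id']``; listwise
    deletion applies per cell.  Significance tiers: ** p<0.01, * p<0.05,
    # p<0.1 (one-sided).
    """
    persons = list(phenotypes["person_id"])
    Km = K.loc[persons, persons].to_numpy()
    eig = np.linalg.eigh(Km)
    eig = (np.maximum(eig[0], 0.0), eig[1])
    Wm = covariates.loc[persons].to_numpy(float) if hasattr(covariates, "loc") else np.asarray(covariates)
    rows = []
    for disc, profile in profiles.items():
        smap = {pid: i for i, pid in enumerate(profile.persons)}
        order = [smap[p] for p in persons]
        for ti, t in enumerate(profile.thresholds):
            svec = profile.scores[order, ti]
            for trait in traits:
                res = mixed_assoc(
                    phenotypes[trait].to_numpy(float), svec, Wm, Km, eig=eig
                )
                tier = (
                    "**" if res.p_one_sided < 0.01 else "*" if res.p_one_sided < 0.05 else "#" if res.p_one_sided < 0.1 else ""
                )
                rows.append(
                    {
                        "discovery": disc,
                        "threshold": t,
                        "phenotype": trait,
                        "n_variants": profile.n_variants[t],
                        "beta": res.beta,
                        "se": res.se,
                        "p_one_sided": res.p_one_sided,
                        "r2_signed": res.r2_signed,
                        "sigma2_g": res.sigma2_g,
                        "sigma2_e": res.sigma2_e,
                        "n": res.n,
                        "sig": tier,
                    }
                )
    return pd.DataFrame(rows)
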