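"""Genotype QC, harmonization, clumping, scoring, mixed-model association."""

import math

import numpy as np
import pandas as pd
import pytest

from twincort import prs
from twincort.io import VariantTable


def make_table(dosages, pos=None, chrom=None, ref="A", alt="G"):
    dosages = np.asarray(dosages, float)
    m, n = dosages.shape
    variants = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "ref": [ref] * m,
            "alt": [alt] * m,
        }
    )
    return VariantTable(variants=variants, dosages=dosages, persons=[f"P{j}" for j in range(n)])


def hwe_oracle(n_het, n_hom_ref, n_hom_alt):
    """Exact HWE p by integer enumeration (independent of the module)."""
    n = n_het + n_hom_ref + n_hom_alt
    n_a = n_het + 2 * min(n_hom_ref, n_hom_alt)
    probs = {}
    for h in range(n_a % 2, n_a + 1, 2):
        r = (n_a - h) // 2
        c = n - h - r
        if c < 0:
            continue
        num = math.comb(n, h) * math.comb(n - h, r) * 2**h
        probs[h] = num
    denom = sum(probs.values())
    obs = probs[n_het]
    return sum(v for v in probs.values() if v <= obs) / denom


class TestHweExact:
    @pytest.mark.parametrize(
        "het,hom_ref,hom_alt",
        [(0, 90, 10), (25, 60, 15), (10, 10, 10), (57, 21, 22), (1, 0, 99)],
    )
    def test_matches_enumeration_oracle(self, het, hom_ref, hom_alt):
        assert prs.hwe_exact_p(het, hom_ref, hom_alt) == pytest.approx(
            hwe_oracle(het, hom_ref, hom_alt), rel=1e-9
        )

    def test_extreme_deficit_is_excluded_by_threshold(self):
        # 100 persons, AA=90, aa=10, no heterozygotes
        assert prs.hwe_exact_p(0, 90, 10) < 1e-6


class TestQcFilter:
    def test_low_call_rate_variant_excluded(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (20, 100)).astype(float)
        d[0, :6] = np.nan  # 94% variant call rate; persons keep 19/20
        table = make_table(d)
        out, report = prs.qc_filter(table, maf=0.0, hwe_p=0.0)
        assert out.n_variants == 19
        row = report[report["id"] == "v0"].iloc[0]
        assert row["reason"] == "call_rate"

    def test_all_pass_panel_unchanged(self):
        rng = np.random.default_rng(1)
        freq = rng.uniform(0.2, 0.5, 30)
        d = (rng.random((30, 200)) < freq[:, None]).astype(float) + (
            rng.random((30, 200)) < freq[:, None]
        ).astype(float)
        table = make_table(d)
        out, report = prs.qc_filter(table)
        assert out.n_variants == 30
        assert out.n_persons == 200
        assert len(report) == 0

    def test_low_maf_and_hwe_failures_reported(self):
        rng = np.random.default_rng(2)
        common = (rng.random((1, 300)) < 0.3).astype(float) + (
            rng.random((1, 300)) < 0.3
        ).astype(float)
        rare = np.zeros((1, 300))
        rare[0, 0] = 1.0  # MAF ~ 0.0017
        weird = np.zeros((1, 300))
        weird[0, :30] = 2.0  # AA=270, aa=30, no hets
        table = make_table(np.vstack([common, rare, weird]))
        out, report = prs.qc_filter(table)
        reasons = report.set_index("id")["reason"]
        assert reasons["v1"] == "maf"
        assert reasons["v2"] == "hwe"
        assert out.n_variants == 1

    def test_empty_result_rejected(self):
        table = make_table(np.zeros((1, 50)))
        with pytest.raises(ValueError, match="no variants"):
            prs.qc_filter(table)


class TestHarmonize:
    def stats_df(self, a1, a2, beta=0.2):
        return pd.DataFrame(
            {
                "SNP": ["v0"],
                "CHR": ["1"],
                "BP": [1000],
                "A1": [a1],
                "A2": [a2],
                "FREQ": [0.3],
                "BETA": [beta],
                "SE": [0.05],
                "P": [1e-4],
            }
        )

    def test_matching_effect_allele_keeps_sign(self):
        table = make_table(np.zeros((1, 4)), ref="A", alt="G")
        aligned, _ = prs.harmonize_alleles(self.stats_df("G", "A"), table)
        assert aligned["beta"].iloc[0] == pytest.approx(0.2)

    def test_effect_on_other_allele_flips_sign(self):
        table = make_table(np.zeros((1, 4)), ref="G", alt="A")
        aligned, _ = prs.harmonize_alleles(self.stats_df("G", "A"), table)
        assert aligned["beta"].iloc[0] == pytest.approx(-0.2)

    def test_strand_flip_resolved(self):
        table = make_table(np.zeros((1, 4)), ref="T", alt="C")
        aligned, _ = prs.harmonize_alleles(self.stats_df("G", "A"), table)
        # G complements to C = target ALT: counted allele, sign kept
        assert aligned["beta"].iloc[0] == pytest.approx(0.2)

    @pytest.mark.parametrize("a1,a2", [("A", "T"), ("C", "G")])
    def test_ambiguous_variants_removed(self, a1, a2):
        table = make_table(np.zeros((1, 4)), ref=a1, alt=a2)
        aligned, report = prs.harmonize_alleles(self.stats_df(a1, a2), table)
        assert len(aligned) == 0
        assert report["reason"].iloc[0] == "strand_ambiguous"

    def test_mismatch_dropped_with_reason(self):
        table = make_table(np.zeros((1, 4)), ref="A", alt="G")
        aligned, report = prs.harmonize_alleles(self.stats_df("A", "C"), table)
        assert len(aligned) == 0
        assert report["reason"].iloc[0] == "allele_mismatch"


def clump_oracle(aligned, table, r2_max, window_kb):
    """Brute-force greedy clumping, written independently."""
    dos = {}
    for i, vid in enumerate(table.variants["id"]):
        d = table.dosages[i]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        dos[vid] = d
    order = aligned.sort_values(["p", "chrom", "pos", "id"], kind="mergesort")
    kept = []
    for rec in order.itertuples(index=False):
        accept = True
        for other in kept:
            if other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) > window_kb * 1000:
                continue
            r = np.corrcoef(dos[rec.id], dos[other.id])[0, 1]
            if r * r > r2_max:
                accept = False
                break
        if accept:
            kept.append(rec)
    return [k.id for k in kept]


class TestClump:
    def make_block_panel(self, seed=0, m=50, n=400, block=5, rho=0.9):
        rng = np.random.default_rng(seed)
        dosages = np.empty((m, n))
        hap = None
        for i in range(m):
            f = rng.uniform(0.2, 0.8)
            if i % block == 0 or hap is None:
                hap = (rng.random((2, n)) < f).astype(float)
            else:  # copy previous haplotypes with prob rho -> block LD
                keep = rng.random((2, n)) < rho
                hap = np.where(keep, hap, (rng.random((2, n)) < f).astype(float))
            dosages[i] = hap.sum(axis=0)
        table = make_table(
            dosages,
            pos=(np.arange(m) % 25 + 1) * 10_000,
            chrom=[str(i // 25 + 1) for i in range(m)],
        )
        aligned = pd.DataFrame(
            {
                "id": table.variants["id"],
                "chrom": table.variants["chrom"],
                "pos": table.variants["pos"],
                "beta": rng.normal(0, 0.1, m),
                "p": rng.uniform(1e-8, 1, m),
            }
        )
        return table, aligned

    def test_independent_variants_all_retained(self):
        rng = np.random.default_rng(3)
        table = make_table((rng.random((20, 500)) < 0.4).astype(float) * 2)
        aligned = pd.DataFrame(
            {
                "id": table.variants["id"],
                "chrom": "1",
                "pos": table.variants["pos"],
                "beta": 0.1,
                "p": rng.uniform(0, 1, 20),
            }
        )
        out = prs.clump(aligned, table, r2_max=0.1)
        assert len(out) == 20

    def test_perfectly_correlated_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, 200).astype(float)
        table = make_table(np.vstack([g, g]), pos=[1000, 2000])
        aligned = pd.DataFrame(
            {
                "id": ["v0", "v1"],
                "chrom": ["1", "1"],
                "pos": [1000, 2000],
                "beta": [0.1, 0.1],
                "p": [1e-4, 1e-8],
            }
        )
        out = prs.clump(aligned, table)
        assert list(out["id"]) == ["v1"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_block_panel(self, seed):
        table, aligned = self.make_block_panel(seed=seed)
        out = prs.clump(aligned, table, r2_max=0.1, window_kb=500)
        assert list(out["id"]) == sorted(
            clump_oracle(aligned, table, 0.1, 500),
            key=lambda v: aligned.set_index("id").loc[v, "p"],
        )

    def test_clumped_sets_nested_under_loosening_r2(self):
        table, aligned = self.make_block_panel(seed=5)
        tight = set(prs.clump(aligned, table, r2_max=0.05)["id"])
        loose = set(prs.clump(aligned, table, r2_max=0.5)["id"])
        assert tight <= loose


class TestScoring:
    def test_hand_computed_score(self):
        table = make_table(np.array([[2.0], [1.0]]))
        aligned = pd.DataFrame(
            {
                "id": ["v0", "v1"],
                "chrom": "1",
                "pos": [1000, 2000],
                "beta": [0.5, -0.2],
                "p": [0.001, 0.001],
            }
        )
        profile = prs.score_at_thresholds(table, aligned, thresholds=(1.0,), standardize=False)
        assert profile.scores[0, 0] == pytest.approx(0.8)

    def test_zero_betas_zero_scores_and_nesting(self):
        rng = np.random.default_rng(6)
        table = make_table(rng.integers(0, 3, (10, 30)).astype(float))
        aligned = pd.DataFrame(
            {
                "id": table.variants["id"],
                "chrom": "1",
                "pos": table.variants["pos"],
                "beta": np.zeros(10),
                "p": rng.uniform(0, 1, 10),
            }
        )
        profile = prs.score_at_thresholds(table, aligned, standardize=False)
        assert np.allclose(profile.scores, 0.0)
        counts = [profile.n_variants[t] for t in profile.thresholds]
        assert counts == sorted(counts)

    def test_threshold_additivity(self):
        rng = np.random.default_rng(7)
        table = make_table(rng.integers(0, 3, (40, 50)).astype(float))
        aligned = pd.DataFrame(
            {
                "id": table.variants["id"],
                "chrom": "1",
                "pos": table.variants["pos"],
                "beta": rng.normal(0, 0.2, 40),
                "p": rng.uniform(0, 1, 40),
            }
        )
        profile = prs.score_at_thresholds(
            table, aligned, thresholds=(0.5, 1.0), standardize=False
        )
        tail = aligned[aligned["p"] > 0.5]
        idx = {v: i for i, v in enumerate(table.variants["id"])}
        manual = np.zeros(50)
        for rec in tail.itertuples(index=False):
            manual += rec.beta * table.dosages[idx[rec.id]]
        assert np.allclose(profile.scores[:, 1], profile.scores[:, 0] + manual)

    def test_invalid_threshold_rejected(self):
        table = make_table(np.zeros((1, 2)))
        aligned = pd.DataFrame(
            {"id": ["v0"], "chrom": "1", "pos": [1000], "beta": [0.1], "p": [0.5]}
        )
        with pytest.raises(ValueError, match="thresholds"):
            prs.score_at_thresholds(table, aligned, thresholds=(0.0,))

    def test_variant_order_and_allele_flip_invariance(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, (6, 40)).astype(float)
        table = make_table(d)
        aligned = pd.DataFrame(
            {
                "id": table.variants["id"],
                "chrom": "1",
                "pos": table.variants["pos"],
                "beta": rng.normal(0, 0.3, 6),
                "p": rng.uniform(0, 1, 6),
            }
        )
        base = prs.score_at_thresholds(table, aligned, standardize=False)
        shuffled = aligned.sample(frac=1, random_state=1)
        assert np.allclose(
            prs.score_at_thresholds(table, shuffled, standardize=False).scores, base.scores
        )
        # flip variant 0: dosage 2-d, beta -beta => score shifts by 2*beta
        d2 = d.copy()
        d2[0] = 2 - d2[0]
        flipped = aligned.copy()
        flipped.loc[flipped["id"] == "v0", "beta"] *= -1
        alt = prs.score_at_thresholds(make_table(d2), flipped, standardize=False)
        shift = alt.scores - base.scores
        assert np.allclose(shift, shift[0], atol=1e-12)  # constant per threshold


class TestKinshipAndPca:
    def test_mz_pair_plus_singleton_matrix(self):
        ped = pd.DataFrame(
            {
                "family_id": ["F0", "F0", "F1"],
                "person_id": ["a", "b", "c"],
                "zygosity": ["MZ", "MZ", "singleton"],
                "role": ["twin1", "twin2", "singleton"],
                "sex": [0, 0, 1],
                "age_t1": [14.0] * 3,
                "age_t2": [np.nan] * 3,
            }
        )
        K = prs.pedigree_kinship(ped)
        assert np.allclose(K.to_numpy(), np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]]))

    def test_singleton_cohort_identity(self):
        ped = pd.DataFrame(
            {
                "family_id": [f"F{i}" for i in range(4)],
                "person_id": list("abcd"),
                "zygosity": ["singleton"] * 4,
                "role": ["singleton"] * 4,
                "sex": [0] * 4,
                "age_t1": [15.0] * 4,
                "age_t2": [np.nan] * 4,
            }
        )
        assert np.allclose(prs.pedigree_kinship(ped).to_numpy(), np.eye(4))

    def test_genomic_kinship_tracks_pedigree(self, study):
        K_ped = prs.pedigree_kinship(study.cohort.pedigree())
        K_hat = prs.genomic_kinship(study.genotypes)
        K_hat = K_hat.loc[K_ped.index, K_ped.columns]
        off = ~np.eye(len(K_ped), dtype=bool)
        err = (K_hat.to_numpy() - K_ped.to_numpy())[off]
        assert np.abs(err).mean() < 0.05

    def test_pca_separates_subpopulations(self):
        rng = np.random.default_rng(9)
        m, n = 300, 200
        f1, f2 = rng.uniform(0.1, 0.9, m), None
        f2 = np.clip(f1 + rng.choice([-0.25, 0.25], m), 0.05, 0.95)
        pop = np.repeat([0, 1], n // 2)
        d = np.empty((m, n))
        for i in range(m):
            f = np.where(pop == 0, f1[i], f2[i])
            d[i] = (rng.random(n) < f) + (rng.random(n) < f)
        pcs = prs.pca_ancestry(make_table(d), n_pcs=2)
        r = np.corrcoef(pcs["PC1"], pop)[0, 1]
        assert abs(r) > 0.9

    def test_homogeneous_population_flat_spectrum(self):
        rng = np.random.default_rng(10)
        m, n = 2000, 100  # many variants per person: flat null spectrum
        f = rng.uniform(0.2, 0.8, m)
        d = ((rng.random((m, n)) < f[:, None]).astype(float)
             + (rng.random((m, n)) < f[:, None]).astype(float))
        table = make_table(d)
        freq = table.alt_frequency()
        sd = np.sqrt(2 * freq * (1 - freq))
        Z = ((d - 2 * freq[:, None]) / sd[:, None]).T
        Z = Z - Z.mean(axis=0)
        ev = np.linalg.svd(Z, compute_uv=False) ** 2
        assert ev[0] < 2 * np.median(ev)

    def test_zero_pcs_empty_frame(self):
        table = make_table(np.zeros((3, 5)))
        assert prs.pca_ancestry(table, n_pcs=0).shape[1] == 0
        with pytest.raises(ValueError, match="fewer variants"):
            prs.pca_ancestry(table, n_pcs=10)


class TestMixedAssoc:
    def family_null(self, seed, n_fam=30, sg2=0.5):
        rng = np.random.default_rng(seed)
        K = np.kron(np.eye(n_fam), np.array([[1.0, 0.5], [0.5, 1.0]]))
        L = np.linalg.cholesky(sg2 * K + (1 - sg2) * np.eye(2 * n_fam))
        y = L @ rng.standard_normal(2 * n_fam)
        W = np.column_stack([np.ones(2 * n_fam), rng.standard_normal(2 * n_fam)])
        s = rng.standard_normal(2 * n_fam)
        return y, s, W, K

    def test_sigma_g_zero_matches_ols(self):
        import statsmodels.api as sm

        y, s, W, K = self.family_null(0)
        res = prs.mixed_assoc(y, s, W, K, constrain_sigma_g=0.0)
        ols = sm.OLS(y, np.column_stack([W, s])).fit()
        assert res.beta == pytest.approx(ols.params[-1], abs=1e-8)
        assert res.se == pytest.approx(ols.bse[-1], abs=1e-8)

    def test_orthogonal_score_is_null(self):
        rng = np.random.default_rng(12)
        y = rng.standard_normal(400)
        W = np.ones((400, 1))
        s = rng.standard_normal(400)
        yc = y - y.mean()
        s = s - yc * (yc @ s) / (yc @ yc)  # exactly orthogonal to y
        res = prs.mixed_assoc(y, s, W, np.eye(400))
        assert res.p_one_sided == pytest.approx(0.5, abs=0.05)
        assert abs(res.r2_signed) < 0.01

    def test_two_sided_consistency(self):
        y, s, W, K = self.family_null(13)
        res = prs.mixed_assoc(y, s, W, K)
        assert res.p_two_sided == pytest.approx(
            2 * min(res.p_one_sided, 1 - res.p_one_sided), rel=1e-9
        )

    def test_generator_truth_prs_predicts_own_trait_only(self, study, prepared):
        from twincort.cohort import TRAITS

        qced, _ = prs.qc_filter(study.genotypes, study.cohort.pedigree())
        aligned, _ = prs.harmonize_alleles(study.sumstats["hcc"], qced)
        clumped = prs.clump(aligned, qced)
        profile = prs.score_at_thresholds(qced, clumped)
        t1 = prepared.table[prepared.table["time_point"] == 1].set_index("person_id")
        t1 = t1.loc[qced.persons]
        K = prs.pedigree_kinship(study.cohort.pedigree(), persons=qced.persons)
        age = t1["age"] - t1["age"].mean()
        W = np.column_stack([np.ones(len(t1)), t1["sex"], age, age**2])
        own = prs.mixed_assoc(
            t1["hcc_resid"].to_numpy(), profile.scores[:, -1], W, K.to_numpy()
        )
        other = prs.mixed_assoc(
            t1["stress"].to_numpy(), profile.scores[:, -1], W, K.to_numpy()
        )
        assert own.p_one_sided < 0.05
        assert other.p_one_sided > 0.05
        assert own.r2_signed > 0

    def test_non_psd_kinship_rejected(self):
        y = np.zeros(4)
        K = np.eye(4)
        K[0, 1] = K[1, 0] = 2.0
        with pytest.raises(ValueError, match="PSD"):
            prs.mixed_assoc(y, np.ones(4), np.ones((4, 1)), K)


class TestThresholdSweep:
    def test_grid_shape_and_duplicate_phenotype(self, study, prepared):
        qced, _ = prs.qc_filter(study.genotypes, study.cohort.pedigree())
        profiles = {}
        for disc in ("hcc", "neuro"):
            aligned, _ = prs.harmonize_alleles(study.sumstats[disc], qced)
            profiles[disc] = prs.score_at_thresholds(qced, prs.clump(aligned, qced))
        t1 = prepared.table[prepared.table["time_point"] == 1].set_index("person_id")
        t1 = t1.loc[qced.persons]
        t1["hcc_copy"] = t1["hcc_resid"]
        K = prs.pedigree_kinship(study.cohort.pedigree(), persons=qced.persons)
        age = t1["age"] - t1["age"].mean()
        W = pd.DataFrame(
            {"const": 1.0, "sex": t1["sex"], "age": age}, index=t1.index
        )
        sweep = prs.threshold_sweep(
            t1.reset_index(), profiles, W, K, traits=("hcc_resid", "hcc_copy")
        )
        assert len(sweep) == 2 * 8 * 2
        for disc in ("hcc", "neuro"):
            for t in prs.PRS_THRESHOLDS:
                cell = sweep[(sweep["discovery"] == disc) & (sweep["threshold"] == t)]
                a = cell[cell["phenotype"] == "hcc_resid"].iloc[0]
                b = cell[cell["phenotype"] == "hcc_copy"].iloc[0]
                assert a["beta"] == pytest.approx(b["beta"], rel=1e-9)
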