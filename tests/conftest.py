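import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from twincort import phenotypes as phen
from twincort.cohort import (
    CohortDesign,
    TRAITS,
    TrueModel,
    build_cohort,
    draw_latent_traits,
    simulate_study,
)


@pytest.fixture(scope="session")
def study():
    """Default-size simulated study with a reduced genotype panel."""
    return simulate_study(
        seed=11,
        gwas_kwargs={"m_variants": 600, "n_causal": 30, "discovery_n": 2500},
        prs_effect=0.5,
    )


@pytest.fixture(scope="session")
def prepared(study):
    return phen.prepare_phenotypes(study.phenotypes)


@pytest.fixture(scope="session")
def pedigree(study):
    return study.cohort.pedigree()


def univariate_twin_frame(
    n_mz: int,
    n_dz: int,
    a2: float = 0.72,
    seed: int = 0,
    c2: float = 0.0,
    trait: str = "y",
):
    """Prepared-phenotype frame for a univariate ACE/AE truth."""
    design = CohortDesign(
        n_mz_pairs=n_mz,
        n_dz_pairs=n_dz,
        n_triplet_sets=0,
        n_extra_siblings=0,
        retest_fraction=0.0,
        seed=seed,
    )
    cohort = build_cohort(design)
    e2 = 1.0 - a2 - c2
    truth = TrueModel(
        X=np.array([[np.sqrt(a2)]]),
        Y=np.array([[np.sqrt(c2)]]),
        Z=np.array([[np.sqrt(e2)]]),
        stability=np.array([0.5]),
    )
    lat = draw_latent_traits(cohort, truth, seed=seed + 1, include_retest=False)[1]
    frame = pd.DataFrame(
        {
            "person_id": cohort.individuals["person_id"],
            "time_point": 1,
            "sex": cohort.individuals["sex"],
            "age": cohort.individuals["age_t1"],
            trait: lat[:, 0],
        }
    )
    return frame, cohort.pedigree()


@pytest.fixture(scope="session")
def multivariate_frame():
    """Noise-free 4-trait latent frame at ten times the study's family
    counts, drawn from the default generating paths (no polygenic
    blend), plus its pedigree — for model-recovery checks."""
    design = CohortDesign(
        n_mz_pairs=1160,
        n_dz_pairs=1870,
        n_triplet_sets=0,
        n_extra_siblings=0,
        retest_fraction=0.0,
        seed=77,
    )
    cohort = build_cohort(design)
    truth = TrueModel()  # published AE paths, zero mean model
    lat = draw_latent_traits(cohort, truth, seed=78, include_retest=False)[1]
    ind = cohort.individuals
    frame = pd.DataFrame(
        {
            "person_id": ind["person_id"],
            "time_point": 1,
            "sex": ind["sex"],
            "age": ind["age_t1"],
        }
    )
    for j, t in enumerate(TRAITS):
        frame[t] = lat[:, j]
    return frame, cohort.pedigree()
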