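"""Shared fixtures: small simulated cohorts reused across test modules.

All fixtures are deterministic (fixed seeds) and session-scoped where the
simulation is expensive.
"""

import pandas as pd
import pytest

from assortmr import SimulationConfig, inject_decoys, simulate_cohort
from assortmr.pairs import derive_spouse_pairs


@pytest.fixture(scope="session")
def small_cohort():
    """2,000 individuals under assortative mating; quick general-purpose cohort."""
    cfg = SimulationConfig(n_individuals=2000, n_pgs_snps=50, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def uncensored_cohort():
    """20,000 individuals, assortative C=0.37, censoring disabled: the
    bivariate-normal regime the closed-form expectations describe."""
    cfg = SimulationConfig(n_individuals=20_000, assort_C=0.37,
                           censor_at_zero=False, seed=31)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def decoy_cohort():
    """4,000 individuals + decoys over a 1,001-marker panel, for derivation tests."""
    cfg = SimulationConfig(n_individuals=4000, n_pgs_snps=1000, seed=5)
    cohort = simulate_cohort(cfg)
    return inject_decoys(cohort, n_same_sex=20, n_sib_pairs=50, n_key_trios=5, seed=2)


@pytest.fixture(scope="session")
def decoy_derivation(decoy_cohort):
    """Full spouse-pair derivation run on the decoy cohort."""
    return derive_spouse_pairs(
        decoy_cohort.individuals,
        decoy_cohort.genotypes,
        positions=decoy_cohort.variants["pos"],
        chrom=decoy_cohort.variants["chrom"],
    )


@pytest.fixture(scope="session")
def true_pairs(small_cohort):
    """Retained true-couple id pairs of the small cohort."""
    return small_cohort.couple_frame()[["id_a", "id_b"]].reset_index(drop=True)


def pairs_of(cohort) -> pd.DataFrame:
    return cohort.couple_frame()[["id_a", "id_b"]].reset_index(drop=True)
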