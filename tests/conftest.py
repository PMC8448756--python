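"""Shared fixtures: a reduced synthetic cohort reused across module tests.

The small cohort keeps the default study structure (4 subpopulations, a
triploid AAB founder rooted in the last one, 2 non-founder triploids) but
shrinks the site grid so the whole suite stays fast; divergence rates are
raised accordingly so het-site counts remain informative.
"""

import numpy as np
import pytest

from clonetrace import (
    CallingParams,
    PloidyParams,
    SimConfig,
    call_genotypes,
    simulate_cohort_depths,
    simulate_population,
)

SMALL_SEED = 20210917


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_sites=12_000,
        genome_length=1_200_000,
        samples_per_subpop=(3, 3, 3, 3),
        founder_AB_divergence=0.01,
        within_subpop_diversity=0.008,
        pool_haplotypes=2,
        n_triploid_samples=2,
        mito_length=4_000,
        seed=SMALL_SEED,
    )
    base.update(overrides)
    return SimConfig(**base)


#: het-site floor matched to the small cohort's reduced site grid
SMALL_PLOIDY = PloidyParams(min_het_sites=80)


@pytest.fixture(scope="session")
def small_truth():
    return simulate_population(small_config())


@pytest.fixture(scope="session")
def small_profiles(small_truth):
    return simulate_cohort_depths(small_truth)


@pytest.fixture(scope="session")
def small_calls(small_profiles):
    return [call_genotypes(p, CallingParams()) for p in small_profiles]


@pytest.fixture(scope="session")
def subpop_of(small_truth):
    return {g.sample_id: small_truth.subpop_names[g.subpop] for g in small_truth.genomes}
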