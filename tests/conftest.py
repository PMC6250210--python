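import numpy as np
import pytest

from introscan import (
    DemographicModel,
    PopulationMap,
    allele_counts,
    make_windows,
    simulate,
)


@pytest.fixture(scope="session")
def small_model():
    """The study demography at test scale: 200 kb instead of 25 Mb."""
    return DemographicModel(chromosome_length=200_000, seed=42)


@pytest.fixture(scope="session")
def sim_small(small_model):
    return simulate(small_model)


@pytest.fixture(scope="session")
def popmap_small(small_model):
    return PopulationMap.for_simulation(small_model)


@pytest.fixture(scope="session")
def counts_small(sim_small, popmap_small, small_model):
    groups = {
        p: popmap_small.population_samples(p)
        for p in small_model.population_labels
    }
    return allele_counts(sim_small.haplotypes, groups, ploidy=1)


@pytest.fixture(scope="session")
def windows_small(small_model, sim_small):
    return make_windows(
        {sim_small.haplotypes.scaffold: small_model.chromosome_length}, 50_000
    )
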