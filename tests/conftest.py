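import numpy as np
import pandas as pd
import pytest

from namgwas.design import generate_smarthouse
from namgwas.genmap import GeneticMap, simulate_map
from namgwas.phenosim import SimulationTruth, TraitArchitecture, simulate_experiment
from namgwas.population import simulate_population
from namgwas.traits import derive_trait_table


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    return simulate_map(6, 150.0, seed=101)


@pytest.fixture(scope="session")
def small_population(small_map):
    return simulate_population(small_map, [10, 10, 10], seed=102,
                               allow_any_family_count=True)


@pytest.fixture(scope="session")
def small_layout(small_population):
    lines = list(small_population.nam_lines())
    return generate_smarthouse(lines, zones=2, lanes=4, positions=10,
                               n_check_mainplots_per_zone=3,
                               n_recurrent_mainplots=2, seed=103)


@pytest.fixture(scope="session")
def small_experiment(small_population, small_layout):
    truth = SimulationTruth(
        architecture=TraitArchitecture(intercept=0.0, family_effect_sd=5.0))
    psa, harvest = simulate_experiment(small_population, small_layout, truth,
                                       seed=104)
    return psa, harvest, truth


@pytest.fixture(scope="session")
def small_trait_table(small_experiment):
    psa, harvest, _ = small_experiment
    return derive_trait_table(psa, harvest)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def two_marker_map(d_cM: float) -> GeneticMap:
    """Map with two markers ``d_cM`` apart on 1H (test helper)."""
    return GeneticMap(pd.DataFrame({
        "snp_id": ["m1", "m2"], "chromosome": ["1H", "1H"],
        "position": [50.0, 50.0 + d_cM]}))
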