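"""Shared fixtures: one small synthetic study reused across the suite."""

import numpy as np
import pytest

from holomap.config import SimConfig
from holomap.env_layers import apply_study_mask
from holomap.diversity import rarefy
from holomap.grid import PRESENT
from holomap.sdm import add_pseudo_absences, cross_validate_sdm, grid_records
from holomap.simulate import (default_microbiome, default_niches,
                              generate_asv_table, generate_env_grid,
                              generate_host_occurrences)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=7, lat_min=43.0, lat_max=45.5, lon_min=-64.0,
                     lon_max=-61.0, records_per_species=300)


@pytest.fixture(scope="session")
def masked_grid(sim_config):
    return apply_study_mask(generate_env_grid(sim_config))


@pytest.fixture(scope="session")
def niches(sim_config):
    return default_niches(sim_config)


@pytest.fixture(scope="session")
def records(masked_grid, niches, sim_config):
    return generate_host_occurrences(masked_grid, niches, sim_config)


@pytest.fixture(scope="session")
def gridded(records, masked_grid):
    return grid_records(records, masked_grid)


@pytest.fixture(scope="session")
def sdm_records(gridded):
    return add_pseudo_absences(gridded)


@pytest.fixture(scope="session")
def truth(sim_config):
    return default_microbiome(sim_config)


@pytest.fixture(scope="session")
def asv_table(records, masked_grid, truth, sim_config):
    return generate_asv_table(records, masked_grid, truth, sim_config)


@pytest.fixture(scope="session")
def rarefied(asv_table):
    return rarefy(asv_table, 6000, seed=11)


@pytest.fixture(scope="session")
def vaz_sdm(sdm_records, masked_grid):
    sub = (sdm_records[sdm_records["species"] == "V. pourtalesii"]
           .reset_index(drop=True))
    return cross_validate_sdm(sub, masked_grid, PRESENT, k=5, n_trees=100,
                              block_size_cells=5, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
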