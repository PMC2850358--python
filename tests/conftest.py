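from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from tilingsweep import SimConfig
from tilingsweep import synthetic as syn

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_sweep_table() -> pd.DataFrame:
    """Reference sweep-region table (five regions) used to check interval
    arithmetic and table parsing."""
    return pd.read_csv(DATA_DIR / "sweep_regions_reference.tsv", sep="\t")


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    """Default desk-scale generator configuration."""
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def small_study(sim_config):
    """One fully generated small study shared across read-only tests."""
    probes = syn.generate_probe_map(sim_config)
    annotation = syn.generate_annotation(sim_config)
    population, qmatrix, geo = syn.generate_population(sim_config)
    truth = syn.plant_variants(population, sim_config, probes, annotation)
    return {
        "config": sim_config,
        "probes": probes,
        "annotation": annotation,
        "population": population,
        "qmatrix": qmatrix,
        "geo": geo,
        "truth": truth,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
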