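import numpy as np
import pandas as pd
import pytest

from nichescope.simulate import SimulationConfig, simulate_repertoires, simulate_timeseries


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down community: 24 rMAGs, 4 types, 12 timepoints."""
    return SimulationConfig(
        seed=7,
        n_rmags=24,
        n_types=4,
        n_timepoints=12,
        ko_universe=1200,
        n_core_kos=300,
        type_specific_kos=(120, 90, 140, 70),
        pair_shared_kos=50,
        private_kos_per_rmag=20,
        genes_per_rmag=120,
        n_contigs_per_rmag=4,
        disturbance_window=(6, 8),
        n_disturbance_rmags=6,
        n_metabolites=30,
        n_contaminants=4,
    )


@pytest.fixture(scope="session")
def small_community(small_config):
    matrix, truth = simulate_repertoires(small_config)
    ts = simulate_timeseries(small_config, matrix, truth)
    return small_config, matrix, truth, ts


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def toy_annotations() -> pd.DataFrame:
    rows = [
        ("g1", "A", "K1", "CatX", 1000),
        ("g2", "A", "K1", "CatX", 500),
        ("g3", "A", "K2", "", 800),
        ("g4", "B", "K2", "CatY", 900),
        ("g5", "B", "K3", "CatY", 700),
        ("g6", "B", "", "", 600),
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "rmag_id", "ko_id", "foam_l1", "length_bp"]
    )
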