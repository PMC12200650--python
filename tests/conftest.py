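from datetime import date

import numpy as np
import pandas as pd
import pytest

from opioid_trends import SimulationConfig, generate_dataset, run_phenotype_pipeline
from opioid_trends.products import DEFAULT_FORMULARY, products_to_frame


@pytest.fixture(scope="session")
def products():
    return products_to_frame(DEFAULT_FORMULARY)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_patients=2500, seed=1234)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset, small_config):
    return run_phenotype_pipeline(small_dataset, small_config)


@pytest.fixture(scope="session")
def default_pipeline():
    """Full default-scale run (~13k registered patients/year)."""
    cfg = SimulationConfig()
    ds = generate_dataset(cfg)
    return cfg, ds, run_phenotype_pipeline(ds, cfg)


def random_prescriptions(rng: np.random.Generator, index: pd.Timestamp,
                         n_max: int = 12) -> pd.DataFrame:
    """Random cleaned-prescription table for one patient around an index
    date: issue offsets in [-30, 500], supplies 1..90 days."""
    n = int(rng.integers(0, n_max + 1))
    offs = rng.integers(-30, 501, size=n)
    supply = rng.integers(1, 91, size=n)
    return pd.DataFrame({
        "patient_id": "p0",
        "supply_start": index + pd.to_timedelta(offs, unit="D"),
        "supply_days": supply,
    })
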