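import numpy as np
import pandas as pd
import pytest

import nichetransfer as nt


@pytest.fixture(scope="session")
def small_config():
    """A compact landscape used by fast unit tests."""
    return nt.LandscapeConfig(grid_rows=60, grid_cols=60,
                              decadal_drift_sd=0.0, rng_seed=11)


@pytest.fixture(scope="session")
def small_stacks(small_config):
    return nt.generate_climate(small_config)


@pytest.fixture(scope="session")
def clean_world():
    """Zero-drift, noise-free survey world: detections equal truth."""
    cfg = nt.LandscapeConfig(grid_rows=80, grid_cols=80,
                             decadal_drift_sd=0.0, rng_seed=11)
    specs = [{"species_id": f"sp{i:02d}",
              "range_class": ["WC", "WR", "NEC", "NER"][i % 4],
              "trend": "stable"} for i in range(8)]
    return nt.build_world(cfg, species_specs=specs, misid_rate=0.0,
                          detectability=1.0)


@pytest.fixture
def detection_table():
    """Hand-built detection table: one circle surveyed 30 years."""
    def make(years_detected, n_surveyed=30, start=1950):
        years = list(range(start, start + n_surveyed))
        rec = pd.DataFrame({
            "circle_id": "C0",
            "species_id": "sp",
            "year": years_detected,
            "detected": True,
        })
        return nt.DetectionTable(records=rec, effort={"C0": set(years)})
    return make


@pytest.fixture(scope="session")
def trait_table():
    return nt.load_trait_table()
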