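import numpy as np
import pandas as pd
import pytest

from sdmens import (
    BaseModelPrediction,
    PipelineConfig,
    SyntheticConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_world():
    """20x20 synthetic county world with 4 base models, shared across tests."""
    cfg = SyntheticConfig(
        n_rows=20,
        n_cols=20,
        seed=7,
        model_specs=[(0.85, 0.8), (0.75, 0.9), (0.9, 0.7), (0.65, 0.95)],
    )
    counties, truth, calls = simulate_dataset(cfg)
    return cfg, counties, truth, calls


@pytest.fixture(scope="session")
def small_models(small_world):
    _, _, _, calls = small_world
    return {
        sp: [
            BaseModelPrediction(model_name=n, kind="binary", score=df[n])
            for n in df.columns
        ]
        for sp, df in calls.items()
    }


@pytest.fixture()
def toy_counties():
    """Five hand-placed counties on the equator (1 deg ~ 111.19 km)."""
    return pd.DataFrame(
        {
            "county_id": ["00001", "00002", "00003", "00004", "00005"],
            "name": list("abcde"),
            "lat": [0.0, 0.0, 0.0, 0.0, 0.0],
            "lon": [0.0, 0.7, 1.5, 3.0, 5.0],
            "present_A": [1, 0, 0, 0, 0],
            "present_B": [0, 1, 1, 0, 0],
            "surveyed": [0, 0, 0, 1, 0],
        }
    )


@pytest.fixture()
def simple_labels():
    """Ten labeled counties with a train/test split."""
    return pd.DataFrame(
        {
            "county_id": [f"{i:05d}" for i in range(12)],
            "species": "A",
            "label": pd.array([1, 1, 1, 1, 0, 0, 0, 0, 1, 0, None, None], dtype="Int64"),
            "split": ["train"] * 8 + ["test", "test", "none", "none"],
        }
    )
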