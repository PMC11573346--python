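import numpy as np
import pytest
from hypothesis import settings

from patchwalk.config import ExperimentConfig
from patchwalk.slice_synth import ConnectionModel, SliceSpec, generate_slice, sample_ground_truth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_model() -> ConnectionModel:
    return ConnectionModel.default()


@pytest.fixture()
def perfect_config() -> ExperimentConfig:
    """All stages succeed; deterministic durations — pure strategy structure."""
    return ExperimentConfig(
        hunt_success=1.0,
        seal_success=1.0,
        breakin_success=1.0,
        durations={
            "pipette_finding": {"mean_s": 30.0},
            "neuron_hunting": {"mean_s": 60.0},
            "gigaseal": {"mean_s": 60.0},
            "break_in": {"mean_s": 20.0},
            "connectivity_test": {"mean_s": 90.0},
            "cleaning": {"mean_s": 45.0},
        },
    )


@pytest.fixture()
def small_slice(default_model):
    cells = generate_slice(SliceSpec(n_cells=8, seed=42))
    truth = sample_ground_truth(cells, default_model, seed=43)
    return cells, truth
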