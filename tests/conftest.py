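import numpy as np
import pytest

from uvquant.spectra_io import SampleMeta, SpectraDataset, WavelengthGrid
from uvquant.synth import NoiseModel, build_cospike_design, simulate_dataset


@pytest.fixture
def small_grid() -> WavelengthGrid:
    return WavelengthGrid(np.array([200.0, 210.0, 220.0, 230.0]))


@pytest.fixture
def small_dataset(small_grid) -> SpectraDataset:
    meta = [
        SampleMeta("s1", "day1", 1, 1, {"BSA": 100.0}, "calibration"),
        SampleMeta("s2", "day1", 1, 2, {"BSA": 100.0}, "calibration"),
        SampleMeta("s3", "day2", 2, 1, {"BSA": 0.0}, "blank"),
    ]
    ab = np.array(
        [
            [0.11, 0.42, 0.80, 0.35],
            [0.12, 0.40, 0.78, 0.36],
            [0.01, 0.05, 0.10, 0.04],
        ]
    )
    return SpectraDataset(small_grid, ab, meta)


@pytest.fixture(scope="session")
def noiseless_cospike() -> SpectraDataset:
    """Deterministic co-spike dataset with every noise term switched off."""
    noise = NoiseModel(additive_sd=0.0, pathlength_sd=0.0, baseline_drift=(0.0, 0.0), seed=0)
    return simulate_dataset(build_cospike_design(), noise=noise)


@pytest.fixture(scope="session")
def default_cospike() -> SpectraDataset:
    """Co-spike dataset under the default study conditions (seed 1)."""
    noise = NoiseModel(additive_sd=0.005, pathlength_sd=0.05, seed=1)
    return simulate_dataset(build_cospike_design(), noise=noise)
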