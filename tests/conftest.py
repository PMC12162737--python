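from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import radiomaps as rm
from radiomaps.pipeline import RunConfig, run_experimental

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_region(seed: int, shape=(8, 8), n_levels: int = 6, bin_width: float = 25.0):
    """A random discretizable region: intensities on a 25-unit lattice, random mask."""
    rng = np.random.default_rng(seed)
    values = bin_width * rng.integers(0, n_levels, size=shape).astype(float)
    mask = rng.random(shape) < 0.75
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return values, mask


@pytest.fixture(scope="session")
def random_regions():
    return [random_region(seed) for seed in range(100)]


def small_run_config(**overrides) -> RunConfig:
    """A reduced-geometry config for fast end-to-end tests."""
    acq = (
        rm.AcquisitionSpec(fov_mm=(120.0, 100.0), matrix=(80, 64)),
        rm.AcquisitionSpec(fov_mm=(140.0, 116.0), matrix=(80, 64)),
    )
    defaults = dict(n_subjects=2, seed=11, acquisitions=acq)
    defaults.update(overrides)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def experimental_result():
    """The default seeded 12-subject x 3-FOV study, run once per session."""
    return run_experimental(RunConfig(seed=0))
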