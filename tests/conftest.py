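import dataclasses

import numpy as np
import pytest

from scatterid import (AcquisitionConfig, Epoch, RunConfig,
                       default_study_design, run_pipeline)

STUDY_SEED = 7


@pytest.fixture(scope="session")
def default_run():
    """One full default-study pipeline run (66 x 120 s, fixed seed).

    Session-scoped: it backs the headline-behavior checks and the
    dataset bookkeeping, and takes a couple of minutes.
    """
    return run_pipeline(RunConfig(seed=STUDY_SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def gaussian_epoch(rng):
    """A 2 s white-Gaussian epoch at the study sampling rate."""
    return Epoch(samples=rng.normal(size=10_000), fs=5000.0,
                 particle_id="p0", class_label="ps", index=0)


@pytest.fixture()
def small_design():
    """Four-class design scaled down to 1 particle and 10 s per class."""
    specs = [dataclasses.replace(s, count=1) for s in default_study_design()]
    cfg = AcquisitionConfig(duration=10.0, seed=3)
    return specs, cfg
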