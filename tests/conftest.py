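import logging

import numpy as np
import pytest

from sleeptransfer.synthgen import (
    HypnogramSpec,
    StageSpec,
    default_stage_specs,
    generate_recording,
)

# the bias fallback logs a warning by design; keep test output readable
logging.getLogger("sleeptransfer.tsvm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def stage_specs():
    return default_stage_specs()


@pytest.fixture(scope="session")
def noise_free_specs():
    """Single-rhythm, noise-free recipes: spectral content is exactly the band."""
    return {
        "W": StageSpec("W", [(9.0, 11.0, 30.0)]),
        "N1": StageSpec("N1", [(5.0, 7.0, 40.0)]),
        "N2": StageSpec("N2", [(12.0, 14.0, 35.0)]),
        "N3": StageSpec("N3", [(0.75, 3.0, 75.0)]),
        "REM": StageSpec("REM", [(4.2, 5.0, 25.0)]),
    }


@pytest.fixture(scope="session")
def small_recording(stage_specs):
    """40-epoch labeled synthetic recording at 125 Hz (25-s epochs)."""
    spec = HypnogramSpec(n_epochs=40, n_cycles=2, seed=11)
    return generate_recording(spec, stage_specs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
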