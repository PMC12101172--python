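import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import driftlab as dl

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def layout():
    """3 lines x 5 words, 50 px spacing, line centers at 110/160/210."""
    return dl.grid_layout(3, 5)


@pytest.fixture
def big_layout():
    return dl.grid_layout(4, 6)


def clean_params(**overrides):
    """Generator params for perfectly recoverable trials: no jitter, no
    skipping, no regressions unless overridden."""
    defaults = dict(
        regression_probability=0.0,
        jitter_sd_x=0.0,
        jitter_sd_y=0.0,
        skip_enabled=False,
        seed=0,
    )
    defaults.update(overrides)
    return dl.GeneratorParams(**defaults)


@pytest.fixture
def clean_trial(layout):
    """Undistorted, regression-free, zero-jitter trial: one fixation per word."""
    return dl.generate_between_line(layout, clean_params(), trial_id="clean")


def random_sequence(rng, n=None, x_range=(0, 1000), y_range=(0, 500)):
    n = n if n is not None else int(rng.integers(1, 40))
    x = rng.uniform(*x_range, n)
    y = rng.uniform(*y_range, n)
    d = rng.uniform(50, 600, n)
    return dl.FixationSequence.from_arrays(x, y, d)
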