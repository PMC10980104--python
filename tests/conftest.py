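import dataclasses

import numpy as np
import pytest

from cardiogan.phantom import make_class_presets, render_cell_field


@pytest.fixture(scope="session")
def presets():
    return make_class_presets(0.3)


@pytest.fixture(scope="session")
def day6_params(presets):
    return presets["day6"]


@pytest.fixture(scope="session")
def noiseless_day6(day6_params):
    return dataclasses.replace(day6_params, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_field(day6_params):
    """One rendered 300x300 phantom field, reused across read-only tests."""
    return render_cell_field(day6_params, seed=5, label="day6")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
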