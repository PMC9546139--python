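import numpy as np
import pytest

import rxmix as rx

# the reference two-wave parameter sets used across the suite
REFERENCE_PARAMS = {
    "bass": [(0.0583, 4.36), (3.86e-5, 3.84)],
    "lognormal": [(-0.112, 0.223), (1.09, 0.0274)],
    "weibull": [(2.38, 1.15), (6.80, 3.24)],
}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(params=sorted(REFERENCE_PARAMS))
def family(request):
    return request.param


@pytest.fixture
def reference_components(family):
    return [rx.ComponentParams(family, p) for p in REFERENCE_PARAMS[family]]


@pytest.fixture
def lognormal_truth():
    return rx.study_truth("lognormal")


@pytest.fixture
def small_dataset(rng):
    """n=150 from the lognormal reference truth (base design)."""
    spec, truth = rx.study_truth("lognormal")
    cfg = rx.SimConfig(spec=spec, truth=truth, n=150, seed=7)
    return spec, truth, rx.generate_base(cfg, rng)
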