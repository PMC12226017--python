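import numpy as np
import pytest

import varxnet as vn


@pytest.fixture(scope="session")
def small_varx_dataset():
    """A modest simulated VARX recording reused by several test modules."""
    spec = vn.oscillator_ground_truth(d_y=3, d_x=2, n_a=2, n_b=6, seed=7)
    x = vn.make_stimulus(
        8000,
        60.0,
        [{"kind": "pulse", "rate": 1.0}, {"kind": "continuous", "smoothness": 0.1}],
        seed=8,
    )
    y = vn.simulate_varx(spec, x, seed=9)
    return spec, y, x


@pytest.fixture(scope="session")
def fitted_small_model(small_varx_dataset):
    spec, y, x = small_varx_dataset
    model = vn.VARX(n_a=2, n_b=6, lambda_reg=0.0).fit(y, x)
    return spec, model
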