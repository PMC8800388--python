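import numpy as np
import pytest

from coralbti.modelfit import ModGaussParams, predict
from coralbti.trajectory import RGSeries


@pytest.fixture
def clean_curve():
    """A noiseless bleaching trajectory with known parameters."""
    p = ModGaussParams(y0=2.0, a=98.0, x0=1.0, b=6.0, c=3.0)
    t = np.arange(0.0, 25.01, 0.5)
    return RGSeries("clean", t, np.asarray(predict(p, t))), p


def make_series(p: ModGaussParams, t_max=25.0, step=0.5, noise_sd=0.0,
                seed=0, fragment_id="s"):
    t = np.arange(0.0, t_max + 1e-9, step)
    y = np.asarray(predict(p, t), dtype=float)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(t))
    return RGSeries(fragment_id, t, y)
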