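import numpy as np
import pytest

from phenomap import COMPOSITE_DOYS, ReflectanceSeries, double_sigmoid

TRUE_PARAMS = dict(v_b=0.15, v_a=0.55, p=0.12, d_i=160.0, q=0.10, d_d=250.0)


@pytest.fixture
def true_params():
    return dict(TRUE_PARAMS)


@pytest.fixture
def clean_evi():
    """Noise-free double-sigmoid EVI sampled at the 46 composite DOYs."""
    t = COMPOSITE_DOYS.astype(float)
    return t, double_sigmoid(t, **TRUE_PARAMS)


def make_series(dates=None, bands=None, quality=None):
    dates = COMPOSITE_DOYS.astype(float) if dates is None else np.asarray(dates, float)
    n = len(dates)
    if bands is None:
        bands = np.full((n, 7), 0.2)
    if quality is None:
        quality = np.ones((n, 7), dtype=bool)
    return ReflectanceSeries(dates, bands, quality)


@pytest.fixture
def flat_series():
    return make_series()
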