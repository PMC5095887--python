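"""Double-sigmoid fitting and phenological-metric derivation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenomap import (COMPOSITE_DOYS, HALF_WIDTH_CONST, compute_evi,
                      derive_pheno_metrics, double_sigmoid, fit_double_sigmoid)
from phenomap.phenology import PhenoCurve


class TestComputeEvi:
    @pytest.mark.parametrize(
        "nir,red,blue,expected",
        [(0.5, 0.1, 0.05, 1.0 / 1.725), (0.2, 0.2, 0.2, 0.0)],
    )
    def test_formula(self, nir, red, blue, expected):
        evi, ok = compute_evi(red, nir, blue)
        assert ok
        assert evi == pytest.approx(expected, abs=1e-12)

    def test_degenerate_denominator_flags_invalid(self):
        evi, ok = compute_evi(red=0.9, nir=0.0, blue=1.0)
        assert not ok and np.isnan(evi)

    def test_vectorized_mask(self):
        evi, ok = compute_evi(np.array([0.1, 0.9]), np.array([0.5, 0.0]),
                              np.array([0.05, 1.0]))
        assert ok.tolist() == [True, False]


class TestFit:
    def test_noise_free_recovery(self, clean_evi, true_params):
        t, y = clean_evi
        c = fit_double_sigmoid(t, y, "full")
        assert c.success
        assert c.v_b == pytest.approx(true_params["v_b"], abs=1e-3)
        assert c.v_a == pytest.approx(true_params["v_a"], abs=1e-3)
        assert c.p == pytest.approx(true_params["p"], abs=1e-3)
        assert c.q == pytest.approx(true_params["q"], abs=1e-3)
        assert c.d_i == pytest.approx(true_params["d_i"], abs=0.1)
        assert c.d_d == pytest.approx(true_params["d_d"], abs=0.1)

    def test_flat_series(self):
        t = COMPOSITE_DOYS.astype(float)
        c = fit_double_sigmoid(t, np.full_like(t, 0.2), "full")
        assert c.success
        assert c.v_b + c.v_a * 0.0 <= 0.3  # background near 0.2, tiny amplitude
        assert abs(c(t).mean() - 0.2) < 1e-3

    def test_early_mode_truncated(self, true_params):
        t = COMPOSITE_DOYS.astype(float)
        keep = t <= 224
        y = double_sigmoid(t, **true_params)[keep]
        c = fit_double_sigmoid(t[keep], y, "early")
        assert c.success
        assert c.d_i == pytest.approx(true_params["d_i"], abs=0.5)
        assert c.q is None and c.d_d is None

    def test_too_few_observations_unfit(self):
        t = COMPOSITE_DOYS.astype(float)[:8]
        c = fit_double_sigmoid(t, np.full_like(t, 0.3), "full")
        assert not c.success and np.isnan(c.v_b)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_parameter_recovery(self, seed):
        """Noise-free refit recovers crop-like parameters within bounds."""
        rng = np.random.default_rng(seed)
        params = dict(
            v_b=rng.uniform(0.05, 0.3), v_a=rng.uniform(0.2, 0.8),
            p=rng.uniform(0.06, 0.25), d_i=rng.uniform(140, 180),
            q=rng.uniform(0.06, 0.25),
        )
        params["d_d"] = params["d_i"] + rng.uniform(60, 110)
        t = COMPOSITE_DOYS.astype(float)
        c = fit_double_sigmoid(t, double_sigmoid(t, **params), "full")
        assert c.success
        assert abs(c.d_i - params["d_i"]) <= 0.5
        assert abs(c.d_d - params["d_d"]) <= 0.5
        for name in ("v_b", "v_a", "p", "q"):
            assert abs(getattr(c, name) - params[name]) <= 1e-2


def numeric_second_derivative_extrema(fn, center, slope):
    """Independent oracle: locate extrema of a segment's second derivative
    by finite differences on a dense grid."""
    h = 0.001
    t = np.arange(center - 3.5 / slope, center + 3.5 / slope, 0.005)
    f2 = (fn(t + h) - 2 * fn(t) + fn(t - h)) / h**2
    return t[np.argmax(f2)], t[np.argmin(f2)]


def rising_segment(c):
    from phenomap import rising_sigmoid
    return lambda t: rising_sigmoid(t, c.v_b, c.v_a, c.p, c.d_i)


def falling_segment(c):
    from phenomap.phenology import _sigma
    return lambda t: c.v_b - c.v_a * _sigma(c.q * (t - c.d_d))


class TestMetrics:
    def test_closed_form_d1_d2(self):
        c = PhenoCurve(0.1, 0.5, 0.12, 160.0, 0.1, 250.0, "full", 0.0, 46)
        m = derive_pheno_metrics(c, COMPOSITE_DOYS.astype(float))
        assert m.values["D_2"] == pytest.approx(160 + HALF_WIDTH_CONST / 0.12, abs=1e-9)
        assert m.values["D_1"] == pytest.approx(160 - HALF_WIDTH_CONST / 0.12, abs=1e-9)
        assert m.values["D_2"] == pytest.approx(170.97, abs=0.01)

    def test_closed_form_matches_numeric_oracle(self):
        """D_1..D_4 match finite-difference f'' extrema of the green-up and
        senescence logistic segments to well under 0.05 day."""
        c = PhenoCurve(0.12, 0.6, 0.09, 165.0, 0.07, 255.0, "full", 0.0, 46)
        m = derive_pheno_metrics(c, COMPOSITE_DOYS.astype(float))
        d1, d2 = numeric_second_derivative_extrema(rising_segment(c), c.d_i, c.p)
        d4, d3 = numeric_second_derivative_extrema(falling_segment(c), c.d_d, c.q)
        assert m.values["D_1"] == pytest.approx(d1, abs=0.05)
        assert m.values["D_2"] == pytest.approx(d2, abs=0.05)
        assert m.values["D_3"] == pytest.approx(d3, abs=0.05)
        assert m.values["D_4"] == pytest.approx(d4, abs=0.05)

    def test_symmetric_peak_at_midpoint(self):
        c = PhenoCurve(0.1, 0.5, 0.1, 160.0, 0.1, 250.0, "full", 0.0, 46)
        m = derive_pheno_metrics(c, COMPOSITE_DOYS.astype(float))
        assert m.values["D_peak"] == pytest.approx(205.0, abs=1e-3)

    def test_ordering_invariants(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p, q = rng.uniform(0.05, 0.3, 2)
            d_i = rng.uniform(130, 190)
            d_d = d_i + rng.uniform(40, 120)
            c = PhenoCurve(0.1, 0.5, p, d_i, q, d_d, "full", 0.0, 46)
            m = derive_pheno_metrics(c, COMPOSITE_DOYS.astype(float))
            v = m.values
            assert v["D_1"] < v["D_i"] < v["D_2"]
            assert v["D_3"] < v["D_d"] < v["D_4"]
            assert v["L_id"] == pytest.approx(d_d - d_i)
            assert v["L_14"] == pytest.approx(v["D_4"] - v["D_1"])
            assert v["D_i"] <= v["D_peak"] <= v["D_d"]

    def test_early_mode_has_seven_metrics_and_observed_peak(self):
        c = PhenoCurve(0.1, 0.5, 0.12, 160.0, None, None, "early", 0.0, 28)
        t = COMPOSITE_DOYS.astype(float)[:28]
        evi = np.linspace(0.1, 0.2, 28)
        evi[20] = 0.9  # DOY 161
        m = derive_pheno_metrics(c, t, evi)
        assert len(m.names) == 7
        assert m.values["D_peak"] == t[20]
        assert not m.available("q") and not m.available("D_d")

    def test_early_peak_tie_breaks_earlier(self):
        c = PhenoCurve(0.1, 0.5, 0.12, 160.0, None, None, "early", 0.0, 28)
        t = COMPOSITE_DOYS.astype(float)[:28]
        evi = np.zeros(28)
        evi[[10, 15]] = 0.8
        m = derive_pheno_metrics(c, t, evi)
        assert m.values["D_peak"] == t[10]

    def test_unfit_curve_rejected(self):
        c = PhenoCurve(np.nan, np.nan, np.nan, np.nan, None, None, "full",
                       np.nan, 3, success=False)
        with pytest.raises(ValueError):
            derive_pheno_metrics(c, COMPOSITE_DOYS.astype(float))
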