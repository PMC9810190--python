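import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.polynomial import Polynomial

from germcount import (
    QuinticFit,
    RefinementResult,
    find_threshold,
    fit_quintic,
    gaussian_smooth_histogram,
    red_histogram,
    refine,
)
from germcount.refine import gaussian_kernel


def bimodal_quintic(peak1, valley, peak2, far_root=400.0):
    """Quintic with maxima at peak1/peak2 and a minimum at valley.

    Built by integrating f'(x) = (x - peak1)(x - valley)(x - peak2)
    (x - far_root); with ``far_root`` beyond the last bin the
    derivative is positive before peak1, negative between peak1 and
    the valley, and so on, giving the max/min/max pattern on [0, 255].
    """
    base = Polynomial([1.0])
    for r in (peak1, valley, peak2, far_root):
        base *= Polynomial([-r, 1.0])
    poly = base.integ()
    coef = np.zeros(6)
    coef[: poly.coef.size] = poly.coef[:6]
    return QuinticFit(coef=coef)


class TestRedHistogram:
    def test_point_mass(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[..., 0] = 85
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2, :5] = True
        h = red_histogram(img, mask)
        assert h[85] == mask.sum() and h.sum() == mask.sum()

    def test_two_value_tally(self):
        img = np.zeros((1, 10, 3), dtype=np.uint8)
        img[0, :5, 0] = 85
        img[0, 5:, 0] = 234
        h = red_histogram(img, np.ones((1, 10), bool))
        assert h[85] == 5 and h[234] == 5 and h.sum() == 10

    def test_empty_mask_rejected(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            red_histogram(img, np.zeros((4, 4), bool))


class TestSmoothing:
    def test_uniform_is_fixed_point(self):
        h = np.full(256, 7.0)
        assert np.allclose(gaussian_smooth_histogram(h), h)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 10_000), min_size=256, max_size=256))
    def test_mass_conserved(self, counts):
        h = np.array(counts, dtype=float)
        if h.sum() == 0:
            return
        out = gaussian_smooth_histogram(h)
        assert out.min() >= -1e-9
        assert abs(out.sum() - h.sum()) <= 1e-6 * h.sum()

    def test_delta_becomes_centred_kernel(self):
        h = np.zeros(256)
        h[128] = 1.0
        out = gaussian_smooth_histogram(h)
        k = gaussian_kernel(100, 7.5)
        assert np.allclose(out[128 - 50 : 128 + 51], k, atol=1e-12)
        assert out.argmax() == 128


class TestQuinticFit:
    def test_recovers_exact_quintic(self):
        coef = np.array([120.0, -3.0, 0.05, -4e-4, 1.2e-6, -1.5e-9])
        x = np.arange(256)
        h = np.polynomial.polynomial.polyval(x, coef)
        fit = fit_quintic(h)
        assert np.allclose(fit.coef, coef, rtol=1e-6, atol=1e-10)

    def test_constant_histogram(self):
        fit = fit_quintic(np.full(256, 42.0))
        assert np.allclose(fit(np.arange(256)), 42.0, atol=1e-8)

    def test_nested_model_residual(self, rng):
        """The quintic residual never exceeds the best quartic's."""
        h = rng.random(256) * 100
        x = np.arange(256, dtype=float)
        quintic = fit_quintic(h)
        quartic = Polynomial.fit(x, h, deg=4).convert()
        r5 = ((quintic(x) - h) ** 2).sum()
        r4 = ((quartic(x) - h) ** 2).sum()
        assert r5 <= r4 + 1e-6 * abs(r4)


class TestFindThreshold:
    def test_valley_between_stated_peaks(self):
        fit = bimodal_quintic(85.0, 150.0, 234.0)
        res = find_threshold(fit)
        assert res.threshold_d is not None
        assert res.peak_a < res.valley_c < res.peak_b
        assert 85 < res.valley_c < 234

    def test_monotone_curve_yields_no_threshold(self):
        fit = QuinticFit(coef=np.array([0.0, 1.0, 0, 0, 0, 0]))  # f(x) = x
        assert find_threshold(fit).threshold_d is None

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        p1 = float(rng.integers(30, 100))
        p2 = float(rng.integers(150, 230))
        v = float(rng.integers(int(p1) + 20, int(p2) - 20))
        fit = bimodal_quintic(p1, v, p2, far_root=float(rng.integers(300, 900)))
        res = find_threshold(fit)
        # independent exhaustive scan over integer bins
        y = fit(np.arange(256))
        maxima = [i for i in range(1, 255) if y[i] > y[i - 1] and y[i] > y[i + 1]]
        top = sorted(sorted(maxima, key=lambda i: y[i])[-2:])
        lo, hi = top
        valley = min(range(lo + 1, hi), key=lambda i: y[i])
        assert res.valley_c == valley


class TestRefine:
    def test_zero_threshold_is_noop(self, rng):
        img = rng.integers(0, 256, size=(6, 6, 3), dtype=np.uint8)
        mask = rng.random((6, 6)) > 0.5
        out = refine(img, mask, RefinementResult(threshold_d=0))
        assert np.array_equal(out, mask)

    def test_saturating_threshold_empties_mask(self):
        img = np.zeros((5, 5, 3), dtype=np.uint8)
        img[..., 0] = 100
        out = refine(img, np.ones((5, 5), bool), RefinementResult(threshold_d=255))
        assert not out.any()

    def test_anti_extensive(self, rng):
        img = rng.integers(0, 256, size=(20, 20, 3), dtype=np.uint8)
        mask = rng.random((20, 20)) > 0.4
        for d in (None, 0, 80, 200, 255):
            out = refine(img, mask, RefinementResult(threshold_d=d))
            assert not (out & ~mask).any()

    def test_shadow_border_removed_core_kept(self, small_scene):
        """On a synthetic scene the refined mask equals the true grain cores."""
        from germcount import run_pipeline

        _, img, truth = small_scene
        result = run_pipeline(img)
        assert result.refinement.threshold_d is not None
        assert np.array_equal(result.grain_mask, truth.grain_label_image > 0)
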