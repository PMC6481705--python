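import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from talbotct.stepping import (
    Coefficients,
    extract_coefficients,
    reference_for_angle,
    roi_visibility,
    signals,
    visibility_map,
    wrap,
)


def make_curve(a0, a1, phi, n=7, m=2, shape=()):
    j = np.arange(n).reshape(-1, *([1] * len(shape)))
    return a0 + a1 * np.cos(2 * math.pi * m * j / n + phi) * np.ones((n, *shape))


def lstsq_oracle(curve, n_periods):
    """Brute-force least squares of a0 + a1*cos(wj + phi) via normal equations."""
    n = curve.shape[0]
    j = np.arange(n)
    w = 2 * math.pi * n_periods * j / n
    design = np.stack([np.ones(n), np.cos(w), np.sin(w)], axis=1)
    beta, *_ = np.linalg.lstsq(design, curve, rcond=None)
    a0, c_cos, c_sin = beta
    return a0, math.hypot(c_cos, c_sin), math.atan2(-c_sin, c_cos)


class TestWrap:
    @given(x=st.floats(min_value=-50, max_value=50, allow_nan=False))
    @settings(derandomize=True, max_examples=100)
    def test_range_and_idempotence(self, x):
        w = float(wrap(x))
        assert -math.pi < w <= math.pi
        assert float(wrap(w)) == pytest.approx(w, abs=1e-12)
        # wrapping preserves the phase modulo 2*pi
        assert math.cos(w) == pytest.approx(math.cos(x), abs=1e-9)
        assert math.sin(w) == pytest.approx(math.sin(x), abs=1e-9)

    def test_boundary_maps_to_plus_pi(self):
        assert float(wrap(math.pi)) == pytest.approx(math.pi)
        assert float(wrap(-math.pi)) == pytest.approx(math.pi)


class TestExtraction:
    def test_known_sinusoid_machine_precision(self):
        curve = make_curve(100.0, 25.0, 0.7)
        c = extract_coefficients(curve, 2)
        assert float(c.a0) == pytest.approx(100.0, abs=1e-12)
        assert float(c.a1) == pytest.approx(25.0, abs=1e-12)
        assert float(c.phi) == pytest.approx(0.7, abs=1e-13)

    def test_constant_series_has_no_fringe(self):
        c = extract_coefficients(np.full((7, 3, 3), 42.0), 2)
        assert np.allclose(c.a1, 0.0, atol=1e-12)
        assert c.valid.all()

    def test_zero_mean_pixels_flagged(self):
        frames = np.zeros((7, 2, 2))
        c = extract_coefficients(frames, 2)
        assert not c.valid.any()

    @given(
        a0=st.floats(min_value=1.0, max_value=1e5),
        ratio=st.floats(min_value=0.0, max_value=1.0),
        phi=st.floats(min_value=-3.1, max_value=3.1),
        n=st.sampled_from([3, 4, 5, 7, 11]),
    )
    @settings(derandomize=True, max_examples=100)
    def test_exact_retrieval_property(self, a0, ratio, phi, n):
        m = 2 if math.gcd(2, n) == 1 else 1
        curve = make_curve(a0, ratio * a0, phi, n=n, m=m)
        c = extract_coefficients(curve, m)
        assert float(c.a0) == pytest.approx(a0, rel=1e-10)
        assert float(c.a1) == pytest.approx(ratio * a0, rel=1e-9, abs=1e-8 * a0)
        if ratio * a0 > 1e-6 * a0:
            assert math.cos(float(c.phi) - phi) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_least_squares_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a0 = rng.uniform(10, 1e4)
            a1 = rng.uniform(0, a0)
            phi = rng.uniform(-math.pi, math.pi)
            curve = make_curve(a0, a1, phi)
            c = extract_coefficients(curve, 2)
            o_a0, o_a1, o_phi = lstsq_oracle(curve.ravel(), 2)
            assert float(c.a0) == pytest.approx(o_a0, rel=1e-10)
            assert float(c.a1) == pytest.approx(o_a1, rel=1e-10, abs=1e-10)
            assert float(wrap(c.phi - o_phi)) == pytest.approx(0.0, abs=1e-10)

    def test_aliasing_period_count_rejected(self):
        with pytest.raises(ValueError, match="coprime"):
            extract_coefficients(np.ones((6, 2, 2)), 2)


class TestVisibility:
    def test_ratio_definition_and_flux_invariance(self):
        curve = make_curve(200.0, 50.0, 0.3, shape=(4, 4))
        c1 = extract_coefficients(curve, 2)
        c2 = extract_coefficients(10 * curve, 2)
        v1 = visibility_map(c1.a0, c1.a1)
        v2 = visibility_map(c2.a0, c2.a1)
        assert np.allclose(v1, 0.25, atol=1e-12)
        assert np.allclose(v1, v2, atol=1e-12)

    def test_zero_amplitude_gives_zero(self):
        v = visibility_map(np.ones((3, 3)), np.zeros((3, 3)))
        assert np.all(v == 0)

    def test_roi_must_fit(self):
        with pytest.raises(ValueError, match="ROI"):
            roi_visibility(np.ones((10, 10)), 30, 30)

    def test_configured_visibility_recovered(self, disc_scan):
        ref = disc_scan.references[0]
        c = extract_coefficients(ref.frames - 2.0, disc_scan.manifest["n_periods"])
        v = visibility_map(c.a0, c.a1)
        mean, sd = roi_visibility(v, 30, 30)
        assert abs(mean - 0.256) <= 3 * sd


class TestSignals:
    def test_identical_sample_and_reference(self):
        curve = make_curve(120.0, 30.0, 0.4, shape=(5, 5))
        c = extract_coefficients(curve, 2)
        maps = signals(c, c)
        assert np.allclose(maps.transmission, 1.0, atol=1e-12)
        assert np.allclose(maps.dphase, 0.0, atol=1e-12)
        assert np.allclose(maps.darkfield, 1.0, atol=1e-12)

    def test_injected_phase_patch_recovered(self):
        rng = np.random.default_rng(1)
        shape = (20, 20)
        phi_r = np.full(shape, 0.2)
        dphi = np.zeros(shape)
        dphi[5:15, 5:15] = 0.3
        n, m = 7, 2
        j = np.arange(n).reshape(-1, 1, 1)
        i0, v0 = 1e4, 0.25
        ref = rng.poisson(i0 * (1 + v0 * np.cos(2 * math.pi * m * j / n + phi_r)))
        sam = rng.poisson(i0 * (1 + v0 * np.cos(2 * math.pi * m * j / n + phi_r + dphi)))
        maps = signals(extract_coefficients(sam.astype(float), m),
                       extract_coefficients(ref.astype(float), m))
        sigma = math.sqrt(2.0 / (n * i0 * v0**2)) * math.sqrt(2)  # both series noisy
        patch = maps.dphase[6:14, 6:14].mean()
        assert patch == pytest.approx(0.3, abs=4 * sigma / 8)

    def test_phase_bias_below_standard_error(self):
        # Poisson retrieval at V = 0.25, 1e4 counts: bias << statistical error
        rng = np.random.default_rng(9)
        n, m, i0, v0, dphi = 7, 2, 1e4, 0.25, 0.15
        j = np.arange(n)
        lam = i0 * (1 + v0 * np.cos(2 * math.pi * m * j / n + dphi))
        draws = rng.poisson(np.tile(lam, (1000, 1))).astype(float)
        c = extract_coefficients(draws.T, m)
        est = np.array([float(wrap(p)) for p in np.atleast_1d(c.phi)])
        bias = est.mean() - dphi
        assert abs(bias) < 3 * est.std(ddof=1) / math.sqrt(len(est))


class TestReferenceInterpolation:
    @staticmethod
    def coeffs_from(a0, a1, phi, shape=(4, 4)):
        curve = make_curve(a0, a1, phi, shape=shape)
        return extract_coefficients(curve, 2)

    def test_exact_checkpoint_returned(self):
        refs = {0: self.coeffs_from(100, 20, 0.1), 50: self.coeffs_from(100, 20, 0.5)}
        out = reference_for_angle(50, refs)
        assert out is refs[50]

    def test_identical_references_noop(self):
        refs = {0: self.coeffs_from(100, 20, 0.1), 50: self.coeffs_from(100, 20, 0.1)}
        out = reference_for_angle(25, refs)
        assert np.allclose(out.phi, refs[0].phi, atol=1e-12)
        assert np.allclose(out.a0, refs[0].a0, atol=1e-12)

    def test_linear_phase_drift_recovered(self):
        phi0, phi1 = 0.30, 0.40
        refs = {0: self.coeffs_from(100, 25, phi0), 50: self.coeffs_from(100, 25, phi1)}
        mid = reference_for_angle(25, refs)
        expected = (phi0 + phi1) / 2
        assert np.allclose(mid.phi, expected, rtol=0.01)

    def test_ends_use_nearest(self):
        refs = {10: self.coeffs_from(100, 20, 0.2), 60: self.coeffs_from(100, 20, 0.6)}
        assert np.allclose(reference_for_angle(0, refs).phi, 0.2)
        assert np.allclose(reference_for_angle(99, refs).phi, 0.6)

    def test_no_references_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            reference_for_angle(3, {})
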