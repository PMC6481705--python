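import math

import numpy as np
import pytest
from scipy import ndimage

from talbotct import InterferometerConfig
from talbotct.phantom import MATERIALS
from talbotct.recon import (
    ReconVolume,
    Sinogram,
    detrend_air,
    dphase_to_derivative,
    fbp_hilbert,
    fbp_ramp,
    median_prefilter,
    reconstruct_volume,
    rho_e_from_delta,
)
from tests.conftest import disc_region_median

PITCH = 1e-4


def disc_projection(n, radius, value):
    c = (n - 1) / 2.0
    xs = (np.arange(n) - c) * PITCH
    return value * 2 * np.sqrt(np.clip(radius**2 - xs**2, 0, None))


def fov_mask(n, fraction=0.48):
    c = (n - 1) / 2.0
    xs = np.arange(n) - c
    yy, xx = np.meshgrid(xs, xs, indexing="ij")
    return np.sqrt(yy**2 + xx**2) < fraction * n


class TestMedianFilter:
    def test_constant_unchanged(self):
        assert np.array_equal(median_prefilter(np.full((8, 8), 3.0)), np.full((8, 8), 3.0))

    def test_hot_pixel_removed(self):
        frame = np.full((9, 9), 5.0)
        frame[4, 4] = 1e6
        assert np.array_equal(median_prefilter(frame), np.full((9, 9), 5.0))

    def test_matches_brute_force_interior(self):
        rng = np.random.default_rng(2)
        frame = rng.random((32, 32))
        filtered = median_prefilter(frame)
        for _ in range(100):
            r, c = rng.integers(1, 31, size=2)
            assert filtered[r, c] == np.median(frame[r - 1 : r + 2, c - 1 : c + 2])


class TestRampFBP:
    def test_homogeneous_disc_recovered(self):
        n, mu, r = 128, 50.0, 3e-3
        angles = np.arange(600) * (2 * math.pi / 600)
        sino = Sinogram(np.tile(disc_projection(n, r, mu), (600, 1)),
                        "attenuation", angles, PITCH)
        rec = fbp_ramp(sino)
        c = (n - 1) / 2.0
        xs = (np.arange(n) - c) * PITCH
        yy, xx = np.meshgrid(xs, xs, indexing="ij")
        interior = np.sqrt(yy**2 + xx**2) < 0.7 * r
        assert rec[interior].mean() == pytest.approx(mu, rel=0.02)

    def test_zero_sinogram(self):
        angles = np.arange(16) * (2 * math.pi / 16)
        sino = Sinogram(np.zeros((16, 32)), "attenuation", angles, PITCH)
        assert np.all(fbp_ramp(sino) == 0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        angles = np.arange(32) * (2 * math.pi / 32)
        data = rng.random((32, 24))
        a = fbp_ramp(Sinogram(data, "attenuation", angles, PITCH))
        b = fbp_ramp(Sinogram(3 * data, "attenuation", angles, PITCH))
        assert np.allclose(b, 3 * a, atol=1e-9 * np.abs(a).max())

    def test_kind_mismatch_rejected(self):
        angles = np.arange(8) * (2 * math.pi / 8)
        with pytest.raises(ValueError, match="attenuation"):
            fbp_ramp(Sinogram(np.zeros((8, 8)), "dphase", angles, PITCH))


class TestPhaseConversion:
    def test_reference_arithmetic(self):
        cfg = InterferometerConfig()
        angles = np.arange(4) * (2 * math.pi / 4)
        sino = Sinogram(np.full((4, 8), 0.1), "dphase", angles, PITCH)
        g = dphase_to_derivative(sino, cfg)
        assert g.kind == "dphase-derivative"
        expected = 0.1 * 7e-6 / (2 * math.pi * 0.296) * (0.296 / 0.140)
        assert np.allclose(g.data, expected, rtol=1e-6)
        assert expected == pytest.approx(7.96e-7, rel=1e-3)

    def test_zero_phase_zero_derivative(self):
        cfg = InterferometerConfig()
        angles = np.arange(4) * (2 * math.pi / 4)
        g = dphase_to_derivative(Sinogram(np.zeros((4, 8)), "dphase", angles, PITCH), cfg)
        assert np.all(g.data == 0)

    def test_inverse_in_d2(self):
        angles = np.arange(4) * (2 * math.pi / 4)
        sino = Sinogram(np.full((4, 8), 0.1), "dphase", angles, PITCH)
        g1 = dphase_to_derivative(sino, InterferometerConfig())
        g2 = dphase_to_derivative(sino, InterferometerConfig(d2=2 * 0.296))
        assert np.allclose(g2.data, g1.data / 2, rtol=1e-12)


class TestHilbertFBP:
    def test_dual_route_oracle_smooth_phantom(self):
        # off-center smooth blob: derivative route vs integral route
        n, n_angles = 128, 400
        angles = np.arange(n_angles) * (2 * math.pi / n_angles)
        c = (n - 1) / 2.0
        xs = (np.arange(n) - c) * PITCH
        x0, y0, sig = 1.5e-3, -1.0e-3, 1.2e-3
        p = np.empty((n_angles, n))
        for a, th in enumerate(angles):
            s0 = x0 * math.cos(th) + y0 * math.sin(th)
            p[a] = np.exp(-((xs - s0) ** 2) / (2 * sig**2))
        g = np.gradient(p, PITCH, axis=-1)
        ra = fbp_ramp(Sinogram(p, "attenuation", angles, PITCH))
        hi = fbp_hilbert(Sinogram(g, "dphase-derivative", angles, PITCH))
        fov = fov_mask(n)
        contrast = ra.max() - ra.min()
        rmse = np.sqrt(((ra - hi)[fov] ** 2).mean())
        assert rmse < 0.01 * contrast
        # the blob lands at the right spot (rotation convention check)
        iy, ix = np.unravel_index(np.argmax(hi), hi.shape)
        assert (ix - c) * PITCH == pytest.approx(x0, abs=2 * PITCH)
        assert (iy - c) * PITCH == pytest.approx(y0, abs=2 * PITCH)

    def test_homogeneous_disc_delta(self):
        n, delta, r = 128, 2.4e-7, 3e-3
        angles = np.arange(600) * (2 * math.pi / 600)
        g = np.gradient(disc_projection(n, r, delta), PITCH)
        rec = fbp_hilbert(Sinogram(np.tile(g, (600, 1)), "dphase-derivative", angles, PITCH))
        c = (n - 1) / 2.0
        xs = (np.arange(n) - c) * PITCH
        yy, xx = np.meshgrid(xs, xs, indexing="ij")
        interior = np.sqrt(yy**2 + xx**2) < 0.7 * r
        assert rec[interior].mean() == pytest.approx(delta, rel=0.02)

    def test_zero_input(self):
        angles = np.arange(8) * (2 * math.pi / 8)
        rec = fbp_hilbert(Sinogram(np.zeros((8, 16)), "dphase-derivative", angles, PITCH))
        assert np.all(rec == 0)


class TestDensityConversion:
    def test_pp_density(self):
        lam = InterferometerConfig().wavelength
        assert rho_e_from_delta(2.4053e-7, lam) == pytest.approx(3.14e29, rel=1e-3)

    def test_round_trip(self):
        from talbotct.geometry import delta_from_rho_e

        lam = InterferometerConfig().wavelength
        rho = 4.01e29
        assert rho_e_from_delta(delta_from_rho_e(rho, lam), lam) == pytest.approx(
            rho, rel=1e-12
        )

    def test_linearity(self):
        lam = InterferometerConfig().wavelength
        assert rho_e_from_delta(2e-7, lam) == pytest.approx(2 * rho_e_from_delta(1e-7, lam))


class TestDetrend:
    def test_row_offsets_removed(self):
        rng = np.random.default_rng(1)
        base = np.zeros((5, 40))
        base[:, 15:25] = rng.random((5, 10))
        offsets = rng.random((5, 1))
        assert np.allclose(detrend_air(base + offsets), detrend_air(base), atol=1e-12)


class TestVolumeReconstruction:
    def test_disc_densities_within_two_percent(self, disc_rho_volume, disc_phantom):
        for name in ("PP", "PEEK", "PVC"):
            med = disc_region_median(disc_rho_volume.values, disc_phantom, name)
            assert med == pytest.approx(MATERIALS[name].rho_e, rel=0.02)

    def test_density_ordering(self, disc_rho_volume, disc_phantom):
        meds = [disc_region_median(disc_rho_volume.values, disc_phantom, n)
                for n in ("PP", "PEEK", "PVC")]
        assert meds[0] < meds[1] < meds[2]

    def test_modes_share_shape(self, disc_maps, config, disc_phantom, disc_rho_volume):
        mu_vol = reconstruct_volume(disc_maps, config, "absorption", disc_phantom.voxel_pitch)
        assert mu_vol.values.shape == disc_rho_volume.values.shape
        assert mu_vol.meaning == "mu"
        assert disc_rho_volume.meaning == "rho_e"

    def test_air_region_is_zero_after_normalization(self, disc_rho_volume, disc_phantom):
        n = disc_rho_volume.values.shape[-1]
        c = (n - 1) / 2.0
        xs = np.arange(n) - c
        yy, xx = np.meshgrid(xs, xs, indexing="ij")
        ring = (np.sqrt(yy**2 + xx**2) > 0.44 * n) & (np.sqrt(yy**2 + xx**2) < 0.495 * n)
        air_mean = disc_rho_volume.values[:, ring].mean()
        assert abs(air_mean) < 0.02 * MATERIALS["PP"].rho_e

    def test_missing_angles_reported(self, disc_maps, config, disc_phantom):
        with pytest.raises(ValueError, match="missing projection angles"):
            reconstruct_volume(disc_maps[:-5], config, "phase",
                               disc_phantom.voxel_pitch, expected_angles=200)

    def test_rotated_phantom_permutes_sinogram(self, config):
        # quarter-turn of the object == quarter-turn shift of the angle axis
        from talbotct.forward import project

        rng = np.random.default_rng(3)
        vol = np.zeros((1, 48, 48))
        vol[0, 14:30, 18:40] = rng.random((16, 22))
        n_angles = 8
        angles = np.arange(n_angles) * (2 * math.pi / n_angles)
        sino = np.stack([project(vol, a, PITCH)[0] for a in angles])
        rotated = np.rot90(vol, k=1, axes=(1, 2))  # +90 degrees about z
        sino_rot = np.stack([project(rotated, a, PITCH)[0] for a in angles])
        shift = n_angles // 4
        assert np.allclose(sino_rot, np.roll(sino, -shift, axis=0), atol=1e-2 * sino.max())
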