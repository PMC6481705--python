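"""Shared fixtures: one noisy disc-stack scan and one knee scan per session.

The simulations are deliberately desk-scale (sub-100-um voxels would be
overkill for testing signal recovery): 96^2-class grids, 200 angles, 7
steps, seeded Poisson noise.
"""

from __future__ import annotations

import numpy as np
import pytest

from talbotct import InterferometerConfig, ScanPlan, simulate_scan
from talbotct.phantom import build_disc_phantom, build_knee_phantom
from talbotct.recon import reconstruct_volume
from talbotct.stepping import extract_scan


@pytest.fixture(scope="session")
def config() -> InterferometerConfig:
    return InterferometerConfig()


@pytest.fixture(scope="session")
def disc_phantom():
    return build_disc_phantom(voxel_pitch=100e-6)


@pytest.fixture(scope="session")
def disc_scan(disc_phantom, config):
    plan = ScanPlan(n_angles=200, reference_interval=50, rng_seed=7, noise=True)
    return simulate_scan(disc_phantom, config, plan)


@pytest.fixture(scope="session")
def disc_maps(disc_scan):
    return extract_scan(disc_scan)


@pytest.fixture(scope="session")
def disc_rho_volume(disc_maps, config, disc_phantom):
    return reconstruct_volume(disc_maps, config, "phase", disc_phantom.voxel_pitch)


@pytest.fixture(scope="session")
def knee_phantom():
    return build_knee_phantom(n_z=20)


@pytest.fixture(scope="session")
def knee_run(knee_phantom, config):
    plan = ScanPlan(n_angles=200, reference_interval=50, rng_seed=11, noise=True)
    scan = simulate_scan(knee_phantom, config, plan)
    maps = extract_scan(scan)
    vols = {
        mode: reconstruct_volume(maps, config, mode, knee_phantom.voxel_pitch)
        for mode in ("phase", "absorption", "darkfield")
    }
    return {"scan": scan, "maps": maps, "volumes": vols}


def disc_region_median(volume: np.ndarray, phantom, name: str) -> float:
    """Median reconstructed value inside the eroded core of a disc."""
    from scipy import ndimage

    mask2d = ndimage.binary_erosion(phantom.mask(name).any(axis=0), iterations=3)
    zsel = phantom.mask(name).any(axis=(1, 2))
    return float(np.median(volume[zsel][:, mask2d]))
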