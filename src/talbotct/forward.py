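"""Synthetic instrument: projections, stepping-curve image formation, scans.

The forward model is parallel-beam: the cone geometry enters only through
the effective pixel size at the sample plane and through the d_o/d1
reduction of fringe-phase sensitivity for a sample upstream of G1 (which
the reconstruction later undoes with the d1/d_o renormalization).

For each projection angle the model computes line integrals of mu (->
transmission), of delta (-> refraction angle via the transverse
derivative) and of the dark-field extinction coefficient (-> visibility
reduction), then samples N stepping frames

    I_j = I0 * T * [1 + V0 * Df * cos(2*pi*M*j/N + phi_r + dphi)]

with Poisson counting noise.  Reference series use T = 1, Df = 1,
dphi = 0; dark frames contain only the detector dark level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import ndimage

from .geometry import InterferometerConfig
from .phantom import Phantom, delta_map, mu_map, scatter_map

__all__ = [
    "ScanPlan",
    "SteppingSeries",
    "ScanResult",
    "project",
    "refraction_projection",
    "stepping_images",
    "reference_phase_map",
    "simulate_scan",
    "reference_positions",
]


class ScanPlan(BaseModel):
    """Acquisition schedule: angles, stepping, reference cadence, seed.

    Defaults follow the tomographic protocol of the instrument: 600
    equi-angular projections over 360 degrees, 7 phase steps spanning two
    analyzer periods, reference (flat) and dark series every 50 angular
    positions.  Every stochastic draw flows from ``rng_seed``; the stream is
    split per series so partial re-runs are reproducible.
    """

    model_config = ConfigDict(frozen=True)

    n_angles: int = 600
    angular_range: float = 2.0 * math.pi
    n_steps: int = 7
    n_periods: int = 2
    exposure: float = 10.0
    reference_interval: int = 50
    rng_seed: int = 0
    dark_level: float = 2.0
    noise: bool = True

    @model_validator(mode="after")
    def _check(self) -> "ScanPlan":
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.reference_interval < 1:
            raise ValueError("reference_interval must be >= 1")
        if self.n_steps < 3:
            raise ValueError("n_steps must be >= 3")
        if math.gcd(self.n_periods, self.n_steps) != 1:
            raise ValueError("n_periods must be coprime with n_steps")
        if self.dark_level < 0:
            raise ValueError("dark_level must be >= 0")
        return self

    @property
    def angles(self) -> np.ndarray:
        """Equi-spaced projection angles (rad) over the angular range."""
        return np.arange(self.n_angles) * (self.angular_range / self.n_angles)


@dataclass
class SteppingSeries:
    """One phase-stepping acquisition: N frames at equidistant G2 positions."""

    frames: np.ndarray  # (N, rows, cols) counts
    angle: float
    kind: str  # sample | reference | dark
    step_positions: np.ndarray  # (N,) grating displacements in m
    angle_index: int = -1

    def __post_init__(self) -> None:
        if self.kind not in ("sample", "reference", "dark"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (N, rows, cols)")
        if np.any(self.frames < 0):
            raise ValueError("counts must be >= 0")


@dataclass
class ScanResult:
    """Ordered output of simulate_scan plus its manifest."""

    samples: list[SteppingSeries]
    references: list[SteppingSeries]
    darks: list[SteppingSeries]
    manifest: dict


def _inplane_rotation(n: int, angle: float, ndim: int) -> tuple[np.ndarray, np.ndarray]:
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, s], [-s, c]])
    center = (n - 1) / 2.0
    if ndim == 3:
        m = np.eye(3)
        m[1:, 1:] = rot
        offset = np.array([0.0, center, center]) - m @ np.array([0.0, center, center])
    else:
        m = rot
        offset = np.array([center, center]) - m @ np.array([center, center])
    return m, offset


def project(volume_grid: np.ndarray, angle: float, pitch: float) -> np.ndarray:
    """Parallel-beam line integrals of a (z, y, x) grid at one angle.

    Rays run perpendicular to the detector axis s; the detector rows are
    the z slices, columns the transverse coordinate s = x*cos + y*sin
    (angles measured counterclockwise from +x, distances from grid center).
    Returns an array of shape (n_z, n_x) in units of (field value) * m.
    A 2-D input is treated as a single slice and returns (n_x,).
    """
    vol = np.asarray(volume_grid, dtype=float)
    squeeze = vol.ndim == 2
    if squeeze:
        vol = vol[None]
    if vol.ndim != 3:
        raise ValueError("volume must be 2-D or 3-D")
    if vol.shape[1] != vol.shape[2]:
        raise ValueError("in-plane grid must be square (isotropic sampling)")
    m, offset = _inplane_rotation(vol.shape[1], angle, 3)
    rotated = ndimage.affine_transform(
        vol, m, offset=offset, order=1, mode="constant", cval=0.0
    )
    p = rotated.sum(axis=1) * pitch
    return p[0] if squeeze else p


def refraction_projection(
    delta_grid: np.ndarray, angle: float, pitch: float
) -> np.ndarray:
    """Refraction-angle image alpha = d/ds of the delta line integral (rad)."""
    p = project(delta_grid, angle, pitch)
    return np.gradient(p, pitch, axis=-1)


def reference_phase_map(shape: tuple[int, int], span: float = math.pi) -> np.ndarray:
    """Default reference fringe phase: a slow linear carrier across columns.

    A real interferometer never has a perfectly flat reference phase; a
    smooth carrier exercises the reference-subtraction path.
    """
    rows, cols = shape
    ramp = np.linspace(0.0, span, cols)
    return np.broadcast_to(ramp + 0.1, (rows, cols)).copy()


def stepping_images(
    t_img: np.ndarray,
    alpha_img: np.ndarray,
    darkfield_img: np.ndarray,
    config: InterferometerConfig,
    plan: ScanPlan,
    phase_ref: np.ndarray,
    rng: np.random.Generator | None,
    angle: float = 0.0,
    kind: str = "sample",
) -> SteppingSeries:
    """Form one stepping series from transmission/refraction/dark-field images.

    ``alpha_img`` is the effective fringe-level refraction angle: the fringe
    phase is dphi = 2*pi*d2*alpha/p2.  Reference series are produced by
    passing T = 1, Df = 1, alpha = 0.  ``rng=None`` gives noiseless frames.
    """
    t_img = np.asarray(t_img, dtype=float)
    alpha_img = np.asarray(alpha_img, dtype=float)
    darkfield_img = np.asarray(darkfield_img, dtype=float)
    if not (t_img.shape == alpha_img.shape == darkfield_img.shape == phase_ref.shape):
        raise ValueError("signal images and reference phase must share a shape")
    v_eff = config.visibility * darkfield_img
    if np.any(v_eff > 1.0 + 1e-12):
        raise ValueError("V0 * Df > 1 is unphysical")
    n, m_per = plan.n_steps, plan.n_periods
    dphi = alpha_img / config.phase_to_angle
    j = np.arange(n).reshape(-1, 1, 1)
    fringe = 1.0 + v_eff * np.cos(2.0 * math.pi * m_per * j / n + phase_ref + dphi)
    lam = config.flux_scale * t_img * fringe + plan.dark_level
    frames = rng.poisson(lam).astype(float) if rng is not None else lam
    steps = np.arange(n) * (m_per * config.p2 / n)
    return SteppingSeries(frames, angle, kind, steps, angle_index=-1)


def _dark_series(
    shape: tuple[int, int],
    plan: ScanPlan,
    config: InterferometerConfig,
    rng: np.random.Generator | None,
) -> SteppingSeries:
    lam = np.full((plan.n_steps, *shape), plan.dark_level)
    frames = rng.poisson(lam).astype(float) if rng is not None else lam
    steps = np.arange(plan.n_steps) * (plan.n_periods * config.p2 / plan.n_steps)
    return SteppingSeries(frames, 0.0, "dark", steps)


def reference_positions(n_angles: int, interval: int) -> list[int]:
    """Angle indices at which reference/dark series are acquired.

    References are taken before the first projection and after every
    ``interval`` projections, including a closing one after the last angle:
    positions 0, interval, 2*interval, ..., n_angles.
    """
    pos = list(range(0, n_angles, interval))
    if pos[-1] != n_angles:
        pos.append(n_angles)
    return pos


def simulate_scan(
    phantom: Phantom,
    config: InterferometerConfig,
    plan: ScanPlan,
) -> ScanResult:
    """Simulate a full tomographic stepping scan of a phantom.

    Per sample angle: line integrals of mu, delta and the dark-field
    extinction give T = exp(-int mu), Df = exp(-int eps) and the refraction
    angle alpha = d/ds int delta; the fringe-level angle is reduced by
    d_o/d1 (cone geometry, sample upstream of G1).  Reference and dark
    series are interleaved per ``plan.reference_interval``.  The per-series
    RNG stream is split from ``plan.rng_seed`` so any series can be
    regenerated independently.
    """
    wavelength = config.wavelength
    pitch = phantom.voxel_pitch
    dmap = delta_map(phantom, wavelength)
    mumap = mu_map(phantom)
    smap = scatter_map(phantom)
    shape = (phantom.shape[0], phantom.shape[2])
    phi_r = reference_phase_map(shape)
    cone = config.d_o / config.d1

    def series_rng(index: int) -> np.random.Generator | None:
        if not plan.noise:
            return None
        return np.random.default_rng(
            np.random.SeedSequence(entropy=plan.rng_seed, spawn_key=(index,))
        )

    ref_at = reference_positions(plan.n_angles, plan.reference_interval)
    samples: list[SteppingSeries] = []
    references: list[SteppingSeries] = []
    darks: list[SteppingSeries] = []
    records: list[dict] = []
    stream = 0
    ones = np.ones(shape)
    zeros = np.zeros(shape)

    def take_reference(position: int) -> None:
        nonlocal stream
        ref = stepping_images(
            ones, zeros, ones, config, plan, phi_r,
            series_rng(stream), angle=0.0, kind="reference",
        )
        ref.angle_index = position
        references.append(ref)
        records.append({"kind": "reference", "angle_index": position, "stream": stream})
        stream += 1
        dark = _dark_series(shape, plan, config, series_rng(stream))
        dark.angle_index = position
        darks.append(dark)
        records.append({"kind": "dark", "angle_index": position, "stream": stream})
        stream += 1

    angles = plan.angles
    for k, angle in enumerate(angles):
        if k in ref_at:
            take_reference(k)
        t_img = np.exp(-project(mumap, angle, pitch))
        df_img = np.exp(-project(smap, angle, pitch))
        alpha = refraction_projection(dmap, angle, pitch) * cone
        series = stepping_images(
            t_img, alpha, df_img, config, plan, phi_r,
            series_rng(stream), angle=angle, kind="sample",
        )
        series.angle_index = k
        samples.append(series)
        records.append(
            {"kind": "sample", "angle_index": k, "angle": float(angle), "stream": stream}
        )
        stream += 1
    if plan.n_angles in ref_at:
        take_reference(plan.n_angles)

    manifest = {
        "schema_version": 1,
        "n_angles": plan.n_angles,
        "n_steps": plan.n_steps,
        "n_periods": plan.n_periods,
        "reference_interval": plan.reference_interval,
        "reference_positions": ref_at,
        "rng_seed": plan.rng_seed,
        "noise": plan.noise,
        "voxel_pitch": pitch,
        "records": records,
        "counts": {
            "sample": len(samples),
            "reference": len(references),
            "dark": len(darks),
        },
    }
    return ScanResult(samples, references, darks, manifest)
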