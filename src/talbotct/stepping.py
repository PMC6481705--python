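"""Phase-stepping signal retrieval.

Each detector pixel sees a sinusoid over the N stepping frames,

    I_j = a0 + a1 * cos(2*pi*M*j/N + phi),      j = 0..N-1,

whose DFT at bin M gives the three signals exactly (it is the least-squares
fit for equidistant steps): mean intensity a0 (absorption), fringe phase
phi (refraction) and amplitude a1 (scattering).  Comparing a sample series
with a reference (flat) series yields transmission T = a0_s/a0_r,
differential phase dphi = wrap(phi_s - phi_r) and dark field
Df = (a1_s/a0_s)/(a1_r/a0_r) = V_s/V_r.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .forward import ScanResult, SteppingSeries

__all__ = [
    "Coefficients",
    "SignalMaps",
    "wrap",
    "extract_coefficients",
    "visibility_map",
    "roi_visibility",
    "signals",
    "reference_for_angle",
    "dark_correct",
    "extract_scan",
]

logger = logging.getLogger(__name__)


def wrap(phase: np.ndarray | float) -> np.ndarray | float:
    """Wrap any real phase into (-pi, pi]; idempotent."""
    return -np.mod(-np.asarray(phase) + math.pi, 2.0 * math.pi) + math.pi


@dataclass
class Coefficients:
    """Per-pixel stepping-curve fit: mean a0, amplitude a1, phase phi.

    ``c`` is the complex DFT bin (a1/2 * N * exp(-i*phi) up to convention);
    it is kept because references are interpolated in the complex plane.
    ``valid`` flags pixels where the fit is meaningful (a0 > 0).
    """

    a0: np.ndarray
    a1: np.ndarray
    phi: np.ndarray
    c: np.ndarray
    valid: np.ndarray


@dataclass
class SignalMaps:
    """Transmission, differential phase, dark field and visibility maps."""

    transmission: np.ndarray
    dphase: np.ndarray
    darkfield: np.ndarray
    visibility: np.ndarray
    a0: np.ndarray
    a1: np.ndarray
    valid: np.ndarray
    angle: float = 0.0
    angle_index: int = -1


def dark_correct(series: SteppingSeries, dark: SteppingSeries | None) -> np.ndarray:
    """Subtract the mean dark frame; negative residuals are clipped at 0."""
    frames = series.frames.astype(float)
    if dark is None:
        return frames
    corrected = frames - dark.frames.mean(axis=0)
    n_neg = int((corrected < 0).sum())
    if n_neg:
        logger.debug("dark correction clipped %d negative counts", n_neg)
    return np.clip(corrected, 0.0, None)


def extract_coefficients(
    frames: np.ndarray | SteppingSeries, n_periods: int
) -> Coefficients:
    """DFT retrieval of (a0, a1, phi) from a stepping series.

    For equidistant steps this equals the least-squares fit of
    a0 + a1*cos(2*pi*M*j/N + phi) exactly.  Pixels with a0 == 0 are flagged
    invalid rather than raising.
    """
    if isinstance(frames, SteppingSeries):
        frames = frames.frames
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    if n < 3:
        raise ValueError("need at least 3 steps")
    if math.gcd(n_periods, n) != 1:
        raise ValueError("n_periods must be coprime with the step count")
    j = np.arange(n).reshape(-1, *([1] * (frames.ndim - 1)))
    kernel = np.exp(-2j * math.pi * n_periods * j / n)
    c = (frames * kernel).sum(axis=0)
    a0 = frames.mean(axis=0)
    a1 = 2.0 / n * np.abs(c)
    phi = np.angle(c)
    valid = a0 > 0
    return Coefficients(a0=a0, a1=a1, phi=phi, c=c, valid=valid)


def visibility_map(a0: np.ndarray, a1: np.ndarray) -> np.ndarray:
    """Fringe visibility V = a1/a0 (0 where a0 == 0)."""
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    out = np.zeros_like(a0)
    np.divide(a1, a0, out=out, where=a0 > 0)
    return out


def roi_visibility(
    v: np.ndarray, roi_rows: int = 30, roi_cols: int = 30
) -> tuple[float, float]:
    """Mean and sd of visibility in a centered ROI (default 30 x 30 pixels)."""
    rows, cols = v.shape
    if roi_rows > rows or roi_cols > cols:
        raise ValueError(
            f"ROI {roi_rows}x{roi_cols} does not fit in frame {rows}x{cols}"
        )
    r0 = (rows - roi_rows) // 2
    c0 = (cols - roi_cols) // 2
    patch = v[r0 : r0 + roi_rows, c0 : c0 + roi_cols]
    return float(patch.mean()), float(patch.std(ddof=1))


def signals(
    sample: Coefficients, reference: Coefficients, df_clip_eps: float = 0.05
) -> SignalMaps:
    """Combine sample and reference coefficients into signal maps.

    T = a0_s/a0_r; dphi = wrap(phi_s - phi_r); Df = V_s/V_r clipped to
    [0, 1 + eps] (Poisson noise can push the visibility ratio slightly
    above 1; large excursions are logged).
    """
    if sample.a0.shape != reference.a0.shape:
        raise ValueError("sample and reference shapes differ")
    valid = sample.valid & reference.valid & (reference.a1 > 0)
    t = np.ones_like(sample.a0)
    np.divide(sample.a0, reference.a0, out=t, where=reference.valid)
    dphi = wrap(sample.phi - reference.phi)
    v_s = visibility_map(sample.a0, sample.a1)
    v_r = visibility_map(reference.a0, reference.a1)
    df = np.ones_like(v_s)
    np.divide(v_s, v_r, out=df, where=v_r > 0)
    n_clip = int((df > 1.0 + df_clip_eps).sum())
    if n_clip:
        logger.debug("dark-field ratio clipped at %d pixels", n_clip)
    df = np.clip(df, 0.0, 1.0 + df_clip_eps)
    return SignalMaps(
        transmission=t,
        dphase=np.where(valid, dphi, 0.0),
        darkfield=df,
        visibility=v_s,
        a0=sample.a0,
        a1=sample.a1,
        valid=valid,
    )


def reference_for_angle(
    angle_index: int,
    reference_coeffs: dict[int, Coefficients],
) -> Coefficients:
    """Reference coefficients at a sample angle, by complex interpolation.

    (a0, c) are interpolated linearly between the two bracketing reference
    acquisitions; the phase comes from the interpolated complex bin, which
    avoids branch cuts that interpolating wrapped phases directly would hit.
    Nearest reference is used beyond the ends.
    """
    if not reference_coeffs:
        raise ValueError("no reference series available")
    positions = sorted(reference_coeffs)
    if angle_index in reference_coeffs:
        return reference_coeffs[angle_index]
    lo = [p for p in positions if p < angle_index]
    hi = [p for p in positions if p > angle_index]
    if not lo:
        return reference_coeffs[positions[0]]
    if not hi:
        return reference_coeffs[positions[-1]]
    p0, p1 = lo[-1], hi[0]
    w = (angle_index - p0) / (p1 - p0)
    r0, r1 = reference_coeffs[p0], reference_coeffs[p1]
    a0 = (1 - w) * r0.a0 + w * r1.a0
    c = (1 - w) * r0.c + w * r1.c
    n_steps_factor = np.abs(c)
    a1 = 2.0 / _infer_n(r0) * n_steps_factor
    return Coefficients(
        a0=a0, a1=a1, phi=np.angle(c), c=c, valid=r0.valid & r1.valid
    )


def _infer_n(coeffs: Coefficients) -> float:
    # a1 = 2|c|/N  =>  N = 2|c|/a1; robust median over valid pixels
    ok = coeffs.valid & (coeffs.a1 > 0)
    if not ok.any():
        raise ValueError("cannot infer step count from degenerate coefficients")
    return float(np.median(2.0 * np.abs(coeffs.c[ok]) / coeffs.a1[ok]))


def extract_scan(scan: ScanResult, n_periods: int | None = None) -> list[SignalMaps]:
    """Retrieve signal maps for every sample series of a simulated scan.

    Dark frames are averaged per checkpoint and subtracted; references are
    interpolated between checkpoints in the complex plane.
    """
    if n_periods is None:
        n_periods = scan.manifest["n_periods"]
    darks = {d.angle_index: d for d in scan.darks}

    def nearest_dark(idx: int) -> SteppingSeries | None:
        if not darks:
            return None
        key = min(darks, key=lambda p: abs(p - idx))
        return darks[key]

    ref_coeffs = {
        r.angle_index: extract_coefficients(
            dark_correct(r, nearest_dark(r.angle_index)), n_periods
        )
        for r in scan.references
    }
    out: list[SignalMaps] = []
    for s in scan.samples:
        coeffs = extract_coefficients(dark_correct(s, nearest_dark(s.angle_index)), n_periods)
        ref = reference_for_angle(s.angle_index, ref_coeffs)
        maps = signals(coeffs, ref)
        maps.angle = s.angle
        maps.angle_index = s.angle_index
        out.append(maps)
    return out
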