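"""Interferometer and scan geometry arithmetic.

A symmetric double-grating (Talbot) interferometer consists of a pi-shift
phase grating G1 at distance ``d1`` from a micrometer-sized source and an
absorbing analyzer grating G2 a further ``d2`` downstream, placed at a
fractional Talbot distance where the interference fringe has maximum
contrast.  The sample sits between the source and G1 at distance ``d_o``;
the detector just behind G2.  Everything here is pure, deterministic
arithmetic on that geometry, internally in SI units (m, rad); photon energy
crosses the boundary in keV.
"""

from __future__ import annotations

import math
from functools import cached_property

from pydantic import BaseModel, ConfigDict, model_validator

from .constants import HC_EV_M, N_A, R_E

__all__ = [
    "InterferometerConfig",
    "wavelength_from_energy",
    "fractional_talbot_distance",
    "symmetric_setup",
    "effective_pixel",
    "renormalization_factor",
    "pi_shift_thickness",
    "min_refraction_angle",
    "delta_from_rho_e",
    "rho_e_from_mass_density",
]


def wavelength_from_energy(energy_kev: float) -> float:
    """X-ray wavelength (m) for a photon energy in keV, lambda = hc/E."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev} keV")
    return HC_EV_M / (energy_kev * 1e3)


def fractional_talbot_distance(p1: float, wavelength: float, order: int = 1) -> float:
    """Plane-wave fractional Talbot distance D_n = n * p1**2 / (8 * lambda).

    For a pi-shift phase grating the fringe period is p1/2 and the
    high-contrast planes sit at odd fractional orders n = 1, 3, 5, ...
    Even orders have no fringe and are rejected.
    """
    if p1 <= 0 or wavelength <= 0:
        raise ValueError("grating period and wavelength must be positive")
    if order < 1:
        raise ValueError(f"Talbot order must be >= 1, got {order}")
    if order % 2 == 0:
        raise ValueError(
            f"order {order} is even: a pi-shift grating has zero fringe "
            "contrast at even fractional Talbot orders; use an odd order"
        )
    return order * p1**2 / (8.0 * wavelength)


def symmetric_setup(talbot_distance: float) -> tuple[float, float]:
    """Symmetric spherical-wave geometry (d1 = d2) for a plane-wave distance D.

    With a point source the Talbot condition reads d1*d2/(d1+d2) = D; the
    symmetric solution is d1 = d2 = 2*D.
    """
    if talbot_distance <= 0:
        raise ValueError("Talbot distance must be positive")
    d = 2.0 * talbot_distance
    return d, d


def effective_pixel(detector_pixel: float, d_o: float, d_p: float) -> float:
    """Effective pixel size at the sample plane for cone-beam magnification.

    The source-sample distance ``d_o`` and sample-detector distance ``d_p``
    give magnification M = (d_o + d_p)/d_o, hence l = pixel / M.
    """
    if d_o <= 0:
        raise ValueError("source-sample distance must be positive")
    if d_p < 0:
        raise ValueError("sample-detector distance must be non-negative")
    return detector_pixel * d_o / (d_o + d_p)


def renormalization_factor(d1: float, d_o: float) -> float:
    """Cone-beam renormalization d1/d_o for differential-phase projections.

    A sample upstream of G1 sees its refraction-induced fringe shift reduced
    by d_o/d1 relative to the parallel-beam case; phase projections are
    multiplied by this factor before parallel-beam reconstruction.
    """
    if d_o <= 0:
        raise ValueError("source-sample distance must be positive")
    if d1 <= 0:
        raise ValueError("source-G1 distance must be positive")
    return d1 / d_o


def pi_shift_thickness(delta_material: float, wavelength: float) -> float:
    """Grating structure height t = lambda/(2*delta) giving a pi phase shift.

    The phase shift of a slab of thickness t is Phi = 2*pi*delta*t/lambda;
    setting Phi = pi yields t.
    """
    if delta_material <= 0:
        raise ValueError("refractive-index decrement must be positive")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    return wavelength / (2.0 * delta_material)


def min_refraction_angle(
    visibility: float, counts: float, p2: float, d2: float
) -> float:
    """Smallest detectable refraction angle (rad) of a stepping measurement.

    Standard phase-sensitivity scaling: the fringe-phase noise of a stepped
    sinusoid at visibility V and N_ph detected photons is sqrt(2)/(V*sqrt(N_ph)),
    which maps to an angle through the fringe-to-angle conversion p2/(2*pi*d2):

        alpha_min = p2/(2*pi*d2) * sqrt(2) / (V * sqrt(N_ph))

    The proportionality constant sqrt(2) is a convention; use this figure
    ordinally (to rank configurations), not as an absolute limit.
    """
    if not 0 < visibility <= 1:
        raise ValueError(f"visibility must be in (0, 1], got {visibility}")
    if counts <= 0:
        raise ValueError("counts must be positive")
    if p2 <= 0 or d2 <= 0:
        raise ValueError("p2 and d2 must be positive")
    return p2 / (2.0 * math.pi * d2) * math.sqrt(2.0) / (visibility * math.sqrt(counts))


def delta_from_rho_e(rho_e: float, wavelength: float) -> float:
    """Refractive-index decrement delta = r_e * lambda**2 * rho_e / (2*pi)."""
    return R_E * wavelength**2 * rho_e / (2.0 * math.pi)


def rho_e_from_mass_density(density_g_cm3: float, z: float, a: float) -> float:
    """Electron density (electrons/m^3) from bulk density and Z/A ratio."""
    return density_g_cm3 * 1e6 * N_A * z / a


class InterferometerConfig(BaseModel):
    """Full geometry, energy and stepping description of the instrument.

    All lengths in metres, energy in keV.  ``d_o`` is kept independent of
    ``d1``/``d2``: the source-to-detector distance implied by the scan table
    need not equal d1 + d2 exactly (G2 sits just in front of the detector).
    """

    model_config = ConfigDict(frozen=True)

    p1: float = 7e-6
    p2: float = 7e-6
    design_energy: float = 30.0
    talbot_order: int = 1
    d1: float = 0.296
    d2: float = 0.296
    d_o: float = 0.140
    d_p: float = 0.460
    detector_pixel: float = 100e-6
    n_steps: int = 7
    n_periods: int = 2
    focal_spot: float = 2.0e-6
    flux_scale: float = 1e4
    visibility: float = 0.256

    @model_validator(mode="after")
    def _check(self) -> "InterferometerConfig":
        for name in ("p1", "p2", "design_energy", "d1", "d2", "d_o", "d_p",
                     "detector_pixel", "flux_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 1e-7 <= self.p1 <= 1e-4:
            raise ValueError(
                f"p1 = {self.p1} m is outside the plausible grating-period "
                "range [0.1 um, 100 um]; check the unit suffix in the config"
            )
        if not 1e-7 <= self.p2 <= 1e-4:
            raise ValueError(
                f"p2 = {self.p2} m is outside the plausible grating-period "
                "range [0.1 um, 100 um]; check the unit suffix in the config"
            )
        if self.talbot_order < 1:
            raise ValueError("talbot_order must be >= 1")
        if self.n_steps < 3:
            raise ValueError("need at least 3 phase steps to fit (a0, a1, phi)")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if math.gcd(self.n_periods, self.n_steps) != 1:
            raise ValueError(
                f"n_periods = {self.n_periods} and n_steps = {self.n_steps} "
                "share a factor: the stepping DFT bin would alias"
            )
        if self.d_o > self.d1:
            raise ValueError(
                "d_o > d1: the sample must sit between the source and G1"
            )
        if not 0 < self.visibility <= 1:
            raise ValueError("visibility must be in (0, 1]")
        return self

    @cached_property
    def wavelength(self) -> float:
        """Design wavelength lambda = hc/E (m)."""
        return wavelength_from_energy(self.design_energy)

    @cached_property
    def effective_pixel(self) -> float:
        """Detector pixel demagnified to the sample plane (m)."""
        return effective_pixel(self.detector_pixel, self.d_o, self.d_p)

    @cached_property
    def renormalization(self) -> float:
        """Cone-beam renormalization factor d1/d_o."""
        return renormalization_factor(self.d1, self.d_o)

    @cached_property
    def phase_to_angle(self) -> float:
        """Fringe phase -> refraction angle conversion p2/(2*pi*d2) (rad/rad).

        The analyzer period p2 sets the scale regardless of how many periods
        the stepping scan spans.
        """
        return self.p2 / (2.0 * math.pi * self.d2)
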