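"""Material tables and voxelized phantoms.

Two phantoms mirror the instrument's validation objects: a stack of
polymer calibration discs (PP, PEEK, PVC; 6 mm diameter, 1 mm height each)
and a knee-like object (bone core, ~2 mm cartilage shell, formalin bath,
container wall, air).

Conventions: label grids are (z, y, x) with isotropic voxel pitch, voxel
centers at (i + 0.5) * pitch, rotation axis z; label 0 is always air.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import R_E
from .geometry import delta_from_rho_e

__all__ = [
    "Material",
    "Phantom",
    "MATERIALS",
    "build_disc_phantom",
    "build_knee_phantom",
    "delta_map",
    "mu_map",
    "scatter_map",
    "rho_e_from_delta_value",
]


@dataclass(frozen=True)
class Material:
    """Bulk optical properties of a phantom constituent at the design energy.

    rho_e: electron density (electrons/m^3); mu: linear attenuation (1/m);
    scatter_strength: dark-field extinction coefficient (1/m) — the rate at
    which unresolved sub-pixel structure destroys fringe visibility along the
    beam path.  Homogeneous materials have scatter_strength 0.
    """

    name: str
    rho_e: float
    mu: float
    scatter_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.rho_e < 0 or self.mu < 0 or self.scatter_strength < 0:
            raise ValueError(f"material {self.name!r}: properties must be >= 0")

    def delta(self, wavelength: float) -> float:
        """Refractive-index decrement at the given wavelength."""
        return delta_from_rho_e(self.rho_e, wavelength)


# Reference electron densities of the calibration discs are the
# monochromatic synchrotron values (electrons/m^3).  Attenuation defaults are
# representative monochromatic 30 keV values; the knee constituents use
# offset-free ground-truth densities for formalin/cartilage (the instrument's
# printed values carry a constant calibration offset, which the simulation
# injects separately).
MATERIALS: dict[str, Material] = {
    "air": Material("air", rho_e=3.6e26, mu=0.04),
    "PP": Material("PP", rho_e=3.14e29, mu=22.0),
    "PEEK": Material("PEEK", rho_e=4.01e29, mu=33.0),
    "PVC": Material("PVC", rho_e=4.12e29, mu=90.0),
    "formalin": Material("formalin", rho_e=3.50e29, mu=37.5),
    "cartilage": Material("cartilage", rho_e=3.70e29, mu=37.8),
    "bone": Material("bone", rho_e=5.6e29, mu=120.0, scatter_strength=300.0),
    "container": Material("container", rho_e=3.4e29, mu=30.0, scatter_strength=150.0),
}


@dataclass
class Phantom:
    """Labeled voxel grid plus per-label material properties."""

    label_grid: np.ndarray  # (z, y, x) integer labels
    materials: dict[int, Material]
    voxel_pitch: float

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid)
        if self.label_grid.ndim != 3:
            raise ValueError("label_grid must be 3-D (z, y, x)")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive")
        present = set(np.unique(self.label_grid).tolist())
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no material entry")
        if 0 not in self.materials:
            raise ValueError("label 0 (air) must be defined")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_grid.shape

    def labels_present(self) -> set[str]:
        return {
            self.materials[int(lab)].name for lab in np.unique(self.label_grid)
        }

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of all voxels belonging to the named material."""
        labs = [lab for lab, m in self.materials.items() if m.name == name]
        if not labs:
            raise KeyError(f"no material named {name!r}")
        return np.isin(self.label_grid, labs)


def _lookup(phantom: Phantom, attr: str, wavelength: float | None = None) -> np.ndarray:
    table = np.zeros(max(phantom.materials) + 1)
    for lab, mat in phantom.materials.items():
        table[lab] = mat.delta(wavelength) if attr == "delta" else getattr(mat, attr)
    return table[phantom.label_grid]


def delta_map(phantom: Phantom, wavelength: float) -> np.ndarray:
    """Ground-truth refractive-index decrement grid."""
    return _lookup(phantom, "delta", wavelength)


def mu_map(phantom: Phantom) -> np.ndarray:
    """Ground-truth linear attenuation grid (1/m)."""
    return _lookup(phantom, "mu")


def scatter_map(phantom: Phantom) -> np.ndarray:
    """Ground-truth dark-field extinction grid (1/m)."""
    return _lookup(phantom, "scatter_strength")


def rho_e_from_delta_value(delta: float, wavelength: float) -> float:
    """Invert delta = r_e*lambda^2*rho_e/(2*pi) for a scalar."""
    return 2.0 * math.pi * delta / (R_E * wavelength**2)


def _radial_grid(n: int, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    c = (n - 1) / 2.0
    y = (np.arange(n) - c) * pitch
    return np.meshgrid(y, y, indexing="ij")


def build_disc_phantom(
    disc_diameter: float = 6e-3,
    disc_height: float = 1e-3,
    materials: list[Material] | None = None,
    voxel_pitch: float = 50e-6,
    margin_xy: float | None = None,
    margin_z: int = 3,
    air_material: Material | None = None,
) -> Phantom:
    """Stack of coaxial material discs along z, centered in the grid.

    Defaults reproduce the PP/PEEK/PVC calibration stack: 6 mm diameter,
    1 mm per disc.  The transverse grid leaves an air margin around the
    discs so projections have clean air columns at the edges.
    """
    if materials is None:
        materials = [MATERIALS["PP"], MATERIALS["PEEK"], MATERIALS["PVC"]]
    if not materials:
        raise ValueError("need at least one disc material")
    if voxel_pitch > disc_diameter / 20:
        raise ValueError(
            f"voxel_pitch {voxel_pitch} too coarse: need <= disc_diameter/20 "
            f"= {disc_diameter / 20}"
        )
    if margin_xy is None:
        # generous air margin: the phase reconstruction anchors its DC level
        # on an outer air annulus, which must clear the edge ringing
        margin_xy = 0.3 * disc_diameter
    n_xy = int(math.ceil((disc_diameter + 2 * margin_xy) / voxel_pitch))
    slices_per_disc = max(1, round(disc_height / voxel_pitch))
    n_z = len(materials) * slices_per_disc + 2 * margin_z

    yy, xx = _radial_grid(n_xy, voxel_pitch)
    inside = yy**2 + xx**2 <= (disc_diameter / 2) ** 2

    grid = np.zeros((n_z, n_xy, n_xy), dtype=np.int16)
    mats: dict[int, Material] = {0: air_material or MATERIALS["air"]}
    for i, mat in enumerate(materials):
        lab = i + 1
        mats[lab] = mat
        z0 = margin_z + i * slices_per_disc
        grid[z0 : z0 + slices_per_disc][:, inside] = lab
    return Phantom(grid, mats, voxel_pitch)


def build_knee_phantom(
    bone_radius: float = 1.2e-3,
    cartilage_thickness: float = 2.0e-3,
    container_radius: float = 4.5e-3,
    voxel_pitch: float = 125e-6,
    wall_thickness: float = 0.4e-3,
    n_z: int = 20,
    margin_xy: float | None = None,
) -> Phantom:
    """Concentric knee-like phantom: bone core, cartilage shell, formalin
    annulus, container wall, air outside.

    The default cartilage shell is 2 mm thick, matching a tibial specimen
    with a preserved cartilage layer in a formalin-filled container.
    """
    if bone_radius + cartilage_thickness >= container_radius - wall_thickness:
        raise ValueError(
            "bone_radius + cartilage_thickness must leave room for formalin "
            "inside the container"
        )
    if margin_xy is None:
        margin_xy = 0.3 * container_radius
    n_xy = int(math.ceil(2 * (container_radius + margin_xy) / voxel_pitch))
    yy, xx = _radial_grid(n_xy, voxel_pitch)
    r = np.sqrt(yy**2 + xx**2)

    grid = np.zeros((n_z, n_xy, n_xy), dtype=np.int16)
    slice2d = np.zeros((n_xy, n_xy), dtype=np.int16)
    mats: dict[int, Material] = {0: MATERIALS["air"]}
    # labels: 1 container, 2 formalin, 3 cartilage, 4 bone
    mats[1] = MATERIALS["container"]
    mats[2] = MATERIALS["formalin"]
    mats[3] = MATERIALS["cartilage"]
    mats[4] = MATERIALS["bone"]
    slice2d[r <= container_radius] = 1
    slice2d[r <= container_radius - wall_thickness] = 2
    if cartilage_thickness > 0:
        slice2d[r <= bone_radius + cartilage_thickness] = 3
    slice2d[r <= bone_radius] = 4
    grid[:] = slice2d
    if cartilage_thickness <= 0:
        del mats[3]
    return Phantom(grid, mats, voxel_pitch)
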