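"""File formats, configuration and fixture generation.

HDF5 is the canonical interchange format (one bundle per stage, geometry in
attributes); TIFF import/export exists for human inspection.  The scan
manifest is plain JSON.  Configuration is TOML with unit-annotated key
names (``p1_um``, ``d1_mm``, ``energy_kev``); everything is converted to SI
on load and validated by the pydantic models.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .forward import ScanPlan, ScanResult, SteppingSeries
from .geometry import InterferometerConfig
from .stepping import SignalMaps

__all__ = [
    "read_frames",
    "write_frames",
    "load_config",
    "dump_config",
    "default_config_text",
    "config_hash",
    "save_scan",
    "load_scan",
    "save_signal_maps",
    "load_signal_maps",
    "save_volume",
    "load_volume",
    "make_fixtures",
]

# ---------------------------------------------------------------- frames

_TIFF_EXT = {".tif", ".tiff"}
_H5_EXT = {".h5", ".hdf5"}


def write_frames(path: str | Path, frames: np.ndarray) -> None:
    """Write a frame stack losslessly, dispatching on the file extension."""
    path = Path(path)
    frames = np.asarray(frames)
    if path.suffix.lower() in _TIFF_EXT:
        tifffile.imwrite(path, frames, photometric="minisblack")
    elif path.suffix.lower() in _H5_EXT:
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=frames)
    else:
        raise ValueError(f"unsupported frame format {path.suffix!r}")


def read_frames(path: str | Path) -> np.ndarray:
    """Read a frame stack written by :func:`write_frames`."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_EXT:
        return tifffile.imread(path)
    if path.suffix.lower() in _H5_EXT:
        with h5py.File(path, "r") as f:
            return f["frames"][()]
    raise ValueError(f"unsupported frame format {path.suffix!r}")


# ---------------------------------------------------------------- config

# key -> (model field, scale to SI)
_GEOMETRY_KEYS = {
    "p1_um": ("p1", 1e-6),
    "p2_um": ("p2", 1e-6),
    "energy_kev": ("design_energy", 1.0),
    "talbot_order": ("talbot_order", 1),
    "d1_mm": ("d1", 1e-3),
    "d2_mm": ("d2", 1e-3),
    "d_o_mm": ("d_o", 1e-3),
    "d_p_mm": ("d_p", 1e-3),
    "detector_pixel_um": ("detector_pixel", 1e-6),
    "n_steps": ("n_steps", 1),
    "n_periods": ("n_periods", 1),
    "focal_spot_um": ("focal_spot", 1e-6),
    "flux_scale": ("flux_scale", 1.0),
    "visibility": ("visibility", 1.0),
}

_SCAN_KEYS = {
    "n_angles": ("n_angles", 1),
    "angular_range_deg": ("angular_range", math.pi / 180.0),
    "n_steps": ("n_steps", 1),
    "n_periods": ("n_periods", 1),
    "exposure_s": ("exposure", 1.0),
    "reference_interval": ("reference_interval", 1),
    "rng_seed": ("rng_seed", 1),
    "dark_level": ("dark_level", 1.0),
    "noise": ("noise", None),
}


def _convert_section(section: dict, keymap: dict, name: str) -> dict:
    out = {}
    for key, value in section.items():
        if key not in keymap:
            raise ValueError(f"unknown key {key!r} in [{name}]")
        field, scale = keymap[key]
        if scale is None or isinstance(value, bool):
            out[field] = value
        elif isinstance(scale, int):
            out[field] = int(value) if scale == 1 and isinstance(value, int) else value * scale
        else:
            out[field] = value * scale
    return out


def load_config(path: str | Path) -> tuple[InterferometerConfig, ScanPlan]:
    """Load and validate a TOML configuration file.

    Unit-suffixed keys are converted to SI; unknown keys are rejected with
    the offending field path.
    """
    import tomllib

    with open(path, "rb") as f:
        raw = tomllib.load(f)
    unknown = set(raw) - {"geometry", "scan"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    geo = _convert_section(raw.get("geometry", {}), _GEOMETRY_KEYS, "geometry")
    scan = _convert_section(raw.get("scan", {}), _SCAN_KEYS, "scan")
    return InterferometerConfig(**geo), ScanPlan(**scan)


def dump_config(config: InterferometerConfig, plan: ScanPlan) -> str:
    """Serialize configuration back to unit-annotated TOML text."""

    def fmt(v) -> str:
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, int):
            return str(v)
        return repr(float(v))

    lines = ["[geometry]"]
    for key, (field, scale) in _GEOMETRY_KEYS.items():
        value = getattr(config, field)
        if isinstance(scale, float) and not isinstance(value, bool):
            value = value / scale
        lines.append(f"{key} = {fmt(value)}")
    lines.append("")
    lines.append("[scan]")
    for key, (field, scale) in _SCAN_KEYS.items():
        value = getattr(plan, field)
        if isinstance(scale, float) and not isinstance(value, bool):
            value = value / scale
        lines.append(f"{key} = {fmt(value)}")
    return "\n".join(lines) + "\n"


def default_config_text() -> str:
    """The shipped default: the instrument's phase-contrast scan geometry."""
    return dump_config(InterferometerConfig(), ScanPlan())


def config_hash(config: InterferometerConfig, plan: ScanPlan) -> str:
    """Stable hash identifying a configuration (carried by stage outputs)."""
    return hashlib.sha256(dump_config(config, plan).encode()).hexdigest()[:16]


# ---------------------------------------------------------------- scans

def save_scan(scan: ScanResult, out_dir: str | Path, tiff: bool = False) -> Path:
    """Write a simulated scan as an HDF5 bundle plus a JSON manifest.

    Series are stored under ``/sample/NNNN``, ``/reference/NNNN`` and
    ``/dark/NNNN`` groups; optional per-frame TIFF export for inspection.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h5path = out_dir / "scan.h5"
    with h5py.File(h5path, "w") as f:
        for kind, series_list in (
            ("sample", scan.samples),
            ("reference", scan.references),
            ("dark", scan.darks),
        ):
            grp = f.create_group(kind)
            for i, s in enumerate(series_list):
                g = grp.create_group(f"{i:04d}")
                g.create_dataset("frames", data=s.frames)
                g.create_dataset("step_positions", data=s.step_positions)
                g.attrs["angle"] = s.angle
                g.attrs["angle_index"] = s.angle_index
                g.attrs["kind"] = s.kind
                if tiff:
                    for j, frame in enumerate(s.frames):
                        tifffile.imwrite(
                            out_dir / f"{kind}_{i:04d}_step{j}.tif",
                            frame.astype(np.float32),
                        )
    (out_dir / "manifest.json").write_text(json.dumps(scan.manifest, indent=1))
    return h5path


def load_scan(in_dir: str | Path) -> ScanResult:
    """Read a scan bundle; ordering follows the manifest, not filenames."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    out: dict[str, list[SteppingSeries]] = {"sample": [], "reference": [], "dark": []}
    with h5py.File(in_dir / "scan.h5", "r") as f:
        for kind in out:
            grp = f[kind]
            for name in sorted(grp):
                g = grp[name]
                out[kind].append(
                    SteppingSeries(
                        frames=g["frames"][()],
                        angle=float(g.attrs["angle"]),
                        kind=str(g.attrs["kind"]),
                        step_positions=g["step_positions"][()],
                        angle_index=int(g.attrs["angle_index"]),
                    )
                )
    for kind in out:
        out[kind].sort(key=lambda s: s.angle_index)
    return ScanResult(out["sample"], out["reference"], out["dark"], manifest)


# ------------------------------------------------------------- signal maps

_MAP_FIELDS = ("transmission", "dphase", "darkfield", "visibility", "a0", "a1")


def save_signal_maps(maps: list[SignalMaps], path: str | Path, attrs: dict | None = None) -> None:
    maps = sorted(maps, key=lambda m: m.angle_index)
    with h5py.File(path, "w") as f:
        for name in _MAP_FIELDS:
            f.create_dataset(name, data=np.stack([getattr(m, name) for m in maps]))
        f.create_dataset("valid", data=np.stack([m.valid for m in maps]))
        f.create_dataset("angles", data=np.array([m.angle for m in maps]))
        f.create_dataset("angle_indices", data=np.array([m.angle_index for m in maps]))
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_signal_maps(path: str | Path) -> tuple[list[SignalMaps], dict]:
    with h5py.File(path, "r") as f:
        arrays = {name: f[name][()] for name in _MAP_FIELDS}
        valid = f["valid"][()]
        angles = f["angles"][()]
        indices = f["angle_indices"][()]
        attrs = dict(f.attrs)
    maps = [
        SignalMaps(
            **{name: arrays[name][i] for name in _MAP_FIELDS},
            valid=valid[i],
            angle=float(angles[i]),
            angle_index=int(indices[i]),
        )
        for i in range(len(angles))
    ]
    return maps, attrs


# ---------------------------------------------------------------- volumes

def save_volume(path: str | Path, values: np.ndarray, meaning: str, voxel_pitch: float,
                attrs: dict | None = None, tiff_dir: str | Path | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=values)
        f.attrs["meaning"] = meaning
        f.attrs["voxel_pitch"] = voxel_pitch
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
    if tiff_dir is not None:
        tiff_dir = Path(tiff_dir)
        tiff_dir.mkdir(parents=True, exist_ok=True)
        for i, sl in enumerate(values):
            tifffile.imwrite(tiff_dir / f"slice_{i:04d}.tif", sl.astype(np.float32))


def load_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        return f["values"][()], dict(f.attrs)


# ---------------------------------------------------------------- fixtures

def make_fixtures(size: str = "tiny", seed: int = 0, out_dir: str | Path | None = None):
    """Deterministic miniature scan for tests and demos.

    'tiny': 3-disc calibration stack on a small grid, 60 angles, references
    every 10; 'small': finer grid, 120 angles.  Returns (phantom, config,
    plan, scan) and writes a bundle when ``out_dir`` is given.
    """
    from .forward import simulate_scan
    from .phantom import build_disc_phantom

    if size == "tiny":
        pitch, n_angles, interval = 150e-6, 60, 10
    elif size == "small":
        pitch, n_angles, interval = 100e-6, 120, 20
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    phantom = build_disc_phantom(voxel_pitch=pitch, margin_z=2)
    config = InterferometerConfig()
    plan = ScanPlan(
        n_angles=n_angles, reference_interval=interval, rng_seed=seed
    )
    scan = simulate_scan(phantom, config, plan)
    if out_dir is not None:
        save_scan(scan, out_dir)
        (Path(out_dir) / "config.toml").write_text(dump_config(config, plan))
    return phantom, config, plan, scan
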