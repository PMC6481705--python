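# talbotct

Quantitative phase-contrast micro-CT with a symmetric X-ray double-grating
(Talbot) interferometer — simulation, signal retrieval, reconstruction and
image-quality analysis.

Laboratory micro-CT in absorption contrast barely distinguishes soft
tissues: cartilage, formalin and other low-Z materials attenuate 30 keV
X-rays almost identically. A grating interferometer added to such a system
measures instead the *refraction* of the beam, which is set by the real
part of the refractive index, n = 1 − δ, and hence by the electron density
ρ_e = 2π δ/(r_e λ²). This resolves soft-tissue interfaces (e.g. the
cartilage layer on a tibial bone core) that are invisible in attenuation,
at the price of coarser spatial resolution — the two modes are
complementary.

`talbotct` implements the full analysis chain for such an instrument, plus
a synthetic forward model of it, so every stage can be verified without
detector data:

- **geometry** — fractional Talbot distances D_n = n·p1²/(8λ) for a
  π-shift phase grating, the symmetric spherical-wave setup
  d1 = d2 = 2D solving d1·d2/(d1+d2) = D, effective pixel size, the
  cone-beam renormalization d1/d_o, π-shift grating heights t = λ/(2δ),
  and phase-sensitivity scaling.
- **phantom** — voxelized calibration disc stack (PP/PEEK/PVC, 6 mm
  diameter, 1 mm per disc) and a knee-like object (bone core, ~2 mm
  cartilage shell, formalin bath, container wall), with per-material
  electron density, attenuation and dark-field extinction.
- **forward** — parallel-beam line integrals, refraction angles
  α = ∂/∂s ∫δ dz, and phase-stepping image formation
  I_j = I0·T·[1 + V·Df·cos(2πMj/N + φ_r + Δφ)] with Poisson noise,
  interleaved reference/dark series on the acquisition schedule
  (600 angles/360°, 7 steps over two analyzer periods, checkpoints every
  50 angles by default).
- **stepping** — exact DFT retrieval of (a0, a1, φ) per pixel;
  transmission T, wrapped differential phase Δφ, dark field Df = V_s/V_r
  and visibility maps; complex-plane interpolation of references between
  checkpoints.
- **recon** — sinogram assembly, 3×3 median filtering, ramp-filtered
  back-projection for attenuation and the Hilbert-kernel
  (H(ν) = sgn(ν)/(2πi)) filtered back-projection for differential-phase
  data, cone-beam renormalization, air-anchored DC restoration, and the
  δ → ρ_e conversion.
- **quant** — Gaussian VOI statistics, CNR = |I_a − I_b|/σ_b, edge-based
  spatial resolution from the 10% crossing of the normalized MTF,
  multi-Gaussian histogram decomposition, and constant-offset
  electron-density calibration against reference materials.
- **io / cli** — TOML configuration with unit-annotated keys, HDF5/TIFF
  bundles, manifests, and the `talbotct` command
  (`simulate | extract | reconstruct | calibrate | metrics | run-all`).

## Worked example

Simulate a noisy tomographic scan of the calibration disc stack, retrieve
the stepping signals, reconstruct electron density through the Hilbert
kernel, and calibrate:

```python
import numpy as np
from scipy import ndimage
from talbotct import (
    InterferometerConfig, ScanPlan, simulate_scan, extract_scan,
    reconstruct_volume, build_disc_phantom, calibrate_offset,
)
from talbotct.phantom import MATERIALS

config = InterferometerConfig()          # the instrument's phase-scan geometry
print(f"lambda = {config.wavelength:.4e} m, "
      f"effective pixel = {config.effective_pixel*1e6:.1f} um, "
      f"d1/d_o = {config.renormalization:.2f}")

phantom = build_disc_phantom(voxel_pitch=100e-6)   # PP/PEEK/PVC stack
plan = ScanPlan(n_angles=200, reference_interval=50, rng_seed=7)
scan = simulate_scan(phantom, config, plan)
maps = extract_scan(scan)
volume = reconstruct_volume(maps, config, "phase", phantom.voxel_pitch)

reference = {n: MATERIALS[n].rho_e for n in ("PP", "PEEK", "PVC")}
measured = {}
for name in reference:
    core = ndimage.binary_erosion(phantom.mask(name).any(axis=0), iterations=3)
    zsel = phantom.mask(name).any(axis=(1, 2))
    measured[name] = float(np.median(volume.values[zsel][:, core]))
    print(f"{name}: recovered {measured[name]:.3e} e/m^3 "
          f"(reference {reference[name]:.3e})")

cal = calibrate_offset(measured, reference)
print(f"mean offset = {cal.mean_offset:.2e} +/- {cal.sd_offset:.2e} e/m^3; "
      f"max deviation after correction = {100*cal.max_relative_deviation:.2f}%")
```

Output:

```
lambda = 4.1328e-11 m, effective pixel = 23.3 um, d1/d_o = 2.11
PP: recovered 3.150e+29 e/m^3 (reference 3.140e+29)
PEEK: recovered 4.002e+29 e/m^3 (reference 4.010e+29)
PVC: recovered 4.128e+29 e/m^3 (reference 4.120e+29)
mean offset = 3.22e+26 +/- 1.01e+27 e/m^3; max deviation after correction = 0.29%
```

The recovered per-disc medians agree with the reference electron densities
to well under 1%; `calibrate_offset` subtracts the mean measured-minus-
reference offset (here negligible — a real instrument shows a constant
overestimation of order 10²⁸ e/m³, which the same call removes).

The same pipeline is available from the shell:

```sh
talbotct simulate    --config cfg.toml --out scan/
talbotct extract     --config cfg.toml --in scan/ --out signals.h5
talbotct reconstruct --config cfg.toml --signals signals.h5 --mode phase --out rho.h5
talbotct calibrate   --vol rho.h5 --vois vois.toml --out calibration.json
talbotct metrics     --vol rho.h5 --vois vois.toml --out report.json
```

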