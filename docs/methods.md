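# Methods

## The instrument model

A symmetric double-grating interferometer sits inside a cone-beam micro-CT
system: a π-shift phase grating G1 (period p1 = 7 µm, designed for 30 keV)
at d1 = 29.6 cm from a micrometer-sized transmission source, and an
absorbing analyzer grating G2 (period p2 = 7 µm) a further d2 = 29.6 cm
downstream, just in front of a 100 µm-pixel detector. The spacing is the
first fractional Talbot distance for spherical illumination:
the plane-wave distance is D_1 = p1²/(8λ) (the fringe of a π grating has
period p1/2, which shortens the classical Talbot distance by a factor 8),
and the spherical-wave condition d1·d2/(d1+d2) = D gives d1 = d2 = 2D for
the symmetric case. The sample sits at d_o = 14.0 cm, upstream of G1.

Everything is monochromatic at the design energy. The real instrument runs
a polychromatic tube spectrum; modeling it (and beam hardening) is out of
scope, so per-material attenuation coefficients are user-supplied values
at the design energy rather than spectrum-weighted averages.

Geometry enters the data chain in exactly three places:

* the **effective pixel** l = detector_pixel · d_o/(d_o + d_p) = 23.3 µm,
  which is the sampling pitch of every projection at the sample plane;
* the **fringe-to-angle conversion** p2/(2π d2), turning a measured fringe
  phase into a refraction angle;
* the **cone renormalization** d1/d_o = 2.11. A refracting sample upstream
  of G1 displaces the fringe less than in parallel geometry by d_o/d1, so
  the forward model attenuates the fringe phase by that factor and the
  reconstruction multiplies it back before back-projection.

The forward projector itself is parallel-beam. This mirrors the
reconstruction assumption (the instrument's own parallel-vs-cone
comparison found no practical difference at this geometry) and keeps the
simulated and reconstructed grids trivially aligned, which is why no
registration stage exists in the synthetic pipeline.

## Stepping-curve formation and retrieval

At each of N = 7 analyzer positions spanning M = 2 periods the detector
sees

    I_j = I0 · T · [1 + V0 · Df · cos(2πMj/N + φ_r + Δφ)] + dark,

with transmission T = exp(−∫µ), dark field Df = exp(−∫ε) (ε a
per-material extinction coefficient; zero for homogeneous materials, large
for bone and the container wall, reproducing the qualitative dark-field
contrast of structured tissue), fringe phase Δφ from the refraction angle,
a smooth reference carrier φ_r, and Poisson counting noise. N and M must
be coprime or the stepping DFT bin aliases; the configuration refuses such
combinations.

Retrieval takes the DFT bin M of the background-corrected stepping curve:
a0 = mean, a1 = (2/N)|c_M|, φ = arg c_M. For equidistant steps this *is*
the least-squares fit of a0 + a1·cos(2πMj/N + φ) — the test suite checks
equality against explicit normal equations — and is exact to machine
precision on noiseless curves. Signals follow as T = a0_s/a0_r,
Δφ = wrap(φ_s − φ_r) ∈ (−π, π], Df = (a1_s/a0_s)/(a1_r/a0_r).

References are acquired every `reference_interval` angles (plus a closing
checkpoint). Between checkpoints, (a0, c_M) are interpolated linearly *in
the complex plane*; interpolating wrapped phases directly would break at
the ±π branch cut. Since M·p2-stepping still samples the fringe of period
p2, all phase-to-angle conversions use p2, never M·p2. Mean dark frames
are subtracted before retrieval (negative residuals clipped at zero,
logged); pixels with a0 ≤ 0 are flagged and their sinogram bins linearly
inpainted along the detector axis.

## Reconstruction

Attenuation sinograms (−ln T) go through ramp-filtered back-projection;
differential-phase sinograms are converted to the transverse derivative of
the δ line integral, g = Δφ · p2/(2π d2) · d1/d_o, and filtered with the
Hilbert kernel H(ν) = sgn(ν)/(2πi) — exactly the ramp filter divided by
the 2πiν a derivative contributes, so both routes share one back-projector
and the π/n_angles weighting (correct for uniform coverage of either a
half or a full turn; 360° data are used as-is, not folded).

Numerical choices that matter:

* **Filter discretization.** Both kernels are built from their
  band-limited real-space samples (ramp: h[0] = 1/(4d²),
  h[odd n] = −1/(πnd)²; Hilbert: h[odd n] = 1/(π²nd)) and transformed,
  rather than sampling |ν| or sgn(ν) on the DFT grid. Direct frequency
  sampling biases the low-frequency response and shifts reconstructed
  means by a few percent; with the sampled kernels a homogeneous disc
  reconstructs to 0.1%. Projections are zero-padded to the next power of
  two ≥ 2× the column count to suppress circular convolution. An optional
  Hann apodization exists and is off by default.
* **Back-projection** uses linear interpolation; detector coordinates
  falling outside the measured row contribute zero (clamping to edge
  values visibly corrupts the periphery). Values are only trusted inside
  the inscribed circle, where angular coverage is complete.
* **DC restoration.** The derivative route cannot know the constant of
  each projection. Two anchors restore it: each derivative row is
  detrended by the mean of its outer 5% columns (assumed air), and the
  reconstructed slice is shifted so an air annulus just inside the
  inscribed circle (0.44–0.495 of the grid size in radius) averages zero.
  The annulus must clear both the object and its edge ringing — phantoms
  built by this package leave a ≥ 30% air margin for that reason.
* A 3×3 median filter (reflection boundaries) is available both on raw
  frames before retrieval and on reconstructed slices; the latter is on by
  default in `reconstruct_volume`.

Finally ρ_e = 2πδ/(r_e λ²) converts the phase volume to electron density.

## Quantification

* **VOI statistics** fit a single Gaussian to the VOI histogram
  (Freedman–Diaconis binning with a floor of 128 bins — fit stability
  depends on the floor) and fall back to sample moments when the fit fails.
* **CNR** = |I_a − I_b|/σ_b with the background VOI supplying σ; invariant
  under affine rescaling of the volume, so it can be computed on raw
  reconstruction values or calibrated densities alike.
* **Edge resolution.** The edge profile is smoothed with a span-5 moving
  average, differentiated, and Fourier-transformed into an MTF. The known
  responses of those two estimator steps (boxcar sinc and
  central-difference sinc) are divided out — otherwise the smoothing span,
  not the data, dominates the result — and the correction is only applied
  where that response exceeds 0.1; if the 10% crossing has not occurred by
  then, the resolution is reported as at/below the sampling limit. The
  crossing frequency f10 (linearly interpolated between bins) is converted
  to a length as SR = 1/(2·f10), a half-period criterion; the conversion
  convention is isolated in this one function.
* **Multi-Gaussian histograms** are fitted by nonlinear least squares with
  each component's center bounded to half the distance to its nearest
  neighbouring initial value; unbounded fits of overlapping components
  (formalin and cartilage differ by ~4σ here) collapse unpredictably. The
  initial centers are meant to come from VOI estimates, matching how such
  decompositions are seeded in practice.
* **Calibration** computes per-material offsets (measured − reference),
  their arithmetic mean ± sd, subtracts the mean voxelwise, and reports
  the maximal relative deviation after correction *against the reference
  table*. On the published laboratory/synchrotron disc densities this
  yields per-material offsets of (0.72, 0.86, 0.87)×10²⁹ e/m³, an
  arithmetic mean of 0.82×10²⁹ and a residual deviation of 3.1%; note the
  arithmetic mean differs slightly from the 0.86×10²⁹ quoted alongside
  those numbers, so both the per-material offsets and their mean are
  reported rather than forcing either summary.

## Synthetic-data defaults and what they do (not) show

The generator's defaults are the acquisition protocol of the instrument:
600 equi-angular projections over 360°, 7 steps over two analyzer
periods, references/darks every 50 angles, fringe visibility 0.256 (the
measured value at the 2.0 µm focal spot), and Poisson noise at a nominal
10⁴ counts/pixel. Disc-stack and knee phantoms default to the published
specimen dimensions (6 mm × 1 mm discs; ~2 mm cartilage shell). Test runs
scale the *problem size* down (96²-class grids, 100–150 µm voxels, 200
angles), never the physics; those sizes sit inside the acceptance
protocol's stated ranges and reconstruct per-disc densities to well under
the 2% criterion.

Ground-truth densities for formalin (3.50×10²⁹ e/m³) and cartilage
(3.70×10²⁹) are offset-free values; the published in-instrument numbers
(4.34/4.56×10²⁹) include the constant calibration offset, which the
simulation treats as a separate, injectable bias rather than a material
property.

The model deliberately omits: polychromatic spectra and beam hardening,
detector PSF/scintillator blur, grating imperfections and shadowing,
mechanical drift (references are stationary; the interpolation path is
exercised with synthetic drift in tests), phase wrapping beyond the
(−π, π] convention (the simulated geometry keeps |Δφ| < π; strongly
refracting edges at finer pitches would wrap), and cone-beam ray
divergence beyond the effective-pixel/renormalization treatment. Passing
tests therefore demonstrate the correctness of the *analysis chain* under
the stated image-formation model, not robustness to these instrument
non-idealities; real data additionally require registration between
modes, which is out of scope (synthetic volumes are aligned by
construction).

## RNG and reproducibility

All randomness flows from `ScanPlan.rng_seed` through a per-series
`SeedSequence` spawn, so any single stepping series can be regenerated
without replaying the scan. The CLI refuses to simulate without an
explicit seed, and every stage output carries the configuration hash;
stages abort on mismatched hashes instead of silently combining
incompatible data.
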