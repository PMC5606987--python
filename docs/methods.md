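# Methods

## Forward model (virtual microscope)

The simulator renders one detection-camera image per light-sheet
position from a 3D fluorophore-density grid (axes `(z, y, x)`, physical
units μm; `x` is the sheet propagation and modulation axis; `z` is the
axial stepping axis).

**Light-sheet geometry.** The sheet is a Gaussian beam: intensity FWHM
`w(d) = w_FWHM·sqrt(1 + (d/z_R)²)` at distance `d` from the waist, with
`w0 = w_FWHM/√(2 ln 2)` and Rayleigh length `z_R = π·n·w0²/λ`. The
waist sits at a configurable field position (`waist_x_um`), the peak
excitation amplitude falls as `w0/w(x)` (energy conservation within the
sheet), and an optional entrance-angle tilt displaces the sheet centre
linearly across `x`. Defaults (λ = 0.488 μm, FWHM 10–16 μm, n = 1.45)
give z_R ≈ 0.7–1.7 mm, the regime in which a single sweep covers a
millimetre-scale field.

**Structured excitation.** The patterned sweep multiplies the
excitation by `(1 + M·cos(2π x/period + φ))/2`. The ½ reflects the
instrument: a laser modulated between zero and full power delivers half
the average power of the uniform sweep, so at `M = 0` the structured
image is exactly half the uniform one, and `U − 2S = −M·cos(·)·U`
exactly — the algebra the HiLo demodulation relies on. Default period
16 μm (16 px at the default 1 μm pixel, i.e. 1/16 cycles/px).

**First-order defocus.** The detection focus needed for emission from
depth `z` is `Δz(z) = ∫₀ᶻ (n(z′) − n_imm) dz′`, evaluated by adaptive
quadrature honouring layer discontinuities (exact for homogeneous and
piecewise-constant profiles). This is the differential-index reading of
the "focal plane moves by about index × path length" rule: the absolute
product cannot vanish in matched media, so the difference against the
immersion index is the only self-consistent form. Index values are
restricted to [1.0, 1.6].

**Image formation.** Each z-slice of the specimen is weighted by the
sheet profile, multiplied by the pattern (structured sweep), blurred
laterally by a Gaussian of width `σ(m) = σ0·sqrt(1 + (m/DOF)²)` where
`m = applied_offset − Δz(z_slice)` is *that slice's* focal mismatch,
then summed along z. Blurring per slice (rather than once after
projection) is what makes out-of-focus haze lose its pattern contrast —
the mechanism HiLo exploits — and makes the focus metrics respond to
defocus the way real images do. Slices receiving < 10⁻⁴ of the peak
sheet weight are skipped. No diffraction PSF, scattering, shadow
stripes or photobleaching are modelled: first-order defocus is the only
aberration, which is the failure mode the method corrects.

**Noise.** Poisson noise on the expected counts followed by zero-mean
Gaussian read noise (default σ = 2 counts), both driven by one integer
seed; `seed=None` returns the noiseless expectation. Phantom
intensities (default ≈ 400 density units, giving mean plane signals of
~2000–3500 counts) put the Poisson-limited SNR near 50, comfortably
above the ≥ 10 regime in which the autofocus is specified to work.

## Phantoms

* **Beads** — hard ellipsoids (radius 2 μm) at uniform random positions;
  sparse, used for geometric checks.
* **Fibers** — random straight tracks with Gaussian cross-section,
  emulating myelinated fibers.
* **Foam** — Voronoi tessellation of seeded nuclei; voxels whose two
  nearest-nucleus distances differ by less than the wall thickness
  become fluorescent wall, the rest is air. The generator returns the
  exact boolean air mask — ground truth for intercept stereology. Cell
  density is set so the mean cell diameter equals the requested
  airspace size.
* **Slab foam** — deterministic alternating air/wall slabs; every
  interior chord equals the gap exactly (the hand-checkable oracle).

What the phantoms do *not* reproduce: real tissue's anisotropic,
multi-scale structure, absorption and scattering, and labeling
heterogeneity. Green tests therefore demonstrate algorithmic
correctness under the stated optics model, not performance on any
particular tissue.

## Focus metrics

* **Pattern frequency** — the structured image is summed along the
  non-modulated axis, mean-removed, and the largest non-DC DFT bin is
  refined by three-point parabolic interpolation of log-magnitude
  (error ≪ 1 bin for clean sinusoids at any period ≥ 4 px). The
  estimate carries a *prominence* (peak over median non-DC magnitude)
  used to distinguish a genuine lock from a noise peak. Callers that
  know the commanded frequency may restrict the peak search to a
  frequency band; the coarse autofocus uses ±25% of the commanded
  value, since dense specimens can have structural spectral peaks that
  out-power the modulation line.
* **SE-DCT** — 3×3 median filter (minimal shot-noise suppression), then
  the orthonormal type-II DCT; absolute coefficients are normalized to
  a probability vector and its Shannon entropy (bits) returned. Sharp
  images spread spectral energy and score high. Normalization makes the
  metric invariant to exposure scale, which cross-plane comparison
  needs. An optional radial coefficient cutoff is exposed but off by
  default.
* **Brightness** — plain mean intensity.

## Autofocus and calibration

Coarse stage: sweep candidate detection offsets, score each structured
image by the squared error of its measured pattern frequency against
the commanded one, keep candidates whose lock is genuine (prominence
≥ 5, error below half a DFT bin when gating is requested), pick the
minimum; ties go to the smallest |offset| (least actuation). Fine
stage: sweep ±30 μm at 3 μm around the coarse pick and maximize SE-DCT
of the uniform image; if the maximum lands on a window edge the window
re-centres there and repeats (≤ 3 times) — the coarse frequency-MSE
valley is ~±30 μm wide because the pattern survives mild defocus, so
the fine stage must be able to climb out of a coarse pick at the valley
rim.

Calibration visits 4–10 (configurable) sheet positions, coarse-centred
on a linear extrapolation of the points already found (the software
stand-in for the operator's "user-specified estimate"); a failed lock
doubles the coarse window up to 32×. Each surviving point also records
excitation-lens (ETL-1) sweep limits: during a sweep of the excitation
waist across the field, the three summed pixel columns at far left,
centre and far right identify the sweep values that park the waist at
each field edge. This edge-maximization rule is one interpretation of
an under-specified instrument procedure and is only meaningful when
the Rayleigh length is comparable to the field width. Positions that
never lock are excluded; at least two must survive.

Between calibration points the focus offset and ETL-1 limits are
piecewise-linearly interpolated (evaluated lazily per query; queries
beyond the ends clamp). The scan modes differ only in the offset
policy: the calibrated scan follows the interpolation; the standard
scan holds one constant offset, so its residual defocus grows as
`(n − n_imm)·depth` in homogeneous mismatch.

## HiLo reconstruction

`D = |U − 2S|` isolates patterned (in-focus) content; the fusion is
`I = η·G(D) + (U − G(U))` with a single Gaussian kernel `G` whose
transfer is ½ at the cutoff frequency (`σ = √(2 ln 2)/(2π f_c)`), so
the high-pass is the exact complement of the low-pass and `I → U`
whenever `η·G(D) = G(U)`. Default cutoff: half the modulation
frequency. Borders are handled by reflective padding; identity checks
use interior norms. With `M = 1`, `η = π/2` and a smooth in-focus
scene, `G(D) ≈ (2/π)·G(U)` (mean of |cos|), giving the flat-field
identity `I ≈ U`; on the default 16 px pattern the residual interior
error is ≈ 1.3%, dominated by the discrete sampling of |cos| (the
identity is asymptotic in pattern period and in cutoff/frequency
ratio).

**Automatic η.** `auto_eta` reconstructs a stack subset over a log grid
of candidates (default 16 values in [π/16, 4π]) and returns the argmax
of the product of min-max-normalized mean SE-DCT and mean brightness,
ties to the smaller η; the per-candidate metrics are exposed for audit.
A caveat measured on this simulator and documented deliberately:
brightness of the unclamped reconstruction is exactly linear in η and
SE-DCT decreases monotonically with η, so the product's argmax is
governed largely by the candidate-grid geometry rather than by the
modulation depth; the theoretical η = π/(2M) remains the recommended
default (`HiLoParams.for_pair`), and the automatic selection should be
treated as a heuristic for manual review, not an estimator of M.

## Quantification

**Mean linear intercept.** Sample lines run along the requested axes on
a lattice with configurable spacing and offset. A chord is a maximal
run of air voxels lying wholly inside the analysis region and bounded
at both ends by in-region tissue; runs touching the image or region
border are censored (uncensored-chords-only, the conservative
convention). L_m is the pooled chord mean, reported with SD, chord and
line counts, and per-axis sub-results for anisotropy inspection. The 3D
variant uses the three axis-aligned line families; oblique families are
not included. Oracles: slab gap exactly; sphere of radius R → 4R/3
(within 2% at R = 20 voxels, spacing 1); disk → πR/2 in 2D.

**Cell counting.** Background (Gaussian, σ default ≈ 10× a cell
diameter) is subtracted, pixels above the user threshold are labelled
with full connectivity (8 in 2D, 26 in 3D), and objects within the
single-cell size window count as one cell. Objects above the window
count as `round(size / median in-range size)` — the multi-cellular
correction; objects below it are debris. If only oversize objects
exist the single-cell size cannot be estimated and the call errors.

## I/O and tiling

Stacks are multi-page TIFF (uint16 for counts, float32 for noiseless
ground truth) with a flat `key=value` sidecar (`*.meta.txt`) holding
voxel geometry, modulation period, seed and scan mode. Tiled
acquisitions use the classic two-level stitching hierarchy
`V/V_H/V_H_D.tif` with coordinates in tenths of μm, zero-padded to six
digits, derived from the tile size and overlap fraction (20–30%
typical); a validator checks the naming convention, nesting consistency
and coordinate monotonicity. Every CLI run writes a provenance sidecar
(command, package version, parameters, seed) sufficient to regenerate
its outputs.

## Problem sizes and numerical choices

The validation suite runs the full calibration at 21 positions over a
3 mm, 201×96×96-voxel foam (15 μm axial voxels) and 21-plane paired
scans — sizes chosen so every stage exercises its real logic while a
complete run stays interactive on one CPU. Tie-breaks are always
deterministic (smallest |offset|, then smallest offset; smaller η).
Degenerate inputs have defined behaviour: all-zero images give SE-DCT
0; constant profiles raise a no-modulation error; uniform ETL-1 sweeps
warn and return equal limits; empty regions and chord-free masks raise.
Seeds: one integer per acquisition drives Poisson and read noise
jointly; compound procedures derive per-exposure seeds from their
single seed argument.

## Known limitations

* The defocus model is first-order only; no depth-dependent PSF shape,
  spherical aberration or scattering.
* The ETL-1 limit rule and the automatic-η scalarization implement
  under-specified instrument procedures; both are flagged above.
* MLI assumes axis-aligned lattices; strongly anisotropic voxels bias
  per-axis chord populations unless voxel sizes are passed explicitly.
* The camera's light-sheet (rolling slit) timing is recorded as
  metadata but not simulated.
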