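# cdslm

Cleared-tissue digital scanned light-sheet microscopy (C-DSLM) in
software: the computational core of an autofocusing light-sheet
microscope for optically cleared, refractive-index-heterogeneous
tissue, together with a virtual microscope so that every algorithm can
be exercised and validated without hardware.

## The problem

Tissue-clearing protocols (PACT/CLARITY and relatives) leave residual
refractive-index heterogeneity. In light-sheet imaging this displaces
the true focal plane with depth — *first-order defocus*, accumulating
as

    Δz_focus(z) = ∫₀ᶻ (n(z′) − n_imm) dz′          (≈ (n − n_imm)·z in homogeneous media)

so a scan that holds the detection focus fixed drifts out of focus by
hundreds of micrometres over a few millimetres of depth. C-DSLM
corrects this by (1) patterning the excitation light-sheet with a
sinusoid of known spatial frequency, (2) locating the co-planar
detection focus at a handful of sheet positions by a two-stage search —
minimum mean-squared error of the imaged pattern frequency against the
commanded one (coarse), then maximum Shannon entropy of the image's
discrete cosine transform, SE-DCT (fine) — and (3) linearly
interpolating that calibration during the full volumetric scan. The
same patterned/uniform image pairs feed HiLo structured-illumination
reconstruction,

    D(x) = |U(x) − 2·S(x)|,      I_HiLo = η·LP(D) + HP(U),      η = π/(2M) in theory,

which suppresses out-of-focus haze. Downstream quantification covers
the standard readouts of the imaging studies this instrument serves:
mean linear intercept (L_m) stereology in 2D and on a 3D line lattice,
and threshold/connected-component counting of fluorescent cell bodies
with a median-size correction for fused objects.

## What is in the package

| module | contents |
| --- | --- |
| `cdslm.scope` | virtual microscope: Gaussian-beam sheet, index profiles, defocus-dependent blur, Poisson + read noise |
| `cdslm.phantoms` | seeded specimen generators: beads, fibers, Voronoi foam (with ground-truth air mask), slab foam |
| `cdslm.metrics` | pattern-frequency estimation (FFT + parabolic refinement), frequency MSE, SE-DCT, brightness |
| `cdslm.autofocus` | coarse/fine focus search, ETL-1 sweep limits, calibration build + interpolation, C-DSLM and standard scans |
| `cdslm.hilo` | demodulation, LP/HP fusion, theoretical and automatic η selection |
| `cdslm.quant` | chord extraction, 2D/3D mean linear intercept, cell counting |
| `cdslm.io` / `cdslm.cli` | TIFF + sidecar metadata, TeraStitcher-compatible tiled layout, `cdslm` command line |

## Worked example

Calibrate the detection focus at four light-sheet positions through a
3 mm foam phantom cleared to n = 1.45 under air detection optics
(n_imm = 1.0), then compare a calibrated scan with a constant-offset
(standard LSFM) scan:

```python
import cdslm as c
from cdslm.autofocus import SearchConfig, build_calibration, cdslm_scan, standard_scan

vol, _ = c.make_foam_volume(40.0, 6.0, (201, 96, 96), (1, 1, 15), seed=3, intensity=400.0)
scope = c.VirtualScope(
    vol,
    c.LightSheetModel(waist_fwhm_um=16.0, modulation_period_um=16.0),
    c.DetectionModel(depth_of_field_um=10.0, base_blur_sigma_um=1.0,
                     pixel_size_um=1.0, image_shape=(96, 96)),
    c.RefractiveIndexProfile.homogeneous(1.45, 1.0, z_max_um=3200.0))

curve = build_calibration(scope, [0.0, 1000.0, 2000.0, 3000.0], SearchConfig(), seed=5)
print(curve.to_frame())
```

```
 sheet_z_um  focus_offset_um  etl1_low  etl1_high
        0.0              0.0 15.833333  79.166667
     1000.0            453.0  0.000000  63.333333
     2000.0            897.0 63.333333  63.333333
     3000.0           1350.0  0.000000  63.333333
```

The ground-truth offsets are (1.45 − 1.0)·z = 0, 450, 900, 1350 μm:
the autofocus lands within its 3 μm fine step at every position. A
calibrated scan then stays in focus while the constant-offset scan
accumulates defocus:

```python
cd = cdslm_scan(scope, curve, 0.0, 3000.0, 750.0, seed=9)
st = standard_scan(scope, 0.0, 3000.0, 750.0, seed=9)
print(cd.report[["z_um", "residual_um", "sedct"]])
print(st.report[["z_um", "residual_um", "sedct"]])
```

```
  z_um  residual_um    sedct          z_um  residual_um    sedct
   0.0         0.00 9.437114           0.0          0.0 9.437114
 750.0         2.25 9.311253         750.0        337.5 4.808822
1500.0         0.00 9.578901        1500.0        675.0 4.921049
2250.0         2.25 9.243975        2250.0       1012.5 4.453751
3000.0         0.00 9.517565        3000.0       1350.0 5.209256
```

The calibrated scan's residual defocus never exceeds 2.25 μm and its
SE-DCT (sharpness, in bits) stays near the in-focus value of ~9.4;
the standard scan's residual grows as 0.45·depth and its SE-DCT drops
to ~4.5–5.2 bits.

The same pipeline is scriptable from a shell:

```sh
cdslm --seed 5 calibrate --positions 4 --out cal.csv
cdslm --seed 9 scan --mode cdslm --calibration cal.csv --out stack.tif
cdslm hilo --uniform stack.tif --structured stack_structured.tif --out recon.tif
```

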