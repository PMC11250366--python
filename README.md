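# mfias

Simulation and analysis toolkit for **multifocal imaging of arbitrary
surfaces** — widefield fluorescence macroscopy in which a spinning disc of
plane-parallel glass slabs sweeps the focal plane through a ladder of depths
within one camera exposure, while a DMD (digital micromirror device)
illuminates, at each instant, only the parts of a curved specimen that are in
focus. One exposure then integrates in-focus signal from the whole surface:
millimetre-scale depth of field at the lateral resolution of the bare
objective, with no deconvolution.

The package is aimed at microscope builders and computational imaging
researchers who want to explore the design space (disc layout, NA, aberration
budget) and the reconstruction pipeline (depth-from-focus surface estimation,
mask generation, functional readouts) without hardware, using seeded
synthetic phantoms of curved specimens.

## The physics in brief

A glass slab of thickness *d* and refractive index *n* in a telecentric
detection path displaces the focus away from the lens by

    Δz = d (n − 1) / n

and adds fourth-order spherical aberration with peak wavefront error

    W₀₄₀ = (n² − 1) / (8 n³) · d · θ₀⁴ ,   θ₀ = arcsin(NA)

(≈ d·θ₀⁴/20 for n = 1.5). PSFs are computed with the scalar Debye pupil
integral including this quartic phase. The design calculators follow from the
same law: a thickness increment of 2nL/(n−1) steps the focus by exactly 2L,
and covering a depth of field DOF takes N = DOF/(2L) + 1 slots; selective
illumination needs N× excitation power but cuts the per-point photodose N-fold.

Modules:

| module        | contents |
|---------------|----------|
| `mfias.optics`      | slab focal shift & aberration, Debye PSF, Strehl/enclosed-energy/FWHM, design calculators |
| `mfias.phantom`     | curved surfaces (the cranial-window profile h = −0.06x² − 0.0007x⁴ mm), beads, blinking somata, noisy renders |
| `mfias.surface`     | depth-from-focus: extended-maxima feature detection, depth assignment, polynomial/smooth surface fit, K-level masks, single-exposure patch probing |
| `mfias.acquisition` | coded-exposure simulator, conventional baseline, disc timing, dual-plane mode |
| `mfias.calibration` | DMD↔camera affine fit, refractive-index recovery from focal-shift series |
| `mfias.metrics`     | PSNR, soma detection, ΔF/F₀ traces, orientation-selectivity index |
| `mfias.pipeline` / `mfias.cli` | end-to-end runs, `mfias` command-line tool |

## Worked example

Design a disc for a 450 µm depth of field with ±25 µm per layer:

```text
$ mfias design --dof 450 -l 25 -n 1.5
depth_of_field_um: 450.0
half_defocus_um: 25.0
num_layers: 10
glass_interval_um: 150.0
aperture_diameter_mm: 40.0
num_slots: 10
min_disc_radius_mm: 91.19349550499538
illumination_power_factor: 10.0
dose_vs_full_3d_scan: 0.1
```

Ten slots — an open one plus nine glasses in 150 µm thickness steps — cover
450 µm in 50 µm focal increments; excitation power rises 10× while each point
on the specimen receives a tenth of the dose of a full 3D scan.

Simulate the PSF under increasing glass thickness at NA 0.3, λ 0.5 µm:

```text
$ mfias psf -d 0 -d 1.8 -d 2.4
 thickness_mm  focal_shift_um   strehl  fwhm_um  enclosed_energy_r5um
          0.0             0.0 1.000000 0.858603              0.973711
          1.8           600.0 0.641282 0.859486              0.944563
          2.4           800.0 0.446554 0.846264              0.921210
```

The lateral FWHM stays at the Airy width (0.51 λ/NA ≈ 0.85 µm) for every
thickness, but the Strehl ratio drops below the 0.8 diffraction-limited
criterion by 1.8 mm of glass. The resolution penalty is mild in practice:
even at the worst-case 2.4 mm (0.8 mm of focal shift) more than 90% of the
energy stays within a 5 µm radius.

In Python, the full pipeline on a synthetic curved specimen:

```python
from mfias.io import RunConfig
from mfias.pipeline import run_pipeline

manifest = run_pipeline(RunConfig(seed=1), "demo_run")
```

writes the focal stack, estimated depth map, the ten binary illumination
masks, one coded and one conventional exposure, a blinking-somata movie with
its ground truth, and per-source PSNR tables, all under `demo_run/` with a
JSON manifest for bit-exact reproduction.

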