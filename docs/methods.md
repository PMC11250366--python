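# Methods

## Optical model

**Slab optics.** A plane-parallel glass plate (thickness *d*, index *n*) in a
telecentric detection path shifts the focus by Δz = d(n − n_med)/n away from
the lens (n_med = 1 for air) and introduces fourth-order spherical aberration
with peak wavefront error W₀₄₀ = (n²−1)/(8n³)·d·θ₀⁴, where θ₀ =
arcsin(NA/n_med) is the marginal-ray half-angle. Telecentricity means the
shift and aberration are field-independent, which is what makes a spinning
disc of flat glasses usable across a centimetre-scale field.

**PSF.** PSFs are computed with the *scalar* Debye integral over the
aperture: U(r, z) = ∫₀^θ₀ sinθ √cosθ · J₀(k r sinθ) · exp[i k((z−Δz)cosθ +
W₀₄₀(sinθ/sinθ₀)⁴)] dθ, evaluated by Gauss–Legendre quadrature (256 nodes by
default; doubling changes the peak by < 1%). The scalar treatment is accurate
for the NA ≤ 0.3 regime the system targets; the high-NA (0.95) configuration
reuses the same model and should be read qualitatively there. The bulk focal
shift is carried as a defocus offset, so the axial coordinate is always
absolute sample space; the balancing defocus that minimizes the aberrated
spot is *not* applied analytically — best focus is found empirically as the
axial plane of peak intensity, matching how an experimenter refocuses.

**Metrics.** Strehl is the peak-intensity ratio of the aberrated PSF to the
unaberrated reference, each refocused to its own best plane and normalized to
that plane's total energy (Debye plane energy is z-invariant, so this only
guards against grid truncation). Enclosed energy is the fraction of a plane's
energy inside a circle about the plane centroid. FWHM is linear-interpolated
at half of (peak − background). Note the classic Airy encircled-energy
anchor: 83.8% falls inside the first dark ring at radius 0.61 λ/NA.

**Design calculators.** Thickness increment 2nL/(n−1) (focal step exactly
2L), layer count N = DOF/2L + 1 (rounded, with a warning when DOF/2L is not
integral), excitation power ×N with photodose 1/N, image-space relay scaling
1/M², and the nested three-disc ladder in which each coarser disc's increment
equals the finer disc's span, giving m·n·k distinct uniform positions. The
minimum disc radius packs the slot apertures around the circumference with a
configurable clearance; the geometry behind the quoted ~100 mm figure is not
specified anywhere, so this rule is explicitly an approximation.

## Synthetic phantoms

The generator emulates the study conditions rather than any particular
dataset:

- **Surface**: the cranial-window profile h(x) = −0.06x² − 0.0007x⁴ (mm),
  extended translationally along y by default (`radial` optional). It spans
  ~0.6 mm of depth over a 6 mm aperture. Desk-scale simulations use a small
  field of view (≈1 mm at 2 µm pixels), so tests raise the `scale` factor to
  present the same 0–450 µm depth range to the 10-level disc within that
  field; the profile shape is unchanged.
- **Emitters**: 0.5 µm beads (sub-resolution points) and 15 µm soma-like
  discs rendered as PSF-convolved Gaussian blobs of the stated diameter;
  brightness defaults (beads 4000, somata 3000–6000 detected photons/frame in
  focus) are chosen so single frames have realistic tens-of-counts peaks over
  a 10-count background. Neurons can be offset 130–200 µm below the surface
  via `depth_band_um`.
- **Dynamics**: spike-triggered double-exponential calcium kinetics (rise
  50 ms, decay 400 ms, GCaMP6f-like) sampled at 10 Hz.
- **Noise**: Poisson photon noise over a 10-count background plus σ = 2
  counts Gaussian read noise. All randomness flows through explicit seeds.
- **Rendering**: per-emitter radial Debye profiles cached per quantized
  defocus; pixels integrate the PSF over their area (3×3 sub-samples near
  focus, where defocus rings are finer than a pixel). Kernels keep the
  defocus-invariant Debye plane energy, so photon count is conserved across
  defocus to within window truncation (~2%). An optional `max_defocus_um`
  cull drops contributions whose per-pixel intensity is orders of magnitude
  below the noise floor, trading exact linearity for speed.

What the phantoms deliberately omit: tissue scattering and depth-dependent
attenuation, vascular/hemodynamic background, sample motion within an
exposure, and camera fixed-pattern artifacts. Passing recovery tests
therefore demonstrate the *algorithms* under controlled optics and shot
noise, not robustness to those real-tissue effects.

## Acquisition model

One coded exposure integrates, for each disc slot k, the widefield image
focused at that slot's depth gated by binary mask k: frame = Σₖ maskₖ ⊙
imageₖ, with excitation power ×N and per-slot exposure fraction 1/N
(configurable), so all-ones masks reproduce the plain focal-stack sum and a
correctly masked in-focus source keeps its conventional photon yield. Masks
gate on the detection grid after the affine DMD mapping; edges binarize at
0.5 (a binary DMD has no grey levels). The specimen is frozen within an
exposure — valid at the 10 Hz frame rates the disc targets. Because the level
masks partition the frame, a static specimen's movie is composed from
precomputed per-emitter footprints, which is what makes long functional
movies cheap.

Bead-sharpness accounting: with masks matching the true levels, a source's
residual defocus is the quantization remainder (≤ L = 25 µm). The ±L design
value is set by soma-scale (15 µm) feature visibility; sub-micron beads stay
at their in-focus width only when they sit near a level depth, which is how
the sharpness comparison is constructed.

## Surface estimation

Neural mode reduces each per-depth time sub-stack to its temporal standard
deviation (blinking sources stand out; static background cancels); vessel
mode uses single images. Planes are re-ordered by focal shift. Features are
connected regions of the extended-maxima transform (`h_maxima`), h defaulting
to 3× the MAD-based noise σ of a lightly pre-smoothed (σ = 1 px) image —
without pre-smoothing, shot-noise pixels dominate the maxima. Regions are
filtered by area and eccentricity. Depth per feature is the plane maximizing
the window-max focus score (ties to the shallower plane; optional three-point
parabolic refinement between planes). The surface fit is a least-squares 2D
polynomial on centred/scaled coordinates — degree 4 by default, matching the
quartic window profile; the degree used in the original workflow is not
stated — or, for non-polynomial surfaces, scattered interpolation plus
median/Gaussian smoothing. Discretization assigns each pixel the nearest
level depth (ties shallower); level depths default to the disc's focal-shift
ladder so each mask maps one physical slot.

The depth-from-focus scan may be sampled finer than the level ladder (the
calibration procedure images tens of depths); desk-scale tests use a 25 µm
scan against 50 µm levels with ~300 beads per mm², which brings the fitted
map's error to ~1.5 µm RMS. Beads lying within that error of a level
boundary are inherent coin flips, which is what bounds the end-to-end level
recovery rate (>95% observed).

The single-exposure mode tiles the frame into non-overlapping patches, each
illuminated at one probe depth per exposure (cyclic assignment across
exposures); a patch's depth is the probe with the best (max − median) score,
unprobed patches are flagged rather than guessed.

## Calibration

The DMD→camera map is an affine fitted by least squares to ≥ 3 non-collinear
point pairs, matched by display order. The refractive index comes from the
through-origin slope s of focal shift vs thickness, n = 1/(1−s); the
through-origin constraint is physically forced (no glass, no shift), with an
intercept option for diagnosing systematic offsets.

**Aberration-displacement correction.** Any intensity-based focus localizer
(axial peak, half-max midpoint, centroid) of a spherically aberrated PSF sits
≈ 2W₀₄₀/θ₀² beyond the paraxial focus. Since W₀₄₀ ∝ d, this inflates the
slope ~2.5% at NA 0.3 and biases the recovered index from 1.52 to ≈ 1.540 —
numerically the same offset separating the in vivo estimate (1.54 ± 0.04)
from the nominal glass value (1.52). The calibration pipeline therefore
subtracts the model-predicted peak displacement, iterating the model index to
self-consistency (two iterations suffice); noiseless simulated stacks then
return the true index to < 10⁻⁴. The uncorrected estimate remains available
(`correct_aberration=False`).

## Functional metrics

- **PSNR**: both the source peak and the noise are measured on the σ = 10 px
  Gaussian-filtered, per-pixel temporal-median-subtracted movie; noise is the
  median temporal standard deviation over pixels farther than two source
  radii from every source (the background set is not defined in the original
  description; pooled median is this package's choice, as is measuring the
  peak on the filtered movie — it is what makes a signal-free source read the
  O(1) "baseline of 1"). The kernel is specified in pixels, so compare only
  movies with equal sampling.
- **Soma detection**: separable spatio-temporal band-pass (difference of
  Gaussians, σ_xy 2/15 px, σ_t 10/30 frames — the two-scale surrogate those
  parameters imply for a Laplacian-of-Gaussian), then local maxima of the
  temporal-σ projection with centroid refinement.
- **Traces**: raw centre-pixel intensity minus the σ = 15 px
  Gaussian-smoothed background; ΔF/F₀ with F₀ the 10th percentile of the
  background-subtracted trace (F₀ is not defined in the original workflow;
  the percentile is configurable). A uniform intensity offset cancels in the
  subtraction.
- **OSI**: one-way ANOVA across the eight direction groups and the blank
  group gates responsiveness at P < 0.01 (per source, uncorrected). θ_pref
  maximizes the trial-averaged response; r_orth is the smaller of the two
  responses 90° away; OSI = (r_pref − r_orth)/(r_pref + r_orth) on raw
  trial-averaged responses. A double-Gaussian fit (circular Gaussians at
  θ_pref and the orthogonal direction with the larger response) is reported
  alongside, never used in the index. The trimmed standard deviation drops
  the single extreme trial at each end (sample std, ddof = 1).

## Numerical choices and degenerate inputs

Ties always resolve to the shallower plane/level. Depth maps must be finite;
under-determined polynomial fits are rejected with the required feature
count. FWHM rejects boundary peaks; enclosed energy rejects circles that
leave the grid; PSNR flags zero noise rather than returning infinity; ΔF/F is
flagged undefined when F₀ ≤ 0; slope estimates outside (0, 1) are rejected as
unphysical. Config files round-trip losslessly and name the missing group on
validation failure; every stochastic step draws from a generator derived from
the run seed.

## Known limitations

Scalar (not vectorial) diffraction; no chromatic effects; no scattering or
attenuation in the specimen; mask gating is applied on the detection side of
the rendered image (excitation-side gating differs only through defocused
cross-talk of out-of-level sources, which the selective-illumination
approximation ignores); the disc-radius rule is a stated approximation; and
the sharpness/PSNR comparisons quantify the mechanism on phantoms, not
performance on real tissue.
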