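"""Seeded synthetic specimens: curved surfaces, beads, blinking somata, noisy renders.

Coordinate convention (used package-wide): pixel centres, 0-based, x to the
right, y downward, z in micrometres increasing *away* from the objective
(deeper). The lateral origin sits at the image centre. A surface's "depth"
is therefore non-negative, with 0 at its highest point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .optics import OpticalConfig, debye_radial_intensity

__all__ = [
    "SurfaceModel",
    "Emitter",
    "CalciumTrace",
    "NoiseModel",
    "brain_surface",
    "scatter_emitters",
    "render_plane",
    "render_stack",
    "render_time_series",
    "random_traces",
    "ground_truth_table",
]

# Cranial-window height profile fitted to the mouse skull: h(x) in mm for x in mm.
CRANIAL_WINDOW_COEFFS_MM = (0.0, 0.0, -0.06, 0.0, -0.0007)


@dataclass(frozen=True)
class SurfaceModel:
    """Analytic height field h(x) (mm), extended across the second lateral axis.

    ``orientation='x'`` extends the 1D profile translationally (cylindrical)
    along y — the default, matching a window bent about one axis; 'radial'
    sweeps the profile around the optical axis. ``scale`` multiplies the
    height (depth exaggeration for small simulated fields of view).
    """

    coeffs_mm: tuple[float, ...] = CRANIAL_WINDOW_COEFFS_MM
    lateral_extent_mm: float = 6.0
    orientation: str = "x"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.orientation not in ("x", "y", "radial"):
            raise ValueError("orientation must be 'x', 'y' or 'radial'")
        if self.lateral_extent_mm <= 0:
            raise ValueError("lateral_extent_mm must be positive")

    def height_mm(self, x_um, y_um):
        """Signed height h (mm, <= 0 for the window profile) at lateral positions."""
        x_um = np.asarray(x_um, dtype=float)
        y_um = np.asarray(y_um, dtype=float)
        if self.orientation == "x":
            t = x_um / 1000.0
        elif self.orientation == "y":
            t = y_um / 1000.0
        else:
            t = np.hypot(x_um, y_um) / 1000.0
        return self.scale * np.polynomial.polynomial.polyval(t, self.coeffs_mm)

    def depth_um(self, x_um, y_um):
        """Depth below the surface apex (um, >= 0, increasing away from the lens)."""
        h = self.height_mm(x_um, y_um)
        apex = self.scale * max(
            np.polynomial.polynomial.polyval(0.0, self.coeffs_mm), 0.0
        )
        return (apex - h) * 1000.0

    def depth_span_um(self, half_extent_um: float | None = None) -> float:
        """Total depth range across the (half-)extent of the field."""
        if half_extent_um is None:
            half_extent_um = self.lateral_extent_mm * 1000.0 / 2.0
        t = np.linspace(-half_extent_um, half_extent_um, 501)
        d = self.depth_um(t, np.zeros_like(t))
        return float(d.max() - d.min())


def brain_surface(
    scale: float = 1.0, orientation: str = "x", extent_mm: float = 6.0
) -> SurfaceModel:
    """The cranial-window profile h = -0.06 x^2 - 0.0007 x^4 (x in mm)."""
    return SurfaceModel(
        coeffs_mm=CRANIAL_WINDOW_COEFFS_MM,
        lateral_extent_mm=extent_mm,
        orientation=orientation,
        scale=scale,
    )


@dataclass
class Emitter:
    """A point or soma-like fluorescent source."""

    x_um: float
    y_um: float
    z_um: float
    diameter_um: float = 0.5
    peak_brightness: float = 2000.0  # photons/frame collected in focus
    trace_id: int | None = None

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")


BEAD_DIAMETER_UM = 0.5
SOMA_DIAMETER_UM = 15.0
# Neurons imaged in the paper's regime sit 130-200 um below the dura.
NEURON_DEPTH_BAND_UM = (130.0, 200.0)


def scatter_emitters(
    surface: SurfaceModel,
    count: int,
    kind: str = "bead",
    extent_um: tuple[float, float] = (400.0, 400.0),
    depth_band_um: tuple[float, float] = (0.0, 0.0),
    brightness: float = 2000.0,
    seed: int | np.random.Generator = 0,
) -> list[Emitter]:
    """Scatter emitters uniformly in x, y over a centred box, on or below the surface.

    ``z = surface depth + U(depth_band)``: the band offsets sources below the
    surface (toward larger z). Deterministic under a fixed seed.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if kind not in ("bead", "soma"):
        raise ValueError("kind must be 'bead' or 'soma'")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    diam = BEAD_DIAMETER_UM if kind == "bead" else SOMA_DIAMETER_UM
    lo, hi = depth_band_um
    if lo > hi:
        raise ValueError("depth_band_um must be (low, high)")
    out = []
    for i in range(count):
        x = rng.uniform(-extent_um[0] / 2.0, extent_um[0] / 2.0)
        y = rng.uniform(-extent_um[1] / 2.0, extent_um[1] / 2.0)
        z = float(surface.depth_um(x, y)) + rng.uniform(lo, hi)
        out.append(Emitter(x, y, z, diameter_um=diam, peak_brightness=brightness))
    return out


@dataclass
class CalciumTrace:
    """Spike-triggered double-exponential fluorescence kinetics (GCaMP6f-like).

    trace(t) = baseline * (1 + amplitude * sum_k g(t - t_k)) with
    g(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) scaled to unit peak.
    """

    spike_frames: tuple[int, ...]
    rise_s: float = 0.05
    decay_s: float = 0.4
    amplitude: float = 1.0
    baseline: float = 1.0
    frame_rate_hz: float = 10.0

    def kernel(self, n_frames: int) -> np.ndarray:
        t = np.arange(n_frames) / self.frame_rate_hz
        g = np.exp(-t / self.decay_s) - np.exp(-t / self.rise_s)
        peak = g.max()
        return g / peak if peak > 0 else g

    def generate(self, n_frames: int) -> np.ndarray:
        """Brightness multiplier per frame (>= 0)."""
        out = np.zeros(n_frames)
        ker = self.kernel(n_frames)
        for s in self.spike_frames:
            if 0 <= s < n_frames:
                out[s:] += ker[: n_frames - s]
        return self.baseline * (1.0 + self.amplitude * out)


def random_traces(
    count: int,
    n_frames: int,
    rate_hz: float = 0.2,
    frame_rate_hz: float = 10.0,
    amplitude: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> list[CalciumTrace]:
    """Poisson-spiking calcium traces, deterministic under seed."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    p = rate_hz / frame_rate_hz
    traces = []
    for _ in range(count):
        spikes = tuple(np.flatnonzero(rng.random(n_frames) < p).tolist())
        traces.append(
            CalciumTrace(
                spike_frames=spikes,
                amplitude=amplitude,
                frame_rate_hz=frame_rate_hz,
            )
        )
    return traces


@dataclass(frozen=True)
class NoiseModel:
    """Poisson photon noise plus Gaussian read noise over a constant background."""

    poisson: bool = True
    read_sigma: float = 2.0
    background: float = 10.0

    def __post_init__(self) -> None:
        if self.read_sigma < 0 or self.background < 0:
            raise ValueError("read_sigma and background must be >= 0")

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        img = image + self.background
        if self.poisson:
            img = rng.poisson(img).astype(float)
        if self.read_sigma > 0:
            img = img + rng.normal(0.0, self.read_sigma, size=img.shape)
        return img


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_PROFILE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
_TOTAL_CACHE: dict[tuple, float] = {}


def _cfg_key(cfg: OpticalConfig) -> tuple:
    return (cfg.numerical_aperture, cfg.wavelength_um, cfg.medium_index)


def _in_focus_total(cfg: OpticalConfig) -> float:
    """Total in-focus plane energy 2*pi*int I(r,0) r dr (Debye plane energy is
    z-independent up to truncation, so this normalizes every defocus)."""
    key = _cfg_key(cfg)
    if key not in _TOTAL_CACHE:
        r = np.linspace(0.0, 200.0, 20001)
        prof = debye_radial_intensity(cfg, None, r, np.zeros(1))[0]
        _TOTAL_CACHE[key] = float(2.0 * np.pi * np.trapezoid(prof * r, r))
    return _TOTAL_CACHE[key]


def _radial_profile(cfg: OpticalConfig, defocus_um: float, r_max_um: float):
    """Cached radial intensity profile at one defocus (defocus quantized to 0.25 um)."""
    dq = round(defocus_um * 4.0) / 4.0
    rq = float(np.ceil(r_max_um / 10.0) * 10.0)
    key = _cfg_key(cfg) + (dq, rq)
    if key not in _PROFILE_CACHE:
        r = np.linspace(0.0, rq, max(int(rq / 0.1), 64) + 1)
        prof = debye_radial_intensity(cfg, None, r, np.array([dq]))[0]
        _PROFILE_CACHE[key] = (r, prof)
    return _PROFILE_CACHE[key]


def _kernel_radius_um(cfg: OpticalConfig, defocus_um: float, diameter_um: float) -> float:
    airy = 1.22 * cfg.wavelength_um / cfg.numerical_aperture
    geom = abs(defocus_um) * np.tan(cfg.half_angle_rad)
    return 1.4 * geom + 6.0 * airy + 2.0 * diameter_um


def _emitter_patch(
    e: Emitter,
    cfg: OpticalConfig,
    z_plane_um: float,
    shape: tuple[int, int],
    supersample: int = 3,
):
    """(y-slice, x-slice, patch) for one emitter on one focal plane, or None.

    Pixel values integrate the PSF over the pixel area (``supersample``^2
    sub-samples per pixel), as a camera does; point sampling would alias the
    ring structure of defocused PSFs.
    """
    h, w = shape
    px = cfg.pixel_size_sample_um
    defocus = z_plane_um - e.z_um
    rad_um = _kernel_radius_um(cfg, defocus, e.diameter_um)
    rad_px = int(np.ceil(rad_um / px))

    # emitter position in pixel coordinates (origin at image centre)
    ex = e.x_um / px + (w - 1) / 2.0
    ey = e.y_um / px + (h - 1) / 2.0
    cx, cy = int(round(ex)), int(round(ey))
    x0, x1 = cx - rad_px, cx + rad_px + 1
    y0, y1 = cy - rad_px, cy + rad_px + 1
    if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
        return None

    r_grid, prof = _radial_profile(cfg, defocus, rad_um + 2 * px)
    # far from focus the blur is smooth over a pixel; sub-pixel integration
    # only matters while the PSF carries structure finer than the pixel pitch
    s = max(int(supersample), 1)
    if abs(defocus) * np.tan(cfg.half_angle_rad) > 4.0 * px:
        s = 1
    n_px_x, n_px_y = x1 - x0, y1 - y0
    sub = (np.arange(s) - (s - 1) / 2.0) / s
    xs = ((np.arange(x0, x1)[:, None] + sub[None, :]).ravel() - ex) * px
    ys = ((np.arange(y0, y1)[:, None] + sub[None, :]).ravel() - ey) * px
    rr = np.hypot(xs[None, :], ys[:, None])
    patch = np.interp(rr, r_grid, prof, right=0.0)
    patch = patch.reshape(n_px_y, s, n_px_x, s).mean(axis=(1, 3))
    if e.diameter_um > 2.0 * px:
        # soma-like source: PSF-convolved Gaussian blob of the stated diameter
        sigma_px = e.diameter_um / 2.3548 / px
        patch = gaussian_filter(patch, sigma_px, mode="constant")
    patch *= e.peak_brightness * px**2 / _in_focus_total(cfg)

    sy = slice(max(y0, 0), min(y1, h))
    sx = slice(max(x0, 0), min(x1, w))
    return sy, sx, patch[
        sy.start - y0 : sy.stop - y0, sx.start - x0 : sx.stop - x0
    ]


def render_plane(
    emitters: Sequence[Emitter],
    cfg: OpticalConfig,
    z_plane_um: float,
    shape: tuple[int, int] = (256, 256),
    brightness_scale: Sequence[float] | None = None,
    max_defocus_um: float | None = None,
) -> np.ndarray:
    """Noiseless widefield image of emitters with the focal plane at ``z_plane_um``.

    Each emitter contributes its defocused PSF (optionally blurred to soma
    size), normalized so an in-focus emitter deposits ``peak_brightness``
    photons in total; defocused kernels keep the energy the Debye model
    conserves, minus finite-window truncation. ``max_defocus_um`` optionally
    culls emitters farther than that from the plane — their per-pixel
    contribution is orders of magnitude below typical noise floors — at the
    cost of exact linearity; leave ``None`` for the exact render.
    """
    img = np.zeros(shape)
    for i, e in enumerate(emitters):
        if max_defocus_um is not None and abs(z_plane_um - e.z_um) > max_defocus_um:
            continue
        res = _emitter_patch(e, cfg, z_plane_um, shape)
        if res is None:
            continue
        sy, sx, patch = res
        s = 1.0 if brightness_scale is None else float(brightness_scale[i])
        img[sy, sx] += s * patch
    return img


def render_stack(
    emitters: Sequence[Emitter],
    cfg: OpticalConfig,
    z_planes_um: Sequence[float],
    shape: tuple[int, int] = (256, 256),
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    max_defocus_um: float | None = None,
) -> np.ndarray:
    """Focal stack (Z, H, W): one widefield render per focal plane, plus noise."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    planes = np.stack(
        [
            render_plane(emitters, cfg, z, shape, max_defocus_um=max_defocus_um)
            for z in z_planes_um
        ]
    )
    if noise is not None:
        planes = np.stack([noise.apply(p, rng) for p in planes])
    return planes


def render_time_series(
    emitters: Sequence[Emitter],
    traces: Sequence[CalciumTrace],
    cfg: OpticalConfig,
    n_frames: int,
    shape: tuple[int, int] = (256, 256),
    focal_plane_um: float | str = "in_focus",
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Movie (T, H, W) of blinking emitters with its ground truth.

    ``focal_plane_um='in_focus'`` renders every emitter at its own focus —
    the idealization of a selective-illumination acquisition — while a number
    fixes a single conventional focal plane. Emitter ``i`` follows
    ``traces[i % len(traces)]``. Returns (movie, ground-truth table,
    ground-truth trace array of shape (n_emitters, n_frames)).
    """
    if len(emitters) and not len(traces):
        raise ValueError("at least one trace is required")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    values = np.empty((len(emitters), n_frames))
    patches = []
    for i, e in enumerate(emitters):
        values[i] = traces[i % len(traces)].generate(n_frames)
        z = e.z_um if focal_plane_um == "in_focus" else float(focal_plane_um)
        patches.append(_emitter_patch(e, cfg, z, shape))

    movie = np.zeros((n_frames,) + shape)
    for t in range(n_frames):
        frame = movie[t]
        for i, res in enumerate(patches):
            if res is None:
                continue
            sy, sx, patch = res
            frame[sy, sx] += values[i, t] * patch
        if noise is not None:
            movie[t] = noise.apply(frame, rng)

    truth = ground_truth_table(emitters)
    truth["trace_index"] = [i % len(traces) for i in range(len(emitters))] if traces else []
    return movie, truth, values


def ground_truth_table(emitters: Sequence[Emitter]) -> pd.DataFrame:
    """One row per emitter: positions, size, brightness, trace link."""
    return pd.DataFrame(
        {
            "x_um": [e.x_um for e in emitters],
            "y_um": [e.y_um for e in emitters],
            "z_um": [e.z_um for e in emitters],
            "diameter_um": [e.diameter_um for e in emitters],
            "peak_brightness": [e.peak_brightness for e in emitters],
            "trace_id": [e.trace_id for e in emitters],
        }
    )
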