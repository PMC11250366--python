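"""DMD-camera geometric calibration and refractive-index estimation.

The DMD and camera are registered with an affine transform fitted to
corresponding point pairs (sparse bright DMD pixels located on the camera).
The glass refractive index is recovered from the linear relation between
measured focal shift and slab thickness, dz = d (n-1)/n, whose through-origin
slope s gives n = 1/(1 - s).

Intensity-based focus localization under slab spherical aberration is biased:
the axial peak of the aberrated PSF sits ~2 W040 / theta0^2 beyond the
paraxial focus, which inflates the slope by a few percent (and is why a
nominal n = 1.52 glass reads ~1.54 from raw peak positions). The pipeline
here optionally removes that displacement with the same Debye forward model
used for simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates

from .optics import GlassSlab, OpticalConfig, debye_axial_intensity, focal_shift

__all__ = [
    "PointPairs",
    "AffineTransform",
    "ShiftSeries",
    "estimate_affine",
    "masks_to_dmd",
    "estimate_refractive_index",
    "locate_axial_peak",
    "predicted_peak_offset",
    "measure_bead_shift_series",
    "refractive_index_from_profiles",
]


@dataclass
class PointPairs:
    """Index-matched DMD (u, v) and camera (x, y) pixel coordinates."""

    dmd: np.ndarray  # (N, 2)
    camera: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        self.dmd = np.asarray(self.dmd, dtype=float)
        self.camera = np.asarray(self.camera, dtype=float)
        if self.dmd.shape != self.camera.shape or self.dmd.ndim != 2 or self.dmd.shape[1] != 2:
            raise ValueError("dmd and camera must both be (N, 2)")


@dataclass
class AffineTransform:
    """camera = matrix @ dmd + offset, with the fit residual RMSE (camera px)."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    residual_rmse: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine linear part must be invertible")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset, self.residual_rmse)


def estimate_affine(pairs: PointPairs) -> AffineTransform:
    """Least-squares affine minimizing camera-space residuals.

    Requires >= 3 non-collinear pairs; point matching is given by display
    order (the calibration pattern shows known sparse pixels).
    """
    n = len(pairs.dmd)
    if n < 3:
        raise ValueError("affine estimation needs >= 3 point pairs")
    centred = pairs.dmd - pairs.dmd.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max())) < 2:
        raise ValueError("point pairs are collinear; affine is degenerate")
    A = np.hstack([pairs.dmd, np.ones((n, 1))])
    sol, *_ = np.linalg.lstsq(A, pairs.camera, rcond=None)
    matrix = sol[:2].T
    offset = sol[2]
    resid = A @ sol - pairs.camera
    rmse = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform(matrix, offset, rmse)


def masks_to_dmd(
    masks: np.ndarray,
    transform: AffineTransform,
    dmd_shape: tuple[int, int],
    threshold: float = 0.5,
) -> np.ndarray:
    """Warp camera-space binary masks onto the DMD grid.

    Each DMD pixel (u, v) is mapped through the forward transform to camera
    coordinates, the mask is sampled bilinearly there and binarized at 0.5
    (a binary DMD shows no grey levels).
    """
    masks = np.asarray(masks, dtype=float)
    squeeze = masks.ndim == 2
    if squeeze:
        masks = masks[None]
    if masks.ndim != 3:
        raise ValueError("masks must be (H, W) or (K, H, W)")
    hv, wv = dmd_shape
    vv, uu = np.mgrid[0:hv, 0:wv]
    cam_xy = transform.apply(np.stack([uu.ravel(), vv.ravel()], axis=1))
    coords = np.stack([cam_xy[:, 1], cam_xy[:, 0]])  # (row, col) order
    out = np.empty((masks.shape[0], hv, wv), dtype=bool)
    for k in range(masks.shape[0]):
        sampled = map_coordinates(
            masks[k], coords, order=1, mode="constant", cval=0.0
        ).reshape(hv, wv)
        out[k] = sampled >= threshold
    return out[0] if squeeze else out


@dataclass
class ShiftSeries:
    """Measured focal shift (um) versus slab thickness (mm)."""

    thickness_mm: np.ndarray
    shift_um: np.ndarray

    def __post_init__(self) -> None:
        self.thickness_mm = np.asarray(self.thickness_mm, dtype=float)
        self.shift_um = np.asarray(self.shift_um, dtype=float)
        if self.thickness_mm.shape != self.shift_um.shape:
            raise ValueError("thickness and shift arrays must match")
        if len(np.unique(self.thickness_mm[self.thickness_mm > 0])) < 1 or len(
            self.thickness_mm
        ) < 2:
            raise ValueError("need >= 2 measurements with distinct thicknesses")
        if np.any(self.shift_um < 0):
            raise ValueError("shifts must be non-negative")


def estimate_refractive_index(
    series: ShiftSeries, confidence: float = 0.95
) -> tuple[float, float]:
    """Invert the focal-shift law: slope s of the through-origin line of
    shift vs thickness gives n = 1/(1 - s).

    Zero glass forces zero shift, so the line is constrained through the
    origin. Returns (n, confidence-interval half-width) with the half-width
    propagated from the slope's standard error by the delta method.
    """
    d_um = series.thickness_mm * 1000.0
    dz = series.shift_um
    ssd = float(np.sum(d_um**2))
    if ssd == 0:
        raise ValueError("all thicknesses are zero")
    s = float(np.sum(d_um * dz) / ssd)
    if not 0.0 < s < 1.0:
        raise ValueError(f"slope {s:.4f} outside (0, 1): unphysical shift series")
    n = 1.0 / (1.0 - s)
    dof = max(len(d_um) - 1, 1)
    resid = dz - s * d_um
    se_s = float(np.sqrt(np.sum(resid**2) / dof / ssd))
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
    half_width = tcrit * se_s / (1.0 - s) ** 2
    return n, float(half_width)


def locate_axial_peak(scores: np.ndarray, z_um: np.ndarray) -> float:
    """Axial position of the focus-measure maximum, parabolically refined.

    The default focus measure is whatever ``scores`` holds (peak intensity or
    local std per plane); three-point parabolic interpolation around the
    argmax gives sub-plane precision.
    """
    scores = np.asarray(scores, dtype=float)
    z_um = np.asarray(z_um, dtype=float)
    i = int(np.argmax(scores))
    if i == 0 or i == len(scores) - 1:
        return float(z_um[i])
    y0, y1, y2 = scores[i - 1 : i + 2]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(z_um[i])
    frac = 0.5 * (y0 - y2) / denom
    return float(z_um[i] + frac * (z_um[min(i + 1, len(z_um) - 1)] - z_um[i]))


def predicted_peak_offset(
    thickness_mm: float,
    refractive_index: float,
    cfg: OpticalConfig,
    window_um: float = 50.0,
    step_um: float = 0.25,
) -> float:
    """Model-predicted displacement of the axial intensity peak from the
    paraxial shifted focus, for a slab of the given thickness and index."""
    if thickness_mm == 0:
        return 0.0
    slab = GlassSlab(thickness_mm, refractive_index)
    shift = focal_shift(slab, cfg)
    z = shift + np.arange(-window_um, window_um + step_um, step_um)
    prof = debye_axial_intensity(cfg, slab, z)
    return locate_axial_peak(prof, z) - shift


def measure_bead_shift_series(
    thicknesses_mm: np.ndarray,
    refractive_index: float,
    cfg: OpticalConfig,
    coarse_step_um: float = 10.0,
    fine_step_um: float = 0.5,
    patch_px: int = 9,
    pixel_um: float = 0.5,
) -> np.ndarray:
    """Best-focus axial positions of a simulated bead under each slab.

    For every thickness the bead's focal stack is rendered through the full
    slab model (bulk shift + spherical aberration) on a small patch; the
    focus measure is the brightest pixel per plane. A coarse scan over the
    physically possible range (0 to d, since dz = d (n-1)/n < d) brackets the
    peak, a fine scan refines it, and three-point parabolic interpolation
    gives the sub-step position. Returns raw peak positions (um) relative to
    the slab-free focus — deliberately uncorrected for the aberration-induced
    peak displacement (see :func:`refractive_index_from_profiles`).
    """
    from .optics import debye_radial_intensity

    half = patch_px // 2
    xs = (np.arange(patch_px) - half) * pixel_um
    rr = np.hypot(xs[None, :], xs[:, None]).ravel()

    def _score(slab: GlassSlab | None, z: np.ndarray) -> np.ndarray:
        r_grid = np.linspace(0.0, rr.max() + pixel_um, 128)
        prof = debye_radial_intensity(cfg, slab, r_grid, z)
        out = np.empty(len(z))
        for i in range(len(z)):
            out[i] = np.interp(rr, r_grid, prof[i]).max()
        return out

    peaks = []
    for t in np.asarray(thicknesses_mm, dtype=float):
        slab = GlassSlab(t, refractive_index) if t > 0 else None
        z_max = max(t * 1000.0, 50.0)
        z = np.arange(-30.0, z_max + coarse_step_um, coarse_step_um)
        coarse = _score(slab, z)
        z0 = z[int(np.argmax(coarse))]
        zf = np.arange(z0 - 1.5 * coarse_step_um, z0 + 1.5 * coarse_step_um, fine_step_um)
        fine = _score(slab, zf)
        peaks.append(locate_axial_peak(fine, zf))
    return np.asarray(peaks)


def refractive_index_from_profiles(
    thickness_mm: np.ndarray,
    peak_positions_um: np.ndarray,
    cfg: OpticalConfig,
    correct_aberration: bool = True,
    n_iterations: int = 3,
) -> tuple[float, float]:
    """Refractive index from measured best-focus positions per slab thickness.

    ``peak_positions_um`` are axial focus-measure peaks relative to the
    slab-free focus. With ``correct_aberration`` the spherical-aberration
    peak displacement predicted by the Debye model is subtracted before the
    through-origin fit, iterating the model index to self-consistency;
    without it the raw (displaced) peaks are used.
    """
    thickness_mm = np.asarray(thickness_mm, dtype=float)
    peaks = np.asarray(peak_positions_um, dtype=float)
    series = ShiftSeries(thickness_mm, np.clip(peaks, 0, None))
    n_est, half = estimate_refractive_index(series)
    if not correct_aberration:
        return n_est, half
    for _ in range(n_iterations):
        offsets = np.array(
            [predicted_peak_offset(t, n_est, cfg) for t in thickness_mm]
        )
        corrected = np.clip(peaks - offsets, 0.0, None)
        n_new, half = estimate_refractive_index(ShiftSeries(thickness_mm, corrected))
        if abs(n_new - n_est) < 1e-6:
            n_est = n_new
            break
        n_est = n_new
    return n_est, half
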