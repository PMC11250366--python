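"""Depth-from-focus surface estimation and per-level illumination masks.

Workflow: a focal stack (raw single images, or the temporal standard
deviation of per-depth time sub-stacks for blinking sources) is searched for
bright features with the extended-maxima transform; each feature is assigned
the depth maximizing its focus score; the scattered (x, y, depth) samples are
fitted with a 2D polynomial (brain-like smooth surfaces) or a smoothed
interpolant; and the fitted depth map is discretized into K binary level
masks, one per disc layer.

Coordinates follow the package convention (pixel centres, 0-based, x right,
y down, z in um away from the objective). Ties in depth go to the shallower
plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from scipy.ndimage import gaussian_filter, median_filter
from skimage.measure import label, regionprops
from skimage.morphology import h_maxima

__all__ = [
    "FocalStack",
    "DepthMap",
    "LevelMasks",
    "PatchPlan",
    "make_focus_input",
    "detect_features",
    "assign_depths",
    "fit_surface",
    "discretize",
    "make_patch_plan",
    "patch_plan_masks",
    "single_frame_depth",
    "estimate_surface",
]


@dataclass
class FocalStack:
    """Per-depth images with strictly increasing depth values (um)."""

    images: np.ndarray  # (K, H, W)
    depth_values_um: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.depth_values_um = np.asarray(self.depth_values_um, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be (K, H, W)")
        if len(self.depth_values_um) != self.images.shape[0]:
            raise ValueError("one depth value per image required")
        if np.any(np.diff(self.depth_values_um) <= 0):
            raise ValueError("depth values must be strictly increasing")


@dataclass
class DepthMap:
    """Per-pixel estimated depth (um) with fit diagnostics."""

    depth_um: np.ndarray
    pixel_size_um: float = 1.0
    diagnostics: dict = field(default_factory=dict)


@dataclass
class LevelMasks:
    """K binary masks partitioning the frame; pixelwise sum is exactly 1."""

    masks: np.ndarray  # (K, H, W) bool
    level_depths_um: np.ndarray

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        self.level_depths_um = np.asarray(self.level_depths_um, dtype=float)
        if self.masks.shape[0] != len(self.level_depths_um):
            raise ValueError("one depth per mask required")
        if not np.all(self.masks.sum(axis=0) == 1):
            raise ValueError("masks must partition the frame (pixelwise sum 1)")


def make_focus_input(
    images: np.ndarray,
    depth_values_um: np.ndarray,
    mode: str = "single",
) -> FocalStack:
    """Build the depth-from-focus input stack.

    ``mode='temporal_std'`` expects (K, T, H, W) per-depth time sub-stacks and
    reduces each to its per-pixel temporal standard deviation — blinking
    sources stand out while static background cancels. ``mode='single'``
    passes (K, H, W) images through unchanged. Planes are re-ordered by
    increasing focal depth.
    """
    images = np.asarray(images, dtype=float)
    depth_values_um = np.asarray(depth_values_um, dtype=float)
    if mode == "temporal_std":
        if images.ndim != 4:
            raise ValueError("temporal_std mode expects (K, T, H, W)")
        planes = images.std(axis=1)
        provenance = "temporal-std"
    elif mode == "single":
        if images.ndim != 3:
            raise ValueError("single mode expects (K, H, W)")
        planes = images
        provenance = "raw"
    else:
        raise ValueError("mode must be 'temporal_std' or 'single'")
    order = np.argsort(depth_values_um, kind="stable")
    return FocalStack(planes[order], depth_values_um[order], provenance)


def _robust_sigma(image: np.ndarray) -> float:
    med = np.median(image)
    return float(1.4826 * np.median(np.abs(image - med)))


def detect_features(
    image: np.ndarray,
    h: float | None = None,
    area_range: tuple[float, float] = (1.0, np.inf),
    max_eccentricity: float = 0.95,
    presmooth_sigma_px: float = 1.0,
) -> pd.DataFrame:
    """Bright-feature detection via the extended-maxima transform.

    Connected regions of ``h_maxima`` (regional maxima after suppressing
    peaks of prominence < h) become candidate features, filtered by area and
    eccentricity. The image is first smoothed by ``presmooth_sigma_px``
    (set 0 to disable) so shot-noise pixels do not masquerade as features;
    ``h`` defaults to 3x the MAD-based noise sigma of the smoothed image.
    Returns a table with x, y (px), area (px), eccentricity and focus_score
    (the region's peak intensity). An empty image yields an empty table.
    """
    image = np.asarray(image, dtype=float)
    if presmooth_sigma_px > 0:
        image = gaussian_filter(image, presmooth_sigma_px)
    if h is None:
        sigma = _robust_sigma(image)
        h = 3.0 * sigma if sigma > 0 else 1e-6
    maxima = h_maxima(image, h)
    lab = label(maxima)
    rows = []
    for rp in regionprops(lab, intensity_image=image):
        if not (area_range[0] <= rp.area <= area_range[1]):
            continue
        if rp.eccentricity > max_eccentricity:
            continue
        cy, cx = rp.centroid
        rows.append(
            {
                "x": cx,
                "y": cy,
                "area": float(rp.area),
                "eccentricity": float(rp.eccentricity),
                "focus_score": float(rp.intensity_max),
            }
        )
    return pd.DataFrame(rows, columns=["x", "y", "area", "eccentricity", "focus_score"])


def assign_depths(
    stack: FocalStack,
    features: pd.DataFrame,
    window_px: int = 2,
    score: str = "max",
    refine: bool = False,
) -> pd.DataFrame:
    """Assign each feature the depth maximizing its focus score across planes.

    The score is the window maximum ('max') or standard deviation ('std') in
    a (2w+1)^2 neighbourhood of the feature centroid; ties go to the
    shallower plane. With ``refine`` a three-point parabola through the
    winning plane and its neighbours interpolates between planes (the
    reported depth still never leaves the sampled range); without it the
    depth is exactly the winning plane's.
    """
    if score not in ("max", "std"):
        raise ValueError("score must be 'max' or 'std'")
    k, hgt, wid = stack.images.shape
    out = features.copy()
    best, scores = [], []
    for _, row in features.iterrows():
        cx, cy = int(round(row["x"])), int(round(row["y"]))
        sy = slice(max(cy - window_px, 0), min(cy + window_px + 1, hgt))
        sx = slice(max(cx - window_px, 0), min(cx + window_px + 1, wid))
        win = stack.images[:, sy, sx].reshape(k, -1)
        vals = win.max(axis=1) if score == "max" else win.std(axis=1)
        idx = int(np.argmax(vals))  # argmax returns first max: shallower plane
        depth = stack.depth_values_um[idx]
        if refine and 0 < idx < k - 1:
            y0, y1, y2 = vals[idx - 1 : idx + 2]
            denom = y0 - 2 * y1 + y2
            if denom < 0:  # proper maximum
                frac = np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)
                step = stack.depth_values_um[idx + 1] - stack.depth_values_um[idx]
                depth = depth + frac * step
        best.append(float(depth))
        scores.append(float(vals[idx]))
    out["best_depth_um"] = best
    out["focus_score"] = scores
    return out


def _poly_terms(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    cols = [x**i * y**j for i in range(degree + 1) for j in range(degree + 1 - i)]
    return np.stack(cols, axis=-1)


def fit_surface(
    features: pd.DataFrame,
    shape: tuple[int, int],
    pixel_size_um: float = 1.0,
    method: str = "polynomial",
    degree: int = 4,
    smooth_sigma_px: float = 10.0,
) -> DepthMap:
    """Fit a per-pixel depth map to scattered feature depths.

    'polynomial': least-squares 2D polynomial of the given total degree
    (default 4, matching the quartic cranial-window profile) on centred,
    scaled coordinates. 'smooth': nearest/linear scattered interpolation
    followed by median + Gaussian smoothing, for surfaces with no global
    polynomial form.
    """
    if features.empty:
        raise ValueError("no features to fit")
    x = features["x"].to_numpy(float)
    y = features["y"].to_numpy(float)
    z = features["best_depth_um"].to_numpy(float)
    hgt, wid = shape
    gy, gx = np.mgrid[0:hgt, 0:wid]

    if method == "polynomial":
        n_terms = (degree + 1) * (degree + 2) // 2
        if len(features) < n_terms:
            raise ValueError(
                f"polynomial degree {degree} needs >= {n_terms} features, "
                f"got {len(features)}"
            )
        # centre/scale for conditioning
        cx, cy = x.mean(), y.mean()
        sx = x.std() or 1.0
        sy = y.std() or 1.0
        A = _poly_terms((x - cx) / sx, (y - cy) / sy, degree)
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        resid = A @ coef - z
        rmse = float(np.sqrt(np.mean(resid**2)))
        G = _poly_terms((gx - cx) / sx, (gy - cy) / sy, degree)
        depth = G @ coef
        diag = {"method": "polynomial", "degree": degree, "rmse_um": rmse}
    elif method == "smooth":
        depth = griddata((x, y), z, (gx, gy), method="linear")
        nearest = griddata((x, y), z, (gx, gy), method="nearest")
        depth = np.where(np.isfinite(depth), depth, nearest)
        depth = median_filter(depth, size=3)
        depth = gaussian_filter(depth, smooth_sigma_px)
        at_feat = depth[np.clip(y.round().astype(int), 0, hgt - 1),
                        np.clip(x.round().astype(int), 0, wid - 1)]
        rmse = float(np.sqrt(np.mean((at_feat - z) ** 2)))
        diag = {"method": "smooth", "smooth_sigma_px": smooth_sigma_px, "rmse_um": rmse}
    else:
        raise ValueError("method must be 'polynomial' or 'smooth'")

    if not np.all(np.isfinite(depth)):
        raise ValueError("fitted depth map contains non-finite values")
    return DepthMap(depth, pixel_size_um, diag)


def discretize(depthmap: DepthMap, level_depths_um: np.ndarray) -> LevelMasks:
    """Assign every pixel to the nearest level depth; ties go shallower.

    Level depths default (at call sites) to the disc's focal-shift ladder so
    each mask maps one physical glass slot. Idempotent on already-quantized
    maps. Masks partition the frame by construction.
    """
    levels = np.sort(np.asarray(level_depths_um, dtype=float))
    if len(levels) < 1:
        raise ValueError("need at least one level")
    mids = (levels[:-1] + levels[1:]) / 2.0
    idx = np.digitize(depthmap.depth_um, mids, right=True)
    masks = np.stack([idx == k for k in range(len(levels))])
    return LevelMasks(masks, levels)


# ---------------------------------------------------------------------------
# Single-exposure patch-based depth probing
# ---------------------------------------------------------------------------

@dataclass
class PatchPlan:
    """Non-overlapping patch tiling with per-exposure probe-depth assignments.

    ``assignments[e, i, j]`` is the slot (depth index) illuminating patch
    (i, j) during exposure ``e``; -1 marks an unilluminated patch.
    """

    patch_size_px: int
    assignments: np.ndarray  # (E, Py, Px) int
    n_slots: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.assignments.ndim != 3:
            raise ValueError("assignments must be (E, Py, Px)")


def make_patch_plan(
    shape: tuple[int, int],
    patch_size_px: int,
    n_slots: int,
    n_exposures: int | None = None,
) -> PatchPlan:
    """Cyclic plan: patch (i, j) probes slot (i + j + e) mod n_slots at exposure e.

    With n_exposures = n_slots every patch sees every depth; fewer exposures
    leave some (patch, depth) pairs unprobed.
    """
    if n_exposures is None:
        n_exposures = n_slots
    py = int(np.ceil(shape[0] / patch_size_px))
    px = int(np.ceil(shape[1] / patch_size_px))
    e, i, j = np.mgrid[0:n_exposures, 0:py, 0:px]
    return PatchPlan(patch_size_px, (i + j + e) % n_slots, n_slots)


def patch_plan_masks(
    plan: PatchPlan, exposure: int, shape: tuple[int, int]
) -> np.ndarray:
    """Per-slot binary masks (K, H, W) realizing one exposure of the plan."""
    assign = plan.assignments[exposure]
    masks = np.zeros((plan.n_slots,) + tuple(shape), dtype=bool)
    p = plan.patch_size_px
    for i in range(assign.shape[0]):
        for j in range(assign.shape[1]):
            s = assign[i, j]
            if s >= 0:
                masks[s, i * p : (i + 1) * p, j * p : (j + 1) * p] = True
    return masks


def single_frame_depth(
    frames: list[np.ndarray],
    plan: PatchPlan,
    level_depths_um: np.ndarray,
) -> DepthMap:
    """Coarse depth from individually probed patches across one or few exposures.

    Each patch's focus score at its probed depth is its (max - median) pixel
    value; the patch's depth is the probe with the highest score. Patches
    probed at no depth are flagged in diagnostics and left NaN — callers may
    re-fit with :func:`fit_surface` to fill them.
    """
    level_depths_um = np.asarray(level_depths_um, dtype=float)
    if len(frames) > plan.assignments.shape[0]:
        raise ValueError("more frames than planned exposures")
    shape = frames[0].shape
    p = plan.patch_size_px
    py, px = plan.assignments.shape[1:]
    scores = np.full((py, px, plan.n_slots), -np.inf)
    for e, frame in enumerate(frames):
        for i in range(py):
            for j in range(px):
                s = plan.assignments[e, i, j]
                if s < 0:
                    continue
                patch = frame[i * p : (i + 1) * p, j * p : (j + 1) * p]
                if patch.size == 0:
                    continue
                scores[i, j, s] = float(patch.max() - np.median(patch))

    probed = np.isfinite(scores).any(axis=2) & (scores > -np.inf).any(axis=2)
    winner = scores.argmax(axis=2)
    patch_depth = level_depths_um[np.clip(winner, 0, len(level_depths_um) - 1)]
    patch_depth = np.where(probed, patch_depth, np.nan)

    depth = np.full(shape, np.nan)
    for i in range(py):
        for j in range(px):
            depth[i * p : (i + 1) * p, j * p : (j + 1) * p] = patch_depth[i, j]
    n_missing = int(np.sum(~probed))
    if n_missing:
        warnings.warn(f"{n_missing} patches had no probe coverage", stacklevel=2)
    return DepthMap(
        depth,
        diagnostics={
            "method": "patch",
            "patch_size_px": p,
            "unestimated_patches": n_missing,
            "patch_depths_um": patch_depth,
        },
    )


def estimate_surface(
    stack: FocalStack,
    level_depths_um: np.ndarray,
    pixel_size_um: float = 1.0,
    h: float | None = None,
    method: str = "polynomial",
    degree: int = 4,
    detect_on: str = "projection",
) -> tuple[pd.DataFrame, DepthMap, LevelMasks]:
    """End-to-end: detect features, assign depths, fit the surface, cut level masks."""
    image = stack.images.max(axis=0) if detect_on == "projection" else stack.images[0]
    feats = detect_features(image, h=h)
    if feats.empty:
        raise ValueError("no features detected; lower h or add sources")
    feats = assign_depths(stack, feats, refine=True)
    depthmap = fit_surface(
        feats, stack.images.shape[1:], pixel_size_um, method=method, degree=degree
    )
    masks = discretize(depthmap, level_depths_um)
    return feats, depthmap, masks
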