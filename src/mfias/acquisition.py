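"""Simulate one multifocal exposure: a full disc rotation of mask-gated layers.

During each camera exposure the spinning disc completes one rotation; while
glass slot ``k`` sits in the detection path the DMD shows mask ``k``, so the
camera integrates in-focus contributions from every depth layer. The
conventional baseline is a single fixed-focus full-field exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .optics import GlassSlab, OpticalConfig, focal_shift, glass_interval, photon_budget
from .phantom import Emitter, NoiseModel, _emitter_patch, render_plane

__all__ = [
    "DiscSpec",
    "IlluminationPlan",
    "AcquiredFrame",
    "design_disc",
    "paper_disc",
    "simulate_mfias_frame",
    "simulate_conventional_frame",
    "simulate_mfias_movie",
    "simulate_conventional_movie",
    "sync_schedule",
    "dual_plane_mode",
]


@dataclass
class DiscSpec:
    """Ordered glass slots of the spinning disc (thickness 0 = open slot)."""

    slots: tuple[GlassSlab, ...]
    rotation_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if not self.slots:
            raise ValueError("disc needs at least one slot")
        self.slots = tuple(sorted(self.slots, key=lambda s: s.thickness_mm))

    @property
    def num_layers(self) -> int:
        return len(self.slots)

    def focal_depths_um(self, cfg: OpticalConfig | None = None) -> np.ndarray:
        return np.array([focal_shift(s, cfg) for s in self.slots])


def design_disc(
    n_layers: int = 10,
    half_defocus_um: float = 25.0,
    refractive_index: float = 1.5,
    rotation_rate_hz: float = 10.0,
    include_open_slot: bool = True,
) -> DiscSpec:
    """Disc following the design ladder: thickness step 2nL/(n-1), focal step 2L.

    With the defaults this is an open slot plus nine glasses 0.15-1.35 mm,
    spanning the 450 um depth of field in 50 um focal steps.
    """
    step_mm = glass_interval(half_defocus_um, refractive_index) / 1000.0
    start = 0 if include_open_slot else 1
    slots = tuple(
        GlassSlab(step_mm * i, refractive_index)
        for i in range(start, start + n_layers)
    )
    return DiscSpec(slots, rotation_rate_hz)


def paper_disc(refractive_index: float = 1.52, rotation_rate_hz: float = 10.0) -> DiscSpec:
    """The hardware list: an open slot plus nine glasses 0.17-1.8 mm."""
    thicknesses = [0.0] + list(np.linspace(0.17, 1.8, 9))
    return DiscSpec(
        tuple(GlassSlab(t, refractive_index) for t in thicknesses), rotation_rate_hz
    )


@dataclass
class IlluminationPlan:
    """Per-slot binary masks on the camera grid plus per-slot exposure fractions."""

    masks: np.ndarray  # (K, H, W) bool
    exposure_fractions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (K, H, W)")
        k = self.masks.shape[0]
        if self.exposure_fractions is None:
            self.exposure_fractions = np.full(k, 1.0 / k)
        self.exposure_fractions = np.asarray(self.exposure_fractions, dtype=float)
        if len(self.exposure_fractions) != k:
            raise ValueError("one exposure fraction per mask required")
        if not np.isclose(self.exposure_fractions.sum(), 1.0):
            raise ValueError("exposure fractions must sum to 1")

    @classmethod
    def full_field(cls, n_slots: int, shape: tuple[int, int]) -> "IlluminationPlan":
        return cls(np.ones((n_slots,) + shape, dtype=bool))


@dataclass
class AcquiredFrame:
    """One integrated camera frame with acquisition metadata."""

    pixels: np.ndarray
    focal_depths_um: tuple[float, ...]
    frame_index: int = 0
    mode: str = "mfias"
    plane_tag: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.pixels < 0) and self.mode == "noiseless":
            raise ValueError("noiseless frame must be non-negative")


def simulate_mfias_frame(
    emitters: Sequence[Emitter],
    disc: DiscSpec,
    plan: IlluminationPlan,
    cfg: OpticalConfig,
    shape: tuple[int, int] = (256, 256),
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    brightness_scale: Sequence[float] | None = None,
) -> AcquiredFrame:
    """Integrate mask-gated renders from every disc layer into one exposure.

    Excitation power is raised by the layer count N (photon budget) while
    each slot is active for its exposure fraction (1/N by default), so with
    all-ones masks the noiseless frame equals the plain sum of the focal
    stack, and a correctly masked in-focus source keeps its conventional
    in-focus photon yield.
    """
    if plan.masks.shape[0] != disc.num_layers:
        raise ValueError(
            f"plan has {plan.masks.shape[0]} masks but disc has {disc.num_layers} slots"
        )
    if plan.masks.shape[1:] != tuple(shape):
        raise ValueError("mask shape must match the camera frame shape")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    power = photon_budget(disc.num_layers)["illumination_power_factor"]
    depths = disc.focal_depths_um(cfg)
    frame = np.zeros(shape)
    for k, z in enumerate(depths):
        weight = power * plan.exposure_fractions[k]
        if not plan.masks[k].any():
            continue
        img = render_plane(emitters, cfg, z, shape, brightness_scale)
        frame += weight * np.where(plan.masks[k], img, 0.0)
    if noise is not None:
        frame = noise.apply(frame, rng)
    return AcquiredFrame(frame, tuple(depths), mode="mfias")


def simulate_conventional_frame(
    emitters: Sequence[Emitter],
    focal_plane_um: float,
    cfg: OpticalConfig,
    shape: tuple[int, int] = (256, 256),
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    brightness_scale: Sequence[float] | None = None,
) -> AcquiredFrame:
    """Single-plane widefield exposure, full-field illumination at base power."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    frame = render_plane(emitters, cfg, focal_plane_um, shape, brightness_scale)
    if noise is not None:
        frame = noise.apply(frame, rng)
    return AcquiredFrame(frame, (focal_plane_um,), mode="conventional")


def _effective_patches(
    emitters: Sequence[Emitter],
    disc: DiscSpec,
    plan: IlluminationPlan,
    cfg: OpticalConfig,
    shape: tuple[int, int],
) -> list:
    """Per-emitter coded-exposure footprint: because the level masks partition
    the frame, each pixel sees exactly one layer, so an emitter's integrated
    contribution is its per-slot patch mosaicked by the masks (at unit
    exposure weighting, i.e. power factor N x fraction 1/N)."""
    power = photon_budget(disc.num_layers)["illumination_power_factor"]
    depths = disc.focal_depths_um(cfg)
    out = []
    for e in emitters:
        acc = None
        for k, z in enumerate(depths):
            weight = power * plan.exposure_fractions[k]
            res = _emitter_patch(e, cfg, z, shape)
            if res is None:
                continue
            sy, sx, patch = res
            masked = weight * np.where(plan.masks[k][sy, sx], patch, 0.0)
            if acc is None:
                acc = {}
            key = (sy.start, sy.stop, sx.start, sx.stop)
            if key in acc:
                acc[key] += masked
            else:
                acc[key] = masked
        out.append(acc)
    return out


def simulate_mfias_movie(
    emitters: Sequence[Emitter],
    values: np.ndarray,
    disc: DiscSpec,
    plan: IlluminationPlan,
    cfg: OpticalConfig,
    shape: tuple[int, int] = (256, 256),
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Movie (T, H, W) of coded exposures with per-frame emitter brightness.

    ``values`` has shape (n_emitters, T); each frame is one full disc
    rotation. Per-emitter footprints are precomputed once (the specimen is
    static within and across exposures, only brightness varies).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != len(emitters):
        raise ValueError("values must be (n_emitters, T)")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    patches = _effective_patches(emitters, disc, plan, cfg, shape)
    t_len = values.shape[1]
    movie = np.zeros((t_len,) + tuple(shape))
    for t in range(t_len):
        frame = movie[t]
        for i, acc in enumerate(patches):
            if not acc:
                continue
            for (ys, ye, xs, xe), patch in acc.items():
                frame[ys:ye, xs:xe] += values[i, t] * patch
        if noise is not None:
            movie[t] = noise.apply(frame, rng)
    return movie


def simulate_conventional_movie(
    emitters: Sequence[Emitter],
    values: np.ndarray,
    focal_plane_um: float,
    cfg: OpticalConfig,
    shape: tuple[int, int] = (256, 256),
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Fixed-focus widefield movie with per-frame emitter brightness."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != len(emitters):
        raise ValueError("values must be (n_emitters, T)")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    patches = [
        _emitter_patch(e, cfg, focal_plane_um, shape) for e in emitters
    ]
    t_len = values.shape[1]
    movie = np.zeros((t_len,) + tuple(shape))
    for t in range(t_len):
        frame = movie[t]
        for i, res in enumerate(patches):
            if res is None:
                continue
            sy, sx, patch = res
            frame[sy, sx] += values[i, t] * patch
        if noise is not None:
            movie[t] = noise.apply(frame, rng)
    return movie


def sync_schedule(
    disc: DiscSpec,
    frame_rate_hz: float,
    cfg: OpticalConfig | None = None,
    frame_shape: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Timing bookkeeping: one disc rotation per exposure, N DMD patterns per rotation.

    Returns a per-slot table; summary rates live in ``DataFrame.attrs``:
    required rotation rate = frame rate (rev/s), DMD pattern rate = N * frame
    rate, and voxel throughput = H * W * N * fps when a frame shape is given.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    n = disc.num_layers
    period = 1.0 / frame_rate_hz
    depths = disc.focal_depths_um(cfg)
    table = pd.DataFrame(
        {
            "slot": np.arange(n),
            "thickness_mm": [s.thickness_mm for s in disc.slots],
            "focal_depth_um": depths,
            "t_start_s": np.arange(n) * period / n,
            "t_end_s": (np.arange(n) + 1) * period / n,
            "dmd_pattern": np.arange(n),
        }
    )
    table.attrs["rotation_rate_hz"] = frame_rate_hz
    table.attrs["dmd_pattern_rate_hz"] = n * frame_rate_hz
    if frame_shape is not None:
        table.attrs["voxel_throughput_per_s"] = (
            frame_shape[0] * frame_shape[1] * n * frame_rate_hz
        )
    return table


def dual_plane_mode(
    emitters: Sequence[Emitter],
    slots: Sequence[GlassSlab],
    cfg: OpticalConfig,
    n_frames: int,
    frame_rate_hz: float,
    shape: tuple[int, int] = (128, 128),
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[AcquiredFrame], float]:
    """Interleaved multi-depth movie: frame i images slots[i % P], full field.

    Volume rate = frame_rate / number of planes (e.g. two planes at 280 fps
    give 140 volumes/s).
    """
    if not slots:
        raise ValueError("at least one slot required")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    p = len(slots)
    frames = []
    for i in range(n_frames):
        slab = slots[i % p]
        z = focal_shift(slab, cfg)
        img = render_plane(emitters, cfg, z, shape)
        if noise is not None:
            img = noise.apply(img, rng)
        frames.append(
            AcquiredFrame(
                img, (z,), frame_index=i, mode="dual_plane", plane_tag=i % p
            )
        )
    return frames, frame_rate_hz / p
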