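"""Shared I/O: multi-page grayscale TIFF stacks, CSV tables, run configs."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .optics import OpticalConfig

__all__ = [
    "read_stack",
    "write_stack",
    "RunConfig",
    "DiscConfig",
    "PhantomConfig",
    "SurfaceConfig",
    "MetricsConfig",
]

_ALLOWED_DTYPES = (np.uint8, np.uint16, np.float32)


def write_stack(path: str | Path, stack: np.ndarray) -> Path:
    """Write a (Z, H, W) or (H, W) grayscale stack as multi-page TIFF.

    Integer data round-trips bit-exactly; floats are stored as 32-bit.
    """
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("stack must be 2D or 3D grayscale")
    if stack.dtype.kind == "f":
        stack = stack.astype(np.float32)
    elif stack.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        if stack.min() < 0 or stack.max() > np.iinfo(np.uint16).max:
            raise ValueError("integer stack out of uint16 range; convert first")
        stack = stack.astype(np.uint16)
    tifffile.imwrite(path, stack, photometric="minisblack")
    return path


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as (Z, H, W), page order preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        axes = tif.series[0].axes
        if "S" in axes:  # per-pixel samples: RGB/multichannel
            raise ValueError(f"{path} is RGB/multichannel; only grayscale stacks are supported")
        arr = tif.series[0].asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path} is not a grayscale stack (shape {arr.shape})")
    return arr


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class DiscConfig:
    n_layers: int = 10
    half_defocus_um: float = 25.0
    refractive_index: float = 1.5
    rotation_rate_hz: float = 10.0


@dataclass
class PhantomConfig:
    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 2.0
    surface_scale: float = 1.0
    n_beads: int = 60
    n_somas: int = 20
    bead_brightness: float = 4000.0
    soma_brightness: float = 3000.0
    n_frames: int = 60
    frame_rate_hz: float = 10.0
    spike_rate_hz: float = 0.3
    noise_poisson: bool = True
    noise_read_sigma: float = 2.0
    noise_background: float = 10.0


@dataclass
class SurfaceConfig:
    method: str = "polynomial"
    degree: int = 4
    h: float | None = None
    n_levels: int = 10


@dataclass
class MetricsConfig:
    psnr_filter_sigma_px: float = 10.0
    f0_percentile: float = 10.0


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    disc: DiscConfig = field(default_factory=DiscConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    seed: int = 0
    output_dir: str = "mfias_run"
    verbosity: str = "info"

    _GROUPS = {
        "optics": OpticalConfig,
        "disc": DiscConfig,
        "phantom": PhantomConfig,
        "surface": SurfaceConfig,
        "metrics": MetricsConfig,
    }

    def to_dict(self) -> dict:
        d = {}
        for name in self._GROUPS:
            sub = dataclasses.asdict(getattr(self, name))
            for key, val in sub.items():
                if isinstance(val, tuple):
                    sub[key] = list(val)
            d[name] = sub
        d.update(seed=self.seed, output_dir=self.output_dir, verbosity=self.verbosity)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for name, group_cls in cls._GROUPS.items():
            if name not in d:
                raise ValueError(f"config is missing required parameter group '{name}'")
            sub = dict(d[name])
            known = {f.name for f in dataclasses.fields(group_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown field(s) in '{name}': {sorted(unknown)}")
            for key, val in sub.items():
                if isinstance(val, list):
                    sub[key] = tuple(val)
            kwargs[name] = group_cls(**sub)
        for scalar in ("seed", "output_dir", "verbosity"):
            if scalar in d:
                kwargs[scalar] = d[scalar]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        return cls.from_dict(data)
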