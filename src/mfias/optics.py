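"""Plane-parallel-slab focal optics, scalar Debye PSF simulation and design calculators.

Physical model
--------------
A glass slab of thickness ``d`` and refractive index ``n`` inserted in a
telecentric detection path displaces the focal plane *away* from the lens by

    dz = d (n - n_medium) / n          (= d (n - 1)/n in air)

and adds fourth-order spherical aberration with wavefront error

    W(rho) = (n^2 - 1) / (8 n^3) * d * theta0^4 * (rho/rho_max)^4

where ``theta0 = arcsin(NA / n_medium)`` is the marginal-ray half-angle.
The point spread function is computed with the scalar Debye pupil integral,
which is adequate for the NA <= 0.3 regimes this package targets (the
high-NA 0.95 mode inherits the same scalar model with reduced accuracy).

Unit conventions: slab thickness in millimetres, every other length in
micrometres unless a ``_mm`` suffix says otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import j0

__all__ = [
    "OpticalConfig",
    "GlassSlab",
    "PSFGrid",
    "DesignSpec",
    "focal_shift",
    "slab_spherical_aberration",
    "debye_radial_intensity",
    "debye_axial_intensity",
    "compute_psf",
    "best_focus_index",
    "strehl_ratio",
    "enclosed_energy",
    "fwhm",
    "glass_interval",
    "num_layers",
    "relay_shift_scaling",
    "multi_disc_positions",
    "photon_budget",
    "design_system",
    "min_disc_radius",
]

MM_TO_UM = 1000.0


@dataclass(frozen=True)
class OpticalConfig:
    """Detection-path parameters.

    Parameters
    ----------
    numerical_aperture : float
        Objective NA, must be < ``medium_index``.
    wavelength_um : float
        Emission wavelength in micrometres.
    magnification : float
        System magnification M (> 0); a slab in image space produces a
        sample-space focal shift smaller by 1/M^2.
    pixel_size_sample_um : float
        Camera pixel back-projected to sample space.
    medium_index : float
        Refractive index of the immersion medium (1.0 = air).
    """

    numerical_aperture: float = 0.3
    wavelength_um: float = 0.5
    magnification: float = 1.0
    pixel_size_sample_um: float = 0.8
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture < self.medium_index:
            raise ValueError(
                "numerical_aperture must lie in (0, medium_index); got "
                f"NA={self.numerical_aperture}, medium_index={self.medium_index}"
            )
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")

    @property
    def half_angle_rad(self) -> float:
        """Marginal-ray half-angle theta0 = arcsin(NA / n_medium), radians."""
        return float(np.arcsin(self.numerical_aperture / self.medium_index))


@dataclass(frozen=True)
class GlassSlab:
    """A plane-parallel glass plate; ``thickness_mm = 0`` models the open slot."""

    thickness_mm: float
    refractive_index: float = 1.5

    def __post_init__(self) -> None:
        if self.thickness_mm < 0:
            raise ValueError("thickness_mm must be >= 0")
        if self.refractive_index <= 1:
            raise ValueError("refractive_index must exceed 1 (denser than air)")


@dataclass
class PSFGrid:
    """3D sampled PSF intensity with physical voxel spacing.

    ``intensity`` has shape (Z, Y, X); ``z_um`` holds the sample-space axial
    coordinate of each plane (0 = unaberrated, slab-free focus).
    """

    intensity: np.ndarray
    lateral_spacing_um: float
    z_um: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.z_um = np.asarray(self.z_um, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3D (Z, Y, X)")
        if len(self.z_um) != self.intensity.shape[0]:
            raise ValueError("z_um length must match number of planes")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def z_origin_um(self) -> float:
        return float(self.z_um[0])

    @property
    def axial_spacing_um(self) -> float:
        dz = np.diff(self.z_um)
        if len(dz) and not np.allclose(dz, dz[0]):
            raise ValueError("axial spacing is non-uniform")
        return float(dz[0]) if len(dz) else 0.0


# ---------------------------------------------------------------------------
# Slab formulas and design calculators
# ---------------------------------------------------------------------------

def focal_shift(slab: GlassSlab, cfg: OpticalConfig | None = None) -> float:
    """Sample-space focal displacement (um, away from the lens) of a slab.

    dz = d (n - n_medium)/n; exactly linear in thickness and zero for the
    open slot.
    """
    n_med = cfg.medium_index if cfg is not None else 1.0
    n = slab.refractive_index
    return slab.thickness_mm * MM_TO_UM * (n - n_med) / n


def slab_spherical_aberration(slab: GlassSlab, cfg: OpticalConfig) -> float:
    """Peak fourth-order wavefront error W040 (um) of the slab.

    W040 = (n^2 - 1)/(8 n^3) * d * theta0^4, the marginal-ray extra path of a
    plane-parallel plate; the aberration phase applied to the pupil is
    W040 * (rho/rho_max)^4.
    """
    n = slab.refractive_index
    theta0 = cfg.half_angle_rad
    coeff = (n**2 - 1.0) / (8.0 * n**3)
    return coeff * slab.thickness_mm * MM_TO_UM * theta0**4


def glass_interval(half_defocus_um: float, refractive_index: float) -> float:
    """Glass-thickness increment 2 n L / (n - 1) (um) producing a 2L focal step."""
    if half_defocus_um <= 0:
        raise ValueError("half_defocus_um must be positive")
    n = refractive_index
    if n <= 1:
        raise ValueError("refractive_index must exceed 1")
    return 2.0 * n * half_defocus_um / (n - 1.0)


def num_layers(dof_um: float, half_defocus_um: float) -> int:
    """Layer count N = DOF/(2L) + 1, rounded to nearest with a warning."""
    if dof_um < 0 or half_defocus_um <= 0:
        raise ValueError("DOF must be >= 0 and L > 0")
    exact = dof_um / (2.0 * half_defocus_um) + 1.0
    n = int(round(exact))
    if abs(exact - n) > 1e-9:
        warnings.warn(
            f"DOF/(2L) + 1 = {exact:.4f} is not integral; rounding to {n}",
            stacklevel=2,
        )
    return n


def relay_shift_scaling(magnification: float) -> float:
    """Image-space-to-sample-space focal-shift factor 1/M^2.

    A slab inserted in image space shifts the sample-space focus by
    ``focal_shift(slab) * relay_shift_scaling(M)``; equivalently, moving the
    disc to image space multiplies the addressable focal range by M^2.
    """
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    return 1.0 / magnification**2


def multi_disc_positions(
    m: int,
    n: int,
    k: int,
    base_step_um: float = 1.0,
) -> tuple[int, np.ndarray]:
    """Focal ladder of a nested three-disc (hour/minute/second) stack.

    The finest disc steps by ``base_step_um``; each coarser disc's increment
    equals the full span of the next finer one, so the m*n*k combinations
    tile a uniform ladder of distinct positions.

    Returns (count, sorted positions in um).
    """
    if min(m, n, k) < 1:
        raise ValueError("disc slot counts must be >= 1")
    second = np.arange(k) * base_step_um
    minute = np.arange(n) * (k * base_step_um)
    hour = np.arange(m) * (n * k * base_step_um)
    pos = (hour[:, None, None] + minute[None, :, None] + second[None, None, :]).ravel()
    pos = np.sort(pos)
    return m * n * k, pos


def photon_budget(n_layers: int) -> dict[str, float]:
    """Excitation-power and photodose bookkeeping for N-layer selective illumination.

    Power must rise by N to keep per-layer intensity at the conventional
    level; each specimen point is illuminated 1/N of the time, so the dose
    relative to scanning all N layers with full-field light is 1/N.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    return {
        "illumination_power_factor": float(n_layers),
        "dose_vs_full_3d_scan": 1.0 / n_layers,
    }


def min_disc_radius(
    aperture_mm: float, num_slots: int, clearance: float = 1.1
) -> float:
    """Approximate minimum spinning-disc radius (mm) packing ``num_slots``
    circular apertures of diameter ``aperture_mm`` around the circumference.

    This packing rule is an approximation chosen here; adjacent aperture
    centres sit ``clearance * aperture`` apart on the slot circle, and the
    disc must extend half an aperture beyond the slot circle.
    """
    if aperture_mm <= 0 or num_slots < 1:
        raise ValueError("aperture_mm must be > 0 and num_slots >= 1")
    if num_slots == 1:
        return clearance * aperture_mm
    slot_circle = clearance * aperture_mm / (2.0 * np.sin(np.pi / num_slots))
    return float(slot_circle + aperture_mm / 2.0)


@dataclass(frozen=True)
class DesignSpec:
    """System design summary derived from DOF, per-layer half-range and glass index."""

    depth_of_field_um: float
    half_defocus_um: float
    num_layers: int
    glass_interval_um: float
    aperture_diameter_mm: float
    num_slots: int
    min_disc_radius_mm: float
    illumination_power_factor: float
    dose_vs_full_3d_scan: float


def design_system(
    dof_um: float,
    half_defocus_um: float,
    refractive_index: float = 1.5,
    aperture_mm: float = 40.0,
) -> DesignSpec:
    """Run every design calculator for a target DOF and per-layer half-range L."""
    n_lay = num_layers(dof_um, half_defocus_um)
    interval = glass_interval(half_defocus_um, refractive_index)
    budget = photon_budget(n_lay)
    return DesignSpec(
        depth_of_field_um=dof_um,
        half_defocus_um=half_defocus_um,
        num_layers=n_lay,
        glass_interval_um=interval,
        aperture_diameter_mm=aperture_mm,
        num_slots=n_lay,
        min_disc_radius_mm=min_disc_radius(aperture_mm, n_lay),
        illumination_power_factor=budget["illumination_power_factor"],
        dose_vs_full_3d_scan=budget["dose_vs_full_3d_scan"],
    )


# ---------------------------------------------------------------------------
# Scalar Debye PSF
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _gauss_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def _pupil(cfg: OpticalConfig, pupil_samples: int):
    """Gauss-Legendre nodes over the aperture half-angle."""
    theta0 = cfg.half_angle_rad
    x, w = _gauss_nodes(pupil_samples)
    theta = 0.5 * theta0 * (x + 1.0)
    weight = 0.5 * theta0 * w
    return theta, weight, theta0


def debye_radial_intensity(
    cfg: OpticalConfig,
    slab: GlassSlab | None,
    r_um: np.ndarray,
    z_um: np.ndarray,
    pupil_samples: int = 256,
) -> np.ndarray:
    """Scalar Debye intensity I(z, r) on a radial grid.

    ``z_um`` is measured from the slab-free focus; the slab's bulk focal
    shift enters as a defocus offset and its spherical aberration as the
    quartic pupil phase. The integrand carries the sin(theta) aperture
    weight and sqrt(cos(theta)) apodization.
    """
    r_um = np.atleast_1d(np.asarray(r_um, dtype=float))
    z_um = np.atleast_1d(np.asarray(z_um, dtype=float))
    theta, weight, theta0 = _pupil(cfg, pupil_samples)
    k = 2.0 * np.pi * cfg.medium_index / cfg.wavelength_um
    st, ct = np.sin(theta), np.cos(theta)
    apod = np.sqrt(ct)

    shift = focal_shift(slab, cfg) if slab is not None else 0.0
    w040 = slab_spherical_aberration(slab, cfg) if slab is not None else 0.0
    aberr = w040 * (st / np.sin(theta0)) ** 4

    bessel = j0(k * np.outer(r_um, st))  # (R, P)
    base = weight * st * apod
    out = np.empty((len(z_um), len(r_um)))
    for i, z in enumerate(z_um):
        phase = np.exp(1j * k * ((z - shift) * ct + aberr))
        out[i] = np.abs(bessel @ (base * phase)) ** 2
    return out


def debye_axial_intensity(
    cfg: OpticalConfig,
    slab: GlassSlab | None,
    z_um: np.ndarray,
    pupil_samples: int = 256,
) -> np.ndarray:
    """On-axis intensity I(z, r=0)."""
    return debye_radial_intensity(cfg, slab, np.zeros(1), z_um, pupil_samples)[:, 0]


def compute_psf(
    cfg: OpticalConfig,
    slab: GlassSlab | None = None,
    z_planes_um: np.ndarray | None = None,
    lateral_extent_um: float = 40.0,
    lateral_spacing_um: float | None = None,
    pupil_samples: int = 256,
    require_focus_in_range: bool = True,
) -> PSFGrid:
    """Sample the (circularly symmetric) Debye PSF onto a 3D grid.

    ``z_planes_um`` defaults to a +/-30 um window around the slab's shifted
    focus. Default lateral spacing is lambda/(8 NA) so sidelobes and the
    5 um enclosed-energy circle are well resolved; extent >= 40 um.
    """
    if z_planes_um is None:
        centre = focal_shift(slab, cfg) if slab is not None else 0.0
        z_planes_um = centre + np.linspace(-30.0, 30.0, 121)
    z_planes_um = np.asarray(z_planes_um, dtype=float)
    if np.any(np.diff(z_planes_um) <= 0):
        raise ValueError("z_planes_um must be strictly increasing")
    if lateral_spacing_um is None:
        lateral_spacing_um = cfg.wavelength_um / (8.0 * cfg.numerical_aperture)

    if require_focus_in_range and slab is not None:
        shift = focal_shift(slab, cfg)
        if not (z_planes_um[0] <= shift <= z_planes_um[-1]):
            warnings.warn(
                f"shifted focus at {shift:.1f} um lies outside the sampled z "
                "range; best-focus metrics will be unreliable",
                stacklevel=2,
            )

    half = int(np.ceil(lateral_extent_um / 2.0 / lateral_spacing_um))
    ax = np.arange(-half, half + 1) * lateral_spacing_um
    xx, yy = np.meshgrid(ax, ax)
    rr = np.hypot(xx, yy)

    r_grid = np.arange(0.0, rr.max() + 2 * lateral_spacing_um, lateral_spacing_um / 4.0)
    radial = debye_radial_intensity(cfg, slab, r_grid, z_planes_um, pupil_samples)
    planes = np.empty((len(z_planes_um),) + rr.shape)
    flat_r = rr.ravel()
    for i in range(len(z_planes_um)):
        planes[i] = np.interp(flat_r, r_grid, radial[i]).reshape(rr.shape)
    return PSFGrid(planes, lateral_spacing_um, z_planes_um)


# ---------------------------------------------------------------------------
# PSF quality metrics
# ---------------------------------------------------------------------------

def best_focus_index(psf: PSFGrid) -> int:
    """Index of the axial plane with the highest peak intensity (ties -> shallower)."""
    peaks = psf.intensity.reshape(psf.intensity.shape[0], -1).max(axis=1)
    return int(np.argmax(peaks))


def strehl_ratio(psf: PSFGrid, reference: PSFGrid) -> float:
    """Peak-intensity ratio of an aberrated PSF to the ideal reference.

    Each volume is refocused to its own best-focus plane and normalized to
    that plane's total energy before the peaks are compared, so Strehl of a
    PSF against itself is exactly 1.
    """
    if not np.isclose(psf.lateral_spacing_um, reference.lateral_spacing_um):
        raise ValueError("PSF grids must share lateral spacing")

    def _norm_peak(p: PSFGrid) -> float:
        plane = p.intensity[best_focus_index(p)]
        total = plane.sum()
        if total <= 0:
            raise ValueError("best-focus plane has zero energy")
        return float(plane.max() / total)

    return _norm_peak(psf) / _norm_peak(reference)


def enclosed_energy(
    psf: PSFGrid, radius_um: float, plane: int | None = None
) -> float:
    """Fraction of a plane's energy inside a circle of ``radius_um`` about the centroid.

    ``plane`` defaults to the best-focus plane. The circle must fit within
    the lateral grid.
    """
    if plane is None:
        plane = best_focus_index(psf)
    img = psf.intensity[plane]
    total = img.sum()
    if total <= 0:
        raise ValueError("plane has zero energy")
    dy, dx = np.indices(img.shape)
    cy = (dy * img).sum() / total
    cx = (dx * img).sum() / total
    s = psf.lateral_spacing_um
    max_fit = min(cy, cx, img.shape[0] - 1 - cy, img.shape[1] - 1 - cx) * s
    if radius_um > max_fit:
        raise ValueError(
            f"radius {radius_um} um exceeds the {max_fit:.1f} um that fits in the grid"
        )
    rr = np.hypot((dy - cy) * s, (dx - cx) * s)
    return float(img[rr <= radius_um].sum() / total)


def fwhm(profile: np.ndarray, spacing_um: float, background: float | None = None) -> float:
    """Linear-interpolated full width at half maximum of a single-peaked profile.

    ``background`` defaults to the profile minimum; the half level is midway
    between background and peak. A peak touching the boundary is rejected.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or len(profile) < 3:
        raise ValueError("profile must be 1D with >= 3 samples")
    if np.any(profile < 0):
        raise ValueError("profile must be non-negative")
    ipk = int(np.argmax(profile))
    if ipk in (0, len(profile) - 1):
        raise ValueError("peak lies on the profile boundary; widen the window")
    bg = float(profile.min()) if background is None else float(background)
    half = bg + 0.5 * (profile[ipk] - bg)

    def _cross(idx_range) -> float:
        prev = ipk
        for i in idx_range:
            if profile[i] < half:
                frac = (profile[prev] - half) / (profile[prev] - profile[i])
                return prev + frac * (i - prev)
            prev = i
        raise ValueError("profile does not fall below half maximum on one side")

    left = _cross(range(ipk - 1, -1, -1))
    right = _cross(range(ipk + 1, len(profile)))
    return float((right - left) * spacing_um)
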