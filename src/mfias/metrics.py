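"""Quantitative readouts on acquired movies: PSNR, soma detection, traces, OSI.

PSNR here is the peak value of a light source divided by the temporal
fluctuation of the background, both measured on the sigma = 10 px
Gaussian-filtered movie; a source buried in noise reads near the unit
baseline. Soma detection uses a separable spatio-temporal band-pass
(difference of Gaussians at sigma 2/15 px in space and 10/30 frames in time)
followed by peak finding on the temporal-standard-deviation projection.
Calcium traces are centre-pixel intensities minus a sigma = 15 px Gaussian
background, normalized to a low-percentile baseline F0. Orientation
selectivity follows OSI = (r_pref - r_orth)/(r_pref + r_orth) on
trial-averaged responses to eight drifting-grating directions 45 deg apart,
gated by a one-way ANOVA (P < 0.01) against blank periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit
from scipy.stats import f_oneway
from skimage.feature import peak_local_max

__all__ = [
    "SourceTrace",
    "PSNRReport",
    "TuningCurve",
    "OSIResult",
    "psnr",
    "detect_somas",
    "extract_trace",
    "osi",
    "trimmed_std",
    "fit_double_gaussian",
]


@dataclass
class SourceTrace:
    """Per-frame intensity readout of one source."""

    x: float
    y: float
    raw: np.ndarray
    background: np.ndarray
    dff: np.ndarray
    f0: float


@dataclass
class PSNRReport:
    """Per-source peak over pooled background noise sigma."""

    table: pd.DataFrame  # columns: x, y, peak, psnr
    noise_sigma: float


@dataclass
class TuningCurve:
    """Trial responses to 8 grating directions (45 deg apart) plus blanks."""

    orientations_deg: np.ndarray  # (8,)
    trial_responses: np.ndarray  # (8, n_trials) mean dF/F during stimulus
    blank_responses: np.ndarray  # (n_blank,)

    def __post_init__(self) -> None:
        self.orientations_deg = np.asarray(self.orientations_deg, dtype=float)
        self.trial_responses = np.asarray(self.trial_responses, dtype=float)
        self.blank_responses = np.asarray(self.blank_responses, dtype=float)
        expected = np.arange(8) * 45.0
        if not np.array_equal(np.sort(self.orientations_deg), expected):
            raise ValueError("orientations must be the 8 angles 0,45,...,315 deg")
        if self.trial_responses.shape[0] != 8:
            raise ValueError("trial_responses must be (8, n_trials)")
        if self.trial_responses.shape[1] < 2:
            raise ValueError("need >= 2 trials per orientation")

    def mean_responses(self) -> np.ndarray:
        return self.trial_responses.mean(axis=1)


@dataclass
class OSIResult:
    osi: float
    responsive: bool
    anova_p: float
    theta_pref_deg: float
    r_pref: float
    r_orth: float
    fit_params: dict | None = None


# ---------------------------------------------------------------------------
# PSNR
# ---------------------------------------------------------------------------

def psnr(
    movie: np.ndarray,
    sources: pd.DataFrame,
    filter_sigma_px: float = 10.0,
    source_radius_px: int = 8,
    background_exclusion_radius_px: int | None = None,
) -> PSNRReport:
    """Peak-to-noise ratio per source on the Gaussian-filtered movie.

    The movie is filtered laterally (sigma = 10 px) and its per-pixel
    temporal median removed. A source's peak is its window maximum over all
    frames; the noise sigma is the median, over pixels farther than two
    source radii from any source, of the per-pixel temporal standard
    deviation. Adding a static background image changes nothing.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be (T, H, W) with >= 2 frames")
    if background_exclusion_radius_px is None:
        background_exclusion_radius_px = 2 * source_radius_px
    filt = gaussian_filter(movie, (0, filter_sigma_px, filter_sigma_px))
    filt = filt - np.median(filt, axis=0, keepdims=True)

    t, h, w = movie.shape
    yy, xx = np.mgrid[0:h, 0:w]
    bg = np.ones((h, w), dtype=bool)
    rows = []
    for _, s in sources.iterrows():
        bg &= np.hypot(xx - s["x"], yy - s["y"]) > background_exclusion_radius_px
    sigma_map = filt.std(axis=0)
    if not bg.any():
        raise ValueError("no background pixels left; shrink the exclusion radius")
    noise_sigma = float(np.median(sigma_map[bg]))
    if noise_sigma <= 0:
        warnings.warn("zero background fluctuation: PSNR undefined", stacklevel=2)
        noise_sigma = np.nan

    r = source_radius_px
    for _, s in sources.iterrows():
        cx, cy = int(round(s["x"])), int(round(s["y"]))
        sy = slice(max(cy - r, 0), min(cy + r + 1, h))
        sx = slice(max(cx - r, 0), min(cx + r + 1, w))
        peak = float(filt[:, sy, sx].max())
        rows.append({"x": s["x"], "y": s["y"], "peak": peak, "psnr": peak / noise_sigma})
    return PSNRReport(pd.DataFrame(rows, columns=["x", "y", "peak", "psnr"]), noise_sigma)


# ---------------------------------------------------------------------------
# Soma detection and trace extraction
# ---------------------------------------------------------------------------

def detect_somas(
    movie: np.ndarray,
    space_sigmas_px: tuple[float, float] = (2.0, 15.0),
    time_sigmas_frames: tuple[float, float] = (10.0, 30.0),
    min_distance_px: int = 10,
    threshold_rel: float = 0.2,
) -> pd.DataFrame:
    """Locate blinking soma-like sources in a (T, H, W) movie.

    A separable spatio-temporal band-pass — the difference of a
    (sigma_t1, sigma_xy1) and a (sigma_t2, sigma_xy2) Gaussian smoothing, the
    two-scale surrogate of a Laplacian-of-Gaussian — suppresses static
    background and slow drift; soma centres are the local maxima of the
    temporal standard deviation of the band-passed movie. Static gradients
    and empty movies yield no detections.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (T, H, W)")
    s1, s2 = space_sigmas_px
    t1, t2 = time_sigmas_frames
    fine = gaussian_filter(movie, (t1, s1, s1))
    coarse = gaussian_filter(movie, (t2, s2, s2))
    band = fine - coarse
    std_proj = band.std(axis=0)
    # a temporally static movie leaves only float round-off in the projection
    if std_proj.max() <= 1e-9 * max(1.0, float(np.abs(movie).max())):
        return pd.DataFrame(columns=["x", "y", "score"])
    floor = np.median(std_proj) + 4.0 * _mad_sigma(std_proj)
    peaks = peak_local_max(
        std_proj,
        min_distance=min_distance_px,
        threshold_abs=max(floor, threshold_rel * std_proj.max()),
        exclude_border=False,
    )
    rows = []
    for py, px in peaks:
        # refine to the intensity-weighted centroid of the local window
        r = min_distance_px // 2
        sy = slice(max(py - r, 0), min(py + r + 1, std_proj.shape[0]))
        sx = slice(max(px - r, 0), min(px + r + 1, std_proj.shape[1]))
        win = std_proj[sy, sx]
        wy, wx = np.mgrid[sy, sx]
        tot = win.sum()
        rows.append(
            {
                "x": float((wx * win).sum() / tot),
                "y": float((wy * win).sum() / tot),
                "score": float(std_proj[py, px]),
            }
        )
    return pd.DataFrame(rows, columns=["x", "y", "score"])


def _mad_sigma(a: np.ndarray) -> float:
    med = np.median(a)
    return float(1.4826 * np.median(np.abs(a - med)))


def extract_trace(
    movie: np.ndarray,
    x: float,
    y: float,
    background_sigma_px: float = 15.0,
    f0_percentile: float = 10.0,
    background_movie: np.ndarray | None = None,
) -> SourceTrace:
    """Background-subtracted trace and dF/F0 at a detected soma centre.

    raw(t) is the pixel at the centre; background(t) is the sigma = 15 px
    Gaussian-smoothed frame sampled there (pass ``background_movie`` to reuse
    a precomputed smoothing across many sources). F0 is a low percentile
    (default 10th) of the background-subtracted trace; a uniform offset added
    to the movie cancels in F = raw - background and so leaves dF/F unchanged.
    """
    movie = np.asarray(movie, dtype=float)
    cy, cx = int(round(y)), int(round(x))
    raw = movie[:, cy, cx].copy()
    if background_movie is None:
        background_movie = gaussian_filter(
            movie, (0, background_sigma_px, background_sigma_px)
        )
    bg = background_movie[:, cy, cx].copy()
    f = raw - bg
    f0 = float(np.percentile(f, f0_percentile))
    if f0 <= 0:
        warnings.warn(
            "baseline F0 <= 0; dF/F undefined at this source", stacklevel=2
        )
        dff = np.full_like(f, np.nan)
    else:
        dff = (f - f0) / f0
    return SourceTrace(x=x, y=y, raw=raw, background=bg, dff=dff, f0=f0)


# ---------------------------------------------------------------------------
# Orientation selectivity
# ---------------------------------------------------------------------------

def _ang_diff(a: np.ndarray, b: float) -> np.ndarray:
    """Circular difference in degrees, wrapped to [-180, 180)."""
    return (np.asarray(a) - b + 180.0) % 360.0 - 180.0


def fit_double_gaussian(tuning: TuningCurve) -> dict:
    """Fit the tuning curve with two circular Gaussians centred on theta_pref
    and the orthogonal (90 deg offset) direction; parameters are reported
    alongside the raw-response OSI, not used in it."""
    theta = tuning.orientations_deg
    r = tuning.mean_responses()
    theta_pref = float(theta[np.argmax(r)])
    orth = (theta_pref + 90.0) % 360.0
    if r[np.argmin(np.abs(_ang_diff(theta, orth)))] < r[
        np.argmin(np.abs(_ang_diff(theta, (theta_pref - 90.0) % 360.0)))
    ]:
        orth = (theta_pref - 90.0) % 360.0

    def model(th, base, a1, a2, width):
        g1 = a1 * np.exp(-(_ang_diff(th, theta_pref) ** 2) / (2 * width**2))
        g2 = a2 * np.exp(-(_ang_diff(th, orth) ** 2) / (2 * width**2))
        return base + g1 + g2

    p0 = [float(r.min()), float(r.max() - r.min()), 0.1 * float(r.max() - r.min() + 1e-9), 30.0]
    try:
        popt, _ = curve_fit(
            model, theta, r, p0=p0,
            bounds=([-np.inf, 0, 0, 5.0], [np.inf, np.inf, np.inf, 180.0]),
            maxfev=5000,
        )
        fitted = model(theta, *popt)
        rss = float(np.sum((fitted - r) ** 2))
        return {
            "baseline": float(popt[0]),
            "amp_pref": float(popt[1]),
            "amp_orth": float(popt[2]),
            "width_deg": float(popt[3]),
            "theta_pref_deg": theta_pref,
            "theta_orth_deg": orth,
            "rss": rss,
        }
    except RuntimeError:
        return {"theta_pref_deg": theta_pref, "theta_orth_deg": orth, "failed": True}


def osi(tuning: TuningCurve, alpha: float = 0.01) -> OSIResult:
    """Orientation selectivity index with the ANOVA responsiveness gate.

    responsive <=> one-way ANOVA across the eight orientation trial groups
    and the blank group rejects at P < alpha. theta_pref maximizes the
    trial-averaged response; r_pref is that maximum and r_orth the smaller of
    the two responses 90 deg away. OSI = (r_pref - r_orth)/(r_pref + r_orth),
    invariant to positive rescaling of all responses.
    """
    groups = [tuning.trial_responses[i] for i in range(8)]
    if len(tuning.blank_responses) >= 2:
        groups = groups + [tuning.blank_responses]
    p = float(f_oneway(*groups).pvalue)
    r = tuning.mean_responses()
    i_pref = int(np.argmax(r))
    theta_pref = float(tuning.orientations_deg[i_pref])
    r_pref = float(r[i_pref])
    orth_idx = [
        int(np.argmin(np.abs(_ang_diff(tuning.orientations_deg, (theta_pref + off) % 360.0))))
        for off in (90.0, -90.0)
    ]
    r_orth = float(min(r[j] for j in orth_idx))
    denom = r_pref + r_orth
    if denom == 0:
        warnings.warn("r_pref + r_orth is zero: OSI undefined", stacklevel=2)
        value = np.nan
    else:
        value = (r_pref - r_orth) / denom
    return OSIResult(
        osi=float(value),
        responsive=p < alpha,
        anova_p=p,
        theta_pref_deg=theta_pref,
        r_pref=r_pref,
        r_orth=r_orth,
        fit_params=fit_double_gaussian(tuning),
    )


def trimmed_std(trials: np.ndarray, ddof: int = 1) -> float:
    """Standard deviation after dropping the single maximum and minimum trial."""
    trials = np.sort(np.asarray(trials, dtype=float))
    if trials.ndim != 1 or len(trials) <= 2:
        raise ValueError("need > 2 trials to trim the extremes")
    trimmed = trials[1:-1]
    if len(trimmed) <= ddof:
        ddof = 0
    return float(np.std(trimmed, ddof=ddof))
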