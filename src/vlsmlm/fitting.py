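"""Spot detection and five-parameter 2D Gaussian fitting.

Every detected spot is fitted by unweighted least squares with

    f(px, py) = A * exp(-((px - x0)^2 + (py - y0)^2) / (2 s^2)) + B

over a square region of interest in photon units, yielding the centre
(x0, y0), the width s (standard deviation of a circular Gaussian — no
elliptical fit), the peak amplitude A above the local offset B.  Results
are reported in canonical units: positions and widths in nm, the amplitude
as a peak surface brightness in photons/um^2 (peak photons/pixel divided by
the pixel area in um^2 — this convention puts single-fluorophore amplitudes
in the low thousands for a 100 nm pixel), the offset in photons/pixel, and
the integrated intensity A * 2 pi s_px^2 in photons.

The localization precision column follows the Mortensen least-squares
variance for a Gaussian PSF:

    sigma_a^2 = s^2 + a^2 / 12
    var(x)    = sigma_a^2 / N * (16/9 + 8 pi sigma_a^2 b^2 / (N a^2))

with N the integrated photons, a the pixel size and b^2 the background
variance per pixel (approximated by the fitted offset, i.e. Poisson
background).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .models import CameraModel, FrameStack, OpticsModel

__all__ = [
    "LOC_COLUMNS",
    "detect_spots",
    "fit_gaussian2d",
    "localization_precision",
    "amplitude_to_photon_density",
    "fit_frame",
    "localize_stack",
]

#: canonical localization-table columns, in writing order
LOC_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "sigma_nm",
    "amplitude_photons_um2",
    "offset_photons",
    "intensity_photons",
    "precision_nm",
    "fit_ok",
]


def amplitude_to_photon_density(
    peak_amplitude_photons_per_pixel: float, pixel_size: float
) -> float:
    """Convert a peak height in photons/pixel to photons/um^2.

    A 15 photons/pixel peak on 100 nm pixels is 1500 photons/um^2.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return peak_amplitude_photons_per_pixel / (pixel_size * 1e-3) ** 2


def localization_precision(
    width: float,
    photons: float,
    background_var_photons: float,
    pixel_size: float,
) -> float:
    """Expected standard error (nm) of a least-squares localization.

    ``width`` is the fitted PSF standard deviation in nm, ``photons`` the
    integrated photon count, ``background_var_photons`` the per-pixel
    background variance in photons^2 and ``pixel_size`` the pixel size in
    nm.  Strictly decreasing in ``photons``; the zero-background limit is
    (4/3)^(1/2) * sigma_a / sqrt(N) ... squared, i.e. (4/3) sigma_a^2 / N.
    """
    if photons <= 0:
        raise ValueError("photons must be > 0")
    if width <= 0:
        raise ValueError("width must be > 0")
    sigma_a2 = width**2 + pixel_size**2 / 12.0
    var = (sigma_a2 / photons) * (
        16.0 / 9.0
        + 8.0 * math.pi * sigma_a2 * background_var_photons / (photons * pixel_size**2)
    )
    return math.sqrt(var)


def detect_spots(
    frame: np.ndarray,
    camera: CameraModel,
    min_snr: float = 5.0,
    min_separation_px: int = 5,
    smooth_sigma_px: float = 1.0,
) -> list[tuple[int, int]]:
    """Candidate spot pixels: local maxima of a smoothed frame above noise.

    The frame is converted to photons, Gaussian-smoothed, and local maxima
    exceeding ``median + min_snr * robust_sd`` (robust sd from the median
    absolute deviation) and separated by at least ``min_separation_px``
    are returned as (row, col) integer pixels.  Deterministic.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("frame is empty")
    photons = camera.counts_to_photons(frame)
    smoothed = gaussian_filter(photons, smooth_sigma_px)
    med = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - med)))
    robust_sd = 1.4826 * mad
    threshold = med + min_snr * robust_sd
    if not np.any(smoothed > threshold):
        return []
    peaks = peak_local_max(
        smoothed,
        min_distance=min_separation_px,
        threshold_abs=threshold,
        exclude_border=False,
    )
    # stable order: by row then column
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    return [tuple(p) for p in peaks[order]]


def _gauss2d(coords, A, x0, y0, s, B):
    px, py = coords
    return A * np.exp(-((px - x0) ** 2 + (py - y0) ** 2) / (2.0 * s**2)) + B


@dataclass
class _FitResult:
    x_px: float
    y_px: float
    sigma_px: float
    amplitude: float
    offset: float
    ok: bool


def _fit_roi(roi: np.ndarray, x_off: int, y_off: int, cand_x: float, cand_y: float,
             expected_sigma_px: float) -> _FitResult:
    """Least-squares 2D Gaussian fit of one ROI (photon units)."""
    bad = _FitResult(np.nan, np.nan, np.nan, np.nan, np.nan, False)
    if roi.size < 7 or np.ptp(roi) == 0:
        return bad
    ny, nx = roi.shape
    py, px = np.mgrid[0:ny, 0:nx]
    px = px + x_off
    py = py + y_off
    b0 = float(np.median(roi))
    a0 = float(roi.max() - b0)
    p0 = [max(a0, 1e-3), cand_x, cand_y, expected_sigma_px, b0]
    try:
        popt, _ = curve_fit(
            _gauss2d,
            (px.ravel().astype(float), py.ravel().astype(float)),
            roi.ravel().astype(float),
            p0=p0,
            maxfev=400,
        )
    except (RuntimeError, ValueError):
        return bad
    A, x0, y0, s, B = popt
    s = abs(s)
    ok = (
        A > 0
        and 0.25 * expected_sigma_px < s < 10.0 * expected_sigma_px
        and np.isfinite([A, x0, y0, s, B]).all()
    )
    return _FitResult(x0, y0, s, A, B, bool(ok))


def fit_gaussian2d(
    frame: np.ndarray,
    candidate: tuple[int, int],
    camera: CameraModel,
    roi_halfwidth_px: int | None = None,
    expected_sigma_nm: float = 175.0,
) -> dict:
    """Fit one candidate spot; returns a canonical localization row (dict).

    The ROI is a square of half-width ``roi_halfwidth_px`` (default: three
    in-focus sigmas, rounded up) centred on the candidate, shrunk at the
    frame border.  ``fit_ok`` is False when the optimizer fails, the peak
    is non-positive, or the width leaves (0.25, 10) times the expected
    in-focus sigma.
    """
    frame = np.asarray(frame, dtype=float)
    expected_sigma_px = expected_sigma_nm / camera.pixel_size
    if roi_halfwidth_px is None:
        roi_halfwidth_px = int(math.ceil(3.0 * expected_sigma_px))
    r, c = candidate
    h, w = frame.shape
    y_lo, y_hi = max(r - roi_halfwidth_px, 0), min(r + roi_halfwidth_px + 1, h)
    x_lo, x_hi = max(c - roi_halfwidth_px, 0), min(c + roi_halfwidth_px + 1, w)
    roi = camera.counts_to_photons(frame[y_lo:y_hi, x_lo:x_hi])
    res = _fit_roi(roi, x_lo, y_lo, float(c), float(r), expected_sigma_px)

    px_size = camera.pixel_size
    if res.ok:
        width_nm = res.sigma_px * px_size
        intensity = res.amplitude * 2.0 * math.pi * res.sigma_px**2
        amp_density = amplitude_to_photon_density(res.amplitude, px_size)
        bg_var = max(res.offset, 0.0)
        precision = (
            localization_precision(width_nm, intensity, bg_var, px_size)
            if intensity > 0
            else np.nan
        )
        return {
            "frame": -1,
            "x_nm": (res.x_px + 0.5) * px_size,
            "y_nm": (res.y_px + 0.5) * px_size,
            "sigma_nm": width_nm,
            "amplitude_photons_um2": amp_density,
            "offset_photons": res.offset,
            "intensity_photons": intensity,
            "precision_nm": precision,
            "fit_ok": True,
        }
    return {
        "frame": -1,
        "x_nm": (res.x_px + 0.5) * px_size if np.isfinite(res.x_px) else np.nan,
        "y_nm": (res.y_px + 0.5) * px_size if np.isfinite(res.y_px) else np.nan,
        "sigma_nm": res.sigma_px * px_size if np.isfinite(res.sigma_px) else np.nan,
        "amplitude_photons_um2": (
            amplitude_to_photon_density(res.amplitude, px_size)
            if np.isfinite(res.amplitude)
            else np.nan
        ),
        "offset_photons": res.offset,
        "intensity_photons": np.nan,
        "precision_nm": np.nan,
        "fit_ok": False,
    }


def fit_frame(
    frame: np.ndarray,
    camera: CameraModel,
    frame_index: int = 0,
    min_snr: float = 5.0,
    min_separation_px: int = 5,
    roi_halfwidth_px: int | None = None,
    expected_sigma_nm: float = 175.0,
) -> pd.DataFrame:
    """Detect and fit all spots in one frame; canonical localization table."""
    rows = []
    for cand in detect_spots(frame, camera, min_snr=min_snr, min_separation_px=min_separation_px):
        row = fit_gaussian2d(
            frame,
            cand,
            camera,
            roi_halfwidth_px=roi_halfwidth_px,
            expected_sigma_nm=expected_sigma_nm,
        )
        row["frame"] = frame_index
        rows.append(row)
    return pd.DataFrame(rows, columns=LOC_COLUMNS)


def localize_stack(
    stack: FrameStack,
    min_snr: float = 5.0,
    min_separation_px: int = 5,
    roi_halfwidth_px: int | None = None,
    optics: OpticsModel | None = None,
    expected_sigma_nm: float | None = None,
) -> pd.DataFrame:
    """Fit every frame of a stack into one localization table.

    For calibration stacks (``z_per_frame`` present) a ``true_z_nm`` column
    records the stage position of each localization's frame.  The output is
    a pure function of the input stack.
    """
    if expected_sigma_nm is None:
        expected_sigma_nm = (optics or OpticsModel()).sigma0
    tables = []
    for t in range(stack.n_frames):
        table = fit_frame(
            stack.frames[t],
            stack.camera,
            frame_index=t,
            min_snr=min_snr,
            min_separation_px=min_separation_px,
            roi_halfwidth_px=roi_halfwidth_px,
            expected_sigma_nm=expected_sigma_nm,
        )
        if len(table):
            tables.append(table)
    out = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=LOC_COLUMNS)
    if stack.z_per_frame is not None and len(out):
        out["true_z_nm"] = stack.z_per_frame[out["frame"].to_numpy(dtype=int)]
    elif stack.z_per_frame is not None:
        out["true_z_nm"] = pd.Series(dtype=float)
    return out
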