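"""Virtual light-sheet calibration from a bead z-stack.

The calibration turns a z-scan of immobile sub-diffraction beads into a pair
of (width, amplitude) thresholds with known confidence and recall:

1. fit every frame, link localizations into per-bead traces;
2. locate the focal plane as the z maximizing the boxed integrated
   intensity, and fit the axial intensity profile with a 1D Gaussian;
3. define the virtual light-sheet (vls) as a slab around the focal plane;
4. label every localization in/out of the vls using the known stage z —
   the "parameter plot" data;
5. scan width thresholds (keep width <= t) computing per threshold
   confidence = TP/(TP+FP) and recall = TP/(TP+FN);
6. select the width threshold — structural mode: the confidence/recall
   crossing; confidence mode: the confidence maximum;
7. repeat the scan over amplitude thresholds (keep amplitude >= t) on the
   width-thresholded list and pick the loosest threshold reaching the
   mode's target confidence (0.90 structural, 0.95 confidence mode).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .fitting import localize_stack
from .models import FrameStack, OpticsModel

__all__ = [
    "CalibrationError",
    "BeadTrace",
    "AxialProfile",
    "VlsBounds",
    "LabeledLocalizationSet",
    "ThresholdCurve",
    "VlsCalibration",
    "CalibrationConfig",
    "CalibrationResult",
    "link_beads",
    "find_focal_plane",
    "fit_axial_profile",
    "define_vls",
    "label_localizations",
    "confidence_recall_curve",
    "select_width_threshold",
    "select_amplitude_threshold",
    "evaluate_thresholds",
    "calibrate",
    "export_parameter_profiles",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class CalibrationError(RuntimeError):
    """Raised when a calibration stage cannot produce a result."""

    def __init__(self, message: str, stage: str | None = None, **context):
        super().__init__(f"[{stage}] {message}" if stage else message)
        self.stage = stage
        self.context = context


@dataclass
class BeadTrace:
    """All localizations of one bead across the z-scan, plus its boxed
    integrated-intensity profile."""

    bead_id: int
    locs: pd.DataFrame          # member localizations, incl. true_z_nm
    z_steps: np.ndarray         # strictly increasing step positions, nm
    boxed_intensity: np.ndarray | None = None  # photons per step

    def __post_init__(self) -> None:
        self.z_steps = np.asarray(self.z_steps, dtype=float)
        if len(self.z_steps) < 3:
            raise ValueError("a bead trace needs >= 3 z steps")
        if np.any(np.diff(self.z_steps) <= 0):
            raise ValueError("z steps must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.z_steps)

    def per_step(self, column: str) -> pd.Series:
        """Mean of one localization column at each z step."""
        return self.locs.groupby("true_z_nm")[column].mean()


@dataclass
class AxialProfile:
    """Axial profile of a quantity with its Gaussian fit."""

    z_centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    center: float = np.nan         # fitted Gaussian z0, nm
    sigma_ax: float = np.nan       # fitted axial standard deviation, nm
    amplitude: float = np.nan
    baseline: float = np.nan
    focal_plane_z: float = np.nan  # z of the max-intensity step, nm

    @property
    def fwhm(self) -> float:
        """Full width at half maximum, exactly 2 sqrt(2 ln 2) * sigma_ax."""
        return FWHM_PER_SIGMA * self.sigma_ax


@dataclass(frozen=True)
class VlsBounds:
    """The virtual light-sheet: a slab [z0 - h, z0 + h], boundaries inclusive."""

    z0: float
    half_thickness: float

    def __post_init__(self) -> None:
        if not self.half_thickness > 0:
            raise ValueError("half_thickness must be > 0")

    def contains(self, z: np.ndarray | float) -> np.ndarray | bool:
        return np.abs(np.asarray(z, dtype=float) - self.z0) <= self.half_thickness


@dataclass
class LabeledLocalizationSet:
    """Localizations with ground-truth axial labels (the parameter-plot data)."""

    table: pd.DataFrame  # includes boolean in_vls
    bounds: VlsBounds

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ThresholdCurve:
    """Confidence/recall as a function of one scanned threshold.

    ``confidence`` is NaN where undefined (no localization kept).
    """

    parameter: str  # "width" | "amplitude"
    thresholds: np.ndarray
    confidence: np.ndarray
    recall: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray


@dataclass
class VlsCalibration:
    """Selected thresholds for one imaging mode, with achieved statistics."""

    mode: str                       # "structural" | "confidence"
    z0: float
    half_thickness_nm: float
    width_max_nm: float
    amplitude_min_photons_um2: float
    achieved_confidence: float
    achieved_recall: float
    width_curve: ThresholdCurve | None = None
    amplitude_curve: ThresholdCurve | None = None

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "z0": self.z0,
            "half_thickness_nm": self.half_thickness_nm,
            "width_max_nm": self.width_max_nm,
            "amplitude_min_photons_um2": self.amplitude_min_photons_um2,
            "achieved_confidence": self.achieved_confidence,
            "achieved_recall": self.achieved_recall,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VlsCalibration":
        return cls(**{k: d[k] for k in (
            "mode", "z0", "half_thickness_nm", "width_max_nm",
            "amplitude_min_photons_um2", "achieved_confidence", "achieved_recall")})


# ---------------------------------------------------------------------------
# trace building


def link_beads(
    localizations: pd.DataFrame,
    z_per_frame: np.ndarray,
    link_radius_nm: float = 500.0,
    stack: FrameStack | None = None,
    box_halfwidth_px: int | None = None,
    min_step_fraction: float = 0.5,
) -> list[BeadTrace]:
    """Group a calibration stack's localizations into per-bead traces.

    A localization joins the trace whose running mean (x, y) lies within
    ``link_radius_nm``; otherwise it starts a new trace.  Any two traces
    whose mean positions end up closer than ``link_radius_nm`` are both
    discarded with a warning (ambiguous linking), as are traces covering
    fewer than ``min_step_fraction`` of the z steps.  When ``stack`` is
    given, each trace's boxed integrated-intensity profile is measured
    (see :func:`find_focal_plane`).
    """
    z_per_frame = np.asarray(z_per_frame, dtype=float)
    z_steps = np.unique(z_per_frame)
    locs = localizations[localizations["fit_ok"].astype(bool)].reset_index(drop=True)
    if "true_z_nm" not in locs.columns:
        locs = locs.copy()
        locs["true_z_nm"] = z_per_frame[locs["frame"].to_numpy(dtype=int)]

    sums_x: list[float] = []
    sums_y: list[float] = []
    counts: list[int] = []
    membership = np.full(len(locs), -1, dtype=int)
    xs = locs["x_nm"].to_numpy()
    ys = locs["y_nm"].to_numpy()
    order = np.argsort(locs["frame"].to_numpy(), kind="stable")
    for i in order:
        if sums_x:
            mx = np.array(sums_x) / np.array(counts)
            my = np.array(sums_y) / np.array(counts)
            d2 = (mx - xs[i]) ** 2 + (my - ys[i]) ** 2
            j = int(np.argmin(d2))
            if d2[j] <= link_radius_nm**2:
                sums_x[j] += xs[i]
                sums_y[j] += ys[i]
                counts[j] += 1
                membership[i] = j
                continue
        sums_x.append(xs[i])
        sums_y.append(ys[i])
        counts.append(1)
        membership[i] = len(sums_x) - 1

    mx = np.array(sums_x) / np.array(counts)
    my = np.array(sums_y) / np.array(counts)
    n_traces = len(mx)
    drop = np.zeros(n_traces, dtype=bool)
    # two resolved traces closer than the link radius are ambiguous
    for a in range(n_traces):
        for b in range(a + 1, n_traces):
            if (mx[a] - mx[b]) ** 2 + (my[a] - my[b]) ** 2 < link_radius_nm**2:
                drop[a] = drop[b] = True
    # a trace absorbing two localizations from one frame means two beads
    # sat inside one link radius and were merged: equally ambiguous
    frames_arr = locs["frame"].to_numpy()
    for j in range(n_traces):
        member_frames = frames_arr[membership == j]
        if len(member_frames) != len(np.unique(member_frames)):
            drop[j] = True
    if drop.any():
        warnings.warn(
            f"discarding {int(drop.sum())} ambiguous bead traces closer than "
            f"{link_radius_nm:.0f} nm",
            stacklevel=2,
        )

    traces: list[BeadTrace] = []
    for j in range(n_traces):
        if drop[j]:
            continue
        member = locs[membership == j]
        covered = member["true_z_nm"].nunique()
        if covered < min_step_fraction * len(z_steps):
            continue
        trace = BeadTrace(bead_id=len(traces), locs=member.reset_index(drop=True),
                          z_steps=z_steps)
        traces.append(trace)

    if stack is not None:
        for trace in traces:
            trace.boxed_intensity = _boxed_intensity_profile(
                stack, trace, box_halfwidth_px
            )
    return traces


def _boxed_intensity_profile(
    stack: FrameStack,
    trace: BeadTrace,
    box_halfwidth_px: int | None = None,
    expected_sigma_nm: float = 175.0,
) -> np.ndarray:
    """Background-subtracted photon sum in a fixed box around the bead,
    averaged over the frames of each z step.

    The default box half-width is one in-focus sigma: with the total
    photon flux roughly conserved under defocus, a tight box maximizes
    the axial contrast of the boxed intensity, which keeps the focal-plane
    fit well conditioned (a box of several sigmas integrates nearly all
    photons at every z and flattens the profile).
    """
    px = stack.camera.pixel_size
    if box_halfwidth_px is None:
        box_halfwidth_px = int(math.ceil(expected_sigma_nm / px))
    cx = int(round(trace.locs["x_nm"].mean() / px - 0.5))
    cy = int(round(trace.locs["y_nm"].mean() / px - 0.5))
    h, w = stack.frame_shape
    y_lo, y_hi = max(cy - box_halfwidth_px, 0), min(cy + box_halfwidth_px + 1, h)
    x_lo, x_hi = max(cx - box_halfwidth_px, 0), min(cx + box_halfwidth_px + 1, w)
    area = (y_hi - y_lo) * (x_hi - x_lo)

    sums = np.zeros(trace.n_steps)
    ns = np.zeros(trace.n_steps)
    step_of = {z: i for i, z in enumerate(trace.z_steps)}
    for t in range(stack.n_frames):
        idx = step_of.get(float(stack.z_per_frame[t]))
        if idx is None:
            continue
        photons = stack.photons(t)
        bg = float(np.median(photons))
        sums[idx] += photons[y_lo:y_hi, x_lo:x_hi].sum() - bg * area
        ns[idx] += 1
    with np.errstate(invalid="ignore"):
        return np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)


def find_focal_plane(trace: BeadTrace, box_halfwidth_px: int | None = None) -> int:
    """Index of the z step with maximal boxed integrated intensity.

    Exact ties are broken toward the median step index.  Raises when the
    profile is flat (no focus).
    """
    if trace.boxed_intensity is None:
        raise CalibrationError(
            "trace has no boxed intensity profile; link with a stack first",
            stage="find_focal_plane",
        )
    return _argmax_median_ties(trace.boxed_intensity, stage="find_focal_plane")


def _argmax_median_ties(profile: np.ndarray, stage: str) -> int:
    prof = np.asarray(profile, dtype=float)
    finite = prof[np.isfinite(prof)]
    if finite.size == 0 or np.ptp(finite) == 0:
        raise CalibrationError("no focus: axial intensity profile is flat", stage=stage)
    best = np.nanmax(prof)
    candidates = np.flatnonzero(prof == best)
    median_idx = (len(prof) - 1) / 2.0
    return int(candidates[np.argmin(np.abs(candidates - median_idx))])


def _gauss1d(z, A, z0, s, C):
    return A * np.exp(-((z - z0) ** 2) / (2.0 * s**2)) + C


def fit_axial_profile(
    traces: list[BeadTrace],
    box_halfwidth_px: int | None = None,
) -> AxialProfile:
    """Average the per-bead boxed-intensity profiles (unit-peak normalized)
    and fit a 1D Gaussian plus baseline.

    Returns the profile with fitted centre z0, axial sigma, and FWHM
    (= 2 sqrt(2 ln 2) sigma).  Raises on fit non-convergence with the raw
    profile attached to the error.
    """
    if not traces:
        raise CalibrationError("no traces", stage="fit_axial_profile")
    z = traces[0].z_steps
    profiles = []
    for tr in traces:
        if tr.boxed_intensity is None:
            raise CalibrationError(
                "trace lacks boxed intensity", stage="fit_axial_profile"
            )
        p = np.asarray(tr.boxed_intensity, dtype=float)
        peak = np.nanmax(p)
        if not peak > 0:
            continue
        profiles.append(p / peak)
    arr = np.array(profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1) if len(arr) > 1 else np.zeros_like(mean)
    good = np.isfinite(mean)
    zf, mf = z[good], mean[good]
    span = zf.max() - zf.min()
    p0 = [np.ptp(mf), zf[np.argmax(mf)], span / 4.0, mf.min()]
    try:
        popt, _ = curve_fit(_gauss1d, zf, mf, p0=p0, maxfev=5000)
    except (RuntimeError, ValueError) as exc:
        err = CalibrationError(f"axial Gaussian fit failed: {exc}",
                              stage="fit_axial_profile")
        err.context["profile"] = (z, mean, sd)
        raise err from exc
    A, z0, s, C = popt
    return AxialProfile(
        z_centers=z, mean=mean, sd=sd,
        center=float(z0), sigma_ax=float(abs(s)),
        amplitude=float(A), baseline=float(C),
        focal_plane_z=float(z[_argmax_median_ties(mean, "fit_axial_profile")]),
    )


def define_vls(
    profile: AxialProfile,
    thickness_mode: str = "fwhm",
    explicit_thickness_nm: float | None = None,
    center_mode: str = "focal-plane",
) -> VlsBounds:
    """Define the virtual light-sheet slab around the focal plane.

    ``thickness_mode="fwhm"`` uses the axial profile's FWHM as the slab
    thickness; ``"explicit"`` uses ``explicit_thickness_nm`` (the field
    convention for high-NA objectives is ~600 nm).  Bounds are inclusive.

    ``center_mode="focal-plane"`` (default) centres the slab on the
    maximum-intensity z step — the operational focal-plane definition,
    which inherits the z-scan's sampling granularity (this is why coarse
    z-steps degrade the calibration); ``"fit"`` uses the fitted Gaussian
    centre instead.
    """
    if center_mode == "focal-plane":
        z0 = profile.focal_plane_z if np.isfinite(profile.focal_plane_z) else profile.center
    elif center_mode == "fit":
        z0 = profile.center
    else:
        raise ValueError(f"unknown center_mode {center_mode!r}")
    if thickness_mode == "fwhm":
        thickness = profile.fwhm
    elif thickness_mode == "explicit":
        if explicit_thickness_nm is None:
            raise ValueError("explicit thickness mode needs explicit_thickness_nm")
        thickness = float(explicit_thickness_nm)
    else:
        raise ValueError(f"unknown thickness_mode {thickness_mode!r}")
    if not thickness > 0:
        raise ValueError(f"vls thickness must be > 0, got {thickness}")
    return VlsBounds(z0=float(z0), half_thickness=thickness / 2.0)


def label_localizations(
    localizations: pd.DataFrame,
    bounds: VlsBounds,
) -> LabeledLocalizationSet:
    """Tag each localization in/out of the vls from its known z.

    Boundary localizations (|z - z0| exactly equal to the half-thickness)
    count as inside.
    """
    if "true_z_nm" not in localizations.columns:
        raise ValueError("localizations need a true_z_nm column to be labeled")
    z = localizations["true_z_nm"].to_numpy(dtype=float)
    if np.isnan(z).any():
        raise ValueError("true_z_nm contains missing values")
    table = localizations.copy()
    table["in_vls"] = bounds.contains(z)
    return LabeledLocalizationSet(table=table, bounds=bounds)


# ---------------------------------------------------------------------------
# threshold statistics

_PARAM_COLUMN = {"width": "sigma_nm", "amplitude": "amplitude_photons_um2"}


def _keep_mask(values: np.ndarray, parameter: str, threshold: float) -> np.ndarray:
    if parameter == "width":
        return values <= threshold
    if parameter == "amplitude":
        return values >= threshold
    raise ValueError(f"unknown parameter {parameter!r}")


def confidence_recall_curve(
    labeled: LabeledLocalizationSet,
    parameter: str,
    thresholds: np.ndarray,
    prior_filter: np.ndarray | None = None,
) -> ThresholdCurve:
    """Confidence and recall at every threshold of one parameter scan.

    Width semantics: keep iff width <= threshold; amplitude semantics:
    keep iff amplitude >= threshold.  ``prior_filter`` marks localizations
    surviving an earlier stage (e.g. the width cut before the amplitude
    scan); false negatives count in-vls localizations removed by either
    stage.  Confidence is NaN (undefined) where nothing is kept.
    """
    if len(labeled) == 0:
        raise ValueError("empty labeled localization set")
    column = _PARAM_COLUMN[parameter]
    values = labeled.table[column].to_numpy(dtype=float)
    in_vls = labeled.table["in_vls"].to_numpy(dtype=bool)
    n = len(values)
    prior = np.ones(n, dtype=bool) if prior_filter is None else np.asarray(prior_filter, bool)
    thresholds = np.asarray(thresholds, dtype=float)

    kept = _keep_mask(values[:, None], parameter, thresholds[None, :]) & prior[:, None]
    tp = (kept & in_vls[:, None]).sum(axis=0)
    fp = (kept & ~in_vls[:, None]).sum(axis=0)
    fn = (~kept & in_vls[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        confidence = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan)
    return ThresholdCurve(
        parameter=parameter, thresholds=thresholds,
        confidence=confidence, recall=recall, tp=tp, fp=fp, fn=fn,
    )


def select_width_threshold(
    curve: ThresholdCurve, mode: str, min_support: int = 10
) -> float:
    """Pick the width threshold for an imaging mode.

    structural
        The threshold where the confidence and recall curves cross, found
        as the sign change of (confidence - recall) and refined by linear
        interpolation between the bracketing sampled thresholds; with
        several crossings the one at the largest threshold is used
        (maximal recall).
    confidence
        The threshold maximizing confidence; exact ties break toward the
        larger threshold (retain more localizations).  Thresholds keeping
        fewer than ``min_support`` localizations are excluded from the
        argmax: a confidence ratio estimated from a handful of survivors
        is not a meaningful maximum.
    """
    if curve.parameter != "width":
        raise ValueError("select_width_threshold needs a width curve")
    t = np.asarray(curve.thresholds, dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 thresholds")
    conf, rec = curve.confidence, curve.recall
    defined = np.isfinite(conf) & np.isfinite(rec)
    if not defined.any():
        raise CalibrationError("confidence undefined over the whole scan",
                               stage="select_width_threshold")
    if mode == "confidence":
        supported = np.isfinite(conf) & (curve.tp + curve.fp >= min_support)
        if not supported.any():
            supported = np.isfinite(conf)
        cmax = np.max(conf[supported])
        winners = np.flatnonzero(supported & (conf == cmax))
        return float(t[winners[-1]])
    if mode != "structural":
        raise ValueError(f"unknown mode {mode!r}")

    d = conf - rec
    idx = np.flatnonzero(defined)
    td, dd = t[idx], d[idx]
    crossings = []
    for k in range(len(dd) - 1):
        if dd[k] == 0:
            crossings.append(td[k])
        elif dd[k] * dd[k + 1] < 0:
            frac = dd[k] / (dd[k] - dd[k + 1])
            crossings.append(td[k] + frac * (td[k + 1] - td[k]))
    if dd[-1] == 0:
        crossings.append(td[-1])
    if not crossings:
        raise CalibrationError(
            "confidence and recall curves do not cross; widen the width scan",
            stage="select_width_threshold",
        )
    return float(max(crossings))


def select_amplitude_threshold(
    labeled: LabeledLocalizationSet,
    width_max: float,
    target_confidence: float,
) -> float:
    """Smallest amplitude threshold reaching the target confidence.

    Candidate thresholds are the distinct amplitudes observed among the
    localizations surviving the width cut, so the scan is exhaustive; the
    smallest qualifying threshold maximizes recall subject to the
    confidence floor.  Raises (reporting the maximum achievable
    confidence) when the target cannot be reached.
    """
    if not 0 < target_confidence < 1:
        raise ValueError("target_confidence must be in (0, 1)")
    table = labeled.table
    surviving = table[table["sigma_nm"].to_numpy(dtype=float) <= width_max]
    if len(surviving) == 0:
        raise CalibrationError("no localizations survive the width cut",
                               stage="select_amplitude_threshold")
    amps = surviving["amplitude_photons_um2"].to_numpy(dtype=float)
    in_vls = surviving["in_vls"].to_numpy(dtype=bool)
    candidates = np.unique(amps)
    # kept iff amplitude >= threshold: cumulative counts from the top
    order = np.argsort(amps)
    amps_sorted = amps[order]
    in_sorted = in_vls[order]
    # for each candidate c, kept = amps_sorted >= c
    idx = np.searchsorted(amps_sorted, candidates, side="left")
    total = len(amps)
    cum_in = np.concatenate(([0], np.cumsum(in_sorted)))
    tp = cum_in[-1] - cum_in[idx]
    kept = total - idx
    with np.errstate(invalid="ignore"):
        conf = np.where(kept > 0, tp / np.maximum(kept, 1), np.nan)
    ok = np.flatnonzero(np.isfinite(conf) & (conf >= target_confidence))
    if ok.size == 0:
        best = np.nanmax(conf)
        raise CalibrationError(
            f"amplitude target confidence {target_confidence:.2f} unreachable; "
            f"maximum achievable is {best:.3f}",
            stage="select_amplitude_threshold",
            max_achievable=float(best),
        )
    return float(candidates[ok[0]])


def evaluate_thresholds(
    labeled: LabeledLocalizationSet,
    width_max: float,
    amplitude_min: float,
) -> tuple[float, float]:
    """(confidence, recall) of a (width, amplitude) threshold pair on a
    labeled set; confidence is NaN when nothing is kept."""
    table = labeled.table
    width = table["sigma_nm"].to_numpy(dtype=float)
    amp = table["amplitude_photons_um2"].to_numpy(dtype=float)
    in_vls = table["in_vls"].to_numpy(dtype=bool)
    kept = (width <= width_max) & (amp >= amplitude_min)
    tp = int((kept & in_vls).sum())
    fp = int((kept & ~in_vls).sum())
    fn = int((~kept & in_vls).sum())
    confidence = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    return confidence, recall


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class CalibrationConfig:
    """Tunable parameters of the calibration pipeline.

    The default vls thickness is the explicit ~600 nm convention for
    high-NA objectives rather than the fitted profile FWHM: on shallow
    axial intensity profiles the fitted FWHM is poorly constrained, while
    the slab thickness is, by construction, an instrument convention.
    """

    min_snr: float = 5.0
    link_radius_nm: float = 500.0
    box_halfwidth_px: int | None = None
    expected_sigma_nm: float = 175.0
    width_scan_nm: tuple[float, float, float] = (100.0, 500.0, 1.0)  # lo, hi, step
    thickness_mode: str = "explicit"
    explicit_thickness_nm: float = 600.0
    center_mode: str = "focal-plane"
    targets: dict = field(default_factory=lambda: {"structural": 0.90, "confidence": 0.95})

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown calibration config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.width_scan_nm, list):
            cfg.width_scan_nm = tuple(cfg.width_scan_nm)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CalibrationResult:
    """Full output of :func:`calibrate`: shared geometry plus one
    :class:`VlsCalibration` per imaging mode."""

    profile: AxialProfile
    bounds: VlsBounds
    labeled: LabeledLocalizationSet
    traces: list[BeadTrace]
    modes: dict[str, VlsCalibration]

    def __getitem__(self, mode: str) -> VlsCalibration:
        return self.modes[mode]


def _stage(fn, stage_name, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except CalibrationError:
        raise
    except Exception as exc:
        raise CalibrationError(str(exc), stage=stage_name) from exc


def calibrate(
    stack: FrameStack,
    config: CalibrationConfig | None = None,
    localizations: pd.DataFrame | None = None,
) -> CalibrationResult:
    """Run the full calibration pipeline on a bead z-stack.

    Fits all frames (unless a pre-fitted ``localizations`` table with
    ``true_z_nm`` is supplied), links beads, fits the axial profile,
    defines the vls, labels the parameter plot, scans width thresholds
    (default 100-500 nm in 1 nm steps) and then amplitude thresholds, and
    selects the threshold pair for both the structural and the confidence
    imaging mode.
    """
    config = config or CalibrationConfig()
    if stack.z_per_frame is None:
        raise CalibrationError("calibration stack needs z_per_frame", stage="input")

    if localizations is None:
        localizations = _stage(
            localize_stack, "fit", stack,
            min_snr=config.min_snr,
            expected_sigma_nm=config.expected_sigma_nm,
        )
    locs = localizations[localizations["fit_ok"].astype(bool)]
    if len(locs) == 0:
        raise CalibrationError("no successful fits in the stack", stage="fit")

    traces = _stage(
        link_beads, "link_beads", locs, stack.z_per_frame,
        link_radius_nm=config.link_radius_nm,
        stack=stack, box_halfwidth_px=config.box_halfwidth_px,
    )
    if not traces:
        raise CalibrationError("no bead traces survived linking", stage="link_beads")

    profile = _stage(fit_axial_profile, "fit_axial_profile", traces,
                     box_halfwidth_px=config.box_halfwidth_px)
    bounds = _stage(
        define_vls, "define_vls", profile,
        thickness_mode=config.thickness_mode,
        explicit_thickness_nm=config.explicit_thickness_nm,
        center_mode=config.center_mode,
    )
    labeled = _stage(label_localizations, "label", locs, bounds)

    lo, hi, step = config.width_scan_nm
    width_thresholds = np.arange(lo, hi + step / 2.0, step)
    width_curve = _stage(
        confidence_recall_curve, "width_curve", labeled, "width", width_thresholds
    )

    modes: dict[str, VlsCalibration] = {}
    for mode, target in config.targets.items():
        width_max = _stage(select_width_threshold, "select_width", width_curve, mode)
        prior = labeled.table["sigma_nm"].to_numpy(dtype=float) <= width_max
        amp_candidates = np.unique(
            labeled.table.loc[prior, "amplitude_photons_um2"].to_numpy(dtype=float)
        )
        amp_curve = _stage(
            confidence_recall_curve, "amplitude_curve",
            labeled, "amplitude", amp_candidates, prior,
        )
        amplitude_min = _stage(
            select_amplitude_threshold, "select_amplitude", labeled, width_max, target
        )
        achieved_conf, achieved_rec = evaluate_thresholds(labeled, width_max, amplitude_min)
        modes[mode] = VlsCalibration(
            mode=mode,
            z0=bounds.z0,
            half_thickness_nm=bounds.half_thickness,
            width_max_nm=width_max,
            amplitude_min_photons_um2=amplitude_min,
            achieved_confidence=achieved_conf,
            achieved_recall=achieved_rec,
            width_curve=width_curve,
            amplitude_curve=amp_curve,
        )

    return CalibrationResult(
        profile=profile, bounds=bounds, labeled=labeled, traces=traces, modes=modes
    )


def export_parameter_profiles(traces: list[BeadTrace]) -> dict[str, pd.DataFrame]:
    """Per-z mean and standard deviation of every fitted parameter.

    For each of width, amplitude, integrated intensity, precision and
    offset, pools the localizations of all traces and returns a table with
    columns ``z_nm``, ``mean``, ``sd`` — the data behind per-parameter
    axial profile plots with +/- 1 sd bands.
    """
    if not traces:
        raise ValueError("no traces")
    pooled = pd.concat([tr.locs for tr in traces], ignore_index=True)
    params = {
        "width": "sigma_nm",
        "amplitude": "amplitude_photons_um2",
        "intensity": "intensity_photons",
        "precision": "precision_nm",
        "offset": "offset_photons",
    }
    out: dict[str, pd.DataFrame] = {}
    for name, col in params.items():
        g = pooled.groupby("true_z_nm")[col]
        table = pd.DataFrame({
            "z_nm": g.mean().index.to_numpy(dtype=float),
            "mean": g.mean().to_numpy(dtype=float),
            "sd": g.std(ddof=1).fillna(0.0).to_numpy(dtype=float),
        })
        out[name] = table.reset_index(drop=True)
    return out
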