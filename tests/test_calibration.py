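"""Bead linking, axial profile, vls definition and threshold selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vlsmlm import (
    AxialProfile,
    LabeledLocalizationSet,
    ThresholdCurve,
    VlsBounds,
    confidence_recall_curve,
    define_vls,
    export_parameter_profiles,
    find_focal_plane,
    fit_axial_profile,
    label_localizations,
    link_beads,
    select_amplitude_threshold,
    select_width_threshold,
)
from vlsmlm.calibration import FWHM_PER_SIGMA, BeadTrace, CalibrationError


def _loc_table(frames, xs, ys, zs):
    return pd.DataFrame({
        "frame": frames,
        "x_nm": xs,
        "y_nm": ys,
        "sigma_nm": 175.0,
        "amplitude_photons_um2": 2000.0,
        "offset_photons": 2.0,
        "intensity_photons": 1000.0,
        "precision_nm": 10.0,
        "fit_ok": True,
        "true_z_nm": zs,
    })


def _fake_trace(z_steps, intensity, bead_id=0):
    n = len(z_steps)
    locs = _loc_table(np.arange(n), np.full(n, 1000.0), np.full(n, 1000.0), z_steps)
    return BeadTrace(bead_id=bead_id, locs=locs, z_steps=np.asarray(z_steps, float),
                     boxed_intensity=np.asarray(intensity, float))


class TestLinkBeads:
    def test_single_bead_full_trace(self, rng):
        z = np.repeat([-100.0, 0.0, 100.0], 4)
        frames = np.arange(12)
        tab = _loc_table(frames, 2000 + rng.normal(0, 5, 12), 3000 + rng.normal(0, 5, 12), z)
        traces = link_beads(tab, z)
        assert len(traces) == 1
        assert len(traces[0].locs) == 12

    def test_two_distant_beads_membership_matches_truth(self, rng):
        z = np.repeat([-100.0, 0.0, 100.0], 2)
        frames = np.tile(np.arange(6), 2)
        xs = np.concatenate([np.full(6, 1000.0), np.full(6, 6000.0)]) + rng.normal(0, 5, 12)
        tab = _loc_table(frames, xs, np.full(12, 2000.0), np.tile(z, 2)[:12])
        tab["true_z_nm"] = np.concatenate([z, z])
        traces = link_beads(tab, z)
        assert len(traces) == 2
        means = sorted(t.locs["x_nm"].mean() for t in traces)
        assert means[0] == pytest.approx(1000.0, abs=20)
        assert means[1] == pytest.approx(6000.0, abs=20)

    def test_close_pair_discarded_with_warning(self, rng):
        z = np.repeat([-100.0, 0.0, 100.0], 2)
        frames = np.tile(np.arange(6), 2)
        xs = np.concatenate([np.full(6, 1000.0), np.full(6, 1100.0)]) + rng.normal(0, 2, 12)
        tab = _loc_table(frames, xs, np.full(12, 2000.0), np.concatenate([z, z]))
        with pytest.warns(UserWarning, match="ambiguous"):
            traces = link_beads(tab, z)
        assert traces == []

    def test_short_trace_dropped(self, rng):
        z = np.repeat(np.arange(-200.0, 201.0, 100.0), 2)  # 5 steps
        frames = np.arange(10)
        tab = _loc_table(frames, np.full(10, 2000.0), np.full(10, 2000.0), z)
        tab = pd.concat([
            tab,
            _loc_table([0], [7000.0], [7000.0], [-200.0]),  # 1 of 5 steps only
        ], ignore_index=True)
        traces = link_beads(tab, z)
        assert len(traces) == 1


class TestFindFocalPlane:
    def test_injected_maximum_recovered(self):
        z = np.arange(-200.0, 201.0, 20.0)  # 21 steps
        prof = np.ones(21)
        prof[17] = 5.0
        assert find_focal_plane(_fake_trace(z, prof)) == 17

    def test_tie_broken_toward_median_index(self):
        z = np.arange(-200.0, 201.0, 20.0)
        prof = np.ones(21)
        prof[10] = prof[12] = 5.0  # median index 10
        assert find_focal_plane(_fake_trace(z, prof)) == 10

    def test_flat_profile_is_an_error(self):
        z = np.arange(-100.0, 101.0, 50.0)
        with pytest.raises(CalibrationError, match="flat"):
            find_focal_plane(_fake_trace(z, np.ones(5)))


class TestAxialProfile:
    def test_fwhm_sigma_ratio_exact(self):
        p = AxialProfile(np.arange(3.0), np.ones(3), np.zeros(3), sigma_ax=283.0)
        assert p.fwhm / p.sigma_ax == FWHM_PER_SIGMA

    def test_noiseless_gaussian_recovers_666_fwhm(self):
        z = np.arange(-1000.0, 1001.0, 10.0)
        shape = np.exp(-(z**2) / (2 * 283.0**2))
        prof = fit_axial_profile([_fake_trace(z, shape)])
        assert prof.sigma_ax == pytest.approx(283.0, abs=0.2)
        assert prof.fwhm == pytest.approx(666.0, abs=0.5)
        assert prof.center == pytest.approx(0.0, abs=0.5)

    def test_mirrored_profile_negates_center(self):
        z = np.arange(-500.0, 501.0, 25.0)
        shape = np.exp(-((z - 120.0) ** 2) / (2 * 283.0**2))
        a = fit_axial_profile([_fake_trace(z, shape)])
        b = fit_axial_profile([_fake_trace(z, shape[::-1])])
        assert b.sigma_ax == pytest.approx(a.sigma_ax, rel=1e-6)
        assert b.center == pytest.approx(-a.center, abs=1e-6)

    def test_noisy_recovery_bias_below_2_percent(self, rng):
        z = np.arange(-800.0, 801.0, 40.0)
        z0s, sigmas = [], []
        for _ in range(20):
            shape = np.exp(-((z - 50.0) ** 2) / (2 * 283.0**2)) + rng.normal(0, 0.02, len(z))
            p = fit_axial_profile([_fake_trace(z, shape)])
            z0s.append(p.center)
            sigmas.append(p.sigma_ax)
        assert np.mean(sigmas) == pytest.approx(283.0, rel=0.02)
        assert np.mean(z0s) == pytest.approx(50.0, abs=0.02 * 283.0)


class TestDefineVls:
    def test_fwhm_thickness(self):
        p = AxialProfile(np.arange(3.0), np.ones(3), np.zeros(3),
                         center=10.0, sigma_ax=283.0)
        b = define_vls(p, thickness_mode="fwhm")
        assert b.z0 == 10.0
        # half the FWHM of a sigma = 283 nm Gaussian: 666.4 / 2
        assert b.half_thickness == pytest.approx(333.2, abs=0.3)

    def test_explicit_600nm_convention(self):
        p = AxialProfile(np.arange(3.0), np.ones(3), np.zeros(3),
                         center=0.0, sigma_ax=283.0)
        b = define_vls(p, thickness_mode="explicit", explicit_thickness_nm=600.0)
        assert b.half_thickness == 300.0

    def test_focal_plane_center_preferred_when_available(self):
        p = AxialProfile(np.arange(3.0), np.ones(3), np.zeros(3),
                         center=7.0, sigma_ax=283.0, focal_plane_z=20.0)
        assert define_vls(p, "explicit", 600.0).z0 == 20.0
        assert define_vls(p, "explicit", 600.0, center_mode="fit").z0 == 7.0

    def test_zero_thickness_rejected(self):
        p = AxialProfile(np.arange(3.0), np.ones(3), np.zeros(3), sigma_ax=283.0)
        with pytest.raises(ValueError):
            define_vls(p, thickness_mode="explicit", explicit_thickness_nm=0.0)


class TestLabeling:
    def test_boundary_inclusive(self):
        tab = _loc_table([0, 1, 2], [0, 0, 0], [0, 0, 0], [0.0, 300.0, 300.1])
        labeled = label_localizations(tab, VlsBounds(0.0, 300.0))
        assert labeled.table["in_vls"].tolist() == [True, True, False]

    def test_counts_match_brute_force(self, rng):
        z = rng.uniform(-800, 800, 300)
        tab = _loc_table(np.zeros(300, int), np.zeros(300), np.zeros(300), z)
        bounds = VlsBounds(25.0, 300.0)
        labeled = label_localizations(tab, bounds)
        expected = sum(1 for v in z if abs(v - 25.0) <= 300.0)
        assert int(labeled.table["in_vls"].sum()) == expected

    def test_missing_z_is_an_error(self):
        tab = _loc_table([0], [0], [0], [np.nan])
        with pytest.raises(ValueError):
            label_localizations(tab, VlsBounds(0.0, 300.0))


def _oracle_counts(widths, amps, in_vls, parameter, threshold, prior=None):
    """Per-point recount, the independent oracle for curve statistics."""
    tp = fp = fn = 0
    n = len(widths)
    prior = [True] * n if prior is None else prior
    for i in range(n):
        v = widths[i] if parameter == "width" else amps[i]
        kept = prior[i] and (v <= threshold if parameter == "width" else v >= threshold)
        if kept and in_vls[i]:
            tp += 1
        elif kept:
            fp += 1
        elif in_vls[i]:
            fn += 1
    return tp, fp, fn


def _random_labeled(rng, n=200):
    tab = _loc_table(np.zeros(n, int), np.zeros(n), np.zeros(n), np.zeros(n))
    tab["sigma_nm"] = rng.uniform(120, 400, n)
    tab["amplitude_photons_um2"] = rng.uniform(500, 5000, n)
    tab["in_vls"] = rng.random(n) < 0.6
    return LabeledLocalizationSet(tab, VlsBounds(0.0, 300.0))


class TestConfidenceRecallCurve:
    def test_formula_on_known_counts(self):
        # 9 in-vls kept, 1 out-vls kept, 1 in-vls rejected
        tab = _loc_table(np.zeros(11, int), np.zeros(11), np.zeros(11), np.zeros(11))
        tab["sigma_nm"] = [150.0] * 10 + [250.0]
        tab["in_vls"] = [True] * 9 + [False] + [True]
        labeled = LabeledLocalizationSet(tab, VlsBounds(0.0, 300.0))
        curve = confidence_recall_curve(labeled, "width", np.array([200.0]))
        assert curve.confidence[0] == pytest.approx(0.9)
        assert curve.recall[0] == pytest.approx(0.9)

    def test_loosest_threshold_limit(self, rng):
        labeled = _random_labeled(rng)
        curve = confidence_recall_curve(labeled, "width", np.array([1e9]))
        assert curve.recall[0] == 1.0
        assert curve.confidence[0] == pytest.approx(labeled.table["in_vls"].mean())

    def test_undefined_confidence_is_nan_not_zero(self, rng):
        labeled = _random_labeled(rng)
        curve = confidence_recall_curve(labeled, "width", np.array([1.0]))
        assert np.isnan(curve.confidence[0])
        assert curve.tp[0] + curve.fp[0] == 0

    @pytest.mark.parametrize("parameter", ["width", "amplitude"])
    def test_full_scan_equals_per_point_oracle(self, rng, parameter):
        labeled = _random_labeled(rng, n=200)
        widths = labeled.table["sigma_nm"].to_numpy()
        amps = labeled.table["amplitude_photons_um2"].to_numpy()
        in_vls = labeled.table["in_vls"].to_numpy()
        thresholds = np.linspace(100, 5000, 60)
        curve = confidence_recall_curve(labeled, parameter, thresholds)
        for k, t in enumerate(thresholds):
            tp, fp, fn = _oracle_counts(widths, amps, in_vls, parameter, t)
            assert (curve.tp[k], curve.fp[k], curve.fn[k]) == (tp, fp, fn)

    def test_prior_filter_feeds_false_negatives(self, rng):
        labeled = _random_labeled(rng, n=150)
        prior = labeled.table["sigma_nm"].to_numpy() <= 250.0
        thresholds = np.array([1000.0, 2500.0])
        curve = confidence_recall_curve(labeled, "amplitude", thresholds, prior)
        widths = labeled.table["sigma_nm"].to_numpy()
        amps = labeled.table["amplitude_photons_um2"].to_numpy()
        in_vls = labeled.table["in_vls"].to_numpy()
        for k, t in enumerate(thresholds):
            tp, fp, fn = _oracle_counts(widths, amps, in_vls, "amplitude", t, list(prior))
            assert (curve.tp[k], curve.fp[k], curve.fn[k]) == (tp, fp, fn)

    def test_recall_monotone_as_width_cut_tightens(self, rng):
        labeled = _random_labeled(rng)
        thresholds = np.linspace(100, 450, 80)
        curve = confidence_recall_curve(labeled, "width", thresholds)
        assert np.all(np.diff(curve.recall) >= 0)  # looser cut, higher recall
        assert np.all(np.diff(curve.fp) >= 0)

    def test_empty_set_rejected(self):
        empty = LabeledLocalizationSet(
            _loc_table([], [], [], []).assign(in_vls=pd.Series(dtype=bool)),
            VlsBounds(0.0, 300.0),
        )
        with pytest.raises(ValueError):
            confidence_recall_curve(empty, "width", np.array([200.0]))


def _curve(thresholds, conf, rec):
    n = len(thresholds)
    kept = np.full(n, 100)
    return ThresholdCurve("width", np.asarray(thresholds, float),
                          np.asarray(conf, float), np.asarray(rec, float),
                          tp=kept, fp=kept, fn=kept)


class TestSelectWidthThreshold:
    def test_exact_crossing_at_sample(self):
        c = _curve([200, 210, 220], [0.95, 0.93, 0.90], [0.80, 0.93, 0.99])
        assert select_width_threshold(c, "structural") == 210.0

    def test_interpolated_crossing_at_223(self):
        # conf-rec: +0.03 at 220, -0.07 at 230 -> crossing at 223.0
        c = _curve([210, 220, 230], [0.99, 0.95, 0.88], [0.80, 0.92, 0.95])
        assert select_width_threshold(c, "structural") == pytest.approx(223.0)

    def test_no_crossing_advises_wider_scan(self):
        c = _curve([200, 210], [0.99, 0.98], [0.50, 0.60])
        with pytest.raises(CalibrationError, match="widen"):
            select_width_threshold(c, "structural")

    def test_confidence_plateau_tie_breaks_larger(self):
        c = _curve([200, 205, 210, 215], [0.97, 0.99, 0.99, 0.95],
                   [0.5, 0.6, 0.7, 0.8])
        assert select_width_threshold(c, "confidence") == 210.0

    def test_confidence_ignores_unsupported_spikes(self):
        c = ThresholdCurve(
            "width", np.array([150.0, 200.0, 250.0]),
            confidence=np.array([1.0, 0.97, 0.90]),
            recall=np.array([0.001, 0.7, 0.95]),
            tp=np.array([2, 700, 950]), fp=np.array([0, 22, 106]),
            fn=np.array([998, 300, 50]),
        )
        assert select_width_threshold(c, "confidence") == 200.0


class TestSelectAmplitudeThreshold:
    def test_separable_case_full_confidence(self):
        tab = _loc_table(np.zeros(20, int), np.zeros(20), np.zeros(20), np.zeros(20))
        tab["amplitude_photons_um2"] = np.r_[np.linspace(3000, 5000, 10),
                                             np.linspace(500, 1500, 10)]
        tab["in_vls"] = [True] * 10 + [False] * 10
        labeled = LabeledLocalizationSet(tab, VlsBounds(0.0, 300.0))
        t = select_amplitude_threshold(labeled, 1e9, 0.95)
        assert t == 3000.0  # smallest qualifying candidate

    def test_matches_exhaustive_oracle(self, rng):
        tab = _loc_table(np.zeros(50, int), np.zeros(50), np.zeros(50), np.zeros(50))
        tab["amplitude_photons_um2"] = rng.uniform(500, 5000, 50)
        tab["in_vls"] = rng.random(50) < 0.6
        labeled = LabeledLocalizationSet(tab, VlsBounds(0.0, 300.0))
        target = 0.75
        amps = tab["amplitude_photons_um2"].to_numpy()
        in_vls = tab["in_vls"].to_numpy()
        best = None
        for t in sorted(np.unique(amps)):
            kept = amps >= t
            conf = (kept & in_vls).sum() / kept.sum()
            if conf >= target:
                best = t
                break
        assert select_amplitude_threshold(labeled, 1e9, target) == best

    def test_unreachable_target_reports_maximum(self, rng):
        tab = _loc_table(np.zeros(40, int), np.zeros(40), np.zeros(40), np.zeros(40))
        tab["amplitude_photons_um2"] = np.tile(np.linspace(500, 5000, 20), 2)
        tab["in_vls"] = [True, False] * 20  # interleaved everywhere
        labeled = LabeledLocalizationSet(tab, VlsBounds(0.0, 300.0))
        with pytest.raises(CalibrationError, match="unreachable"):
            select_amplitude_threshold(labeled, 1e9, 0.999)


class TestExportParameterProfiles:
    def test_extrema_and_sd_recount(self, small_calibration):
        profiles = export_parameter_profiles(small_calibration.traces)
        width = profiles["width"]
        amp = profiles["amplitude"]
        # width minimal and amplitude maximal within one step of focus
        assert abs(width.loc[width["mean"].idxmin(), "z_nm"]) <= 25.0
        assert abs(amp.loc[amp["mean"].idxmax(), "z_nm"]) <= 25.0
        assert (width["sd"] >= 0).all()
        # independent recount of one band
        pooled = pd.concat([t.locs for t in small_calibration.traces])
        z0 = width["z_nm"].iloc[3]
        sub = pooled[pooled["true_z_nm"] == z0]["sigma_nm"]
        assert width["mean"].iloc[3] == pytest.approx(sub.mean())
        assert width["sd"].iloc[3] == pytest.approx(sub.std(ddof=1))
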