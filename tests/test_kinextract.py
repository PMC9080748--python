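"""Kinematic variable extraction: centroid/marker summaries, z-score marker
selection, extrema geometry, frequency, handedness."""

import numpy as np
import pytest

from sidewinderkin import (KinextractConfig, SmoothConfig, TrialGroundTruth,
                           TrialMeta, WaveParams, apply_handedness_sign,
                           centroid_kinematics, cycle_frequency,
                           detect_extrema, extract_trial_kinematics,
                           generate_trajectory, interpolate_extrema,
                           marker_summaries, smooth_trial, wave_geometry,
                           zscore_select)
from sidewinderkin.kinextract import ExtremumEvent, ExtremumTrack
from sidewinderkin.smoothing import SmoothedKinematicsSet


def make_smoothed(position_fn, n=600, n_markers=10, rate=250.0):
    """Build a SmoothedKinematicsSet directly from an analytic motion."""
    from sidewinderkin.smoothing import central_difference

    t = np.arange(n) / rate
    pos = position_fn(t)  # (n, markers, 3)
    x = np.moveaxis(pos, 0, -1)
    vel = np.moveaxis(central_difference(x, 1 / rate, 1), -1, 0)
    acc = np.moveaxis(central_difference(x, 1 / rate, 2), -1, 0)
    return SmoothedKinematicsSet(
        displacement=pos, velocity=vel, acceleration=acc, frame_rate_hz=rate,
        retained_range=(0, n), meta=TrialMeta(trial_id="analytic"))


class TestCentroidKinematics:
    def test_rigid_translation(self):
        def motion(t):
            pos = np.zeros((t.size, 10, 3))
            pos[:, :, 0] = np.arange(10)
            pos[:, :, 1] = 10.0 * t[:, None]
            return pos

        k = make_smoothed(motion)
        mean_s, peak_s, mean_a, peak_a = centroid_kinematics(k)
        assert mean_s == pytest.approx(10.0, abs=1e-8)
        assert peak_s == pytest.approx(10.0, abs=1e-8)
        assert mean_a == pytest.approx(0.0, abs=1e-5)
        assert peak_a == pytest.approx(0.0, abs=1e-5)

    def test_static_trial_all_zero(self):
        k = make_smoothed(lambda t: np.zeros((t.size, 10, 3)))
        assert centroid_kinematics(k) == (0.0, 0.0, 0.0, 0.0)

    def test_missing_marker_rejected(self):
        k = make_smoothed(lambda t: np.zeros((t.size, 10, 3)))
        k.displacement[5, 3, 0] = np.nan
        with pytest.raises(ValueError, match="markers"):
            centroid_kinematics(k)


class TestMarkerSummaries:
    def test_zero_lift_heights(self):
        def motion(t):
            pos = np.zeros((t.size, 10, 3))
            pos[:, :, 1] = 5.0 * t[:, None]
            return pos

        peak_speed, max_height = marker_summaries(make_smoothed(motion))
        np.testing.assert_allclose(max_height, 0.0)
        np.testing.assert_allclose(peak_speed, 5.0, atol=1e-8)


class TestZScoreSelect:
    def test_identical_markers_full_range(self):
        values = np.ones((5, 10))
        with pytest.warns(UserWarning):
            band = zscore_select(values, candidate_range=(1, 10))
        assert band == (1, 10)

    def test_constructed_band_found_by_brute_force(self, rng):
        # markers 3-7 hug the trial mean; head/tail markers sit far away on
        # both sides so their |z| scores stay large
        offsets = np.array([30.0, -30.0, 0, 0, 0, 0, 0, 24.0, -24.0, 30.0])
        n_trials = 8
        values = np.empty((n_trials, 10))
        for i in range(n_trials):
            base = rng.normal(50, 5)
            values[i] = base + offsets + np.r_[np.zeros(2),
                                              rng.normal(0, 0.1, 5),
                                              np.zeros(3)]
        assert zscore_select(values, (1, 10)) == (3, 7)

    def test_paper_bands(self):
        assert zscore_select(np.ones((1, 10)),
                             use_paper_bands="peak_speed") == (3, 7)
        assert zscore_select(np.ones((1, 10)),
                             use_paper_bands="height") == (2, 8)


def _triangle_wave_trial(apex_frames=None, n=600, rate=250.0):
    """Markers on a static triangle wave whose apex bobs slightly in time so
    the temporal angle minimum is well defined."""
    xs = np.arange(10, dtype=float) * 4.0
    ys = np.where(np.arange(10) % 2 == 0, 0.0, 6.0)

    def motion(t):
        pos = np.zeros((t.size, 10, 3))
        pos[:, :, 0] = xs
        pos[:, :, 1] = ys + 0.0 * t[:, None]
        # slight vertical-in-plane oscillation of odd markers sharpens and
        # relaxes the apex angle over time
        wob = 1.0 * np.cos(2 * np.pi * 1.0 * t)[:, None]
        pos[:, 1::2, 1] += wob
        pos[:, :, 1] += 5.0 * t[:, None]  # travel so direction is defined
        return pos

    return make_smoothed(motion, n=n, rate=rate)


class TestDetectExtrema:
    def test_straight_body_no_events(self):
        def motion(t):
            pos = np.zeros((t.size, 10, 3))
            pos[:, :, 0] = np.arange(10) * 3.0
            pos[:, :, 1] = 2.0 * t[:, None]
            return pos

        assert detect_extrema(make_smoothed(motion)) == []

    def test_apex_marker_emits_events(self):
        k = _triangle_wave_trial()
        events = detect_extrema(k, band=(4, 9), prominence_deg=2.0)
        assert events, "apex markers must emit extremum events"
        # events occur when the apex angle is sharpest (wobble maximum)
        markers = {e.marker for e in events}
        assert markers <= {5, 6, 7, 8}

    def test_kind_labels_chiral(self, slow_smoothed):
        events = detect_extrema(slow_smoothed)
        kinds = {e.kind for e in events}
        assert kinds == {"crest", "trough"}


class TestInterpolateExtrema:
    def test_two_event_linear_interpolation(self):
        evs = [ExtremumEvent(5, 0.0, np.array([0.0, 0.0, 0.0]), "crest"),
               ExtremumEvent(6, 1.0, np.array([2.0, 2.0, 0.0]), "crest")]
        tracks = interpolate_extrema(evs)
        assert len(tracks) == 1
        np.testing.assert_allclose(tracks[0].at(np.array([0.5]))[0, :2],
                                   [1.0, 1.0])

    def test_interior_event_reproduced_by_neighbours(self):
        evs = [ExtremumEvent(5, 0.0, np.array([0.0, 0.0, 0.0]), "trough"),
               ExtremumEvent(6, 1.0, np.array([1.0, 3.0, 0.0]), "trough"),
               ExtremumEvent(7, 2.0, np.array([2.0, 6.0, 0.0]), "trough")]
        tracks = interpolate_extrema(evs)
        assert len(tracks) == 1
        mid = ExtremumTrack(
            kind="trough",
            times=np.array([0.0, 2.0]),
            positions=np.array([[0, 0, 0], [2, 6, 0.0]]),
        ).at(np.array([1.0]))
        np.testing.assert_allclose(mid[0], [1.0, 3.0, 0.0])

    def test_single_events_dropped_with_warning(self):
        evs = [ExtremumEvent(5, 0.0, np.zeros(3), "crest")]
        with pytest.warns(UserWarning, match="unchainable"):
            assert interpolate_extrema(evs) == []


class TestWaveGeometry:
    @staticmethod
    def _static_tracks(points, kinds):
        tracks = []
        for (x, y), kind in zip(points, kinds):
            tracks.append(ExtremumTrack(
                kind=kind, times=np.array([0.0, 1.0]),
                positions=np.array([[x, y, 0.0], [x, y, 0.0]])))
        return tracks

    def test_symmetric_triangle_zero_skew(self):
        tracks = self._static_tracks([(0, 0), (5, -8), (10, 0)],
                                     ["trough", "crest", "trough"])
        wl, amp, skew, n = wave_geometry(tracks, np.array([0.5]),
                                         travel=np.array([0.0, 1.0]))
        assert n == 1
        assert wl == pytest.approx(10.0)
        assert amp == pytest.approx(8.0)
        assert skew == pytest.approx(0.0, abs=1e-10)

    def test_amplitude_is_median_times_cos_skew(self):
        # |median| = 10 tilted 30 deg from the base perpendicular; the
        # altitude (peak-to-peak amplitude) is 10*cos(30)
        mx = 10 * np.sin(np.radians(30.0))
        my = -10 * np.cos(np.radians(30.0))
        tracks = self._static_tracks(
            [(-6, 0), (mx, my), (6, 0)],
            ["trough", "crest", "trough"])
        wl, amp, skew, n = wave_geometry(tracks, np.array([0.5]),
                                         travel=np.array([0.0, 1.0]))
        assert n == 1
        assert amp == pytest.approx(10.0 * np.cos(np.radians(30.0)))
        assert abs(skew) == pytest.approx(30.0)

    def test_cos_sixty_halves_the_median(self):
        mx = 10 * np.sin(np.radians(60.0))
        my = -10 * np.cos(np.radians(60.0))
        tracks = self._static_tracks(
            [(-9, 0), (mx, my), (9, 0)],
            ["trough", "crest", "trough"])
        _, amp, skew, n = wave_geometry(tracks, np.array([0.5]),
                                        travel=np.array([0.0, 1.0]))
        assert n == 1
        assert amp == pytest.approx(5.0)
        assert abs(skew) == pytest.approx(60.0)

    def test_no_complete_triple_returns_missing(self):
        tracks = self._static_tracks([(0, 0), (5, -8)], ["trough", "crest"])
        wl, amp, skew, n = wave_geometry(tracks, np.array([0.5]),
                                         travel=np.array([0.0, 1.0]))
        assert n == 0 and np.isnan(wl) and np.isnan(amp) and np.isnan(skew)


class TestCycleFrequency:
    @staticmethod
    def _events(times, marker=5, kind="crest"):
        return [ExtremumEvent(marker, t, np.zeros(3), kind) for t in times]

    def test_exact_half_second_period(self):
        assert cycle_frequency(self._events([0, 0.5, 1.0, 1.5])) == \
            pytest.approx(2.0)

    def test_median_robust_to_spurious_period(self):
        evs = self._events([0.0, 0.5, 1.0, 6.0])  # periods 0.5, 0.5, 5.0
        assert cycle_frequency(evs) == pytest.approx(2.0)

    def test_insufficient_events_missing(self):
        assert np.isnan(cycle_frequency(self._events([0.0])))


class TestHandedness:
    def test_right_unchanged_left_negated(self):
        assert apply_handedness_sign(10.0, "right") == 10.0
        assert apply_handedness_sign(10.0, "left") == -10.0

    def test_unknown_handedness_demands_annotation(self):
        with pytest.raises(ValueError, match="annotated"):
            apply_handedness_sign(10.0, "unknown")

    def test_mirrored_pair_identical_after_correction(self):
        def kin_for(hand):
            wave = WaveParams(frequency_hz=0.3, wavelength_cm=20.0,
                              amplitude_cm=10.0, skew_deg=5.0,
                              lift_height_cm=2.0, duty=0.25,
                              smooth_frac=0.04, handedness=hand)
            gt = TrialGroundTruth(wave=wave, n_frames=4500, seed=3)
            return extract_trial_kinematics(
                smooth_trial(generate_trajectory(gt)))

        right = kin_for("right")
        left = kin_for("left")
        assert right.skew_deg == pytest.approx(left.skew_deg, abs=1e-9)
        assert right.skew_deg == pytest.approx(5.0, abs=2.0)


class TestEndToEnd:
    def test_slow_trial_recovers_all_wave_parameters(self, slow_trial,
                                                     slow_smoothed):
        kin = extract_trial_kinematics(slow_smoothed)
        w = slow_trial.wave
        assert kin.centroid_mean_speed == pytest.approx(
            slow_trial.centroid_speed_cm_s, rel=0.02)
        assert kin.frequency_hz == pytest.approx(w.frequency_hz, rel=0.02)
        assert kin.wavelength_cm == pytest.approx(w.wavelength_cm, rel=0.05)
        assert kin.amplitude_cm == pytest.approx(w.amplitude_cm, rel=0.05)
        assert kin.skew_deg == pytest.approx(w.skew_deg, abs=2.0)
        assert kin.height_lifted_mean == pytest.approx(w.lift_height_cm,
                                                       rel=0.05)

    def test_rigid_motion_invariance(self, slow_tracks):
        from sidewinderkin import MarkerTrackSet

        base = extract_trial_kinematics(smooth_trial(slow_tracks))
        th = np.radians(35.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pos = slow_tracks.positions.copy()
        pos[:, :, :2] = pos[:, :, :2] @ R.T + np.array([12.0, -40.0])
        moved = MarkerTrackSet(positions=pos,
                               frame_rate_hz=slow_tracks.frame_rate_hz,
                               meta=slow_tracks.meta)
        rot = extract_trial_kinematics(smooth_trial(moved))
        for attr in ("centroid_mean_speed", "centroid_peak_speed",
                     "wavelength_cm", "amplitude_cm", "frequency_hz",
                     "height_lifted_mean"):
            assert getattr(rot, attr) == pytest.approx(
                getattr(base, attr), rel=1e-6), attr
        assert abs(rot.skew_deg) == pytest.approx(abs(base.skew_deg),
                                                  rel=1e-6)

    def test_too_short_trial_reports_missing_not_fabricated(self):
        wave = WaveParams(frequency_hz=0.3, wavelength_cm=20.0,
                          amplitude_cm=10.0, skew_deg=5.0, lift_height_cm=2.0,
                          duty=0.25, smooth_frac=0.04)
        gt = TrialGroundTruth(wave=wave, n_frames=700, seed=2,
                              min_cycles=0.5)
        kin = extract_trial_kinematics(smooth_trial(generate_trajectory(gt)))
        # under a single cycle the wave triangle cannot be built
        assert np.isnan(kin.wavelength_cm)
        assert np.isnan(kin.amplitude_cm)
        assert np.isfinite(kin.centroid_mean_speed)

    def test_fast_sharp_wave_recovers_frequency_wavelength_speed(self):
        # fast cycles with a sharp-cornered wave exceed the smoothing
        # filter's passband: frequency, wavelength and speed survive, but
        # waveform shape (amplitude, skew, lift) is low-pass distorted
        wave = WaveParams(frequency_hz=1.5, wavelength_cm=20.0,
                          amplitude_cm=16.0, skew_deg=15.0,
                          lift_height_cm=2.0, duty=0.5, smooth_frac=0.06)
        gt = TrialGroundTruth(wave=wave, n_frames=2500, seed=1)
        kin = extract_trial_kinematics(smooth_trial(generate_trajectory(gt)))
        assert kin.frequency_hz == pytest.approx(1.5, rel=0.02)
        assert kin.wavelength_cm == pytest.approx(20.0, rel=0.05)
        assert kin.centroid_mean_speed == pytest.approx(
            gt.centroid_speed_cm_s, rel=0.05)
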