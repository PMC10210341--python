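"""Kinematic feature extraction: T_M, AS, CI, NS and CI-outlier rejection."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from reacheval import (
    DegenerateTrialError,
    FeatureOptions,
    ReachTarget,
    Session,
    SyntheticConfig,
    ValidationError,
    average_speed,
    curvature_index,
    decompose_submovements,
    extract_features,
    generate_erroneous_session,
    min_jerk_speed,
    movement_time,
    reject_ci_outliers,
    tangential_speed,
)
from reacheval.data import KinematicFeatures, features_to_frame

from conftest import make_trial

DT = 1.0 / 75.0


def min_jerk_trial(duration_s=2.0, displacement_cm=10.0, rate=75.0, recorded=None):
    t = np.arange(0, duration_s + 1e-9, 1.0 / rate)
    tau = t / duration_s
    frac = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return make_trial(t, displacement_cm * frac, np.zeros_like(t), recorded_ms=recorded)


class TestMovementTime:
    def test_recorded_value_passes_through(self):
        tr = min_jerk_trial(recorded=1894.0)
        assert movement_time(tr, use_recorded=True) == 1894.0

    def test_min_jerk_pulse_threshold_span(self):
        # crossings of 30 (tau (1-tau))^2 = 0.02 * 1.875 are at
        # tau (1-tau) = sqrt(0.00125), i.e. tau = 0.03670 / 0.96330:
        # a 1853 ms span for a 2.0 s pulse, inward-quantized by sampling
        tr = min_jerk_trial(2.0)
        tm = movement_time(tr, onset_fraction=0.02, use_recorded=False)
        assert tm == pytest.approx(1853.2, abs=30.0)

    def test_constant_speed_segment(self):
        t = np.arange(0, 2.5 + 1e-9, DT)
        x = np.clip(t - 0.5, 0, 1.5) * 4.0
        tr = make_trial(t, x, np.zeros_like(t))
        tm = movement_time(tr, use_recorded=False)
        assert tm == pytest.approx(1500.0, abs=1000.0 * DT)

    def test_stationary_trial_is_degenerate(self):
        t = np.arange(0, 1.0, DT)
        tr = make_trial(t, np.zeros_like(t), np.zeros_like(t))
        with pytest.raises(DegenerateTrialError):
            movement_time(tr, use_recorded=False)


class TestTangentialSpeed:
    def test_uniform_straight_motion(self):
        t = np.arange(0, 2.0 + 1e-9, DT)
        tr = make_trial(t, 10.0 * t / 2.0, np.zeros_like(t))
        v = tangential_speed(tr)
        np.testing.assert_allclose(v[1:-1], 0.05, rtol=1e-9)

    def test_circular_motion_matches_analytic_derivative(self):
        r_cm, omega = 5.0, 2.0
        t = np.arange(0, 2.0, DT)
        tr = make_trial(t, r_cm * np.cos(omega * t), r_cm * np.sin(omega * t))
        v = tangential_speed(tr)
        expected = r_cm * omega / 100.0
        np.testing.assert_allclose(v[1:-1], expected, rtol=(omega * DT) ** 2)

    def test_provided_speed_column_returned_verbatim(self):
        t = np.arange(0, 1.0, DT)
        vcol = np.linspace(0, 1, len(t))
        tr = make_trial(t, t, np.zeros_like(t), v_mps=vcol)
        assert tangential_speed(tr) is tr.v_mps


class TestAverageSpeedAndCurvature:
    def test_straight_path_average_speed(self):
        t = np.arange(0, 2.0 + 1e-9, DT)
        tr = make_trial(t, 10.0 * t / 2.0, np.zeros_like(t))
        assert average_speed(tr, 2000.0, window="full") == pytest.approx(0.05)

    def test_straight_path_ci_is_one(self):
        t = np.arange(0, 2.0 + 1e-9, DT)
        tr = make_trial(t, 10.0 * t / 2.0, 3.0 * t / 2.0)
        assert curvature_index(tr, window="full") == pytest.approx(1.0, abs=1e-12)

    def test_semicircle_ci_is_half_pi(self):
        th = np.linspace(0, np.pi, 400)
        t = np.linspace(0, 2.0, 400)
        r = 5.0
        tr = make_trial(t, r - r * np.cos(th), r * np.sin(th))
        assert curvature_index(tr, window="full") == pytest.approx(np.pi / 2, abs=1e-3)

    def test_jittered_path_matches_polyline_oracle(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 2.0 + 1e-9, DT)
        x = 10.0 * t / 2.0 + rng.normal(0, 0.05, len(t))
        y = rng.normal(0, 0.05, len(t))
        tr = make_trial(t, x, y)
        ci = curvature_index(tr, window="full")
        # independent polyline implementation
        seg = np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2)
        oracle = seg.sum() / math.hypot(x[-1] - x[0], y[-1] - y[0])
        assert ci > 1.0
        assert ci == pytest.approx(oracle, abs=1e-12)

    @given(
        angle=st.floats(0, 2 * np.pi, allow_nan=False),
        scale=st.floats(0.1, 10.0, allow_nan=False),
    )
    def test_ci_invariant_under_rotation_and_scaling(self, angle, scale):
        rng = np.random.default_rng(7)
        t = np.arange(0, 2.0 + 1e-9, DT)
        x = 10.0 * t / 2.0 + rng.normal(0, 0.1, len(t))
        y = rng.normal(0, 0.1, len(t))
        ci0 = curvature_index(make_trial(t, x, y), window="full")
        c, s = np.cos(angle), np.sin(angle)
        xr = scale * (c * x - s * y)
        yr = scale * (s * x + c * y)
        ci1 = curvature_index(make_trial(t, xr, yr), window="full")
        assert ci1 == pytest.approx(ci0, rel=1e-9)

    def test_closed_path_is_degenerate(self):
        th = np.linspace(0, 2 * np.pi, 200)
        t = np.linspace(0, 2.0, 200)
        tr = make_trial(t, np.cos(th) - 1.0, np.sin(th))
        with pytest.raises(DegenerateTrialError):
            curvature_index(tr, window="full")


class TestDecomposition:
    def test_single_exact_pulse(self):
        t = np.arange(0, 2.0 + 1e-9, DT)
        v = min_jerk_speed(t, 0.0, 2.0, 0.10)
        res = decompose_submovements(v, DT)
        assert res.ns == 1
        assert res.tolerance_met
        assert res.reconstruction_rmse_mps < 1e-6

    def test_two_disjoint_pulses(self):
        t = np.arange(0, 2.0 + 1e-9, DT)
        v = min_jerk_speed(t, 0.0, 0.8, 0.08) + min_jerk_speed(t, 1.0, 0.8, 0.04)
        assert decompose_submovements(v, DT).ns == 2

    def test_monotone_in_tolerance(self):
        # loosening the RMSE tolerance never increases the pulse count
        t = np.arange(0, 2.0 + 1e-9, DT)
        v = min_jerk_speed(t, 0.0, 1.0, 0.10) + min_jerk_speed(t, 0.7, 1.0, 0.05)
        counts = [
            decompose_submovements(v, DT, rmse_tolerance_fraction=tol).ns
            for tol in (0.02, 0.05, 0.2, 0.5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_all_zero_speed_is_degenerate(self):
        with pytest.raises(DegenerateTrialError):
            decompose_submovements(np.zeros(100), DT)

    def test_speed_must_be_non_negative(self):
        with pytest.raises(ValidationError):
            decompose_submovements(np.array([0.1, -0.1, 0.2] * 10), DT)


class TestExtractFeatures:
    def test_normal_session_counts_and_ci(self, pilot_normal_session):
        session, _ = pilot_normal_session
        ext = extract_features(session, FeatureOptions(compute_ns=False))
        assert len(ext.features) == 24
        assert not ext.skipped
        assert all(f.ci < 1.5 for f in ext.features)

    def test_generator_round_trip_fidelity(self, pilot_normal_session):
        session, truth = pilot_normal_session
        ext = extract_features(
            session, FeatureOptions(compute_ns=False, window="full")
        )
        frame = features_to_frame(ext.features)
        period_ms = 1000.0 / session.trials[0].sampling_rate_hz
        assert np.max(np.abs(frame.TM_ms.values - truth.TM_ms.values)) < period_ms
        np.testing.assert_allclose(frame.CI.values, truth.CI.values, atol=1e-3)
        np.testing.assert_allclose(frame.AS_mps.values, truth.AS_mps.values, rtol=1e-2)

    def test_as_times_tm_equals_path(self, pilot_normal_session):
        session, _ = pilot_normal_session
        ext = extract_features(session, FeatureOptions(compute_ns=False))
        for f in ext.features:
            path_m = f.as_mps * (f.tm_ms / 1000.0)
            assert path_m == pytest.approx(f.path_cm / 100.0, rel=1e-9)

    def test_extracted_ns_matches_generated_pulse_count(self):
        cfg = SyntheticConfig(seed=7, distances_cm=(10.0,), reps_per_target=1)
        session, truth = generate_erroneous_session(cfg)
        ext = extract_features(session, FeatureOptions(window="full"))
        ns = np.array([f.ns for f in ext.features])
        assert np.all(np.abs(ns - truth.NS.values) <= 1)

    def test_stationary_trial_reported_as_skipped(self, pilot_normal_session):
        session, _ = pilot_normal_session
        t = np.arange(0, 1.0, DT)
        dead = make_trial(
            t,
            np.zeros_like(t),
            np.zeros_like(t),
            target=session.grid[0],
            arm=session.arm,
        )
        dead.subject = session.subject
        dead.trial_id = 999
        patched = Session(
            session.subject, session.arm, session.trials + [dead], session.grid
        )
        ext = extract_features(patched, FeatureOptions(compute_ns=False))
        assert len(ext.features) == 24
        assert [t for t, _ in ext.skipped] == [999]

    def test_empty_session_rejected(self, pilot_normal_session):
        session, _ = pilot_normal_session
        empty = Session(session.subject, session.arm, [], session.grid)
        with pytest.raises(ValidationError):
            extract_features(empty)


def _feat(ci, target=None):
    return KinematicFeatures(
        subject="S",
        arm="affected",
        target=target or ReachTarget(0, 0.0, 10.0, 2.0),
        tm_ms=2000.0,
        as_mps=0.05,
        ci=ci,
        ns=3,
        path_cm=10.0 * ci,
    )


class TestCiOutlierRejection:
    def test_equal_ci_rejects_nothing(self):
        kept, rejected = reject_ci_outliers([_feat(1.1)] * 6)
        assert len(kept) == 6 and not rejected

    def test_hand_computed_fences(self):
        # CI = [1.00, 1.05, 1.10, 1.20, 1.25, 3.00]: Q1 = 1.0625, Q3 = 1.2375
        # (linear interpolation), IQR = 0.175, upper fence = 1.5875
        feats = [_feat(c) for c in (1.00, 1.05, 1.10, 1.20, 1.25, 3.00)]
        kept, rejected = reject_ci_outliers(feats)
        assert [f.ci for f in rejected] == [3.00]
        assert len(kept) == 5

    def test_injected_spikes_are_rejected(self):
        rng = np.random.default_rng(3)
        cis = list(1.0 + rng.uniform(0, 0.3, 115)) + [4.0] * 5
        feats = [_feat(c) for c in cis]
        kept, rejected = reject_ci_outliers(feats)
        assert sorted(f.ci for f in rejected) == [4.0] * 5

    def test_partition_and_idempotence(self):
        rng = np.random.default_rng(4)
        feats = [_feat(c) for c in 1.0 + rng.gamma(1.0, 0.3, 60)]
        kept, rejected = reject_ci_outliers(feats)
        assert len(kept) + len(rejected) == len(feats)
        # order preserved within the kept subset
        kept_cis = [f.ci for f in kept]
        orig_kept = [f.ci for f in feats if f.ci in kept_cis]
        assert kept_cis == orig_kept
        # fences recomputed from the original sample reject nothing further
        ci = np.array([f.ci for f in feats])
        q1, q3 = np.percentile(ci, [25, 75])
        lo, hi = q1 - 2 * (q3 - q1), q3 + 2 * (q3 - q1)
        assert all(lo <= f.ci <= hi for f in kept)

    def test_too_few_rows_refused(self):
        with pytest.raises(ValidationError):
            reject_ci_outliers([_feat(1.1)] * 4)
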