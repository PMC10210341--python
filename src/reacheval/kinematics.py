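"""Per-trial kinematic features of planar reaching.

Extracts movement time (T_M), average speed (AS), curvature index (CI) and
the number of submovements (NS) from sampled trajectories, and applies the
interquartile-fence rejection of extreme-CI trials used before model
fitting.

The submovement count comes from decomposing the tangential speed profile
into minimum-jerk speed pulses

    v(tau) = (s / D) * (30 tau^2 - 60 tau^3 + 30 tau^4),   tau = (t - t0)/D,

choosing the *smallest* pulse count whose best least-squares fit reaches a
relative RMSE tolerance, so that corrective-movement counts are not
exaggerated by over-segmentation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .data import (
    DegenerateTrialError,
    KinematicFeatures,
    Session,
    TrialTrajectory,
    ValidationError,
)

__all__ = [
    "SubmovementPulse",
    "DecompositionResult",
    "FeatureOptions",
    "FeatureExtraction",
    "min_jerk_speed",
    "tangential_speed",
    "movement_window",
    "movement_time",
    "average_speed",
    "curvature_index",
    "decompose_submovements",
    "extract_features",
    "reject_ci_outliers",
]

# Peak of the unit minimum-jerk speed kernel 30 tau^2 (1 - tau)^2 at tau = 1/2.
MIN_JERK_PEAK = 1.875


@dataclass(frozen=True)
class SubmovementPulse:
    """One minimum-jerk speed pulse: onset t0 [s], duration D [s],
    displacement s [cm]."""

    t0: float
    duration_s: float
    displacement_cm: float

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValidationError("pulse duration must be > 0")
        if not self.displacement_cm > 0:
            raise ValidationError("pulse displacement must be > 0")


@dataclass
class DecompositionResult:
    ns: int
    pulses: list[SubmovementPulse]
    reconstruction_rmse_mps: float
    tolerance_met: bool

    def __post_init__(self) -> None:
        if self.ns != len(self.pulses) or self.ns < 1:
            raise ValidationError("NS must equal the pulse count and be >= 1")
        if self.reconstruction_rmse_mps < 0:
            raise ValidationError("RMSE must be >= 0")


def min_jerk_speed(
    t: np.ndarray, t0: float, duration_s: float, displacement: float
) -> np.ndarray:
    """Minimum-jerk speed pulse sampled at times ``t`` (same displacement
    units per second as ``displacement``)."""
    tau = (np.asarray(t, float) - t0) / duration_s
    v = np.zeros_like(tau)
    m = (tau >= 0) & (tau <= 1)
    tm = tau[m]
    v[m] = (displacement / duration_s) * 30.0 * (tm * (1.0 - tm)) ** 2
    return v


def tangential_speed(trial: TrialTrajectory) -> np.ndarray:
    """Tangential speed series in m/s.

    Returns the recorded speed column verbatim when present; otherwise uses
    centered finite differences of (x, y) over t (one-sided at endpoints).
    """
    if trial.n_samples < 5:
        raise ValidationError("need >= 5 samples")
    if np.any(np.diff(trial.t_s) == 0):
        raise ValidationError("duplicate timestamps")
    if trial.v_mps is not None:
        return trial.v_mps
    vx = np.gradient(trial.x_cm, trial.t_s)
    vy = np.gradient(trial.y_cm, trial.t_s)
    return np.hypot(vx, vy) / 100.0  # cm/s -> m/s


def movement_window(
    trial: TrialTrajectory, onset_fraction: float = 0.02
) -> tuple[int, int]:
    """Index range [i0, i1] of the movement proper.

    Onset is the first sample with tangential speed >= onset_fraction x peak
    speed; offset is the last such sample (trailing sub-threshold dwell is
    excluded).
    """
    if not 0 < onset_fraction < 1:
        raise ValidationError("onset_fraction must be in (0, 1)")
    v = tangential_speed(trial)
    peak = float(np.max(v))
    if peak <= 0:
        raise DegenerateTrialError(
            f"trial {trial.trial_id}: stationary trial (zero peak speed)"
        )
    above = np.flatnonzero(v >= onset_fraction * peak)
    return int(above[0]), int(above[-1])


def movement_time(
    trial: TrialTrajectory,
    onset_fraction: float = 0.02,
    use_recorded: bool = True,
) -> float:
    """Movement time T_M in milliseconds.

    Prefers the robot-recorded movement time when present (the recording
    device is authoritative); otherwise measures the onset-to-offset span of
    the speed profile at the given fraction of peak speed.
    """
    if use_recorded and trial.recorded_movement_time_ms is not None:
        return float(trial.recorded_movement_time_ms)
    i0, i1 = movement_window(trial, onset_fraction)
    if i1 <= i0:
        raise DegenerateTrialError(f"trial {trial.trial_id}: empty movement window")
    return float((trial.t_s[i1] - trial.t_s[i0]) * 1000.0)


def _polyline_length_cm(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


def average_speed(trial: TrialTrajectory, tm_ms: float,
                  onset_fraction: float = 0.02, window: str = "threshold") -> float:
    """Average speed AS = path length / T_M, in m/s."""
    if not tm_ms > 0:
        raise ValidationError("T_M must be > 0")
    i0, i1 = _window_indices(trial, onset_fraction, window)
    path_cm = _polyline_length_cm(trial.x_cm[i0 : i1 + 1], trial.y_cm[i0 : i1 + 1])
    if path_cm <= 0:
        raise DegenerateTrialError(f"trial {trial.trial_id}: zero path length")
    return (path_cm / 100.0) / (tm_ms / 1000.0)


def _window_indices(trial, onset_fraction, window) -> tuple[int, int]:
    if window == "full":
        return 0, trial.n_samples - 1
    if window == "threshold":
        return movement_window(trial, onset_fraction)
    raise ValidationError(f"unknown window {window!r}")


def curvature_index(trial: TrialTrajectory, onset_fraction: float = 0.02,
                    window: str = "threshold") -> float:
    """Curvature index CI = path length / straight start-to-end distance.

    1 for a perfectly straight reach; grows with path deviation.
    """
    i0, i1 = _window_indices(trial, onset_fraction, window)
    x = trial.x_cm[i0 : i1 + 1]
    y = trial.y_cm[i0 : i1 + 1]
    chord = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    path = _polyline_length_cm(x, y)
    if chord <= 1e-9 * max(path, 1e-300):
        raise DegenerateTrialError(
            f"trial {trial.trial_id}: closed path (start equals end)"
        )
    return path / chord


# ---------------------------------------------------------------------------
# Submovement decomposition


def _pulse_sum(t: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Sum of minimum-jerk pulses; params is flat (t0, D, s) per pulse."""
    v = np.zeros_like(t)
    for j in range(0, len(params), 3):
        t0, d, s = params[j : j + 3]
        v += min_jerk_speed(t, t0, d, s)
    return v


def _initial_guesses(
    t: np.ndarray, v: np.ndarray, m: int, span: float
) -> list[np.ndarray]:
    """Multi-start initializations from the M largest local speed maxima."""
    peaks, props = find_peaks(v, height=0.0)
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(v))])
        heights = v[peaks]
    else:
        heights = props["peak_heights"]
    order = np.argsort(heights)[::-1]
    peaks = peaks[order][:m]
    starts: list[np.ndarray] = []

    def pack(centers: np.ndarray, d0: float) -> np.ndarray:
        p = []
        for c in centers:
            vp = max(float(np.interp(c, t, v)), 1e-6)
            s0 = vp * d0 / MIN_JERK_PEAK
            p.extend([c - d0 / 2.0, d0, s0])
        return np.array(p)

    d_peak = max(span / (m + 1), 4.0 * (t[1] - t[0]))
    if len(peaks) == m:
        starts.append(pack(t[peaks], d_peak))
    # evenly spread centers as a fallback / second start
    centers = t[0] + (np.arange(m) + 0.5) * span / m
    starts.append(pack(centers, max(span / m, 4.0 * (t[1] - t[0]))))
    return starts


def decompose_submovements(
    speed_mps: np.ndarray,
    dt_s: float,
    rmse_tolerance_fraction: float = 0.05,
    max_pulses: int = 10,
) -> DecompositionResult:
    """Minimal-count minimum-jerk decomposition of a speed profile.

    Returns the smallest pulse count M <= max_pulses whose best nonlinear
    least-squares fit reaches RMSE <= tolerance x peak speed.  If no count
    satisfies the tolerance the result carries M = max_pulses with
    ``tolerance_met`` False.
    """
    v = np.asarray(speed_mps, float)
    if np.any(v < 0):
        raise ValidationError("speed must be non-negative")
    if max_pulses < 1:
        raise ValidationError("max_pulses must be >= 1")
    if not 0 < rmse_tolerance_fraction < 1:
        raise ValidationError("rmse_tolerance_fraction must be in (0, 1)")
    peak = float(np.max(v))
    if peak <= 0:
        raise DegenerateTrialError("all-zero speed profile")
    t = np.arange(len(v)) * dt_s
    span = t[-1] - t[0]
    target = rmse_tolerance_fraction * peak

    best_fallback: tuple[float, np.ndarray] | None = None
    for m in range(1, max_pulses + 1):
        lo = np.tile([t[0] - span, 2 * dt_s, 1e-9], m)
        hi = np.tile([t[-1], 2 * span, 10.0 * peak * span], m)
        best: tuple[float, np.ndarray] | None = None
        for x0 in _initial_guesses(t, v, m, span):
            x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
            sol = least_squares(
                lambda p: _pulse_sum(t, p) - v,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
                max_nfev=400 * m,
            )
            rmse = float(np.sqrt(np.mean(sol.fun**2)))
            if best is None or rmse < best[0]:
                best = (rmse, sol.x)
        assert best is not None
        if best[0] <= target:
            return DecompositionResult(
                ns=m,
                pulses=_params_to_pulses(best[1]),
                reconstruction_rmse_mps=best[0],
                tolerance_met=True,
            )
        if best_fallback is None or best[0] < best_fallback[0]:
            best_fallback = best
    assert best_fallback is not None
    params = best_fallback[1]
    return DecompositionResult(
        ns=len(params) // 3,
        pulses=_params_to_pulses(params),
        reconstruction_rmse_mps=best_fallback[0],
        tolerance_met=False,
    )


def _params_to_pulses(params: np.ndarray) -> list[SubmovementPulse]:
    pulses = [
        SubmovementPulse(
            t0=float(params[j]),
            duration_s=float(params[j + 1]),
            displacement_cm=float(max(params[j + 2], 1e-12)),
        )
        for j in range(0, len(params), 3)
    ]
    return sorted(pulses, key=lambda p: p.t0)


# ---------------------------------------------------------------------------
# Session-level extraction and outlier rejection


@dataclass
class FeatureOptions:
    """Options for feature extraction.

    window: 'threshold' restricts path/CI to the onset-offset window,
    'full' uses the whole sampled trial.  compute_ns False skips the
    (comparatively expensive) submovement decomposition and reports NS = 1.
    """

    onset_fraction: float = 0.02
    use_recorded_tm: bool = True
    window: str = "threshold"
    compute_ns: bool = True
    rmse_tolerance_fraction: float = 0.05
    max_pulses: int = 10


@dataclass
class FeatureExtraction:
    features: list[KinematicFeatures]
    skipped: list[tuple[int, str]]  # (trial_id, reason)


def extract_features(
    session: Session, options: FeatureOptions | None = None
) -> FeatureExtraction:
    """One KinematicFeatures row per non-degenerate trial.

    Degenerate trials (stationary, zero path, closed path) are reported in
    ``skipped`` rather than raising, mirroring protocols in which a trial is
    skipped when the subject cannot reach the target.
    """
    if not session.trials:
        raise ValidationError("empty session")
    opts = options or FeatureOptions()
    features: list[KinematicFeatures] = []
    skipped: list[tuple[int, str]] = []
    for tr in session.trials:
        try:
            tm = movement_time(tr, opts.onset_fraction, opts.use_recorded_tm)
            i0, i1 = _window_indices(tr, opts.onset_fraction, opts.window)
            x = tr.x_cm[i0 : i1 + 1]
            y = tr.y_cm[i0 : i1 + 1]
            path_cm = _polyline_length_cm(x, y)
            chord = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
            if path_cm <= 0 or chord <= 1e-9 * path_cm:
                raise DegenerateTrialError("zero path or closed path")
            as_mps = (path_cm / 100.0) / (tm / 1000.0)
            ci = max(path_cm / chord, 1.0)
            if opts.compute_ns:
                v = tangential_speed(tr)[i0 : i1 + 1]
                dt = float(np.median(np.diff(tr.t_s)))
                dec = decompose_submovements(
                    v, dt, opts.rmse_tolerance_fraction, opts.max_pulses
                )
                ns = dec.ns
            else:
                ns = 1
            features.append(
                KinematicFeatures(
                    subject=tr.subject,
                    arm=tr.arm,
                    target=tr.target,
                    tm_ms=tm,
                    as_mps=as_mps,
                    ci=ci,
                    ns=ns,
                    path_cm=path_cm,
                    trial_id=tr.trial_id,
                )
            )
        except DegenerateTrialError as exc:
            skipped.append((tr.trial_id, str(exc)))
    return FeatureExtraction(features=features, skipped=skipped)


def reject_ci_outliers(
    features: list[KinematicFeatures],
) -> tuple[list[KinematicFeatures], list[KinematicFeatures]]:
    """Partition features into (kept, rejected) by the CI interquartile fence.

    A trial is rejected when its CI lies beyond two interquartile ranges
    outside [Q1, Q3]: CI > Q3 + 2 IQR or CI < Q1 - 2 IQR.  Quartiles use
    linear interpolation between order statistics.  Rejected rows are
    returned flagged; order is preserved and kept + rejected == input.
    """
    if len(features) < 5:
        raise ValidationError(
            f"need >= 5 feature rows for outlier rejection, got {len(features)}"
        )
    ci = np.array([f.ci for f in features])
    q1, q3 = np.percentile(ci, [25.0, 75.0])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 2.0 * iqr, q3 + 2.0 * iqr
    kept, rejected = [], []
    for f in features:
        if f.ci > hi or f.ci < lo:
            rejected.append(dataclasses.replace(f, outlier_flag=True))
        else:
            kept.append(f)
    return kept, rejected
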