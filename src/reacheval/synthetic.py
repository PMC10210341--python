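"""Seeded synthetic center-out reaching sessions.

Two generative modes emulate a patient:

* **normal** ("less-affected arm"): per trial the average speed AS is drawn
  from a lognormal law, the movement time follows the normal-reaching power
  law T_M = e^k A^alpha AS^beta times multiplicative lognormal noise, and
  the trajectory is realized as a single circular-arc path of chord A and
  arc length L = AS * T_M traversed with one minimum-jerk speed pulse.  The
  realized trajectory is therefore *kinematically consistent*: extracting
  features from it returns the generated (T_M, AS, CI = L/A, NS = 1).

* **erroneous** ("affected arm"): the submovement count NS, the curvature
  index CI and a latent speed trait AS are drawn from their laws and the
  movement time follows T_M = e^k A^alpha AS^beta (NS+1)^d CI^f times
  noise.  The trajectory is a circular arc of chord A and arc length
  CI * A traversed with NS overlapping minimum-jerk pulses whose durations
  sum to T_M.  Geometry fixes path/T_M, so the *extracted* average speed
  equals CI * A / T_M rather than the latent AS; the ground-truth table
  records the latent draw (see docs/methods.md for why the latent trait is
  the quantity the power law is identified from).

Generation is feature-first (draw the feature tuple, then realize a
trajectory consistent with it) so the generative parameters are exactly
recoverable by regression.  Each random quantity draws from its own child
generator of the seed, so degenerate laws leave the other streams
untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import (
    KinematicFeatures,
    ReachTarget,
    Session,
    TrialTrajectory,
    ValidationError,
    make_target_grid,
)
from .kinematics import MIN_JERK_PEAK

__all__ = [
    "SyntheticConfig",
    "generate_normal_session",
    "generate_erroneous_session",
    "generate_patient",
    "arc_path",
]

_EIGHT_DIRECTIONS = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)


@dataclass
class SyntheticConfig:
    """Generative parameters for one synthetic session.

    Power-law parameters use the fitting unit convention (A in m, AS in
    m/s, T_M in s).  Defaults are sized to produce movement times of
    roughly 1.5-5 s and average speeds of 0.02-0.08 m/s over the 6-14 cm
    grid, the magnitudes typical of robot-guided reaching after stroke.
    """

    subject: str = "SYN01"
    directions_deg: tuple[float, ...] = _EIGHT_DIRECTIONS
    distances_cm: tuple[float, ...] = (6.0, 10.0, 14.0)
    width_cm: float = 3.0
    reps_per_target: int = 1
    # normal-reaching law
    k: float = 0.69
    alpha: float = 0.95
    beta: float = -0.8
    # erroneous-law exponents
    d: float = 0.15
    f: float = 0.8
    # speed trait law (lognormal)
    as_median_mps: float = 0.045
    as_log_sd: float = 0.3
    # movement-time multiplicative noise (lognormal sigma)
    tm_noise_log_sd: float = 0.07
    # submovement-count laws.  Normal reaches contain a few submovements
    # too (they just do not inflate the movement time); the erroneous law
    # shifts the count upward.
    ns_support_normal: tuple[int, ...] = (2, 3, 4)
    ns_weights_normal: tuple[float, ...] = (0.30, 0.50, 0.20)
    ns_support: tuple[int, ...] = (2, 3, 4, 5, 6)
    ns_weights: tuple[float, ...] = (0.15, 0.30, 0.25, 0.20, 0.10)
    ci_gamma_shape: float = 1.0
    ci_gamma_scale: float = 0.5
    ci_max: float = 3.0
    pulse_overlap: float = 0.3
    sampling_rate_hz: float = 75.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.distances_cm or not self.directions_deg:
            raise ValidationError("grid lists must be non-empty")
        if min(self.distances_cm) <= 0 or self.width_cm <= 0:
            raise ValidationError("distances and width must be positive")
        for name in ("as_median_mps", "as_log_sd", "sampling_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.tm_noise_log_sd < 0:
            raise ValidationError("tm_noise_log_sd must be >= 0")
        if self.reps_per_target < 1:
            raise ValidationError("reps_per_target must be >= 1")
        for sup, wts in (
            (self.ns_support, self.ns_weights),
            (self.ns_support_normal, self.ns_weights_normal),
        ):
            if len(sup) != len(wts):
                raise ValidationError("NS support and weights lengths differ")
            if min(sup) < 1:
                raise ValidationError("NS support values must be >= 1")
        if not 0 <= self.pulse_overlap < 1:
            raise ValidationError("pulse_overlap must be in [0, 1)")
        if self.beta == -1.0:
            raise ValidationError(
                "beta = -1 makes path length independent of AS; the "
                "consistency rescue for L < A is then unavailable"
            )
        # the speed law must be broadly consistent with reaching the target:
        # the deterministic path length may not undershoot A by more than 50%
        for a_cm in self.distances_cm:
            a_m = a_cm / 100.0
            ci_det = (
                math.exp(self.k)
                * a_m ** (self.alpha - 1.0)
                * self.as_median_mps ** (self.beta + 1.0)
            )
            if ci_det < 0.5:
                raise ValidationError(
                    f"inconsistent speed law: median path length is "
                    f"{ci_det:.2f} x A at A = {a_cm} cm"
                )

    def grid(self) -> list[ReachTarget]:
        return make_target_grid(self.directions_deg, self.distances_cm, self.width_cm)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("directions_deg", "distances_cm", "ns_support", "ns_weights"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def validation_experiment(cls, **overrides) -> "SyntheticConfig":
        """8 directions x 5 distances (6-14 cm), W = 2 cm, 3 reps: 120 trials."""
        base = dict(
            distances_cm=(6.0, 8.0, 10.0, 12.0, 14.0),
            width_cm=2.0,
            reps_per_target=3,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# Arc geometry


def _arc_half_angle(ratio: float) -> float:
    """Solve phi / sin(phi) = L / chord for phi in (0, pi)."""
    if ratio <= 1.0 + 1e-12:
        return 0.0
    if ratio >= math.pi / 2 * 1e6:
        raise ValidationError("arc ratio too large")
    f = lambda p: p / math.sin(p) - ratio
    return brentq(f, 1e-9, math.pi - 1e-9, xtol=1e-13)


def arc_path(
    chord_cm: float,
    arclen_cm: float,
    direction_deg: float,
    fractions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Points along a circular arc from the origin to the target.

    The arc has the given chord (start-to-target distance) and arc length;
    ``fractions`` are cumulative arc-length fractions in [0, 1].  Returns
    (x_cm, y_cm).
    """
    if arclen_cm < chord_cm * (1 - 1e-9):
        raise ValidationError("arc length shorter than chord")
    th = math.radians(direction_deg)
    px, py = chord_cm * math.cos(th), chord_cm * math.sin(th)
    phi = _arc_half_angle(arclen_cm / chord_cm)
    if phi == 0.0:
        return fractions * px, fractions * py
    radius = chord_cm / (2.0 * math.sin(phi))
    ux, uy = px / chord_cm, py / chord_cm
    nx, ny = -uy, ux  # left normal
    h = radius * math.cos(phi)
    cx, cy = px / 2.0 + h * nx, py / 2.0 + h * ny
    ang0 = math.atan2(-cy, -cx)  # angle of (origin - center)
    for sign in (1.0, -1.0):
        ang = ang0 + sign * 2.0 * phi
        ex, ey = cx + radius * math.cos(ang), cy + radius * math.sin(ang)
        if math.hypot(ex - px, ey - py) < 1e-6 * chord_cm:
            angles = ang0 + sign * 2.0 * phi * fractions
            return cx + radius * np.cos(angles), cy + radius * np.sin(angles)
    raise RuntimeError("arc endpoint did not close")  # pragma: no cover


def _min_jerk_fraction(tau: np.ndarray) -> np.ndarray:
    """Cumulative displacement fraction of the minimum-jerk profile."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


# ---------------------------------------------------------------------------
# Trial realization


def _sample_times(duration_s: float, rate_hz: float) -> np.ndarray:
    dt = 1.0 / rate_hz
    n = int(math.floor(duration_s / dt)) + 1
    t = np.arange(n) * dt
    if t[-1] < duration_s - 1e-12:
        t = np.append(t, duration_s)
    return t


def _realize_trial(
    cfg: SyntheticConfig,
    target: ReachTarget,
    trial_id: int,
    arm: str,
    tm_s: float,
    l_m: float,
    ns: int,
) -> TrialTrajectory:
    """Trajectory with path length ``l_m`` along a circular arc of chord A,
    traversed by ``ns`` overlapping minimum-jerk pulses whose durations sum
    to ``tm_s`` (the first, transport pulse twice as long as each
    corrective pulse)."""
    d_rest = tm_s / (ns + 1.0)
    durations = np.full(ns, d_rest)
    durations[0] = 2.0 * d_rest
    onsets = np.zeros(ns)
    for i in range(1, ns):
        onsets[i] = onsets[i - 1] + durations[i - 1] * (1.0 - cfg.pulse_overlap)
    displacements = l_m * durations / tm_s  # proportional to duration
    span = onsets[-1] + durations[-1]

    t = _sample_times(span, cfg.sampling_rate_hz)
    frac = np.zeros_like(t)
    v = np.zeros_like(t)
    for t0, dur, s in zip(onsets, durations, displacements):
        tau = np.clip((t - t0) / dur, 0.0, 1.0)
        frac += (s / l_m) * _min_jerk_fraction(tau)
        v += (s / dur) * 30.0 * (tau * (1 - tau)) ** 2
    x, y = arc_path(target.distance_cm, l_m * 100.0, target.direction_deg, frac)
    return TrialTrajectory(
        subject=cfg.subject,
        arm=arm,
        target=target,
        t_s=t,
        x_cm=x,
        y_cm=y,
        v_mps=v,
        recorded_movement_time_ms=tm_s * 1000.0,
        sampling_rate_hz=cfg.sampling_rate_hz,
        trial_id=trial_id,
    )


def _normal_trial(
    cfg: SyntheticConfig,
    target: ReachTarget,
    trial_id: int,
    arm: str,
    rng_as: np.random.Generator,
    rng_noise: np.random.Generator,
    rng_ns: np.random.Generator,
) -> tuple[TrialTrajectory, dict]:
    a_m = target.distance_cm / 100.0
    ns = int(
        rng_ns.choice(np.asarray(cfg.ns_support_normal), p=_norm_w(cfg.ns_weights_normal))
    )
    as_mps = cfg.as_median_mps * math.exp(cfg.as_log_sd * rng_as.standard_normal())
    z = rng_noise.standard_normal() if cfg.tm_noise_log_sd > 0 else 0.0
    log_noise = cfg.tm_noise_log_sd * z

    def law(speed: float) -> float:
        return math.exp(cfg.k + log_noise) * a_m**cfg.alpha * speed**cfg.beta

    tm_s = law(as_mps)
    l_m = as_mps * tm_s
    if l_m < a_m:
        # re-solve AS so the path exactly reaches the target while the
        # (AS, T_M) pair still satisfies the generative law
        as_mps = (a_m ** (1.0 - cfg.alpha) * math.exp(-(cfg.k + log_noise))) ** (
            1.0 / (1.0 + cfg.beta)
        )
        tm_s = law(as_mps)
        l_m = a_m

    trial = _realize_trial(cfg, target, trial_id, arm, tm_s, l_m, ns)
    truth = {
        "TM_ms": tm_s * 1000.0,
        "AS_mps": as_mps,
        "CI": l_m / a_m,
        "NS": ns,
        "path_cm": l_m * 100.0,
    }
    return trial, truth


def _erroneous_trial(
    cfg: SyntheticConfig,
    target: ReachTarget,
    trial_id: int,
    arm: str,
    rng_as: np.random.Generator,
    rng_noise: np.random.Generator,
    rng_ns: np.random.Generator,
    rng_ci: np.random.Generator,
) -> tuple[TrialTrajectory, dict]:
    a_m = target.distance_cm / 100.0
    as_mps = cfg.as_median_mps * math.exp(cfg.as_log_sd * rng_as.standard_normal())
    z = rng_noise.standard_normal() if cfg.tm_noise_log_sd > 0 else 0.0
    ns = int(rng_ns.choice(np.asarray(cfg.ns_support), p=_norm_w(cfg.ns_weights)))
    ci = _sample_ci(cfg, rng_ci)

    tm_s = (
        math.exp(cfg.k + cfg.tm_noise_log_sd * z)
        * a_m**cfg.alpha
        * as_mps**cfg.beta
        * (ns + 1.0) ** cfg.d
        * ci**cfg.f
    )
    l_m = ci * a_m
    trial = _realize_trial(cfg, target, trial_id, arm, tm_s, l_m, ns)
    truth = {
        "TM_ms": tm_s * 1000.0,
        "AS_mps": as_mps,  # latent speed trait (see module docstring)
        "CI": ci,
        "NS": ns,
        "path_cm": l_m * 100.0,
    }
    return trial, truth


def _norm_w(weights: Sequence[float]) -> np.ndarray:
    w = np.asarray(weights, float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValidationError("ns_weights must be non-negative with positive sum")
    return w / w.sum()


def _sample_ci(cfg: SyntheticConfig, rng: np.random.Generator) -> float:
    if cfg.ci_gamma_shape <= 0 or cfg.ci_gamma_scale <= 0:
        return 1.0
    for _ in range(100):
        ci = 1.0 + float(rng.gamma(cfg.ci_gamma_shape, cfg.ci_gamma_scale))
        if ci <= cfg.ci_max:
            return ci
    raise ValidationError(
        "could not draw CI <= ci_max in 100 attempts; CI law inconsistent"
    )


# ---------------------------------------------------------------------------
# Session generation


def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    ss = np.random.SeedSequence(seed)
    return tuple(np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(4))


def _truth_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def _generate(cfg: SyntheticConfig, mode: str, arm: str) -> tuple[Session, pd.DataFrame]:
    grid = cfg.grid()
    rng_as, rng_noise, rng_ns, rng_ci = _streams(cfg.seed)
    trials: list[TrialTrajectory] = []
    rows: list[dict] = []
    trial_id = 0
    for rep in range(cfg.reps_per_target):
        for target in grid:
            if mode == "normal":
                trial, truth = _normal_trial(
                    cfg, target, trial_id, arm, rng_as, rng_noise, rng_ns
                )
            else:
                trial, truth = _erroneous_trial(
                    cfg, target, trial_id, arm, rng_as, rng_noise, rng_ns, rng_ci
                )
            trials.append(trial)
            rows.append(
                {
                    "subject": cfg.subject,
                    "arm": arm,
                    "target_id": target.index,
                    "trial": trial_id,
                    "direction_deg": target.direction_deg,
                    "A_cm": target.distance_cm,
                    "W_cm": target.width_cm,
                    **truth,
                    "outlier_flag": False,
                    "seed": cfg.seed,
                }
            )
            trial_id += 1
    session = Session(
        subject=cfg.subject, arm=arm, trials=trials, grid=grid, seed=cfg.seed
    )
    return session, _truth_frame(rows)


def generate_normal_session(
    cfg: SyntheticConfig, arm: str = "less_affected"
) -> tuple[Session, pd.DataFrame]:
    """Session governed by the normal-reaching law, plus its ground-truth
    feature table (columns match the feature-table CSV layout)."""
    return _generate(cfg, "normal", arm)


def generate_erroneous_session(
    cfg: SyntheticConfig, arm: str = "affected"
) -> tuple[Session, pd.DataFrame]:
    """Session governed by the erroneous power law (submovements and curved
    paths inflate the movement time), plus its ground-truth table."""
    return _generate(cfg, "erroneous", arm)


def truth_to_features(truth: pd.DataFrame) -> list[KinematicFeatures]:
    """Ground-truth table rows as KinematicFeatures (for model fitting)."""
    from .data import frame_to_features

    return frame_to_features(truth)


def generate_patient(
    normal_cfg: SyntheticConfig,
    erroneous_cfg: SyntheticConfig,
    unreachable_targets: Sequence[int] = (),
) -> tuple[tuple[Session, pd.DataFrame], tuple[Session, pd.DataFrame]]:
    """A synthetic patient: a less-affected (normal-law) session and an
    affected (erroneous-law) session sharing subject, grid and (k, alpha,
    beta).  Targets listed in ``unreachable_targets`` get no affected trials,
    emulating reaches the subject cannot complete."""
    if normal_cfg.subject != erroneous_cfg.subject:
        raise ValidationError("configs must share the subject id")
    if (
        normal_cfg.directions_deg != erroneous_cfg.directions_deg
        or normal_cfg.distances_cm != erroneous_cfg.distances_cm
        or normal_cfg.width_cm != erroneous_cfg.width_cm
    ):
        raise ValidationError("configs must share the target grid")
    if (normal_cfg.k, normal_cfg.alpha, normal_cfg.beta) != (
        erroneous_cfg.k,
        erroneous_cfg.alpha,
        erroneous_cfg.beta,
    ):
        raise ValidationError("configs must share (k, alpha, beta)")
    less = generate_normal_session(normal_cfg, arm="less_affected")
    aff_session, aff_truth = generate_erroneous_session(erroneous_cfg, arm="affected")
    if unreachable_targets:
        drop = set(int(i) for i in unreachable_targets)
        kept = [tr for tr in aff_session.trials if tr.target.index not in drop]
        aff_session = Session(
            subject=aff_session.subject,
            arm=aff_session.arm,
            trials=kept,
            grid=aff_session.grid,
            seed=aff_session.seed,
        )
        aff_truth = aff_truth[~aff_truth["target_id"].isin(drop)].reset_index(
            drop=True
        )
    return less, (aff_session, aff_truth)
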