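"""Domain types and session I/O for planar center-out reaching data.

Canonical units throughout the package: positions and target distance/width
in centimeters, sample time in seconds, movement time in milliseconds,
average speed in m/s.  Coordinates are planar Cartesian with the start
position at the origin; a target at direction ``theta`` (degrees,
counter-clockwise from +x) and distance ``A`` sits at
``(A cos theta, A sin theta)``.

Trial tables are long-format CSV (one row per sample); session-level
metadata (grid, sampling rate, recorded movement times, seed) lives in a
JSON sidecar next to the table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReachEvalError",
    "ValidationError",
    "FormatError",
    "DegenerateTrialError",
    "DomainError",
    "SingularDesignError",
    "ReachTarget",
    "TrialTrajectory",
    "Session",
    "KinematicFeatures",
    "make_target_grid",
    "read_trial_table",
    "write_session",
    "features_to_frame",
    "frame_to_features",
    "sidecar_path",
]


class ReachEvalError(Exception):
    """Base class for package errors."""


class ValidationError(ReachEvalError):
    """An object or file violates a structural invariant."""


class FormatError(ValidationError):
    """A file does not have the expected columns or layout."""


class DegenerateTrialError(ReachEvalError):
    """A trial has no usable movement (stationary, closed path, ...)."""


class DomainError(ReachEvalError):
    """A numeric argument is outside the mathematical domain."""


class SingularDesignError(ReachEvalError):
    """A regression design matrix is rank deficient."""


ARMS = ("dominant", "less_affected", "affected")

# Trial-table CSV columns (canonical names).  ``v_mps`` and ``trial`` are
# optional on read; the writer always emits them.
CANONICAL_COLUMNS = {
    "subject": "subject",
    "arm": "arm",
    "target_id": "target_id",
    "trial": "trial",
    "t_s": "t_s",
    "x_cm": "x_cm",
    "y_cm": "y_cm",
    "v_mps": "v_mps",
}


@dataclass(frozen=True)
class ReachTarget:
    """One reaching target of the center-out grid."""

    index: int
    direction_deg: float
    distance_cm: float  # straight-line start-to-target distance A
    width_cm: float  # target diameter W

    def __post_init__(self) -> None:
        if not self.distance_cm > 0:
            raise ValidationError(f"target {self.index}: distance A must be > 0")
        if not self.width_cm > 0:
            raise ValidationError(f"target {self.index}: width W must be > 0")
        if not 0 <= self.direction_deg < 360:
            raise ValidationError(
                f"target {self.index}: direction must lie in [0, 360), "
                f"got {self.direction_deg}"
            )

    @property
    def center_cm(self) -> tuple[float, float]:
        th = math.radians(self.direction_deg)
        return (self.distance_cm * math.cos(th), self.distance_cm * math.sin(th))


@dataclass
class TrialTrajectory:
    """One reaching trial: sampled planar path plus target and arm metadata."""

    subject: str
    arm: str
    target: ReachTarget
    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    v_mps: np.ndarray | None = None
    recorded_movement_time_ms: float | None = None
    sampling_rate_hz: float = 75.0
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if self.v_mps is not None:
            self.v_mps = np.asarray(self.v_mps, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(
                f"arm must be one of {ARMS}, got {self.arm!r} "
                f"(subject {self.subject}, trial {self.trial_id})"
            )
        n = len(self.t_s)
        if n < 5:
            raise ValidationError(
                f"trial {self.trial_id} of subject {self.subject}: "
                f"needs >= 5 samples, got {n}"
            )
        if len(self.x_cm) != n or len(self.y_cm) != n:
            raise ValidationError(
                f"trial {self.trial_id}: t/x/y lengths differ ({n}, "
                f"{len(self.x_cm)}, {len(self.y_cm)})"
            )
        if self.v_mps is not None and len(self.v_mps) != n:
            raise ValidationError(f"trial {self.trial_id}: v length mismatch")
        if not np.all(np.diff(self.t_s) > 0):
            raise ValidationError(
                f"trial {self.trial_id} of subject {self.subject}: "
                "time must be strictly increasing"
            )
        if not self.sampling_rate_hz > 0:
            raise ValidationError(f"trial {self.trial_id}: sampling rate must be > 0")
        if self.recorded_movement_time_ms is not None:
            if not self.recorded_movement_time_ms > 0:
                raise ValidationError(
                    f"trial {self.trial_id}: recorded movement time must be > 0"
                )
        for name, arr in (("t_s", self.t_s), ("x_cm", self.x_cm), ("y_cm", self.y_cm)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(
                    f"trial {self.trial_id}: non-finite values in {name}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.t_s)


@dataclass
class Session:
    """All trials of one subject/arm over a target grid."""

    subject: str
    arm: str
    trials: list[TrialTrajectory]
    grid: list[ReachTarget]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [t.index for t in self.grid]
        if len(set(ids)) != len(ids):
            raise ValidationError("target indices must be unique within a session")
        grid_ids = set(ids)
        for tr in self.trials:
            if tr.subject != self.subject or tr.arm != self.arm:
                raise ValidationError(
                    f"trial {tr.trial_id}: subject/arm differ from session "
                    f"({tr.subject}/{tr.arm} vs {self.subject}/{self.arm})"
                )
            if tr.target.index not in grid_ids:
                raise ValidationError(
                    f"trial {tr.trial_id}: target {tr.target.index} not in grid"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def target_by_index(self, index: int) -> ReachTarget:
        for t in self.grid:
            if t.index == index:
                return t
        raise KeyError(index)


@dataclass
class KinematicFeatures:
    """Per-trial feature tuple consumed by the movement-time models.

    ``tm_ms`` is the movement time, ``as_mps`` the average speed
    (path length / movement time), ``ci`` the curvature index
    (path length / straight start-to-end distance, >= 1) and ``ns`` the
    number of submovements of the reach.
    """

    subject: str
    arm: str
    target: ReachTarget
    tm_ms: float
    as_mps: float
    ci: float
    ns: int
    path_cm: float
    outlier_flag: bool = False
    trial_id: int = 0

    _CI_TOL = 1e-9

    def __post_init__(self) -> None:
        if not self.tm_ms > 0:
            raise ValidationError(f"trial {self.trial_id}: T_M must be > 0")
        if not self.as_mps > 0:
            raise ValidationError(f"trial {self.trial_id}: AS must be > 0")
        if self.ci < 1 - self._CI_TOL:
            raise ValidationError(
                f"trial {self.trial_id}: CI must be >= 1, got {self.ci}"
            )
        if self.ns < 1:
            raise ValidationError(f"trial {self.trial_id}: NS must be >= 1")
        # a generous tolerance: path may only undershoot A by discretization
        if self.path_cm < self.target.distance_cm * (1 - 1e-2):
            raise ValidationError(
                f"trial {self.trial_id}: path length {self.path_cm:.3f} cm shorter "
                f"than target distance {self.target.distance_cm} cm"
            )

    @property
    def a_cm(self) -> float:
        return self.target.distance_cm

    @property
    def w_cm(self) -> float:
        return self.target.width_cm


def make_target_grid(
    directions_deg: Sequence[float],
    distances_cm: Sequence[float],
    width_cm: float,
) -> list[ReachTarget]:
    """Cartesian product of directions and distances, indexed deterministically
    (sorted by distance, then direction)."""
    if not len(directions_deg) or not len(distances_cm):
        raise ValidationError("directions and distances must be non-empty")
    if not width_cm > 0:
        raise ValidationError("target width must be > 0")
    pairs = [(float(a), float(th)) for a in distances_cm for th in directions_deg]
    if len(set(pairs)) != len(pairs):
        raise ValidationError("duplicate (direction, distance) pair in grid")
    pairs.sort()
    return [
        ReachTarget(index=i, direction_deg=th, distance_cm=a, width_cm=float(width_cm))
        for i, (a, th) in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# I/O


def sidecar_path(path: str | Path) -> Path:
    """JSON metadata sidecar next to a trial-table CSV."""
    p = Path(path)
    return p.with_suffix(".session.json")


def _target_to_dict(t: ReachTarget) -> dict:
    return {
        "index": t.index,
        "direction_deg": t.direction_deg,
        "distance_cm": t.distance_cm,
        "width_cm": t.width_cm,
    }


def _target_from_dict(d: Mapping) -> ReachTarget:
    return ReachTarget(
        index=int(d["index"]),
        direction_deg=float(d["direction_deg"]),
        distance_cm=float(d["distance_cm"]),
        width_cm=float(d["width_cm"]),
    )


def write_session(session: Session, path: str | Path) -> None:
    """Write a session as a trial-table CSV plus a JSON metadata sidecar.

    Numeric fields are serialized with >= 10 significant digits so that a
    read-back round-trips within 1e-9 relative.
    """
    session.validate()
    for tr in session.trials:
        tr.validate()
        if tr.v_mps is not None and not np.all(np.isfinite(tr.v_mps)):
            raise ValidationError(f"trial {tr.trial_id}: non-finite speed values")
    path = Path(path)
    rows = []
    for tr in session.trials:
        frame = pd.DataFrame(
            {
                "subject": tr.subject,
                "arm": tr.arm,
                "target_id": tr.target.index,
                "trial": tr.trial_id,
                "t_s": tr.t_s,
                "x_cm": tr.x_cm,
                "y_cm": tr.y_cm,
                "v_mps": tr.v_mps if tr.v_mps is not None else np.nan,
            }
        )
        rows.append(frame)
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(columns=list(CANONICAL_COLUMNS))
    table.to_csv(path, index=False, float_format="%.12g")

    meta = {
        "subject": session.subject,
        "arm": session.arm,
        "seed": session.seed,
        "grid": [_target_to_dict(t) for t in session.grid],
        "trials": [
            {
                "trial": tr.trial_id,
                "target_id": tr.target.index,
                "sampling_rate_hz": tr.sampling_rate_hz,
                "recorded_movement_time_ms": tr.recorded_movement_time_ms,
            }
            for tr in session.trials
        ],
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_trial_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> Session:
    """Read a trial-table CSV (plus its JSON sidecar, if present) into a Session.

    ``dialect`` maps canonical column names (subject, arm, target_id, trial,
    t_s, x_cm, y_cm, v_mps) to the file's actual column names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(CANONICAL_COLUMNS)
    if dialect:
        cols.update(dialect)
    table = pd.read_csv(path)
    for canon in ("subject", "arm", "target_id", "t_s", "x_cm", "y_cm"):
        if cols[canon] not in table.columns:
            raise FormatError(f"missing column {cols[canon]!r} in {path.name}")

    meta = None
    side = sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())

    if len(table) == 0:
        if meta is None:
            raise FormatError(f"{path.name}: empty table and no sidecar metadata")
        grid = [_target_from_dict(d) for d in meta["grid"]]
        return Session(
            subject=meta["subject"],
            arm=meta["arm"],
            trials=[],
            grid=grid,
            seed=meta.get("seed"),
        )

    subject = str(table[cols["subject"]].iloc[0])
    arm = str(table[cols["arm"]].iloc[0])

    if meta is not None:
        grid = [_target_from_dict(d) for d in meta["grid"]]
        trial_meta = {
            (int(d["trial"]), int(d["target_id"])): d for d in meta.get("trials", [])
        }
        seed = meta.get("seed")
    else:
        grid, trial_meta, seed = None, {}, None

    if cols["trial"] in table.columns:
        group_key = [cols["target_id"], cols["trial"]]
        grouped = table.groupby(group_key, sort=True)
    else:
        # consecutive runs of target_id define trials
        tid = table[cols["target_id"]].to_numpy()
        run = np.concatenate([[0], np.cumsum(tid[1:] != tid[:-1])])
        table = table.assign(__run__=run)
        grouped = table.groupby([cols["target_id"], "__run__"], sort=True)

    if grid is None:
        # reconstruct a grid if direction/distance columns are available
        needed = {"direction_deg", "A_cm", "W_cm"}
        if not needed.issubset(table.columns):
            raise FormatError(
                f"{path.name}: no sidecar metadata and no "
                "direction_deg/A_cm/W_cm columns to reconstruct the grid"
            )
        uniq = table[["target_id", "direction_deg", "A_cm", "W_cm"]].drop_duplicates()
        grid = [
            ReachTarget(int(r.target_id), float(r.direction_deg), float(r.A_cm), float(r.W_cm))
            for r in uniq.itertuples()
        ]

    by_index = {t.index: t for t in grid}
    trials = []
    for key, g in grouped:
        target_id, trial_id = int(key[0]), int(key[1])
        if target_id not in by_index:
            raise ValidationError(f"{path.name}: unknown target id {target_id}")
        t = g[cols["t_s"]].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"{path.name}: non-monotone time in trial {trial_id} "
                f"(target {target_id})"
            )
        v = None
        if cols["v_mps"] in g.columns and not g[cols["v_mps"]].isna().any():
            v = g[cols["v_mps"]].to_numpy(float)
        tm = trial_meta.get((trial_id, target_id), {})
        rate = tm.get("sampling_rate_hz")
        if rate is None:
            dt = np.median(np.diff(t))
            rate = 1.0 / dt if dt > 0 else 75.0
        trials.append(
            TrialTrajectory(
                subject=subject,
                arm=arm,
                target=by_index[target_id],
                t_s=t,
                x_cm=g[cols["x_cm"]].to_numpy(float),
                y_cm=g[cols["y_cm"]].to_numpy(float),
                v_mps=v,
                recorded_movement_time_ms=tm.get("recorded_movement_time_ms"),
                sampling_rate_hz=float(rate),
                trial_id=trial_id,
            )
        )
    return Session(subject=subject, arm=arm, trials=trials, grid=grid, seed=seed)


# ---------------------------------------------------------------------------
# Feature tables

FEATURE_COLUMNS = [
    "subject",
    "arm",
    "target_id",
    "trial",
    "direction_deg",
    "A_cm",
    "W_cm",
    "TM_ms",
    "AS_mps",
    "CI",
    "NS",
    "path_cm",
    "outlier_flag",
]


def features_to_frame(features: Iterable[KinematicFeatures]) -> pd.DataFrame:
    rows = [
        {
            "subject": f.subject,
            "arm": f.arm,
            "target_id": f.target.index,
            "trial": f.trial_id,
            "direction_deg": f.target.direction_deg,
            "A_cm": f.target.distance_cm,
            "W_cm": f.target.width_cm,
            "TM_ms": f.tm_ms,
            "AS_mps": f.as_mps,
            "CI": f.ci,
            "NS": f.ns,
            "path_cm": f.path_cm,
            "outlier_flag": f.outlier_flag,
        }
        for f in features
    ]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def frame_to_features(frame: pd.DataFrame) -> list[KinematicFeatures]:
    missing = set(FEATURE_COLUMNS) - set(frame.columns) - {"trial", "outlier_flag"}
    if missing:
        raise FormatError(f"feature table missing columns: {sorted(missing)}")
    out = []
    for r in frame.itertuples():
        target = ReachTarget(
            index=int(r.target_id),
            direction_deg=float(r.direction_deg),
            distance_cm=float(r.A_cm),
            width_cm=float(r.W_cm),
        )
        out.append(
            KinematicFeatures(
                subject=str(r.subject),
                arm=str(r.arm),
                target=target,
                tm_ms=float(r.TM_ms),
                as_mps=float(r.AS_mps),
                ci=float(r.CI),
                ns=int(r.NS),
                path_cm=float(r.path_cm),
                outlier_flag=bool(getattr(r, "outlier_flag", False)),
                trial_id=int(getattr(r, "trial", 0)),
            )
        )
    return out
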