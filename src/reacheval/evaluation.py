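"""Individually scaled evaluation of affected-arm reaching.

The normalized error of target i,

    e_n(i) = (T_M,a(i) - T_M,e(i)) / T_M,e(i),

compares the actual movement time of the affected arm against the ideal
movement time predicted by the normal-reaching model fitted on the
less-affected arm.  The normalization by T_M,e removes the trivial
far-targets-take-longer bias, so the index is comparable across the
workspace.  e_n is computed per trial and then averaged per target; an
evaluation map lays the per-target means on the direction x distance polar
grid, with an optional display clip at the 95th percentile so a single
extreme target does not flatten the color axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DomainError, KinematicFeatures, ReachTarget, ValidationError
from .models import FittedModel, predict_movement_time

__all__ = [
    "EvaluationRecord",
    "EvaluationMap",
    "normalized_error",
    "evaluate_affected",
    "build_map",
    "render_map",
    "records_to_frame",
    "frame_to_records",
]


def normalized_error(tm_a_ms, tm_e_ms):
    """e_n = (T_M,a - T_M,e) / T_M,e.  Both times must be positive."""
    tm_a = np.asarray(tm_a_ms, float)
    tm_e = np.asarray(tm_e_ms, float)
    if np.any(tm_e <= 0):
        raise DomainError("T_M,e must be positive")
    if np.any(tm_a <= 0):
        raise DomainError("T_M,a must be positive")
    out = (tm_a - tm_e) / tm_e
    return float(out) if np.isscalar(tm_a_ms) else out


@dataclass
class EvaluationRecord:
    """Per-target evaluation: trial-wise times and normalized errors plus
    their target mean.  ``reachable`` is False when the target has no
    successful trial (and the value fields are NaN)."""

    target: ReachTarget
    tm_a_ms: np.ndarray  # per-trial actual movement times
    tm_e_ms: np.ndarray  # per-trial model-estimated ideal movement times
    en_trials: np.ndarray
    en_mean: float
    tm_a_mean_ms: float
    reachable: bool


def evaluate_affected(
    model: FittedModel,
    affected_features: list[KinematicFeatures],
    grid: list[ReachTarget],
) -> list[EvaluationRecord]:
    """Score affected-arm trials against the less-affected normal model.

    Per trial, T_M,e is predicted from the trial's own (A, AS); e_n is
    computed trial-wise and averaged per target (mean-of-e_n, not e_n of
    mean times).  Grid targets with no trial are marked unreachable.
    """
    if not grid:
        raise ValidationError("empty target grid")
    if not affected_features:
        raise ValidationError("no affected-arm features to evaluate")
    if model.family.name != "proposed":
        warnings.warn(
            f"evaluating with comparator family {model.family.name!r}; the "
            "validated normal-reaching model is 'proposed'",
            UserWarning,
            stacklevel=2,
        )
    by_target: dict[int, list[KinematicFeatures]] = {t.index: [] for t in grid}
    for f in affected_features:
        if f.target.index not in by_target:
            raise ValidationError(
                f"feature trial {f.trial_id}: target {f.target.index} not in grid"
            )
        by_target[f.target.index].append(f)

    records = []
    for target in grid:
        feats = by_target[target.index]
        if not feats:
            records.append(
                EvaluationRecord(
                    target=target,
                    tm_a_ms=np.array([]),
                    tm_e_ms=np.array([]),
                    en_trials=np.array([]),
                    en_mean=float("nan"),
                    tm_a_mean_ms=float("nan"),
                    reachable=False,
                )
            )
            continue
        tm_a = np.array([f.tm_ms for f in feats])
        kwargs = {}
        if model.family.name == "fitts":
            kwargs["w_cm"] = np.array([f.w_cm for f in feats])
        else:
            kwargs["as_mps"] = np.array([f.as_mps for f in feats])
        if model.family.name == "almanji_simplified":
            kwargs["ns"] = np.array([f.ns for f in feats], float)
            kwargs["ci"] = np.array([f.ci for f in feats])
        tm_e = np.atleast_1d(
            predict_movement_time(model, np.array([f.a_cm for f in feats]), **kwargs)
        )
        en = normalized_error(tm_a, tm_e)
        records.append(
            EvaluationRecord(
                target=target,
                tm_a_ms=tm_a,
                tm_e_ms=tm_e,
                en_trials=np.atleast_1d(en),
                en_mean=float(np.mean(en)),
                tm_a_mean_ms=float(np.mean(tm_a)),
                reachable=True,
            )
        )
    return records


@dataclass
class EvaluationMap:
    """Polar-grid map of per-target mean e_n or mean T_M,a.

    ``values`` is distances x directions; unreachable cells are masked and
    carry NaN.  ``clip_high`` is the 95th percentile of finite cells when
    clipping is enabled (display range only: stored values are unclipped).
    """

    directions_deg: np.ndarray
    distances_cm: np.ndarray
    values: np.ndarray  # shape (n_distances, n_directions), NaN where masked
    mask: np.ndarray  # True where unreachable
    clip_low: float
    clip_high: float
    value_name: str  # 'en' or 'tm'
    clipped: bool


def build_map(
    records: list[EvaluationRecord],
    value: str = "en",
    clip: bool = True,
) -> EvaluationMap:
    """Assemble per-target means onto the direction x distance grid.

    When ``clip`` is requested the display ceiling is the 95th percentile of
    the finite cell values (linear interpolation) and the floor is their
    minimum; cell values themselves are stored unclipped.
    """
    if value not in ("en", "tm"):
        raise ValidationError("value must be 'en' or 'tm'")
    if not records:
        raise ValidationError("no evaluation records")
    directions = np.array(sorted({r.target.direction_deg for r in records}))
    distances = np.array(sorted({r.target.distance_cm for r in records}))
    values = np.full((len(distances), len(directions)), np.nan)
    seen = np.zeros_like(values, dtype=bool)
    for r in records:
        i = int(np.searchsorted(distances, r.target.distance_cm))
        j = int(np.searchsorted(directions, r.target.direction_deg))
        seen[i, j] = True
        if r.reachable:
            values[i, j] = r.en_mean if value == "en" else r.tm_a_mean_ms
    # holes in the rectangle are treated as unreachable cells
    mask = ~np.isfinite(values)
    finite = values[~mask]
    if finite.size == 0:
        raise ValidationError("no reachable cells in the evaluation map")
    clipped = bool(clip)
    if clip and finite.size < 2:
        warnings.warn(
            "fewer than 2 finite cells: returning unclipped map",
            UserWarning,
            stacklevel=2,
        )
        clipped = False
    low = float(np.min(finite))
    high = float(np.percentile(finite, 95.0)) if clipped else float(np.max(finite))
    return EvaluationMap(
        directions_deg=directions,
        distances_cm=distances,
        values=values,
        mask=mask,
        clip_low=low,
        clip_high=high,
        value_name=value,
        clipped=clipped,
    )


def map_to_frame(emap: EvaluationMap) -> pd.DataFrame:
    """Numeric grid as a DataFrame (rows = distances, columns = directions)."""
    return pd.DataFrame(
        emap.values,
        index=pd.Index(emap.distances_cm, name="distance_cm"),
        columns=pd.Index(emap.directions_deg, name="direction_deg"),
    )


def render_map(
    emap: EvaluationMap,
    path: str | Path,
    style: dict | None = None,
) -> list[Path]:
    """Write the polar contour image (PNG and SVG) plus the numeric grid CSV.

    The color axis runs from clip_low (blue) to clip_high (red); values above
    the ceiling are *displayed* at the ceiling; unreachable cells stay
    uncolored.  Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    style = style or {}
    path = Path(path)
    base = path.with_suffix("") if path.suffix else path
    written: list[Path] = []

    grid_csv = base.with_suffix(".csv")
    map_to_frame(emap).to_csv(grid_csv, float_format="%.12g", na_rep="NA")
    written.append(grid_csv)

    th = np.radians(emap.directions_deg)
    # pad angular axis so cells are centered on their directions and wrap
    order = np.argsort(th)
    th_sorted = th[order]
    step = 2 * np.pi / len(th_sorted)
    th_edges = np.concatenate([th_sorted - step / 2, [th_sorted[-1] + step / 2]])
    r = emap.distances_cm
    dr = np.diff(r).mean() if len(r) > 1 else max(r[0], 1.0)
    r_edges = np.concatenate([[max(r[0] - dr / 2, 0)], r + dr / 2])

    vals = emap.values[:, order]
    masked = np.ma.masked_invalid(vals)
    vmin, vmax = emap.clip_low, emap.clip_high
    if vmax <= vmin:  # constant map
        vmax = vmin + 1e-12

    fig = plt.figure(figsize=style.get("figsize", (5, 5)))
    ax = fig.add_subplot(projection="polar")
    pcm = ax.pcolormesh(
        th_edges,
        r_edges,
        np.clip(masked, vmin, vmax),
        cmap=style.get("colormap", "RdYlBu_r"),
        vmin=vmin,
        vmax=vmax,
        shading="flat",
    )
    ax.set_theta_zero_location("E")
    ax.set_title(
        "normalized error e_n" if emap.value_name == "en" else "movement time [ms]"
    )
    fig.colorbar(pcm, ax=ax, shrink=0.8)
    for ext in (".png", ".svg"):
        out = base.with_suffix(ext)
        fig.savefig(out, dpi=style.get("dpi", 150))
        written.append(out)
    plt.close(fig)
    return written


def records_to_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "target_id": r.target.index,
                "direction_deg": r.target.direction_deg,
                "A_cm": r.target.distance_cm,
                "W_cm": r.target.width_cm,
                "n_trials": len(r.tm_a_ms),
                "tm_a_mean_ms": r.tm_a_mean_ms,
                "en_mean": r.en_mean,
                "reachable": r.reachable,
                "tm_a_ms": ";".join(f"{v:.10g}" for v in r.tm_a_ms),
                "tm_e_ms": ";".join(f"{v:.10g}" for v in r.tm_e_ms),
                "en_trials": ";".join(f"{v:.10g}" for v in r.en_trials),
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[EvaluationRecord]:
    def unpack(s) -> np.ndarray:
        if not isinstance(s, str) or not s:
            return np.array([])
        return np.array([float(v) for v in s.split(";")])

    records = []
    for r in frame.itertuples():
        target = ReachTarget(
            index=int(r.target_id),
            direction_deg=float(r.direction_deg),
            distance_cm=float(r.A_cm),
            width_cm=float(r.W_cm),
        )
        records.append(
            EvaluationRecord(
                target=target,
                tm_a_ms=unpack(r.tm_a_ms),
                tm_e_ms=unpack(r.tm_e_ms),
                en_trials=unpack(r.en_trials),
                en_mean=float(r.en_mean),
                tm_a_mean_ms=float(r.tm_a_mean_ms),
                reachable=bool(r.reachable),
            )
        )
    return records
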