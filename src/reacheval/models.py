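"""Candidate movement-time models for center-out reaching.

Three families, all fitted by ordinary least squares:

* ``fitts`` — Fitts' law, T_M = a + b * log2(2A/W), fitted in millisecond
  space on the index of difficulty ID = log2(2A/W).
* ``almanji_simplified`` — the power law
  T_M = e^k * A^alpha * AS^beta * (NS+1)^d * CI^f, fitted as a linear model
  in log space.  It describes reaching *including* erroneous corrective
  behaviour (submovements, curved paths).
* ``proposed`` — the normal-reaching restriction T_M = e^k * A^alpha *
  AS^beta (the d = f = 0 nested case), used as the individually scaled
  standard of normal performance.

Unit convention inside the power laws: A in meters, AS in m/s, T_M in
seconds; the intercept k absorbs the choice.  The convention is recorded in
the serialized model file so predictions are unambiguous.

R^2 and AIC are computed in each family's fitted space (ms space for Fitts,
log space for the power laws), so the two are not on a common likelihood
scale across spaces; they are reported as-is.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import (
    DomainError,
    KinematicFeatures,
    SingularDesignError,
    ValidationError,
)

__all__ = [
    "ModelFamily",
    "FITTS",
    "ALMANJI_SIMPLIFIED",
    "PROPOSED",
    "FAMILIES",
    "get_family",
    "FittedModel",
    "ModelComparison",
    "index_of_difficulty",
    "fit_model",
    "predict_movement_time",
    "aic",
    "compare_models",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelFamily:
    name: str
    regressors: tuple[str, ...]  # names of the non-intercept regressors
    param_names: tuple[str, ...]  # intercept first


FITTS = ModelFamily("fitts", ("ID",), ("a", "b"))
ALMANJI_SIMPLIFIED = ModelFamily(
    "almanji_simplified",
    ("ln_A", "ln_AS", "ln_NS1", "ln_CI"),
    ("k", "alpha", "beta", "d", "f"),
)
PROPOSED = ModelFamily("proposed", ("ln_A", "ln_AS"), ("k", "alpha", "beta"))

FAMILIES = {f.name: f for f in (FITTS, ALMANJI_SIMPLIFIED, PROPOSED)}


def get_family(name: str) -> ModelFamily:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValidationError(
            f"unknown model family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None


def index_of_difficulty(a_cm: float | np.ndarray, w_cm: float | np.ndarray):
    """Fitts index of difficulty ID = log2(2A/W), in bits."""
    return np.log2(2.0 * np.asarray(a_cm, float) / np.asarray(w_cm, float))


@dataclass
class FittedModel:
    family: ModelFamily
    params: dict[str, float]
    n: int
    rss: float  # residual sum of squares in the fitted space
    r2: float
    aic: float
    residuals_ms: np.ndarray  # T_M,a - back-transformed fit, per trial
    unit_convention: str = "A[m], AS[m/s], T_M[s] inside power laws; fitts in ms"

    @property
    def n_coefficients(self) -> int:
        return len(self.params)


def _design(features: list[KinematicFeatures], family: ModelFamily):
    a_m = np.array([f.a_cm for f in features]) / 100.0
    tm_s = np.array([f.tm_ms for f in features]) / 1000.0
    if np.any(tm_s <= 0) or np.any(a_m <= 0):
        raise DomainError("T_M and A must be positive")
    if family.name == "fitts":
        w_cm = np.array([f.w_cm for f in features])
        x = index_of_difficulty(np.array([f.a_cm for f in features]), w_cm)
        y = np.array([f.tm_ms for f in features])
        cols = [x]
    else:
        as_mps = np.array([f.as_mps for f in features])
        ci = np.array([f.ci for f in features])
        ns = np.array([f.ns for f in features], float)
        if np.any(as_mps <= 0) or np.any(ci <= 0):
            raise DomainError("AS and CI must be positive")
        y = np.log(tm_s)
        cols = [np.log(a_m), np.log(as_mps)]
        if family.name == "almanji_simplified":
            cols += [np.log(ns + 1.0), np.log(ci)]
    X = np.column_stack([np.ones(len(y))] + cols)
    return X, y


def aic(n: int, rss: float, n_coefficients: int) -> float:
    """Gaussian maximum-likelihood AIC of a linear model.

    AIC = n ln(2 pi RSS / n) + n + 2 (p + 1), with p the coefficient count
    including the intercept; the +1 counts the error variance.  A perfect
    fit (RSS = 0) returns -inf with a warning.
    """
    if rss < 0:
        raise DomainError("RSS must be >= 0")
    if rss == 0:
        warnings.warn("perfect fit: AIC is -inf", RuntimeWarning, stacklevel=2)
        return -math.inf
    return n * math.log(2.0 * math.pi * rss / n) + n + 2.0 * (n_coefficients + 1)


def fit_model(
    features: list[KinematicFeatures], family: ModelFamily | str
) -> FittedModel:
    """Ordinary least squares fit of one model family.

    Fitts is fitted on T_M [ms] against ID; the power laws on ln T_M [s]
    against the family's log regressors.  Estimates equal the closed-form
    normal-equations solution (well-conditioned designs) to 1e-8 relative.
    """
    if isinstance(family, str):
        family = get_family(family)
    p = len(family.param_names)
    if len(features) < p + 2:
        raise ValidationError(
            f"{family.name}: need at least {p + 2} trials, got {len(features)}"
        )
    X, y = _design(features, family)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"{family.name}: rank-deficient design (e.g. a single distance "
            "level leaves the slope unidentified)"
        )
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    r2 = float(res.rsquared)
    params = dict(zip(family.param_names, (float(b) for b in res.params)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a = aic(len(y), rss, p)

    tm_ms = np.array([f.tm_ms for f in features])
    if family.name == "fitts":
        resid_ms = tm_ms - res.fittedvalues
    else:
        resid_ms = tm_ms - np.exp(res.fittedvalues) * 1000.0
    return FittedModel(
        family=family,
        params=params,
        n=len(y),
        rss=rss,
        r2=r2,
        aic=a,
        residuals_ms=np.asarray(resid_ms, float),
    )


def predict_movement_time(
    model: FittedModel,
    a_cm: float | np.ndarray,
    as_mps: float | np.ndarray | None = None,
    ns: float | np.ndarray | None = None,
    ci: float | np.ndarray | None = None,
    w_cm: float | np.ndarray | None = None,
) -> float | np.ndarray:
    """Predicted movement time T_M,e in milliseconds."""
    p = model.params
    name = model.family.name
    if name == "fitts":
        if w_cm is None:
            raise ValidationError("fitts prediction requires w_cm")
        return p["a"] + p["b"] * index_of_difficulty(a_cm, w_cm)
    if as_mps is None:
        raise ValidationError(f"{name} prediction requires as_mps")
    a_m = np.asarray(a_cm, float) / 100.0
    as_ = np.asarray(as_mps, float)
    if np.any(a_m <= 0) or np.any(as_ <= 0):
        raise DomainError("A and AS must be positive")
    ln_t = p["k"] + p["alpha"] * np.log(a_m) + p["beta"] * np.log(as_)
    if name == "almanji_simplified":
        if ns is None or ci is None:
            raise ValidationError("almanji_simplified prediction requires ns and ci")
        ns_ = np.asarray(ns, float)
        ci_ = np.asarray(ci, float)
        if np.any(ci_ <= 0):
            raise DomainError("CI must be positive")
        ln_t = ln_t + p["d"] * np.log(ns_ + 1.0) + p["f"] * np.log(ci_)
    out = np.exp(ln_t) * 1000.0
    return float(out) if np.isscalar(a_cm) else out


@dataclass
class ModelComparison:
    """AIC/R^2 table and residual-vs-error-parameter series for the three
    candidate families, all computed on the identical trial set."""

    models: dict[str, FittedModel]
    table: pd.DataFrame  # family x {AIC, R2, mean_abs_residual_ms}
    residual_table: pd.DataFrame  # long: family, residual_ms, NS, CI


def compare_models(features: list[KinematicFeatures]) -> ModelComparison:
    """Fit all three families on one feature set.

    Residuals are back-transformed to milliseconds for the power laws so the
    mean absolute residual is comparable across families, and are paired
    with each trial's NS and CI for residual-vs-error-parameter analysis.
    """
    models: dict[str, FittedModel] = {}
    for family in (FITTS, ALMANJI_SIMPLIFIED, PROPOSED):
        try:
            models[family.name] = fit_model(features, family)
        except ReachEvalLike as exc:
            raise type(exc)(f"{family.name}: {exc}") from exc
    ns = np.array([f.ns for f in features], float)
    ci = np.array([f.ci for f in features])
    rows, long_rows = [], []
    for name, m in models.items():
        rows.append(
            {
                "family": name,
                "AIC": m.aic,
                "R2": m.r2,
                "mean_abs_residual_ms": float(np.mean(np.abs(m.residuals_ms))),
            }
        )
        long_rows.append(
            pd.DataFrame(
                {
                    "family": name,
                    "residual_ms": m.residuals_ms,
                    "NS": ns,
                    "CI": ci,
                }
            )
        )
    return ModelComparison(
        models=models,
        table=pd.DataFrame(rows).set_index("family"),
        residual_table=pd.concat(long_rows, ignore_index=True),
    )


# errors raised by fit_model that compare_models re-annotates with the family
ReachEvalLike = (ValidationError, SingularDesignError, DomainError)


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: FittedModel, path: str | Path, seed: int | None = None,
               input_sha256: str | None = None) -> None:
    """JSON model file with stable key order."""
    payload = {
        "family": model.family.name,
        "params": {k: model.params[k] for k in model.family.param_names},
        "unit_convention": model.unit_convention,
        "n": model.n,
        "rss": model.rss,
        "r2": model.r2,
        "aic": model.aic,
        "seed": seed,
        "input_sha256": input_sha256,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=False))


def load_model(path: str | Path) -> FittedModel:
    d = json.loads(Path(path).read_text())
    family = get_family(d["family"])
    return FittedModel(
        family=family,
        params={k: float(v) for k, v in d["params"].items()},
        n=int(d["n"]),
        rss=float(d["rss"]),
        r2=float(d["r2"]),
        aic=float(d["aic"]) if d["aic"] is not None else -math.inf,
        residuals_ms=np.array([]),
        unit_convention=d.get("unit_convention", ""),
    )
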