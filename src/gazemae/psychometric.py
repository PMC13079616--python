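"""Psychometric condensation and two-parameter sigmoid fitting.

A subject's trials are condensed into per-coherence proportions of
"toward" responses, then fit by unweighted least squares to the logistic

    f(x) = exp((x - x_c) / b) / (1 + exp((x - x_c) / b)),

whose location x_c is the point of subjective equality (the coherence at
which "toward" and "away" are equally likely) and whose scale b sets the
steepness. The optimizer starts at the unbiased values x_c = b = 0.5 and
falls back to a fixed grid of restarts, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import DataError, ParameterError

#: Study starting point for (x_c, b).
START = (0.5, 0.5)

#: Deterministic restart grid used when the primary start leaves residual error.
RESTARTS = ((0.0, 2.0), (0.0, 8.0), (0.0, 30.0),
            (-10.0, 4.0), (10.0, 4.0), (-20.0, 12.0), (20.0, 12.0))

BOUNDS = ((-100.0, 1e-6), (100.0, 1e4))  # (lower, upper) for (x_c, b); b > 0


def condense(trials: pd.DataFrame,
             levels: Sequence[float] | None = None) -> pd.DataFrame:
    """Condense trials into one row per coherence level.

    Returns a frame with columns ``coherence_signed``, ``n_trials``,
    ``prop_toward``, sorted by coherence. With ``levels`` given, unseen
    levels appear with ``n_trials = 0`` and NaN proportion, and trials at
    an unconfigured level are an error.
    """
    if len(trials) == 0:
        raise DataError("cannot condense an empty trial list")
    c = trials["coherence_signed"].to_numpy(dtype=float)
    toward = (trials["response"].to_numpy() == "toward").astype(float)
    seen, inv = np.unique(c, return_inverse=True)
    n = np.bincount(inv)
    out = pd.DataFrame({
        "coherence_signed": seen,
        "n_trials": n,
        "prop_toward": np.bincount(inv, weights=toward) / n,
    })
    if levels is not None:
        levels = np.asarray(sorted(levels), dtype=float)
        unknown = set(out["coherence_signed"]) - set(levels)
        if unknown:
            raise DataError(f"trials at unconfigured coherence levels: {sorted(unknown)}")
        out = out.set_index("coherence_signed").reindex(levels)
        out["n_trials"] = out["n_trials"].fillna(0).astype(int)
        out = out.reset_index()
    return out.sort_values("coherence_signed", ignore_index=True)


def eval_sigmoid(x, x_c: float, b: float):
    """Evaluate the logistic psychometric function; stable for any |x - x_c| / b."""
    if b == 0:
        raise ParameterError("scale b must be nonzero")
    return expit((np.asarray(x, dtype=float) - x_c) / b)


@dataclass
class PsychometricFit:
    """Fitted sigmoid parameters with goodness of fit.

    ``r_squared`` is the coefficient of determination about the mean of
    the fitted proportions (1 - SSE/SStot), as reported by standard
    curve-fitting tools; it can be negative for fits worse than a flat
    line. When every proportion is identical (SStot = 0), it is 1.0 for a
    zero-residual fit and -inf otherwise.
    """

    x_c: float
    b: float
    r_squared: float
    converged: bool
    sse: float

    def predict(self, x):
        return eval_sigmoid(x, self.x_c, self.b)


def _sse(x: np.ndarray, p: np.ndarray, x_c: float, b: float) -> float:
    return float(np.sum((p - expit((x - x_c) / b)) ** 2))


def _r_squared(p: np.ndarray, sse: float) -> float:
    sstot = float(np.sum((p - p.mean()) ** 2))
    if sstot == 0.0:
        return 1.0 if sse < 1e-12 else -np.inf
    return 1.0 - sse / sstot


def fit_sigmoid(summaries: pd.DataFrame) -> PsychometricFit:
    """Fit the logistic to condensed proportions by unweighted least squares.

    Starts at (0.5, 0.5), then from a data-driven guess (interpolated 0.5
    crossing, scale from the level span); a fixed grid of further restarts
    runs only when neither start converges. The lowest-SSE solution is
    kept; restart order is fixed so results are reproducible. The scale is
    bounded positive: a reversed-slope subject fits poorly and is caught
    by the goodness-of-fit screen downstream. Never raises on optimizer
    failure; ``converged=False`` flags it.
    """
    valid = summaries.dropna(subset=["prop_toward"])
    x = valid["coherence_signed"].to_numpy(dtype=float)
    p = valid["prop_toward"].to_numpy(dtype=float)
    if np.unique(x).size < 4:
        raise DataError("sigmoid fit requires >= 4 distinct coherence levels")

    lo, hi = np.array(BOUNDS[0]), np.array(BOUNDS[1])

    def residuals(theta):
        return p - expit((x - theta[0]) / theta[1])

    def jacobian(theta):
        f = expit((x - theta[0]) / theta[1])
        w = f * (1.0 - f)
        return np.column_stack([w / theta[1],
                                w * (x - theta[0]) / theta[1] ** 2])

    def try_start(start):
        theta0 = np.clip(np.asarray(start, dtype=float), lo, hi)
        try:
            return least_squares(residuals, theta0, jac=jacobian,
                                 bounds=(lo, hi), method="trf",
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            return None

    starts = [START]
    # data-driven start: linear interpolation of the 0.5 crossing
    order = np.argsort(x)
    xc0 = float(np.interp(0.5, p[order], x[order])) if p[order][0] < p[order][-1] else 0.0
    span = float(x.max() - x.min())
    starts.append((xc0, max(span / 8.0, 1e-3)))

    best = None
    for i, s in enumerate(starts):
        res = try_start(s)
        if res is None:
            continue
        if best is None or 2 * res.cost < best[0]:
            best = (2 * res.cost, res)
        if i == 0 and 2 * res.cost < 1e-14:
            break  # the primary start already fits exactly
    if best is None or not best[1].success:
        for s in RESTARTS:
            res = try_start(s)
            if res is not None and (best is None or 2 * res.cost < best[0]):
                best = (2 * res.cost, res)

    if best is None:
        return PsychometricFit(x_c=np.nan, b=np.nan, r_squared=np.nan,
                               converged=False, sse=np.inf)
    sse, res = best
    return PsychometricFit(x_c=float(res.x[0]), b=float(res.x[1]),
                           r_squared=_r_squared(p, sse),
                           converged=bool(res.success), sse=float(sse))


def fit_subjects(trials: pd.DataFrame,
                 levels: Sequence[float] | None = None) -> dict[str, PsychometricFit]:
    """Condense and fit every subject in a trial table."""
    return {sid: fit_sigmoid(condense(sub, levels))
            for sid, sub in trials.groupby("subject_id", sort=True)}


def fits_to_frame(fits: dict[str, PsychometricFit]) -> pd.DataFrame:
    return pd.DataFrame([
        {"subject_id": sid, "x_c": f.x_c, "b": f.b, "r_squared": f.r_squared,
         "converged": f.converged, "sse": f.sse}
        for sid, f in fits.items()
    ])
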