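"""Subject exclusion procedure.

Three predefined criteria, applied in two stages exactly as in the study
protocol: (stage 1, before any fitting) accuracy below 80 % in the easiest
condition (|coherence| = 30 %, both signs pooled) or a failed instructional
manipulation check; (stage 2, survivors only) sigmoid goodness of fit
R^2 below 0.9. Both thresholds are strict: accuracy of exactly 0.80 and
R^2 of exactly 0.90 are included. A fit that failed to converge counts as
a fit exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .psychometric import PsychometricFit, condense, fit_sigmoid

ACCURACY_THRESHOLD = 0.80
R_SQUARED_THRESHOLD = 0.90


@dataclass
class SubjectStatus:
    """Inclusion decision for one subject, with the reasons if excluded."""

    subject_id: str
    easiest_accuracy: float
    imc_pass: bool
    r_squared: float | None
    included: bool
    exclusion_reasons: frozenset[str] = field(default_factory=frozenset)


def easiest_accuracy(trials: pd.DataFrame) -> float:
    """Proportion correct over all trials at |coherence| = 30 (signs pooled).

    A response is correct when its direction matches the sign of the
    coherence; 0 %-coherence trials have no correct answer and never enter
    this criterion.
    """
    easiest = trials[np.abs(trials["coherence_signed"]) == 30]
    if len(easiest) == 0:
        raise DataError("no trials at |coherence| = 30; cannot score performance")
    correct = (easiest["response"] == "toward") == (easiest["coherence_signed"] > 0)
    return float(correct.mean())


def apply_exclusions(trials: pd.DataFrame,
                     fits: dict[str, PsychometricFit] | None = None,
                     levels=None, return_fits: bool = False):
    """Apply the two-stage exclusion procedure to a cohort trial table.

    Stage 1 (performance, attention check) never consults a fit; a subject
    removed there has ``r_squared=None`` and contributes to no downstream
    statistic. Stage 2 fits the stage-1 survivors (or looks them up in
    ``fits`` when provided) and removes R^2 < 0.9 or non-convergent fits.
    With ``return_fits``, also returns the survivors' fits so callers
    never refit.
    """
    statuses: list[SubjectStatus] = []
    computed: dict[str, PsychometricFit] = {}
    for sid, sub in trials.groupby("subject_id", sort=True):
        acc = easiest_accuracy(sub)
        imc = bool(sub["imc_pass"].iloc[0])
        reasons = set()
        if acc < ACCURACY_THRESHOLD:
            reasons.add("performance")
        if not imc:
            reasons.add("imc")
        r2: float | None = None
        if not reasons:  # stage 2 only for stage-1 survivors
            if fits is not None and sid in fits:
                fit = fits[sid]
            else:
                fit = fit_sigmoid(condense(sub, levels))
            computed[sid] = fit
            r2 = fit.r_squared
            if not fit.converged or not np.isfinite(r2) or r2 < R_SQUARED_THRESHOLD:
                reasons.add("fit")
        statuses.append(SubjectStatus(
            subject_id=sid, easiest_accuracy=acc, imc_pass=imc, r_squared=r2,
            included=not reasons, exclusion_reasons=frozenset(reasons)))
    return (statuses, computed) if return_fits else statuses


def exclusion_rate(n_total: int, n_excluded: int) -> int:
    """Exclusion rate as a percent rounded to the nearest integer."""
    if n_total <= 0:
        raise DataError("n_total must be positive")
    if not 0 <= n_excluded <= n_total:
        raise DataError("n_excluded must lie in [0, n_total]")
    return int(np.floor(100.0 * n_excluded / n_total + 0.5))


def statuses_to_frame(statuses: list[SubjectStatus]) -> pd.DataFrame:
    return pd.DataFrame([
        {"subject_id": s.subject_id, "easiest_accuracy": s.easiest_accuracy,
         "imc_pass": s.imc_pass, "r_squared": s.r_squared,
         "included": s.included,
         "reasons": "+".join(sorted(s.exclusion_reasons))}
        for s in statuses
    ])
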