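"""Group-level inference on fitted central points.

Each experiment's included central points are compared to 0 with a
two-tailed one-sample t-test; p-values are Bonferroni-corrected across the
five probe positions of an experiment family (multiply by 5, cap at 1).
The one-sample effect size is Cohen's d = mean/sd = t/sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

FAMILY_SIZE = 5
ALPHA = 0.05


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> tuple[float, int, float]:
    """Two-tailed one-sample t-test of the mean against ``mu0``.

    Returns (t, df, raw two-tailed p). t = (mean - mu0) / (sd / sqrt(n))
    with the sample sd (ddof=1); p from the central t distribution.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("t-test requires at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DataError("t-test undefined for zero-variance data")
    t = (v.mean() - mu0) / (sd / np.sqrt(v.size))
    df = v.size - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def bonferroni(p_raw: float, m: int = FAMILY_SIZE) -> float:
    """Bonferroni-corrected p: min(1, m * p_raw)."""
    if not 0.0 <= p_raw <= 1.0:
        raise DataError(f"p_raw must lie in [0, 1], got {p_raw}")
    if m < 1:
        raise DataError("m must be >= 1")
    return min(1.0, m * p_raw)


def cohens_d(values: Sequence[float]) -> float:
    """One-sample Cohen's d: mean / sd."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("effect size requires at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DataError("effect size undefined for zero-variance data")
    return float(v.mean() / sd)


def cohens_d_from_t(t: float, n: int) -> float:
    """Recover the one-sample d from a reported t and sample size: t/sqrt(n)."""
    if n < 1:
        raise DataError("n must be >= 1")
    return float(t / np.sqrt(n))


@dataclass
class GroupResult:
    """One experiment's group inference summary."""

    experiment_id: str
    n: int
    mean_xc: float
    sd: float
    sem: float
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    d: float
    significant: bool
    error: str | None = None

    @classmethod
    def failed(cls, experiment_id: str, n: int, message: str) -> "GroupResult":
        nan = float("nan")
        return cls(experiment_id=experiment_id, n=n, mean_xc=nan, sd=nan,
                   sem=nan, t=nan, df=max(n - 1, 0), p_raw=nan,
                   p_bonferroni=nan, d=nan, significant=False, error=message)


def group_result(values: Sequence[float], experiment_id: str = "",
                 m: int = FAMILY_SIZE, alpha: float = ALPHA) -> GroupResult:
    """Full inference summary for one experiment's included central points."""
    v = np.asarray(values, dtype=float)
    t, df, p_raw = one_sample_t(v)
    p_corr = bonferroni(p_raw, m)
    sd = float(v.std(ddof=1))
    return GroupResult(
        experiment_id=experiment_id, n=int(v.size), mean_xc=float(v.mean()),
        sd=sd, sem=sd / float(np.sqrt(v.size)), t=t, df=df, p_raw=p_raw,
        p_bonferroni=p_corr, d=cohens_d(v), significant=p_corr < alpha)


def analyze_family(xc_by_experiment: Mapping[str, Sequence[float]],
                   m: int | None = None, alpha: float = ALPHA) -> list[GroupResult]:
    """Run the corrected group test for every experiment of one family.

    ``xc_by_experiment`` maps experiment id to that experiment's included
    central points. The correction factor defaults to the family size
    (5 probe positions in the study). An experiment with fewer than 2
    included subjects yields a failed entry; the others are unaffected.
    """
    if m is None:
        m = max(len(xc_by_experiment), 1)
    results = []
    for exp_id, values in xc_by_experiment.items():
        try:
            results.append(group_result(values, exp_id, m=m, alpha=alpha))
        except DataError as exc:
            results.append(GroupResult.failed(exp_id, len(values), str(exc)))
    return results


def results_to_frame(results: list[GroupResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"experiment_id": r.experiment_id, "n": r.n, "mean_xc": r.mean_xc,
         "sd": r.sd, "sem": r.sem, "t": r.t, "df": r.df, "p_raw": r.p_raw,
         "p_bonferroni": r.p_bonferroni, "d": r.d,
         "significant": r.significant, "error": r.error or ""}
        for r in results
    ])


def power_one_sample_t(d: float, n: int, alpha: float) -> float:
    """Analytic two-tailed one-sample t power at effect size d via the
    noncentral t distribution (noncentrality d * sqrt(n))."""
    df = n - 1
    nc = d * np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
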