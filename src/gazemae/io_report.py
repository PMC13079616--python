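"""Table I/O, congruence recoding, and the end-to-end pipeline.

The canonical trial table is comma-separated UTF-8 with a header, one row
per trial: experiment_id, subject_id, block, trial, face_side,
coherence_signed, response, imc_pass. Responses may be given directly in
congruence coding (toward/away relative to the gazed-at object) or as raw
left/right key presses, which the reader recodes using the face side: the
face on the left gazes right, so a "right" response there means "toward".
A declarative column map adapts externally deposited datasets to this
schema without code changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .inference import GroupResult, analyze_family, results_to_frame
from .psychometric import PsychometricFit, fits_to_frame
from .schedule import EXPERIMENT_PRESETS
from .screening import apply_exclusions, statuses_to_frame

log = logging.getLogger("gazemae")

COLUMNS = ("experiment_id", "subject_id", "block", "trial", "face_side",
           "coherence_signed", "response", "imc_pass")

_TRUTHY = {"true", "1", "yes", "t", "pass"}
_FALSY = {"false", "0", "no", "f", "fail"}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def recode_response(response: str, face_side: str) -> str:
    """Recode a raw left/right response to congruence coding.

    "toward" means motion in the gaze direction, i.e. away from the face
    side: with the face on the left the agent gazes right, so a "right"
    response is toward.
    """
    if response not in ("left", "right"):
        raise ValueError(f"unknown response token {response!r}")
    if face_side not in ("left", "right"):
        raise ValueError(f"unknown face side {face_side!r}")
    return "away" if response == face_side else "toward"


def read_trials(path: str | Path, column_map: Mapping[str, str] | None = None,
                strict: bool = True) -> pd.DataFrame:
    """Read and validate a trial table.

    ``column_map`` maps canonical column names to the file's headers.
    Left/right responses are recoded to toward/away (the raw token is kept
    in ``response_raw``). Rows failing validation are reported with their
    file line numbers: in strict mode as a DataError, otherwise they are
    dropped, logged, and listed in ``df.attrs["row_errors"]``.
    """
    raw = pd.read_csv(path, dtype=str)
    if column_map:
        missing_src = [src for src in column_map.values() if src not in raw.columns]
        if missing_src:
            raise DataError(f"column_map source columns absent from {path}: {missing_src}")
        raw = raw.rename(columns={src: dst for dst, src in column_map.items()})
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise DataError(f"trial table {path} is missing required columns: {missing}")

    rows = []
    errors: list[str] = []
    for i, rec in enumerate(raw.to_dict("records")):
        line = i + 2  # header occupies line 1
        try:
            face = str(rec["face_side"]).strip().lower()
            resp = str(rec["response"]).strip().lower()
            raw_resp = resp
            if resp in ("left", "right"):
                resp = recode_response(resp, face)
            elif resp not in ("toward", "away"):
                raise ValueError(f"unknown response token {resp!r}")
            rows.append({
                "experiment_id": str(rec["experiment_id"]),
                "subject_id": str(rec["subject_id"]),
                "block": int(rec["block"]),
                "trial": int(rec["trial"]),
                "face_side": face,
                "coherence_signed": float(rec["coherence_signed"]),
                "response": resp,
                "response_raw": raw_resp,
                "imc_pass": _parse_bool(rec["imc_pass"]),
            })
        except (ValueError, TypeError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")

    if errors:
        if strict:
            raise DataError("invalid rows in trial table:\n" + "\n".join(errors))
        for e in errors:
            log.warning("dropped %s", e)
    df = pd.DataFrame(rows, columns=list(COLUMNS) + ["response_raw"])
    df.attrs["row_errors"] = errors
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table in the canonical schema."""
    trials[list(COLUMNS)].to_csv(path, index=False)


@dataclass
class PipelineResult:
    """All per-experiment pipeline outputs."""

    experiment_id: str
    fits: dict[str, PsychometricFit]
    fits_table: pd.DataFrame
    status_table: pd.DataFrame
    included_xc: pd.Series
    counts: dict = field(default_factory=dict)


def process_experiment(trials: pd.DataFrame, levels=None) -> PipelineResult:
    """Condense, fit, and screen one experiment's trial table.

    Stage-1 exclusions (performance, attention check) happen before any
    fitting; only survivors are fit, then screened on goodness of fit.
    Returns the per-subject fit and status tables and the included
    subjects' central points.
    """
    if len(trials) == 0:
        raise DataError("empty trial table")
    exp_id = str(trials["experiment_id"].iloc[0])
    n_subjects = trials["subject_id"].nunique()

    # stage 1 is fit-free; only its survivors are ever fitted
    statuses, fits = apply_exclusions(trials, levels=levels, return_fits=True)
    stage1_excluded = {s.subject_id for s in statuses
                       if s.exclusion_reasons & {"performance", "imc"}}

    status_table = statuses_to_frame(statuses)
    fits_table = fits_to_frame(fits) if fits else pd.DataFrame(
        columns=["subject_id", "x_c", "b", "r_squared", "converged", "sse"])
    included_ids = [s.subject_id for s in statuses if s.included]
    included_xc = pd.Series({sid: fits[sid].x_c for sid in included_ids},
                            name="x_c", dtype=float)

    counts = {
        "loaded": int(n_subjects),
        "stage1_excluded": len(stage1_excluded),
        "fitted": len(fits),
        "stage2_excluded": len(fits) - len(included_ids),
        "included": len(included_ids),
    }
    log.info("experiment %s: %s", exp_id, counts)
    return PipelineResult(experiment_id=exp_id, fits=fits, fits_table=fits_table,
                          status_table=status_table, included_xc=included_xc,
                          counts=counts)


def run_pipeline(trials_by_experiment: Mapping[str, pd.DataFrame],
                 m: int | None = None, levels=None,
                 out_dir: str | Path | None = None,
                 ) -> tuple[dict[str, PipelineResult], list[GroupResult]]:
    """Run the full analysis over one or more experiments.

    Applies the Bonferroni factor ``m`` (default: the number of
    experiments supplied, i.e. the family size) and optionally writes
    every intermediate table plus the group summary under ``out_dir``.
    """
    pipeline: dict[str, PipelineResult] = {}
    xc_by_exp: dict[str, Sequence[float]] = {}
    for exp_id, trials in trials_by_experiment.items():
        res = process_experiment(trials, levels=levels)
        pipeline[exp_id] = res
        xc_by_exp[exp_id] = res.included_xc.to_numpy()
    results = analyze_family(xc_by_exp, m=m)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for exp_id, res in pipeline.items():
            res.fits_table.to_csv(out / f"fits_{exp_id}.csv", index=False)
            res.status_table.to_csv(out / f"status_{exp_id}.csv", index=False)
        results_to_frame(results).to_csv(out / "group_results.csv", index=False)
        (out / "summary.md").write_text(summary_markdown(results, pipeline))
    return pipeline, results


def summary_markdown(results: list[GroupResult],
                     pipeline: Mapping[str, PipelineResult] | None = None) -> str:
    """Human-readable run summary: stage counts and the group table."""
    lines = ["# Group analysis summary", ""]
    if pipeline:
        lines.append("| experiment | loaded | stage-1 excl. | fitted | stage-2 excl. | included |")
        lines.append("|---|---|---|---|---|---|")
        for exp_id, res in pipeline.items():
            c = res.counts
            lines.append(f"| {exp_id} | {c['loaded']} | {c['stage1_excluded']} | "
                         f"{c['fitted']} | {c['stage2_excluded']} | {c['included']} |")
        lines.append("")
    lines.append("| experiment | n | mean x_c (%) | SEM | t | df | p (corrected) | d | sig |")
    lines.append("|---|---|---|---|---|---|---|---|---|")
    for r in results:
        if r.error:
            lines.append(f"| {r.experiment_id} | {r.n} | — | — | — | — | — | — | {r.error} |")
        else:
            marker = "**" if r.p_bonferroni < 0.01 else ("*" if r.significant else "")
            lines.append(
                f"| {r.experiment_id} | {r.n} | {r.mean_xc:.2f} | {r.sem:.2f} | "
                f"{r.t:.2f} | {r.df} | {min(r.p_bonferroni, 1.0):.3f} | "
                f"{r.d:.2f} | {marker} |")
    return "\n".join(lines) + "\n"


def plot_family(results: list[GroupResult], path: str | Path,
                title: str = "") -> None:
    """Plot mean central point ± SEM against probe position, with
    significance markers (** corrected p < 0.01, * < 0.05)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs, means, sems, labels = [], [], [], []
    for r in results:
        if r.error:
            continue
        offset = EXPERIMENT_PRESETS.get(r.experiment_id, (None, None))[1]
        xs.append(offset if offset is not None else len(xs))
        means.append(r.mean_xc)
        sems.append(r.sem)
        labels.append(r)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.errorbar(xs, means, yerr=sems, fmt="D", color="k", capsize=3)
    for x, m, s, r in zip(xs, means, sems, labels):
        if r.p_bonferroni < 0.01:
            ax.annotate("**", (x, m + s), ha="center", va="bottom")
        elif r.significant:
            ax.annotate("*", (x, m + s), ha="center", va="bottom")
    ax.set_xlabel("probe position relative to line of sight (px)")
    ax.set_ylabel("mean central point $x_c$ (% coherence)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
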