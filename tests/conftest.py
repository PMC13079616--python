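import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from gazemae import ExperimentConfig, preset


@pytest.fixture
def default_config() -> ExperimentConfig:
    return preset("1c", seed=11)


def make_trials(coherences, responses, subject_id="s000", experiment_id="1c",
                imc_pass=True, face_side="left") -> pd.DataFrame:
    """Hand-build a minimal trial table from parallel coherence/response lists."""
    n = len(coherences)
    return pd.DataFrame({
        "experiment_id": experiment_id,
        "subject_id": subject_id,
        "block": np.zeros(n, dtype=int),
        "trial": np.arange(n),
        "face_side": face_side,
        "coherence_signed": np.asarray(coherences, dtype=float),
        "response": list(responses),
        "imc_pass": imc_pass,
    })


def grid_search_sse(x, p, xc_range=(-30.0, 30.0), b_range=(0.5, 60.0)) -> float:
    """Exhaustive-grid oracle for the sigmoid least-squares minimum.

    Coarse 0.5-step scan over (x_c, b), then three 41x41 zooms around the
    incumbent, ending at step < 0.001 in both parameters. Fully vectorized
    and independent of the package optimizer.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    xc = np.arange(xc_range[0], xc_range[1] + 1e-9, 0.5)
    b = np.arange(b_range[0], b_range[1] + 1e-9, 0.5)
    best = np.inf
    for _ in range(4):
        F = expit((x[None, None, :] - xc[:, None, None]) / b[None, :, None])
        S = ((p[None, None, :] - F) ** 2).sum(axis=-1)
        i, j = np.unravel_index(S.argmin(), S.shape)
        best = min(best, float(S[i, j]))
        step_xc = xc[1] - xc[0] if xc.size > 1 else 0.5
        step_b = b[1] - b[0] if b.size > 1 else 0.5
        xc = np.linspace(xc[i] - step_xc, xc[i] + step_xc, 41)
        b = np.linspace(max(b[j] - step_b, 1e-4), b[j] + step_b, 41)
    return best
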