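"""Cohort-level Bayesian model of the motion-effect ratio, and its rivals.

For an observer with trait score Q and discrimination thresholds delta_A
(fixation / high contrast) and delta_B (pursuit / low contrast), the model
predicts the perceived-speed ratio

    V_A / V_B = (k Q + delta_A^2 / 2) / (k Q + delta_B^2 / 2),

where ``k Q`` is the variance of the zero-mean slow-speed prior and
``delta^2 / 2`` is the likelihood variance implied by the 2AFC threshold
under signal detection theory.  A single nonnegative scaling factor ``k``
is fitted per cohort by least squares.

Two reduced one-parameter models serve as comparisons: a prior-only model
``ratio = k Q`` (traits alone) and an evidence-only model
``ratio = k delta_A^2 / delta_B^2`` (thresholds alone).  Models are
compared by RMSE and by mean absolute deviation (MAD), which is less
sensitive to outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .psychometrics import ObserverSummary

__all__ = [
    "ModelFit",
    "MODEL_NAMES",
    "cohort_from_summaries",
    "validate_cohort",
    "predicted_ratio",
    "fit_full",
    "fit_prior_only",
    "fit_evidence_only",
    "fit_all",
    "compare",
]

MODEL_NAMES = ("BAYES", "PRIOR_ONLY", "EVIDENCE_ONLY")

#: columns a cohort table must provide
COHORT_COLUMNS = ("observer_id", "Q", "delta_A", "delta_B", "ratio")


@dataclass(frozen=True)
class ModelFit:
    """A fitted one-parameter model with its per-observer predictions."""

    model: str
    k: float
    predictions: np.ndarray
    rmse: float
    mad: float

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")
        if self.k < 0:
            raise ValueError("k must be nonnegative")


def cohort_from_summaries(summaries: Sequence[ObserverSummary]) -> pd.DataFrame:
    """Build the model's input table from included observer summaries."""
    frame = pd.DataFrame(
        {
            "observer_id": [s.observer_id for s in summaries],
            "Q": [s.Q for s in summaries],
            "delta_A": [s.delta_A for s in summaries],
            "delta_B": [s.delta_B for s in summaries],
            "ratio": [s.ratio_measured for s in summaries],
        }
    )
    validate_cohort(frame)
    return frame


def validate_cohort(cohort: pd.DataFrame) -> None:
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    values = cohort[["Q", "delta_A", "delta_B", "ratio"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("cohort table contains non-finite values")
    if np.any(cohort["Q"].to_numpy() < 0):
        raise ValueError("Q must be nonnegative")
    if np.any(cohort[["delta_A", "delta_B", "ratio"]].to_numpy() <= 0):
        raise ValueError("thresholds and ratios must be positive")


def predicted_ratio(k, Q, delta_A, delta_B):
    """Model prediction (kQ + delta_A^2/2) / (kQ + delta_B^2/2).

    Broadcasts over array arguments.  Equals delta_A^2/delta_B^2 in the
    vanishing-prior limit kQ = 0 and tends monotonically to 1 as the prior
    flattens (kQ -> infinity).
    """
    k = np.asarray(k, dtype=float)
    Q = np.asarray(Q, dtype=float)
    dA = np.asarray(delta_A, dtype=float)
    dB = np.asarray(delta_B, dtype=float)
    if np.any(k < 0) or np.any(Q < 0):
        raise ValueError("k and Q must be nonnegative")
    if np.any(dA <= 0) or np.any(dB <= 0):
        raise ValueError("thresholds must be positive")
    kq = k * Q
    return (kq + dA**2 / 2.0) / (kq + dB**2 / 2.0)


def _finish(model: str, k: float, cohort: pd.DataFrame, predictions: np.ndarray) -> ModelFit:
    residuals = cohort["ratio"].to_numpy(dtype=float) - predictions
    rmse = float(np.sqrt(np.mean(residuals**2)))
    mad = float(np.mean(np.abs(residuals)))
    return ModelFit(model=model, k=float(k), predictions=predictions, rmse=rmse, mad=mad)


def fit_full(cohort: pd.DataFrame, k_grid: np.ndarray | None = None) -> ModelFit:
    """Least-squares fit of the full Bayes model over k >= 0.

    The objective is scanned on a log-spaced grid (plus k = 0), then the
    best bracket is refined by bounded scalar minimisation to an objective
    tolerance near machine precision.
    """
    validate_cohort(cohort)
    if len(cohort) < 2:
        raise ValueError("need at least 2 observers to fit the cohort model")
    q = cohort["Q"].to_numpy(dtype=float)
    dA = cohort["delta_A"].to_numpy(dtype=float)
    dB = cohort["delta_B"].to_numpy(dtype=float)
    r = cohort["ratio"].to_numpy(dtype=float)

    def sse(k: float) -> float:
        return float(np.sum((r - predicted_ratio(k, q, dA, dB)) ** 2))

    if k_grid is None:
        k_grid = np.concatenate([[0.0], np.logspace(-6, 2, 241)])
    losses = np.array([sse(k) for k in k_grid])
    i = int(np.argmin(losses))
    lo = k_grid[max(i - 1, 0)]
    hi = k_grid[min(i + 1, len(k_grid) - 1)]
    if hi <= lo:
        hi = lo + 1e-6
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-14})
    k_star = float(res.x) if res.fun <= losses[i] else float(k_grid[i])
    k_star = max(k_star, 0.0)
    return _finish("BAYES", k_star, cohort, predicted_ratio(k_star, q, dA, dB))


def _scaled_regressor_fit(model: str, cohort: pd.DataFrame, x: np.ndarray) -> ModelFit:
    # least squares through the origin: k = sum(x r) / sum(x^2), clipped at 0
    r = cohort["ratio"].to_numpy(dtype=float)
    denom = float(np.sum(x**2))
    if denom == 0:
        raise ValueError(f"{model}: regressor is identically zero")
    k = max(float(np.sum(x * r) / denom), 0.0)
    return _finish(model, k, cohort, k * x)


def fit_prior_only(cohort: pd.DataFrame) -> ModelFit:
    """Reduced model using traits alone: ratio = k Q (closed form)."""
    validate_cohort(cohort)
    if len(cohort) < 2:
        raise ValueError("need at least 2 observers")
    return _scaled_regressor_fit("PRIOR_ONLY", cohort, cohort["Q"].to_numpy(dtype=float))


def fit_evidence_only(cohort: pd.DataFrame) -> ModelFit:
    """Reduced model using thresholds alone: ratio = k delta_A^2/delta_B^2."""
    validate_cohort(cohort)
    if len(cohort) < 2:
        raise ValueError("need at least 2 observers")
    x = (cohort["delta_A"].to_numpy(dtype=float) ** 2
         / cohort["delta_B"].to_numpy(dtype=float) ** 2)
    return _scaled_regressor_fit("EVIDENCE_ONLY", cohort, x)


def fit_all(cohort: pd.DataFrame) -> dict[str, ModelFit]:
    """Fit the full model and both reduced models on one cohort."""
    return {
        "BAYES": fit_full(cohort),
        "PRIOR_ONLY": fit_prior_only(cohort),
        "EVIDENCE_ONLY": fit_evidence_only(cohort),
    }


def compare(fits: Sequence[ModelFit] | dict[str, ModelFit]) -> pd.DataFrame:
    """Rank fitted models by RMSE (MAD reported alongside).

    All fits must come from the same cohort (same number of observers).
    The returned table is sorted by RMSE with the winner flagged.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    if not fits:
        raise ValueError("no fits to compare")
    sizes = {len(f.predictions) for f in fits}
    if len(sizes) != 1:
        raise ValueError("fits come from cohorts of different sizes")
    table = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "k": [f.k for f in fits],
            "rmse": [f.rmse for f in fits],
            "mad": [f.mad for f in fits],
        }
    ).sort_values("rmse", kind="stable", ignore_index=True)
    table["winner"] = [i == 0 for i in range(len(table))]
    return table
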