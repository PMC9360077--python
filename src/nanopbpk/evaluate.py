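"""Model-fit quality via the average absolute fold error (AAFE).

AAFE = 10^((1/N)·Σ|log10(predicted_i/observed_i)|): the geometric-mean fold
discrepancy between model and data.  It is 1 exactly when every prediction
matches its observation and grows with the average order-of-magnitude error;
it is symmetric in prediction/observation and blind to a common rescaling.
Computed per organ and overall, conventionally at the posterior median
parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import predictions_for
from .data import BiodistributionDataset
from .model import ParameterVector
from .physiology import FixedKinetics, RatPhysiology

__all__ = ["FitEvaluation", "aafe", "evaluate_fit", "overlay_frame"]


@dataclass(frozen=True)
class FitEvaluation:
    """Per-organ and overall AAFE for one dataset at one parameter vector."""

    aafe_overall: float
    aafe_by_organ: dict[str, float]
    n_points: dict[str, int]

    @property
    def n_total(self) -> int:
        return sum(self.n_points.values())

    def to_jsonable(self) -> dict:
        return {
            "aafe_overall": self.aafe_overall,
            "aafe_by_organ": dict(self.aafe_by_organ),
            "n_points": dict(self.n_points),
        }


def aafe(predicted, observed) -> float:
    """Average absolute fold error of paired positive concentration vectors."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size < 1:
        raise ValueError("predicted and observed must be 1-D of equal length >= 1")
    if np.any(p <= 0) or np.any(o <= 0):
        raise ValueError("all predicted and observed values must be positive")
    return float(10.0 ** np.mean(np.abs(np.log10(p / o))))


def evaluate_fit(
    theta: ParameterVector,
    dataset: BiodistributionDataset,
    phys: RatPhysiology,
    fixed: FixedKinetics,
) -> FitEvaluation:
    """One simulation at θ; AAFE per organ and over all records.

    Records are matched to predictions exactly as in the likelihood (shared
    simulation at the union of design times, exact organ/time lookup).
    """
    predicted = predictions_for(theta, dataset, phys, fixed)
    predicted = np.maximum(predicted, 1e-12)
    observed = np.array([r.value for r in dataset.records])
    organs = np.array([r.organ for r in dataset.records])

    by_organ: dict[str, float] = {}
    n_points: dict[str, int] = {}
    for organ in sorted(set(organs)):
        mask = organs == organ
        by_organ[organ] = aafe(predicted[mask], observed[mask])
        n_points[organ] = int(mask.sum())
    return FitEvaluation(
        aafe_overall=aafe(predicted, observed),
        aafe_by_organ=by_organ,
        n_points=n_points,
    )


def overlay_frame(
    theta: ParameterVector,
    dataset: BiodistributionDataset,
    phys: RatPhysiology,
    fixed: FixedKinetics,
    n_curve: int = 200,
):
    """Tidy observed-vs-predicted data for per-organ overlay panels.

    Returns a DataFrame with columns (organ, time_h, value_ug_per_g, kind)
    where kind is "observed" (the dataset's records) or "predicted" (a dense
    model curve at θ over the study's time span), ready for external
    plotting.
    """
    import pandas as pd

    from .model import observe, simulate

    t_max = max(r.time_h for r in dataset.records)
    curve_t = np.concatenate(([0.0], np.geomspace(1e-3, t_max, n_curve)))
    result = simulate(theta, phys, fixed, dataset.design.dose_per_bw, curve_t)
    organs = sorted({r.organ for r in dataset.records})
    parts = [
        pd.DataFrame(
            {
                "organ": [r.organ for r in dataset.records],
                "time_h": [r.time_h for r in dataset.records],
                "value_ug_per_g": [r.value for r in dataset.records],
                "kind": "observed",
            }
        )
    ]
    for organ in organs:
        parts.append(
            pd.DataFrame(
                {
                    "organ": organ,
                    "time_h": curve_t,
                    "value_ug_per_g": observe(result, organ, phys),
                    "kind": "predicted",
                }
            )
        )
    return pd.concat(parts, ignore_index=True)
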