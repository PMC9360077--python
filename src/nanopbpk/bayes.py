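"""Bayesian target density: squared-log-ratio likelihood and bounded Jeffreys prior.

The data likelihood is P(D|θ) = exp(−(1/N)·Σ_i ln²(predicted_i/observed_i)),
with N the total number of observed records; one forward simulation per θ at
the union of the design's measurement times supplies every predicted value by
exact (organ, time) lookup.  The prior is the scale-parameter Jeffreys form
1/θ per parameter — uniform in log space — truncated to a per-parameter
[lower, upper] box; the posterior is the (unnormalized) product of the two.
The normalization integral is never computed: the MCMC sampler works with the
unnormalized density directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .data import BiodistributionDataset
from .model import PARAM_NAMES, ParameterVector, observe, simulate
from .physiology import FixedKinetics, RatPhysiology

__all__ = [
    "ParameterBounds",
    "LogDensity",
    "predictions_for",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "published_bounds",
    "PREDICTION_CLAMP",
]

logger = logging.getLogger(__name__)

#: Floor applied to model predictions inside the likelihood.
PREDICTION_CLAMP = 1e-12


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter lower/upper limits (both strictly positive)."""

    lower: dict[str, float]
    upper: dict[str, float]

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo = self.lower.get(name)
            hi = self.upper.get(name)
            if lo is None or hi is None:
                raise ValueError(f"bounds missing parameter {name!r}")
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {name!r} must satisfy 0 < lower < upper")

    def lower_array(self) -> np.ndarray:
        return np.array([self.lower[p] for p in PARAM_NAMES])

    def upper_array(self) -> np.ndarray:
        return np.array([self.upper[p] for p in PARAM_NAMES])

    def contains(self, theta: ParameterVector) -> bool:
        v = theta.to_array()
        return bool(
            np.all(v >= self.lower_array()) and np.all(v <= self.upper_array())
        )

    def log_midpoint(self) -> ParameterVector:
        """Geometric midpoint of the box — the default chain start."""
        mid = np.sqrt(self.lower_array() * self.upper_array())
        return ParameterVector.from_array(mid)


@dataclass(frozen=True)
class LogDensity:
    """Unnormalized log posterior with its two components."""

    log_prior: float
    log_likelihood: float

    @property
    def value(self) -> float:
        if math.isinf(self.log_prior) or math.isinf(self.log_likelihood):
            return -math.inf
        return self.log_prior + self.log_likelihood


# Printed parameter limits per dataset family (the authors centered a
# manually optimized value and took a factor 30 either side).
_PUBLISHED_LIMITS: dict[str, dict[str, tuple[float, float]]] = {
    "PACA-Cbz": {
        "chi_rich": (1.67e-2, 15.0),
        "P": (3.3e-2, 30.0),
        "k_kidneyEl": (1.0, 900.0),
        "k_ab0": (1.16e-2, 10.5),
        "k_sab0": (1.67e-2, 15.0),
        "k_de": (3.3e-5, 0.03),
    },
    "LipImage": {
        "chi_rich": (1.67e-1, 150.0),
        "P": (1.67e-3, 1.5),
        "k_kidneyEl": (3.3e-2, 30.0),
        "k_ab0": (3.3e-2, 30.0),
        "k_sab0": (3.3e-2, 30.0),
        "k_de": (3.3e-5, 0.03),
    },
}


def published_bounds(dataset_family: str) -> ParameterBounds:
    """Published estimation limits for a dataset family.

    ``dataset_family`` is "PACA-Cbz" or "LipImage" (dataset ids such as
    "paca_low" / "lipimage_mid" are also accepted).
    """
    key = dataset_family
    if key not in _PUBLISHED_LIMITS:
        low = dataset_family.lower()
        if low.startswith("paca"):
            key = "PACA-Cbz"
        elif low.startswith("lipimage"):
            key = "LipImage"
        else:
            raise KeyError(
                f"unknown dataset family {dataset_family!r}; "
                f"expected one of {sorted(_PUBLISHED_LIMITS)}"
            )
    table = _PUBLISHED_LIMITS[key]
    return ParameterBounds(
        lower={p: table[p][0] for p in PARAM_NAMES},
        upper={p: table[p][1] for p in PARAM_NAMES},
    )


def predictions_for(
    theta: ParameterVector,
    dataset: BiodistributionDataset,
    phys: RatPhysiology,
    fixed: FixedKinetics,
) -> np.ndarray:
    """Model prediction for every record, from one shared simulation.

    Records are matched by exact (organ, time) lookup against a simulation
    evaluated at the union of the design's measurement times — no
    interpolation.
    """
    times = dataset.design.all_times()
    result = simulate(theta, phys, fixed, dataset.design.dose_per_bw, times)
    time_pos = {float(t): i for i, t in enumerate(times)}
    trajectories = {
        organ: observe(result, organ, phys)
        for organ in {r.organ for r in dataset.records}
    }
    out = np.empty(dataset.n)
    for i, rec in enumerate(dataset.records):
        try:
            j = time_pos[rec.time_h]
        except KeyError:
            raise ValueError(
                f"record time {rec.time_h} h is not a design measurement time"
            ) from None
        out[i] = trajectories[rec.organ][j]
    return out


def log_likelihood(
    theta: ParameterVector,
    dataset: BiodistributionDataset,
    phys: RatPhysiology,
    fixed: FixedKinetics,
) -> float:
    """ln P(D|θ) = −(1/N)·Σ ln²(predicted_i/observed_i); −inf on solver failure."""
    try:
        predicted = predictions_for(theta, dataset, phys, fixed)
    except Exception as exc:  # solver failure → impossible θ
        logger.warning("simulation failed at θ=%s: %s", theta.as_dict(), exc)
        return -math.inf
    n_clamped = int(np.sum(predicted < PREDICTION_CLAMP))
    if n_clamped:
        logger.debug("clamped %d prediction(s) below %g", n_clamped, PREDICTION_CLAMP)
    predicted = np.maximum(predicted, PREDICTION_CLAMP)
    observed = np.array([r.value for r in dataset.records])
    log_ratios = np.log(predicted / observed)
    return float(-np.mean(log_ratios**2))


def log_prior(theta: ParameterVector, bounds: ParameterBounds) -> float:
    """Unnormalized log of the bounded Jeffreys (1/θ) prior; −inf off the box."""
    if not bounds.contains(theta):
        return -math.inf
    return float(-np.sum(np.log(theta.to_array())))


def log_posterior(
    theta: ParameterVector,
    dataset: BiodistributionDataset,
    bounds: ParameterBounds,
    phys: RatPhysiology,
    fixed: FixedKinetics,
) -> LogDensity:
    """Unnormalized posterior; out-of-bounds θ short-circuits the simulation."""
    lp = log_prior(theta, bounds)
    if math.isinf(lp):
        return LogDensity(log_prior=lp, log_likelihood=-math.inf)
    ll = log_likelihood(theta, dataset, phys, fixed)
    return LogDensity(log_prior=lp, log_likelihood=ll)
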