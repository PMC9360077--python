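"""Posterior summaries: medians, 90% credible intervals, densities, correlations.

The credible interval is equal-tailed — the (5th, 95th) percentile pair — so
it contains 90% of the posterior draws by construction.  Densities are
estimated on a log-scale grid spanning the estimation bounds, matching the
order-of-magnitude spans the parameters live on.  A highest-posterior-density
variant of the interval is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .bayes import ParameterBounds
from .model import PARAM_NAMES
from .sampler import PosteriorSamples

__all__ = [
    "ParameterSummary",
    "summarize",
    "density_estimate",
    "correlation_report",
]

_MIN_DRAWS = 100


@dataclass(frozen=True)
class ParameterSummary:
    """Median, equal-tailed 90% interval and pairwise Pearson correlations."""

    median: dict[str, float]
    ci90_lower: dict[str, float]
    ci90_upper: dict[str, float]
    pairwise_correlation: np.ndarray  # (d, d), order = param_names
    param_names: tuple[str, ...] = PARAM_NAMES

    def correlation(self, a: str, b: str) -> float:
        i, j = self.param_names.index(a), self.param_names.index(b)
        return float(self.pairwise_correlation[i, j])

    def to_jsonable(self) -> dict:
        return {
            p: {
                "median": self.median[p],
                "ci90": [self.ci90_lower[p], self.ci90_upper[p]],
            }
            for p in self.param_names
        }


def _require_draws(samples: PosteriorSamples) -> None:
    if samples.n_draws < _MIN_DRAWS:
        raise ValueError(
            f"need at least {_MIN_DRAWS} draws to summarize, got {samples.n_draws}"
        )


def summarize(samples: PosteriorSamples, hpd: bool = False) -> ParameterSummary:
    """Posterior medians, 90% intervals and correlations over the draws.

    With ``hpd`` the interval is the highest-posterior-density interval
    (narrowest window containing 90% of the draws) instead of equal-tailed.
    """
    _require_draws(samples)
    median, lo, hi = {}, {}, {}
    for p in samples.param_names:
        col = samples.column(p)
        median[p] = float(np.median(col))
        if hpd:
            lo[p], hi[p] = _hpd_interval(col, 0.90)
        else:
            lo[p] = float(np.percentile(col, 5.0))
            hi[p] = float(np.percentile(col, 95.0))
    corr = np.corrcoef(samples.draws, rowvar=False)
    return ParameterSummary(
        median=median,
        ci90_lower=lo,
        ci90_upper=hi,
        pairwise_correlation=corr,
        param_names=samples.param_names,
    )


def _hpd_interval(draws: np.ndarray, mass: float) -> tuple[float, float]:
    x = np.sort(draws)
    n = x.size
    window = max(1, int(np.floor(mass * n)))
    widths = x[window:] - x[: n - window]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + window])


def density_estimate(
    samples: PosteriorSamples,
    param: str,
    bounds: ParameterBounds,
    n_grid: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel density of one parameter on a log-scale grid over its bounds.

    Returns (grid, density) where the grid spans [lower, upper] of the
    parameter geometrically and the density is per unit ln θ, renormalized so
    its trapezoid integral over the grid is 1.
    """
    _require_draws(samples)
    lo = bounds.lower[param]
    hi = bounds.upper[param]
    z = np.log(samples.column(param))
    grid_z = np.linspace(np.log(lo), np.log(hi), n_grid)
    spread = float(np.std(z))
    if spread == 0.0:  # degenerate chain: a narrow box around the point mass
        density = np.zeros(n_grid)
        density[np.argmin(np.abs(grid_z - z[0]))] = 1.0
    else:
        density = gaussian_kde(z)(grid_z)
    integral = np.trapezoid(density, grid_z)
    if integral <= 0:
        raise ValueError(f"degenerate density for parameter {param!r}")
    return np.exp(grid_z), density / integral


def correlation_report(
    samples: PosteriorSamples, threshold: float = 0.7
) -> list[tuple[str, str, float]]:
    """Parameter pairs whose |Pearson r| over the draws exceeds ``threshold``."""
    _require_draws(samples)
    corr = np.corrcoef(samples.draws, rowvar=False)
    names = samples.param_names
    flagged = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = float(corr[i, j])
            if abs(r) > threshold:
                flagged.append((names[i], names[j], r))
    flagged.sort(key=lambda t: -abs(t[2]))
    return flagged
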