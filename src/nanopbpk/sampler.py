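"""Robust adaptive Metropolis (RAM) sampling of the posterior in log space.

The sampler maintains a lower-triangular proposal factor S_n and proposes
z' = z_n + S_n·u_n with u_n standard normal.  After each step the factor is
adapted so that S S' tracks a shape whose acceptance probability approaches a
target rate α* (0.234 by default):

    S_{n+1} S_{n+1}' = S_n (I + η_n (α_n − α*) u_n u_n' / ‖u_n‖²) S_n',
    η_n = min(1, d · n^{−γ}),  γ ∈ (0.5, 1].

Sampling happens in z = ln θ, where the bounded Jeffreys prior is flat, so the
target reduces to the data log-likelihood inside the log-box (the 1/θ prior
density and the exp-transform Jacobian cancel exactly).  Out-of-bounds
proposals are rejected (α_n = 0) but still drive the adaptation, which keeps
the proposal from inflating against the box walls.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .bayes import ParameterBounds, log_posterior
from .data import BiodistributionDataset
from .model import PARAM_NAMES, ParameterVector
from .physiology import FixedKinetics, RatPhysiology

__all__ = [
    "SamplerSettings",
    "PosteriorSamples",
    "ram_sample",
    "run_fit",
    "diagnostics",
    "DiagnosticsReport",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerSettings:
    """Tuning knobs of the RAM sampler.

    Defaults follow the standard recommendations for this sampler family:
    target acceptance 0.234, adaptation step decay n^(−2/3), 1e5 iterations
    with the first half discarded, chain started at the geometric midpoint of
    the bounds with an initial proposal scale of 0.1 of the log-range per
    parameter.
    """

    n_iterations: int = 100_000
    target_acceptance: float = 0.234
    adaptation_decay_exponent: float = 2.0 / 3.0
    burn_in_fraction: float = 0.5
    seed: int = 0
    initial_point: ParameterVector | None = None  # None → log-midpoint
    initial_scale: np.ndarray | float | None = None  # per-dim sd in log space
    adapt: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.target_acceptance < 1:
            raise ValueError("target_acceptance must lie in (0, 1)")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.5 < self.adaptation_decay_exponent <= 1.0:
            raise ValueError("adaptation_decay_exponent must lie in (0.5, 1]")

    def to_jsonable(self) -> dict:
        d = {
            "n_iterations": self.n_iterations,
            "target_acceptance": self.target_acceptance,
            "adaptation_decay_exponent": self.adaptation_decay_exponent,
            "burn_in_fraction": self.burn_in_fraction,
            "seed": self.seed,
            "adapt": self.adapt,
        }
        if self.initial_point is not None:
            d["initial_point"] = self.initial_point.as_dict()
        if self.initial_scale is not None:
            d["initial_scale"] = np.asarray(self.initial_scale).tolist()
        return d


@dataclass(frozen=True)
class PosteriorSamples:
    """Post-burn-in draws with their log-posterior values and chain metadata."""

    draws: np.ndarray  # (n_draws, d), on the natural (exponentiated) scale
    log_posteriors: np.ndarray  # (n_draws,)
    acceptance_rate: float
    settings: SamplerSettings
    param_names: tuple[str, ...] = PARAM_NAMES
    map_point: np.ndarray | None = None
    map_log_likelihood: float | None = None

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def column(self, param: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(param)]

    def n_effective(self) -> dict[str, float]:
        """Effective sample size per parameter (autocorrelation based)."""
        import arviz as az

        return {
            p: float(az.ess(np.asarray(self.column(p))[None, :]))
            for p in self.param_names
        }

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(self.draws, columns=list(self.param_names))
        frame.insert(0, "log_posterior", self.log_posteriors)
        frame.insert(0, "iteration", np.arange(self.n_draws))
        return frame


def ram_sample(
    target: Callable[[np.ndarray], float],
    bounds_lower: np.ndarray,
    bounds_upper: np.ndarray,
    settings: SamplerSettings,
    initial: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Run the RAM chain on a log-density over an axis-aligned box.

    ``target`` maps a point z (here: log-parameters) to its log density;
    points outside [bounds_lower, bounds_upper] are rejected without calling
    ``target``.  Returns (post-burn-in draws in z-space, their log densities,
    overall acceptance rate, final proposal factor S).
    """
    lo = np.asarray(bounds_lower, dtype=float)
    hi = np.asarray(bounds_upper, dtype=float)
    d = lo.size
    rng = np.random.default_rng(settings.seed)

    if initial is None:
        z = 0.5 * (lo + hi)
    else:
        z = np.asarray(initial, dtype=float).copy()
    logp = target(z)
    if not math.isfinite(logp):
        raise ValueError(
            "target is not finite at the initial point; choose a different start"
        )

    scale = settings.initial_scale
    if scale is None:
        scale = 0.1 * (hi - lo)
    S = np.diag(np.broadcast_to(np.asarray(scale, dtype=float), (d,)).copy())

    n = settings.n_iterations
    burn = int(round(settings.burn_in_fraction * n))
    kept = np.empty((n - burn, d))
    kept_logp = np.empty(n - burn)
    n_accept = 0
    alpha_star = settings.target_acceptance
    gamma = settings.adaptation_decay_exponent

    for i in range(n):
        u = rng.standard_normal(d)
        z_prop = z + S @ u
        if np.all(z_prop >= lo) and np.all(z_prop <= hi):
            logp_prop = target(z_prop)
            alpha = min(1.0, math.exp(min(0.0, logp_prop - logp)))
        else:
            logp_prop = -math.inf
            alpha = 0.0
        if rng.random() < alpha:
            z, logp = z_prop, logp_prop
            n_accept += 1
        if settings.adapt:
            eta = min(1.0, d * (i + 1) ** (-gamma))
            norm2 = float(u @ u)
            if norm2 > 0.0:
                M = S @ (
                    np.eye(d) + eta * (alpha - alpha_star) * np.outer(u, u) / norm2
                ) @ S.T
                try:
                    S = np.linalg.cholesky(M)
                except np.linalg.LinAlgError:  # pragma: no cover - safeguard
                    logger.warning("proposal update lost positive definiteness; kept S")
        if i >= burn:
            kept[i - burn] = z
            kept_logp[i - burn] = logp

    return kept, kept_logp, n_accept / n, S


def run_fit(
    dataset: BiodistributionDataset,
    bounds: ParameterBounds,
    phys: RatPhysiology,
    fixed: FixedKinetics,
    settings: SamplerSettings | None = None,
    map_polish: bool = True,
    output_dir: str | Path | None = None,
) -> PosteriorSamples:
    """Sample the posterior of the six kinetic parameters for one dataset.

    Composes the posterior density with :func:`ram_sample` in log-parameter
    space and exponentiates the draws on output.  With ``map_polish`` the
    best sampled point is refined by a bounded local optimization of the log
    posterior, giving a maximum-a-posteriori estimate alongside the chain.
    If ``output_dir`` is given, the samples CSV and a run manifest JSON
    (seed, settings, bounds hash) are written there.
    """
    settings = settings or SamplerSettings()
    lo = np.log(bounds.lower_array())
    hi = np.log(bounds.upper_array())

    def target(z: np.ndarray) -> float:
        theta = ParameterVector.from_array(np.exp(z))
        # Log-box: flat prior in z (1/θ density × e^z Jacobian ≡ 1), so the
        # in-bounds target is just the data log-likelihood.
        density = log_posterior(theta, dataset, bounds, phys, fixed)
        if math.isinf(density.value):
            return -math.inf
        return density.log_likelihood

    initial = None
    if settings.initial_point is not None:
        initial = np.log(settings.initial_point.to_array())

    draws_z, logp, acc_rate, _ = ram_sample(target, lo, hi, settings, initial=initial)
    draws = np.exp(draws_z)

    map_point = None
    map_ll = None
    if map_polish:
        from scipy.optimize import minimize

        z_best = draws_z[int(np.argmax(logp))]
        res = minimize(
            lambda z: -target(z),
            z_best,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        map_point = np.exp(res.x)
        map_ll = float(-res.fun)

    samples = PosteriorSamples(
        draws=draws,
        log_posteriors=logp,
        acceptance_rate=acc_rate,
        settings=settings,
        map_point=map_point,
        map_log_likelihood=map_ll,
    )
    if output_dir is not None:
        _write_run(samples, dataset, bounds, Path(output_dir))
    return samples


def _write_run(
    samples: PosteriorSamples,
    dataset: BiodistributionDataset,
    bounds: ParameterBounds,
    out: Path,
) -> None:
    import hashlib

    out.mkdir(parents=True, exist_ok=True)
    samples.to_frame().to_csv(out / "samples.csv", index=False, float_format="%.17g")
    bounds_blob = json.dumps(
        {"lower": bounds.lower, "upper": bounds.upper}, sort_keys=True
    )
    manifest = {
        "dataset_id": dataset.design.dataset_id,
        "n_records": dataset.n,
        "seed": samples.settings.seed,
        "settings": samples.settings.to_jsonable(),
        "acceptance_rate": samples.acceptance_rate,
        "bounds_sha256": hashlib.sha256(bounds_blob.encode()).hexdigest(),
    }
    if samples.map_point is not None:
        manifest["map"] = dict(zip(PARAM_NAMES, samples.map_point.tolist()))
        manifest["map_log_likelihood"] = samples.map_log_likelihood
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


@dataclass(frozen=True)
class DiagnosticsReport:
    acceptance_rate: float
    ess: dict[str, float]
    rhat: dict[str, float] | None
    flags: tuple[str, ...] = field(default_factory=tuple)


def diagnostics(chains: Sequence[PosteriorSamples]) -> DiagnosticsReport:
    """Chain health report: acceptance, ESS, and split-R̂ when ≥2 chains.

    Parameters with R̂ above 1.05 (or degenerate single-value chains) are
    flagged by name.
    """
    import arviz as az

    if not chains:
        raise ValueError("need at least one chain")
    names = chains[0].param_names
    stacked = {
        p: np.stack([np.asarray(c.column(p)) for c in chains]) for p in names
    }
    flags: list[str] = []
    ess = {}
    for p, arr in stacked.items():
        if np.allclose(arr, arr.flat[0]):
            ess[p] = 1.0
            flags.append(f"{p}: degenerate chain (constant draws)")
        else:
            ess[p] = float(az.ess(arr))
            if ess[p] < 0.01 * arr.size:
                flags.append(f"{p}: ESS below 1% of draws")
    rhat = None
    if len(chains) >= 2:
        rhat = {}
        for p, arr in stacked.items():
            if np.allclose(arr, arr.flat[0]):
                rhat[p] = float("nan")
                continue
            rhat[p] = float(az.rhat(arr))
            if rhat[p] > 1.05:
                flags.append(f"{p}: split-Rhat {rhat[p]:.3f} > 1.05")
    acc = float(np.mean([c.acceptance_rate for c in chains]))
    return DiagnosticsReport(
        acceptance_rate=acc, ess=ess, rhat=rhat, flags=tuple(flags)
    )
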