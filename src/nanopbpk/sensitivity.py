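"""Local one-at-a-time sensitivity of blood AUC, as elasticity coefficients.

The output of interest is the area under the curve of nanobiomaterial
*amounts* in the two blood compartments (venous + arterial) over a time
horizon.  For a parameter p perturbed one at a time by a fraction f (default
10%, upward), the elasticity is

    S = (ΔAUC/AUC) / (Δp/p),   Δp = f·p,

a dimensionless local sensitivity: S = 1 means a 10% parameter increase
yields a 10% AUC increase.  Combined (joint) perturbations are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np

from .model import PARAM_NAMES, ParameterVector, simulate
from .physiology import PERFUSED_ORGANS, FixedKinetics, RatPhysiology

__all__ = ["SensitivityResult", "blood_auc", "elasticity", "oat_scan"]

_THETA_FIELD = {
    "chi_rich": "chi_rich",
    "P": "partition",
    "k_kidneyEl": "k_kidney_el",
    "k_ab0": "k_ab0",
    "k_sab0": "k_sab0",
    "k_de": "k_de",
}
_FIXED_SCALARS = ("k_hepatic_metab", "k_biliary", "k_fecal", "k_lymphnode_to_venous")


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    elasticity: float
    auc_base: float  # µg·h
    auc_perturbed: float  # µg·h
    perturbation_fraction: float


def blood_auc(
    theta: ParameterVector,
    phys: RatPhysiology,
    fixed: FixedKinetics,
    dose_per_bw: float,
    horizon: float = 336.0,
    n_grid: int = 2000,
) -> float:
    """Trapezoidal AUC (µg·h) of arterial+venous amounts over [0, horizon].

    The grid is geometric from 1e-4 h to the horizon (plus t = 0) so the
    fast first-pass redistribution transient is resolved.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    times = np.concatenate(([0.0], np.geomspace(1e-4, horizon, n_grid)))
    result = simulate(theta, phys, fixed, dose_per_bw, times)
    blood = result.amounts("main", "arterial") + result.amounts("main", "venous")
    return float(np.trapezoid(blood, times))


def _perturbed(
    param_name: str,
    factor: float,
    theta: ParameterVector,
    fixed: FixedKinetics,
    dose_per_bw: float,
) -> tuple[ParameterVector, FixedKinetics, float]:
    """Return (theta, fixed, dose) with one named parameter scaled by factor."""
    if param_name == "dose":
        return theta, fixed, dose_per_bw * factor
    if param_name in _THETA_FIELD:
        field_name = _THETA_FIELD[param_name]
        value = getattr(theta, field_name) * factor
        return _dc_replace(theta, **{field_name: value}), fixed, dose_per_bw
    if param_name in _FIXED_SCALARS:
        value = getattr(fixed, param_name) * factor
        return theta, fixed.with_overrides(**{param_name: value}), dose_per_bw
    if param_name.startswith("chi."):
        organ = param_name.split(".", 1)[1]
        if organ not in fixed.chi:
            raise KeyError(f"unknown organ in {param_name!r}")
        chi = dict(fixed.chi)
        chi[organ] *= factor
        return theta, fixed.with_overrides(chi=chi), dose_per_bw
    if param_name.startswith("k_lymph."):
        organ = param_name.split(".", 1)[1]
        if organ not in PERFUSED_ORGANS:
            raise KeyError(f"unknown organ in {param_name!r}")
        k_lymph = dict(fixed.k_lymph)
        k_lymph[organ] = k_lymph.get(organ, 0.0) * factor
        return theta, fixed.with_overrides(k_lymph=k_lymph), dose_per_bw
    raise KeyError(
        f"unknown parameter {param_name!r}; expected one of {PARAM_NAMES}, "
        f"{_FIXED_SCALARS}, 'dose', 'chi.<organ>' or 'k_lymph.<organ>'"
    )


def elasticity(
    theta: ParameterVector,
    param_name: str,
    phys: RatPhysiology,
    fixed: FixedKinetics,
    dose_per_bw: float,
    perturbation_fraction: float = 0.10,
    horizon: float = 336.0,
    central: bool = False,
) -> SensitivityResult:
    """Elasticity of blood AUC with respect to one named parameter.

    The perturbation is one-sided upward by default (p → (1+f)·p); with
    ``central`` a symmetric two-sided difference is used instead.
    ``param_name`` may name any of the six estimated parameters, a fixed
    scalar rate, a per-organ fixed permeability ("chi.<organ>") or lymph rate
    ("k_lymph.<organ>"), or "dose".
    """
    if not 0 < perturbation_fraction < 1:
        raise ValueError("perturbation_fraction must lie in (0, 1)")
    auc0 = blood_auc(theta, phys, fixed, dose_per_bw, horizon)

    t_up, f_up, d_up = _perturbed(param_name, 1.0 + perturbation_fraction, theta, fixed, dose_per_bw)
    auc_up = blood_auc(t_up, phys, f_up, d_up, horizon)
    if central:
        t_dn, f_dn, d_dn = _perturbed(
            param_name, 1.0 - perturbation_fraction, theta, fixed, dose_per_bw
        )
        auc_dn = blood_auc(t_dn, phys, f_dn, d_dn, horizon)
        s = (auc_up - auc_dn) / auc0 / (2.0 * perturbation_fraction)
    else:
        s = (auc_up - auc0) / auc0 / perturbation_fraction
    return SensitivityResult(
        parameter=param_name,
        elasticity=float(s),
        auc_base=auc0,
        auc_perturbed=auc_up,
        perturbation_fraction=perturbation_fraction,
    )


def oat_scan(
    theta: ParameterVector,
    param_list: Sequence[str],
    phys: RatPhysiology,
    fixed: FixedKinetics,
    dose_per_bw: float,
    perturbation_fraction: float = 0.10,
    horizon: float = 336.0,
    low_influence_threshold: float = 0.1,
) -> list[SensitivityResult]:
    """One-at-a-time elasticities for each listed parameter, |S| descending.

    Entries with |S| below ``low_influence_threshold`` classify as
    low-influence (see :func:`is_low_influence`).
    """
    if not param_list:
        raise ValueError("param_list must be non-empty")
    if len(set(param_list)) != len(param_list):
        raise ValueError("duplicate parameter names in param_list")
    results = [
        elasticity(theta, p, phys, fixed, dose_per_bw, perturbation_fraction, horizon)
        for p in param_list
    ]
    results.sort(key=lambda r: -abs(r.elasticity))
    return results


def is_low_influence(result: SensitivityResult, threshold: float = 0.1) -> bool:
    """Whether a parameter's |elasticity| falls below the influence threshold."""
    return abs(result.elasticity) < threshold
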