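"""YAML run configuration: physiology, fixed kinetics, bounds, sampler, seeds.

Every value has a built-in default (the reference physiology, the placeholder
fixed rates, the published estimation bounds, the standard sampler settings),
so an empty or absent configuration is fully usable; a config file overrides
selectively.  Schema errors are reported with their dotted key path.  Each
pipeline run writes a manifest carrying the SHA-256 hash of the resolved
configuration, the seed, and the package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .bayes import ParameterBounds, published_bounds
from .model import PARAM_NAMES
from .physiology import (
    PC_ORGANS,
    PERFUSED_ORGANS,
    FixedKinetics,
    RatPhysiology,
    default_fixed_kinetics,
    default_physiology,
)
from .sampler import SamplerSettings

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config_dict"]


class ConfigError(ValueError):
    """A configuration value failed validation; message carries the key path."""


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration."""

    physiology: RatPhysiology
    fixed_kinetics: FixedKinetics
    bounds: dict[str, ParameterBounds]
    sampler: SamplerSettings
    noise_sigma: float
    seed: int
    output_dir: Path
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def manifest(self) -> dict:
        from . import __version__

        return {
            "package": "nanopbpk",
            "version": __version__,
            "seed": self.seed,
            "config_sha256": self.config_hash(),
        }


def default_config_dict() -> dict:
    """The resolved default configuration as a plain dictionary."""
    phys = default_physiology()
    fixed = default_fixed_kinetics()
    return {
        "physiology": {
            "body_weight": phys.body_weight,
            "provenance": dict(phys.provenance),
        },
        "fixed_kinetics": {
            "k_hepatic_metab": fixed.k_hepatic_metab,
            "k_biliary": fixed.k_biliary,
            "k_fecal": fixed.k_fecal,
            "k_lymphnode_to_venous": fixed.k_lymphnode_to_venous,
            "chi": dict(fixed.chi),
            "k_lymph": dict(fixed.k_lymph),
            "pc_capacity": dict(fixed.pc_capacity),
            "provenance": "placeholder first-order defaults (1e-3 1/h); "
            "capacities unbounded",
        },
        "bounds": {
            family: {
                p: [published_bounds(family).lower[p], published_bounds(family).upper[p]]
                for p in PARAM_NAMES
            }
            for family in ("PACA-Cbz", "LipImage")
        },
        "sampler": {},
        "noise_sigma": 0.3,
        "seed": 0,
        "output_dir": "runs",
    }


def _expect_mapping(value: Any, path: str) -> dict:
    if value is None:
        return {}
    if not isinstance(value, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(value).__name__}")
    return value


def _expect_number(value: Any, path: str, positive: bool = False) -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigError(f"{path}: expected a number, got {value!r}")
    if positive and not value > 0:
        raise ConfigError(f"{path}: must be strictly positive, got {value}")
    return float(value)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config (or the defaults when ``path`` is None)."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        raw = _expect_mapping(loaded, "<root>")

    phys_cfg = _expect_mapping(raw.get("physiology"), "physiology")
    body_weight = _expect_number(
        phys_cfg.get("body_weight", 250.0), "physiology.body_weight", positive=True
    )
    phys = default_physiology(body_weight)
    if "organ_mass" in phys_cfg:
        masses = dict(phys.organ_mass)
        for organ, value in _expect_mapping(
            phys_cfg["organ_mass"], "physiology.organ_mass"
        ).items():
            masses[organ] = _expect_number(
                value, f"physiology.organ_mass.{organ}", positive=True
            )
        phys = phys.with_overrides(organ_mass=masses)

    fk_cfg = _expect_mapping(raw.get("fixed_kinetics"), "fixed_kinetics")
    fixed = default_fixed_kinetics()
    overrides: dict[str, Any] = {}
    for key in ("k_hepatic_metab", "k_biliary", "k_fecal", "k_lymphnode_to_venous"):
        if key in fk_cfg:
            value = _expect_number(fk_cfg[key], f"fixed_kinetics.{key}")
            if value < 0:
                raise ConfigError(f"fixed_kinetics.{key}: rate must be >= 0")
            overrides[key] = value
    if "chi" in fk_cfg:
        chi = dict(fixed.chi)
        for organ, value in _expect_mapping(fk_cfg["chi"], "fixed_kinetics.chi").items():
            if organ not in PERFUSED_ORGANS:
                raise ConfigError(f"fixed_kinetics.chi.{organ}: unknown organ")
            chi[organ] = _expect_number(value, f"fixed_kinetics.chi.{organ}")
        overrides["chi"] = chi
    if "k_lymph" in fk_cfg:
        k_lymph = dict(fixed.k_lymph)
        for organ, value in _expect_mapping(
            fk_cfg["k_lymph"], "fixed_kinetics.k_lymph"
        ).items():
            if organ not in PERFUSED_ORGANS:
                raise ConfigError(f"fixed_kinetics.k_lymph.{organ}: unknown organ")
            k_lymph[organ] = _expect_number(value, f"fixed_kinetics.k_lymph.{organ}")
        overrides["k_lymph"] = k_lymph
    if "pc_capacity" in fk_cfg:
        caps = dict(fixed.pc_capacity)
        for organ, value in _expect_mapping(
            fk_cfg["pc_capacity"], "fixed_kinetics.pc_capacity"
        ).items():
            if organ not in PC_ORGANS:
                raise ConfigError(f"fixed_kinetics.pc_capacity.{organ}: unknown organ")
            caps[organ] = (
                None
                if value in (None, "unbounded")
                else _expect_number(
                    value, f"fixed_kinetics.pc_capacity.{organ}", positive=True
                )
            )
        overrides["pc_capacity"] = caps
    if overrides:
        fixed = fixed.with_overrides(**overrides)

    bounds: dict[str, ParameterBounds] = {
        "PACA-Cbz": published_bounds("PACA-Cbz"),
        "LipImage": published_bounds("LipImage"),
    }
    for family, table in _expect_mapping(raw.get("bounds"), "bounds").items():
        base = bounds.get(family) or published_bounds(family)
        lower = dict(base.lower)
        upper = dict(base.upper)
        for p, pair in _expect_mapping(table, f"bounds.{family}").items():
            if p not in PARAM_NAMES:
                raise ConfigError(f"bounds.{family}.{p}: unknown parameter")
            if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
                raise ConfigError(f"bounds.{family}.{p}: expected [lower, upper]")
            lower[p] = _expect_number(pair[0], f"bounds.{family}.{p}[0]", positive=True)
            upper[p] = _expect_number(pair[1], f"bounds.{family}.{p}[1]", positive=True)
        bounds[family] = ParameterBounds(lower=lower, upper=upper)

    sampler_cfg = _expect_mapping(raw.get("sampler"), "sampler")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError(f"seed: expected an integer, got {seed!r}")
    try:
        sampler = SamplerSettings(
            n_iterations=int(sampler_cfg.get("n_iterations", 100_000)),
            target_acceptance=float(sampler_cfg.get("target_acceptance", 0.234)),
            adaptation_decay_exponent=float(
                sampler_cfg.get("adaptation_decay_exponent", 2.0 / 3.0)
            ),
            burn_in_fraction=float(sampler_cfg.get("burn_in_fraction", 0.5)),
            seed=seed,
        )
    except ValueError as exc:
        raise ConfigError(f"sampler: {exc}") from exc

    noise_sigma = _expect_number(raw.get("noise_sigma", 0.3), "noise_sigma")
    if noise_sigma < 0:
        raise ConfigError("noise_sigma: must be >= 0")

    return RunConfig(
        physiology=phys,
        fixed_kinetics=fixed,
        bounds=bounds,
        sampler=sampler,
        noise_sigma=noise_sigma,
        seed=seed,
        output_dir=Path(raw.get("output_dir", "runs")),
        raw=raw,
    )
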