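"""Rat anatomy, blood flows, and fixed (non-estimated) kinetic rates.

The compartmental model distributes material over fourteen main compartments —
arterial and venous blood, upper airways, tracheobronchial region, pulmonary
region, liver, spleen, kidney, heart, brain, gastro-intestinal (GI) tract, the
remaining organs ("rest"), the lymph nodes, and the GI lumen — all
interconnected via the blood circulation.  Everything in this module is held
fixed during parameter estimation: organ masses, regional blood flows, cardiac
output, and the kinetic rates that are not part of the estimated parameter
vector.

Reference values are standard adult-rat physiology (Brown et al., Toxicol Ind
Health 1997 compilation) expressed as fractions of body weight / cardiac
output and scaled linearly with body weight; each constant carries a
provenance note in the default configuration.  Tissue density is fixed at
1 g/mL, so organ mass in grams and volume in mL are used interchangeably and
concentrations are reported per gram of tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "MAIN_COMPARTMENTS",
    "PERFUSED_ORGANS",
    "SYSTEMIC_ORGANS",
    "RICHLY_PERFUSED",
    "PC_ORGANS",
    "CLEARANCE_ROUTES",
    "ELIMINATION_SINKS",
    "RatPhysiology",
    "FixedKinetics",
    "default_physiology",
    "default_fixed_kinetics",
    "validate_physiology",
]

#: The fourteen main compartments of the circulation model.
MAIN_COMPARTMENTS: tuple[str, ...] = (
    "arterial",
    "venous",
    "upper_airways",
    "tracheobronchial",
    "pulmonary",
    "liver",
    "spleen",
    "kidney",
    "heart",
    "brain",
    "gi_tract",
    "rest",
    "lymph_nodes",
    "gi_lumen",
)

#: Tissue compartments perfused by the blood circulation.
PERFUSED_ORGANS: tuple[str, ...] = (
    "upper_airways",
    "tracheobronchial",
    "pulmonary",
    "liver",
    "spleen",
    "kidney",
    "heart",
    "brain",
    "gi_tract",
    "rest",
)

#: Organs supplied in parallel from the arterial pool; their flows sum to the
#: cardiac output.  The pulmonary region sits in series and receives the
#: entire cardiac output from the venous pool.
SYSTEMIC_ORGANS: tuple[str, ...] = tuple(
    o for o in PERFUSED_ORGANS if o != "pulmonary"
)

#: Organs whose vascular permeability is the estimated chi_rich.
RICHLY_PERFUSED: tuple[str, ...] = (
    "pulmonary",
    "liver",
    "spleen",
    "kidney",
    "heart",
    "gi_tract",
)

#: Organs carrying a phagocytizing-cell (macrophage) sub-compartment.
PC_ORGANS: tuple[str, ...] = (
    "pulmonary",
    "liver",
    "spleen",
    "kidney",
    "heart",
    "brain",
    "gi_tract",
    "rest",
)

#: The four clearance routes of the model.  Lymphatic clearance accumulates in
#: the lymph-node compartment (slowly returning to venous blood); the other
#: three drain into irreversible sinks.
CLEARANCE_ROUTES: tuple[str, ...] = (
    "lymphatic",
    "urine",
    "feces",
    "hepatic_metabolism",
)

#: Irreversible mass sinks tracked alongside the main compartments.
ELIMINATION_SINKS: tuple[str, ...] = ("urine", "feces", "hepatic_metabolism")

# Organ masses as fractions of body weight (g/g).  "rest" is the remainder
# after all named tissues and blood, which keeps total tissue mass = bw.
_MASS_FRACTIONS: dict[str, float] = {
    "upper_airways": 0.0010,
    "tracheobronchial": 0.0005,
    "pulmonary": 0.0050,
    "liver": 0.0366,
    "spleen": 0.0020,
    "kidney": 0.0073,
    "heart": 0.0033,
    "brain": 0.0057,
    "gi_tract": 0.0270,
    "lymph_nodes": 0.0012,
    "gi_lumen": 0.0280,  # lumenal contents, not perfused tissue
}
_BLOOD_FRACTION = 0.074  # blood 7.4% of bw
_ARTERIAL_SHARE = 1.0 / 3.0  # arterial : venous split of blood volume

# Regional blood flows as fractions of cardiac output.  "rest" is the
# remainder, which enforces exact flow balance by construction.
_FLOW_FRACTIONS: dict[str, float] = {
    "upper_airways": 0.010,
    "tracheobronchial": 0.005,
    "liver": 0.174,
    "spleen": 0.010,
    "kidney": 0.141,
    "heart": 0.049,
    "brain": 0.020,
    "gi_tract": 0.150,
}
_CARDIAC_OUTPUT_PER_G = 19.92  # mL/h per g bw (≈83 mL/min for a 250 g rat)


@dataclass(frozen=True)
class RatPhysiology:
    """Anatomical and circulatory constants of one rat.

    Attributes
    ----------
    body_weight:
        Body weight in g.
    organ_mass:
        Mass (g) of every main compartment except the two blood pools;
        with unit tissue density this is also the volume in mL.
    blood_volume:
        Total blood volume (mL).
    arterial_volume, venous_volume:
        Partition of the blood volume over the two blood pools (mL).
    blood_flow:
        Regional blood flow (mL/h) for every perfused organ.  Systemic organ
        flows sum to ``cardiac_output``; the pulmonary entry equals the
        cardiac output (series circulation, single lung pass).
    cardiac_output:
        Total cardiac output (mL/h).
    provenance:
        Free-text provenance note per constant.
    """

    body_weight: float
    organ_mass: dict[str, float]
    blood_volume: float
    arterial_volume: float
    venous_volume: float
    blood_flow: dict[str, float]
    cardiac_output: float
    provenance: dict[str, str] = field(default_factory=dict)

    def mass_of(self, compartment: str) -> float:
        """Mass (g) of a main compartment, blood pools included."""
        if compartment == "arterial":
            return self.arterial_volume
        if compartment == "venous":
            return self.venous_volume
        return self.organ_mass[compartment]

    def with_overrides(self, **kwargs) -> "RatPhysiology":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FixedKinetics:
    """Kinetic parameters held fixed during estimation.

    ``chi`` holds the vascular permeability of the organs *not* governed by
    the estimated chi_rich (blood–brain barrier, airway linings, rest);
    entries exist for every perfused organ and the richly perfused ones are
    overridden by the parameter vector at simulation time.  Transport and
    elimination rates are first-order (1/h).  ``pc_capacity`` bounds the
    phagocytizing-cell load per organ in µg; ``None`` means unbounded
    (linear uptake).
    """

    chi: dict[str, float]
    k_hepatic_metab: float = 1e-3
    k_biliary: float = 1e-3
    k_fecal: float = 1e-3
    k_lymph: dict[str, float] = field(default_factory=dict)
    k_lymphnode_to_venous: float = 1e-3
    pc_capacity: dict[str, float | None] = field(default_factory=dict)

    def capacity_of(self, organ: str) -> float:
        cap = self.pc_capacity.get(organ)
        return math.inf if cap is None else cap

    def is_linear(self) -> bool:
        """True when every phagocytic capacity is unbounded (linear model)."""
        return all(self.capacity_of(o) == math.inf for o in PC_ORGANS)

    def with_overrides(self, **kwargs) -> "FixedKinetics":
        return replace(self, **kwargs)


def default_physiology(body_weight: float = 250.0) -> RatPhysiology:
    """Reference adult-rat physiology scaled linearly to ``body_weight`` (g).

    All masses, volumes and flows scale proportionally with body weight
    (documented linear allometric rule); flow balance (systemic flows summing
    to cardiac output) holds by construction because the "rest" flow is
    defined as the remainder.
    """
    if not body_weight > 0:
        raise ValueError(f"body_weight must be positive, got {body_weight!r}")

    organ_mass = {o: f * body_weight for o, f in _MASS_FRACTIONS.items()}
    named = sum(_MASS_FRACTIONS.values()) + _BLOOD_FRACTION
    organ_mass["rest"] = (1.0 - named) * body_weight

    cardiac_output = _CARDIAC_OUTPUT_PER_G * body_weight
    blood_flow = {o: f * cardiac_output for o, f in _FLOW_FRACTIONS.items()}
    blood_flow["rest"] = cardiac_output - sum(blood_flow.values())
    blood_flow["pulmonary"] = cardiac_output

    blood_volume = _BLOOD_FRACTION * body_weight
    provenance = {
        "organ_mass": "Brown et al. 1997 rat reference fractions of bw; "
        "rest = remainder; density 1 g/mL",
        "blood_volume": "Brown et al. 1997: blood 7.4% of bw",
        "blood_flow": "Brown et al. 1997 fractions of cardiac output; "
        "rest = remainder (exact flow balance)",
        "cardiac_output": "≈83 mL/min for a 250 g rat, scaled linearly with bw",
    }
    return RatPhysiology(
        body_weight=body_weight,
        organ_mass=organ_mass,
        blood_volume=blood_volume,
        arterial_volume=_ARTERIAL_SHARE * blood_volume,
        venous_volume=(1.0 - _ARTERIAL_SHARE) * blood_volume,
        blood_flow=blood_flow,
        cardiac_output=cardiac_output,
        provenance=provenance,
    )


def default_fixed_kinetics() -> FixedKinetics:
    """Placeholder defaults for the non-estimated kinetic parameters.

    The source model's fixed rates live in its own reference; their influence
    on the outcome is small, so small first-order defaults (1e-3 1/h) are
    shipped here, every one overridable through the configuration.  The
    blood–brain barrier is encoded as a low fixed permeability for brain.
    Phagocytic capacities default to unbounded (linear uptake).
    """
    chi = {o: 1e-2 for o in ("upper_airways", "tracheobronchial")}
    chi["brain"] = 1e-3  # blood–brain barrier
    chi["rest"] = 1e-1
    for organ in RICHLY_PERFUSED:
        chi[organ] = 1.0  # replaced by the estimated chi_rich at run time
    return FixedKinetics(
        chi=chi,
        k_hepatic_metab=1e-3,
        k_biliary=1e-3,
        k_fecal=1e-3,
        k_lymph={o: 1e-3 for o in PERFUSED_ORGANS},
        k_lymphnode_to_venous=1e-3,
        pc_capacity={o: None for o in PC_ORGANS},
    )


def validate_physiology(phys: RatPhysiology, rel_tol: float = 1e-9) -> list[str]:
    """Check all physiology invariants; return a list of violation messages.

    An empty list means the physiology is internally consistent: strictly
    positive masses/volumes/flows, a mass and a flow entry for every organ in
    the roster, and systemic blood flows summing to the cardiac output within
    ``rel_tol`` relative tolerance.
    """
    violations: list[str] = []
    if not phys.body_weight > 0:
        violations.append(f"body_weight: must be positive, got {phys.body_weight}")
    for name, value in (
        ("blood_volume", phys.blood_volume),
        ("arterial_volume", phys.arterial_volume),
        ("venous_volume", phys.venous_volume),
        ("cardiac_output", phys.cardiac_output),
    ):
        if not value > 0:
            violations.append(f"{name}: must be positive, got {value}")

    for organ in MAIN_COMPARTMENTS:
        if organ in ("arterial", "venous"):
            continue
        if organ not in phys.organ_mass:
            violations.append(f"organ_mass[{organ}]: missing roster entry")
        elif not phys.organ_mass[organ] > 0:
            violations.append(
                f"organ_mass[{organ}]: must be positive, got {phys.organ_mass[organ]}"
            )
    for organ in PERFUSED_ORGANS:
        if organ not in phys.blood_flow:
            violations.append(f"blood_flow[{organ}]: missing roster entry")
        elif not phys.blood_flow[organ] > 0:
            violations.append(
                f"blood_flow[{organ}]: must be positive, got {phys.blood_flow[organ]}"
            )

    systemic = [phys.blood_flow.get(o, 0.0) for o in SYSTEMIC_ORGANS]
    total = sum(systemic)
    if phys.cardiac_output > 0 and not math.isclose(
        total, phys.cardiac_output, rel_tol=rel_tol
    ):
        violations.append(
            "blood_flow: systemic organ flows sum to "
            f"{total:.12g} mL/h, cardiac_output is {phys.cardiac_output:.12g} mL/h"
        )
    return violations
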