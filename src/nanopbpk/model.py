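"""Compartmental ODE model and forward simulation for an IV bolus dose.

The model tracks nanobiomaterial amounts (µg) in 14 main compartments, 8
phagocytizing-cell (PC) sub-compartments and 3 irreversible elimination sinks
(urine, feces, hepatic metabolism); lymphatic clearance accumulates in the
lymph-node main compartment.  Blood↔tissue exchange is permeability-limited
with no explicit capillary state: χ·Q is an effective permeability–flow
product (so χ may exceed 1), and eliminating the capillary concentration at
quasi-steady state gives the extraction fraction E = χ/(1+χ).  An organ with
regional flow Q takes up E·Q·C_in from its inflowing blood, returns
E·Q·C_tissue/P to the downstream pool, and the balance (1−E)·Q·C_in flows
through.  E → χ for small χ and → 1 (flow-limited) for large χ, and
0 ≤ E < 1 keeps every flux sign-correct, so amounts stay non-negative and the
system is dynamically stable over the whole estimation box.  All systemic
organs draw from arterial blood and return to venous; the pulmonary region
receives the entire cardiac output from venous blood and returns to
arterial.

Phagocytic uptake is saturable through a linear-capacity clamp,
k_up = k_base·max(0, 1 − pc/capacity), with k_base = k_sab0 in the spleen and
k_ab0 in the other seven PC organs; with unbounded capacity (the default) the
whole system is linear in the state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .physiology import (
    ELIMINATION_SINKS,
    MAIN_COMPARTMENTS,
    PC_ORGANS,
    PERFUSED_ORGANS,
    RICHLY_PERFUSED,
    SYSTEMIC_ORGANS,
    FixedKinetics,
    RatPhysiology,
)

__all__ = [
    "PARAM_NAMES",
    "OBSERVABLE_ORGANS",
    "ParameterVector",
    "ModelState",
    "SimulationResult",
    "IntegrationError",
    "state_index",
    "n_states",
    "iv_bolus_initial_state",
    "system_matrix",
    "rhs",
    "simulate",
    "observe",
]

#: External labels of the six estimated parameters, in canonical order.
PARAM_NAMES: tuple[str, ...] = (
    "chi_rich",
    "P",
    "k_kidneyEl",
    "k_ab0",
    "k_sab0",
    "k_de",
)

#: Observables measured in the biodistribution studies.  "lung" maps to the
#: pulmonary compartment; "blood" pools arterial and venous amounts.
OBSERVABLE_ORGANS: tuple[str, ...] = (
    "blood",
    "liver",
    "spleen",
    "lung",
    "kidney",
    "heart",
    "brain",
)

_OBSERVABLE_TO_COMPARTMENT: dict[str, str] = {
    "lung": "pulmonary",
    **{o: o for o in MAIN_COMPARTMENTS if o not in ("arterial", "venous")},
}


@dataclass(frozen=True)
class ParameterVector:
    """The six estimated kinetic parameters.

    chi_rich — permeability of richly perfused organs (dimensionless);
    partition — tissue-blood partition coefficient P (dimensionless);
    k_kidney_el — renal elimination rate (1/h);
    k_ab0 — maximum phagocytic uptake rate outside the spleen (1/h);
    k_sab0 — maximum phagocytic uptake rate in the spleen (1/h);
    k_de — phagocytic release rate (1/h).
    """

    chi_rich: float
    partition: float
    k_kidney_el: float
    k_ab0: float
    k_sab0: float
    k_de: float

    def __post_init__(self) -> None:
        for name, value in zip(PARAM_NAMES, self.to_array()):
            if not value > 0:
                raise ValueError(f"parameter {name} must be strictly positive, got {value}")

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.chi_rich,
                self.partition,
                self.k_kidney_el,
                self.k_ab0,
                self.k_sab0,
                self.k_de,
            ]
        )

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ParameterVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (6,):
            raise ValueError(f"expected 6 parameters, got shape {values.shape}")
        return cls(*values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.to_array()))


# --- state vector layout -------------------------------------------------

_MAIN_INDEX = {c: i for i, c in enumerate(MAIN_COMPARTMENTS)}
_PC_INDEX = {o: len(MAIN_COMPARTMENTS) + i for i, o in enumerate(PC_ORGANS)}
_SINK_INDEX = {
    r: len(MAIN_COMPARTMENTS) + len(PC_ORGANS) + i
    for i, r in enumerate(ELIMINATION_SINKS)
}
_N_STATES = len(MAIN_COMPARTMENTS) + len(PC_ORGANS) + len(ELIMINATION_SINKS)


def n_states() -> int:
    """Length of the flat state vector (14 main + 8 PC + 3 sinks = 25)."""
    return _N_STATES


def state_index(kind: str, name: str) -> int:
    """Index of a state entry: kind ∈ {"main", "pc", "sink"}."""
    table = {"main": _MAIN_INDEX, "pc": _PC_INDEX, "sink": _SINK_INDEX}[kind]
    return table[name]


class ModelState:
    """View over a flat amount vector (µg) with named accessors."""

    __slots__ = ("vector",)

    def __init__(self, vector: np.ndarray):
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (_N_STATES,):
            raise ValueError(f"state vector must have shape ({_N_STATES},)")
        self.vector = vector

    @classmethod
    def zeros(cls) -> "ModelState":
        return cls(np.zeros(_N_STATES))

    def amount(self, compartment: str) -> float:
        return float(self.vector[_MAIN_INDEX[compartment]])

    def pc_amount(self, organ: str) -> float:
        return float(self.vector[_PC_INDEX[organ]])

    def eliminated(self, route: str) -> float:
        return float(self.vector[_SINK_INDEX[route]])

    def total_mass(self) -> float:
        """Total tracked mass including PC pools and elimination sinks."""
        return float(self.vector.sum())

    def validate(self, atol: float = 0.0) -> None:
        if np.any(self.vector < -atol):
            bad = int(np.argmin(self.vector))
            raise ValueError(
                f"negative amount {self.vector[bad]:.3e} µg at state index {bad}"
            )


@dataclass(frozen=True)
class SimulationResult:
    """Forward-simulation output: times (h) and the state at each time."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_states), raw solver output
    dose: float  # administered dose, µg

    def state_at(self, i: int) -> ModelState:
        return ModelState(self.states[i])

    def amounts(self, kind: str, name: str) -> np.ndarray:
        return self.states[:, state_index(kind, name)]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last good time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


def iv_bolus_initial_state(dose_per_bw: float, phys: RatPhysiology) -> ModelState:
    """Initial state for an IV bolus: the whole dose in arterial blood.

    ``dose_per_bw`` is the administered dose per body weight (µg/g bw); the
    absolute dose is dose_per_bw × body_weight.
    """
    if not dose_per_bw > 0:
        raise ValueError(f"dose_per_bw must be positive, got {dose_per_bw!r}")
    state = ModelState.zeros()
    state.vector[_MAIN_INDEX["arterial"]] = dose_per_bw * phys.body_weight
    return state


def _effective_chi(theta: ParameterVector, fixed: FixedKinetics) -> dict[str, float]:
    chi = dict(fixed.chi)
    for organ in RICHLY_PERFUSED:
        chi[organ] = theta.chi_rich
    missing = [o for o in PERFUSED_ORGANS if o not in chi]
    if missing:
        raise ValueError(f"fixed kinetics missing chi entries for {missing}")
    return chi


def _base_uptake(theta: ParameterVector, organ: str) -> float:
    return theta.k_sab0 if organ == "spleen" else theta.k_ab0


def system_matrix(
    theta: ParameterVector, phys: RatPhysiology, fixed: FixedKinetics
) -> np.ndarray:
    """Rate matrix A with dx/dt = A·x for the capacity-unclamped system.

    Every column sums to zero (the sinks are part of the state), so total
    mass is conserved exactly.  When all phagocytic capacities are unbounded
    this matrix *is* the full model; otherwise the uptake entries are scaled
    by the saturation factor inside :func:`rhs`.
    """
    A = np.zeros((_N_STATES, _N_STATES))
    chi = _effective_chi(theta, fixed)
    P = theta.partition
    i_art = _MAIN_INDEX["arterial"]
    i_ven = _MAIN_INDEX["venous"]
    v_art = phys.arterial_volume
    v_ven = phys.venous_volume

    # systemic organs: arterial -> tissue/venous, tissue -> venous
    for organ in SYSTEMIC_ORGANS:
        i = _MAIN_INDEX[organ]
        q = phys.blood_flow[organ]
        e = chi[organ] / (1.0 + chi[organ])  # quasi-steady extraction
        A[i_art, i_art] -= q / v_art
        A[i, i_art] += e * q / v_art
        A[i_ven, i_art] += (1.0 - e) * q / v_art
        back = e * q / (P * phys.organ_mass[organ])
        A[i, i] -= back
        A[i_ven, i] += back

    # pulmonary region: venous -> tissue/arterial, tissue -> arterial
    i_pul = _MAIN_INDEX["pulmonary"]
    q = phys.cardiac_output
    e = chi["pulmonary"] / (1.0 + chi["pulmonary"])
    A[i_ven, i_ven] -= q / v_ven
    A[i_pul, i_ven] += e * q / v_ven
    A[i_art, i_ven] += (1.0 - e) * q / v_ven
    back = e * q / (P * phys.organ_mass["pulmonary"])
    A[i_pul, i_pul] -= back
    A[i_art, i_pul] += back

    # phagocytizing-cell exchange (unclamped maximum uptake rates)
    for organ in PC_ORGANS:
        i = _MAIN_INDEX[organ]
        j = _PC_INDEX[organ]
        k_up = _base_uptake(theta, organ)
        A[i, i] -= k_up
        A[j, i] += k_up
        A[j, j] -= theta.k_de
        A[i, j] += theta.k_de

    # clearance routes
    i_kid = _MAIN_INDEX["kidney"]
    A[i_kid, i_kid] -= theta.k_kidney_el
    A[_SINK_INDEX["urine"], i_kid] += theta.k_kidney_el

    i_liv = _MAIN_INDEX["liver"]
    A[i_liv, i_liv] -= fixed.k_hepatic_metab + fixed.k_biliary
    A[_SINK_INDEX["hepatic_metabolism"], i_liv] += fixed.k_hepatic_metab
    A[_MAIN_INDEX["gi_lumen"], i_liv] += fixed.k_biliary

    i_lum = _MAIN_INDEX["gi_lumen"]
    A[i_lum, i_lum] -= fixed.k_fecal
    A[_SINK_INDEX["feces"], i_lum] += fixed.k_fecal

    i_ln = _MAIN_INDEX["lymph_nodes"]
    for organ, k in fixed.k_lymph.items():
        if k == 0.0:
            continue
        i = _MAIN_INDEX[organ]
        A[i, i] -= k
        A[i_ln, i] += k
    A[i_ln, i_ln] -= fixed.k_lymphnode_to_venous
    A[i_ven, i_ln] += fixed.k_lymphnode_to_venous

    return A


def rhs(
    state: ModelState | np.ndarray,
    theta: ParameterVector,
    phys: RatPhysiology,
    fixed: FixedKinetics,
) -> np.ndarray:
    """Time derivative of the state vector (µg/h).

    Equals ``system_matrix(...) @ x`` except that each organ's phagocytic
    uptake is scaled by the saturation factor max(0, 1 − pc/capacity).
    """
    x = state.vector if isinstance(state, ModelState) else np.asarray(state, float)
    ModelState(x).validate()
    A = system_matrix(theta, phys, fixed)
    return _clamped_derivative(x, A, theta, fixed)


def _clamped_derivative(
    x: np.ndarray, A: np.ndarray, theta: ParameterVector, fixed: FixedKinetics
) -> np.ndarray:
    dx = A @ x
    if not fixed.is_linear():
        for organ in PC_ORGANS:
            cap = fixed.capacity_of(organ)
            if cap == np.inf:
                continue
            i = _MAIN_INDEX[organ]
            j = _PC_INDEX[organ]
            k_up = _base_uptake(theta, organ)
            factor = max(0.0, 1.0 - x[j] / cap)
            correction = k_up * (factor - 1.0) * x[i]
            dx[i] -= correction
            dx[j] += correction
    return dx


def simulate(
    theta: ParameterVector,
    phys: RatPhysiology,
    fixed: FixedKinetics,
    dose_per_bw: float,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    mass_balance_rtol: float = 1e-6,
    negative_tol_fraction: float = 1e-9,
) -> SimulationResult:
    """Integrate the model from an IV bolus and return states at ``times``.

    Uses a stiff-capable solver (LSODA by default, with the analytic Jacobian
    when the system is linear).  Total mass is checked against the dose at
    every output time to ``mass_balance_rtol`` relative tolerance.  The
    continuous system keeps all amounts non-negative; solver undershoots
    smaller than ``negative_tol_fraction``·dose are tolerated in the raw
    states (and floored to zero by :func:`observe`), anything larger raises
    :class:`IntegrationError`.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")

    x0 = iv_bolus_initial_state(dose_per_bw, phys).vector
    dose = float(x0.sum())
    A = system_matrix(theta, phys, fixed)
    linear = fixed.is_linear()

    if linear:
        def f(_t: float, x: np.ndarray) -> np.ndarray:
            return A @ x

        jac = lambda _t, _x: A  # noqa: E731 - constant Jacobian
    else:
        def f(_t: float, x: np.ndarray) -> np.ndarray:
            return _clamped_derivative(x, A, theta, fixed)

        jac = None

    t_eval = t
    prepend_zero = t[0] > 0.0
    if prepend_zero:
        t_eval = np.concatenate(([0.0], t))

    sol = solve_ivp(
        f,
        (0.0, float(t[-1])) if t[-1] > 0 else (0.0, 0.0),
        x0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac=jac,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"ODE solver failed: {sol.message}", last_time=last)

    states = sol.y.T
    if prepend_zero:
        states = states[1:]

    neg_tol = negative_tol_fraction * dose
    worst = float(states.min(initial=0.0))
    if worst < -neg_tol:
        bad = np.flatnonzero(states.min(axis=1) < -neg_tol)
        when = float(t[bad[0]])
        raise IntegrationError(
            f"state went negative beyond tolerance ({worst:.3e} µg) at t={when} h",
            last_time=when,
        )

    totals = states.sum(axis=1)
    err = np.abs(totals - dose) / dose
    if np.any(err > mass_balance_rtol):
        i = int(np.argmax(err))
        raise IntegrationError(
            f"mass balance violated: relative error {err[i]:.3e} at t={t[i]} h",
            last_time=float(t[i]),
        )

    return SimulationResult(times=t, states=states, dose=dose)


def observe(
    result: SimulationResult, organ_or_blood: str, phys: RatPhysiology
) -> np.ndarray:
    """Concentration trajectory (µg/g) of an observable.

    "blood" pools arterial and venous amounts over the blood volume; an organ
    observable pools tissue and phagocytizing-cell amounts over the organ
    mass; "lung" maps to the pulmonary compartment.  Tiny negative solver
    excursions are floored to zero.
    """
    name = organ_or_blood.lower()
    if name == "blood":
        amt = result.amounts("main", "arterial") + result.amounts("main", "venous")
        conc = amt / phys.blood_volume
    else:
        compartment = _OBSERVABLE_TO_COMPARTMENT.get(name)
        if compartment is None:
            raise ValueError(
                f"unknown observable {organ_or_blood!r}; expected 'blood' or one of "
                f"{sorted(_OBSERVABLE_TO_COMPARTMENT)}"
            )
        amt = result.amounts("main", compartment)
        if compartment in PC_ORGANS:
            amt = amt + result.amounts("pc", compartment)
        conc = amt / phys.organ_mass[compartment]
    return np.maximum(conc, 0.0)


def observables_frame(
    result: SimulationResult,
    phys: RatPhysiology,
    organs: Iterable[str] = OBSERVABLE_ORGANS,
):
    """Tidy table of trajectories: columns time_h, observable, value_ug_per_g."""
    import pandas as pd

    rows = []
    for organ in organs:
        conc = observe(result, organ, phys)
        rows.append(
            pd.DataFrame(
                {"time_h": result.times, "observable": organ, "value_ug_per_g": conc}
            )
        )
    return pd.concat(rows, ignore_index=True)
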