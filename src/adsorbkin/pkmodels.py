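"""Compartmental structural models with a device-adsorption pathway.

Two structural models cover the study drugs: a one-compartment model with
first-order absorption (optionally lagged) for the orally dosed
immunosuppressants, parameterized in apparent terms (CL/F, V/F) because
bioavailability in sheep is unknown, and a two-compartment IV model for
methylprednisolone. Either can be combined with an extracorporeal
adsorption pathway drawing on the central compartment while the circuit
session is active:

* constant extraction:  CL_dev(t) = blood_flow · k_constant
* saturable (linear-decrease) extraction:
  CL_dev(t) = CL_max · (1 − A_dev(t) / A_max)

where A_dev(t) is the drug amount already bound to the cartridge and
A_max its maximum capacity. The saturable form makes device clearance
decay linearly in the adsorbed amount, reaching zero at saturation.

During simulation the instantaneous device clearance is capped at the
plasma flow FL = blood_flow × (1 − hematocrit): a flow-limited device
cannot clear more plasma than passes through it. Estimation leaves the
parameter itself unconstrained.

Trajectories are solved piecewise with a stiff-capable integrator
(LSODA, rtol 1e-8 / atol 1e-10 mg), restarting at every dose entry and
session boundary. Absorption lag is implemented by event-time shifting:
an oral dose enters the depot at ``time + ALAG`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .datasets import CircuitConfig, DoseEvent, Route

__all__ = [
    "OneCompartmentOralParams",
    "TwoCompartmentIVParams",
    "AdsorptionConstantParams",
    "AdsorptionSaturableParams",
    "Profile",
    "constant_device_clearance",
    "saturable_device_clearance",
    "outlet_concentration",
    "solve_profile",
    "cumulative_adsorbed",
]

# state vector indices
_DEPOT, _CENTRAL, _PERIPH, _ADSORBED, _ELIM = range(5)


@dataclass(frozen=True)
class OneCompartmentOralParams:
    """One-compartment disposition with first-order (lagged) absorption.

    Apparent parameterization: CL_F = CL/F (L/h), V_F = V/F (L),
    KA in 1/h, ALAG in h. For IV bolus dosing into this model KA and
    ALAG are ignored (the dose enters the central compartment directly).
    """

    CL_F: float
    V_F: float
    KA: float = 0.5
    ALAG: float = 0.0

    def __post_init__(self) -> None:
        if self.CL_F <= 0 or self.V_F <= 0 or self.KA <= 0:
            raise ValueError("CL_F, V_F and KA must be > 0")
        if self.ALAG < 0:
            raise ValueError("ALAG must be >= 0")

    @property
    def ke(self) -> float:
        return self.CL_F / self.V_F


@dataclass(frozen=True)
class TwoCompartmentIVParams:
    """Two-compartment IV disposition (CL, V1, V2, Q; clearance terms).

    Internally the micro-constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2
    drive the ODE; reporting stays in clearance/volume terms.
    """

    CL: float
    V1: float
    V2: float
    Q: float

    def __post_init__(self) -> None:
        if min(self.CL, self.V1, self.V2, self.Q) <= 0:
            raise ValueError("CL, V1, V2 and Q must all be > 0")

    @property
    def k10(self) -> float:
        return self.CL / self.V1

    @property
    def k12(self) -> float:
        return self.Q / self.V1

    @property
    def k21(self) -> float:
        return self.Q / self.V2


@dataclass(frozen=True)
class AdsorptionConstantParams:
    """Constant-extraction device model: CL_dev = flow · k_constant.

    ``flow_basis`` selects whether k multiplies blood flow (default,
    the formula as written) or plasma flow.
    """

    k_constant: float
    flow_basis: str = "blood"

    def __post_init__(self) -> None:
        if not 0.0 <= self.k_constant <= 1.0:
            raise ValueError("k_constant must be in [0, 1]")
        if self.flow_basis not in ("blood", "plasma"):
            raise ValueError("flow_basis must be 'blood' or 'plasma'")


@dataclass(frozen=True)
class AdsorptionSaturableParams:
    """Saturable device model: CL_dev = CL_max · (1 − A_dev/A_max)."""

    CL_max: float
    A_max: float

    def __post_init__(self) -> None:
        if self.CL_max <= 0 or self.A_max <= 0:
            raise ValueError("CL_max and A_max must be > 0")


Adsorption = AdsorptionConstantParams | AdsorptionSaturableParams | None
Structural = OneCompartmentOralParams | TwoCompartmentIVParams


def constant_device_clearance(
    circuit: CircuitConfig, params: AdsorptionConstantParams
) -> float:
    """Time-invariant device clearance in L/h (Eq. flow × k_constant)."""
    if params.flow_basis == "plasma":
        return circuit.plasma_flow_l_h * params.k_constant
    return circuit.blood_flow_l_h * params.k_constant


def saturable_device_clearance(
    adsorbed: float, params: AdsorptionSaturableParams
) -> float:
    """Device clearance (L/h) at a given adsorbed amount (mg).

    Linear in the adsorbed amount; CL_max at an empty cartridge, zero at
    saturation. ``adsorbed > A_max`` signals state corruption.
    """
    if adsorbed < 0 or adsorbed > params.A_max * (1 + 1e-9):
        raise ValueError(
            f"adsorbed amount {adsorbed} mg outside [0, A_max={params.A_max}]"
        )
    return params.CL_max * max(0.0, 1.0 - adsorbed / params.A_max)


def outlet_concentration(
    inlet_conc: float, device_CL: float, plasma_flow: float
) -> float:
    """Post-cartridge concentration given inlet concentration and device CL.

    Inverts CL = ((Ci − Co)/Ci) · FL, so the paired-sample clearance
    computed from (Ci, Co) recovers ``device_CL`` exactly. Units of
    ``device_CL`` and ``plasma_flow`` must match.
    """
    if plasma_flow <= 0:
        raise ValueError("plasma_flow must be > 0")
    if not 0.0 <= device_CL <= plasma_flow * (1 + 1e-12):
        raise ValueError(
            f"device clearance {device_CL} outside [0, plasma flow {plasma_flow}]"
            " — extraction ratio cannot exceed 1"
        )
    return inlet_conc * (1.0 - device_CL / plasma_flow)


@dataclass
class Profile:
    """A solved trajectory: compartment amounts and port concentrations.

    Arrays are aligned with ``times`` (h). ``conc_outlet`` is NaN outside
    the circuit session (no outlet exists then). Amount columns (mg):
    depot, central, peripheral, adsorbed (the running cartridge load) and
    eliminated (systemically cleared), so that their sum equals the total
    amount dosed so far (mass balance, to solver tolerance).
    """

    times: np.ndarray
    A_depot: np.ndarray
    A_central: np.ndarray
    A_peripheral: np.ndarray
    A_adsorbed: np.ndarray
    A_eliminated: np.ndarray
    conc_systemic: np.ndarray
    conc_inlet: np.ndarray
    conc_outlet: np.ndarray
    dosed_in: np.ndarray  # cumulative amount delivered up to each time

    def mass_balance_error(self) -> np.ndarray:
        """Relative mass-balance defect at every output time."""
        total = (
            self.A_depot
            + self.A_central
            + self.A_peripheral
            + self.A_adsorbed
            + self.A_eliminated
        )
        scale = np.maximum(self.dosed_in, 1e-12)
        return np.abs(total - self.dosed_in) / scale


def _effective_dose_events(
    structural: Structural, doses: Sequence[DoseEvent]
) -> list[tuple[float, float, str]]:
    """(effective time, amount, target) with oral lag applied by time shift."""
    out = []
    lag = structural.ALAG if isinstance(structural, OneCompartmentOralParams) else 0.0
    for d in doses:
        if d.route is Route.oral:
            if not isinstance(structural, OneCompartmentOralParams):
                raise ValueError("oral dosing requires the oral structural model")
            out.append((d.time + lag, d.amount, "depot"))
        else:
            out.append((d.time, d.amount, "central"))
    out.sort(key=lambda e: e[0])
    return out


def _device_clearance_l_h(
    adsorption: Adsorption, circuit: CircuitConfig, adsorbed: float
) -> float:
    if adsorption is None:
        return 0.0
    if isinstance(adsorption, AdsorptionConstantParams):
        cl = constant_device_clearance(circuit, adsorption)
    else:
        cl = adsorption.CL_max * max(0.0, 1.0 - adsorbed / adsorption.A_max)
    # a flow-limited device cannot clear more plasma than flows through it
    return min(cl, circuit.plasma_flow_l_h)


def solve_profile(
    structural: Structural,
    adsorption: Adsorption,
    doses: Sequence[DoseEvent],
    circuit: CircuitConfig,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Profile:
    """Solve the full trajectory at the requested output times (h).

    The device pathway is active only within the session window and only
    if ``circuit.device_present``. Integration restarts at every dose
    entry and session boundary; between restarts LSODA integrates the
    five-state system (depot, central, peripheral, adsorbed, eliminated).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0):
        raise ValueError("output times must be a sorted 1-D sequence")
    if not doses:
        raise ValueError("at least one dose event is required")

    one_cpt = isinstance(structural, OneCompartmentOralParams)
    V = structural.V_F if one_cpt else structural.V1
    events = _effective_dose_events(structural, doses)

    device_on = circuit.device_present and adsorption is not None
    s0, s1 = circuit.session_start, circuit.session_end
    FL = circuit.plasma_flow_l_h

    def rhs(t: float, y: np.ndarray, active: bool) -> np.ndarray:
        dy = np.zeros(5)
        conc = y[_CENTRAL] / V
        cl_dev = (
            _device_clearance_l_h(adsorption, circuit, y[_ADSORBED])
            if active
            else 0.0
        )
        if one_cpt:
            absorbed = structural.KA * y[_DEPOT]
            dy[_DEPOT] = -absorbed
            dy[_CENTRAL] = absorbed - structural.CL_F * conc - cl_dev * conc
            dy[_ELIM] = structural.CL_F * conc
        else:
            dy[_CENTRAL] = (
                -structural.CL * conc
                - structural.k12 * y[_CENTRAL]
                + structural.k21 * y[_PERIPH]
                - cl_dev * conc
            )
            dy[_PERIPH] = structural.k12 * y[_CENTRAL] - structural.k21 * y[_PERIPH]
            dy[_ELIM] = structural.CL * conc
        dy[_ADSORBED] = cl_dev * conc
        return dy

    # breakpoints: dose entries and session boundaries
    t_first = min(events[0][0], times[0] if times.size else events[0][0])
    breaks = {e[0] for e in events}
    if device_on:
        breaks.update((s0, s1))
    t_end = max(times.max() if times.size else t_first, max(breaks))
    breaks = sorted(b for b in breaks if t_first <= b <= t_end)
    grid = sorted(set(breaks) | {t_first, t_end})

    y = np.zeros(5)
    out = np.zeros((5, times.size))
    dosed = np.zeros(times.size)
    delivered = 0.0

    # output times before any integration start
    pre = times < t_first
    # (states are zero there)

    ev_idx = 0
    for seg_start, seg_end in zip(grid[:-1], grid[1:]):
        # apply dose entries at seg_start
        while ev_idx < len(events) and events[ev_idx][0] <= seg_start + 1e-12:
            _, amt, target = events[ev_idx]
            y[_DEPOT if target == "depot" else _CENTRAL] += amt
            delivered += amt
            ev_idx += 1
        active = device_on and (s0 - 1e-12 <= seg_start < s1 - 1e-12)
        sel = (times >= seg_start - 1e-12) & (times <= seg_end + 1e-12) & ~pre
        t_eval = times[sel]
        if seg_end > seg_start:
            sol = solve_ivp(
                rhs,
                (seg_start, seg_end),
                y,
                method="LSODA",
                rtol=rtol,
                atol=atol,
                dense_output=True,
                args=(active,),
            )
            if not sol.success:
                raise RuntimeError(
                    f"ODE solver failed in [{seg_start}, {seg_end}] h: {sol.message}"
                )
            if t_eval.size:
                out[:, sel] = sol.sol(t_eval)
                dosed[sel] = delivered
            y = sol.y[:, -1]
        elif t_eval.size:
            out[:, sel] = y[:, None]
            dosed[sel] = delivered

    # trailing doses exactly at t_end (delivered but not integrated over)
    while ev_idx < len(events) and events[ev_idx][0] <= t_end + 1e-12:
        _, amt, target = events[ev_idx]
        y[_DEPOT if target == "depot" else _CENTRAL] += amt
        delivered += amt
        at_end = np.isclose(times, t_end)
        out[:, at_end] = y[:, None]
        dosed[at_end] = delivered
        ev_idx += 1

    out[:, pre] = 0.0
    dosed[pre] = 0.0
    # numerical noise can leave tiny negatives / capacity overshoot
    out = np.where(np.abs(out) < 1e-15, 0.0, out)
    if isinstance(adsorption, AdsorptionSaturableParams):
        out[_ADSORBED] = np.minimum(out[_ADSORBED], adsorption.A_max)

    conc = out[_CENTRAL] / V
    in_session = (times >= s0 - 1e-12) & (times <= s1 + 1e-12)
    conc_outlet = np.full(times.size, np.nan)
    if np.any(in_session):
        cl_dev_at = np.array(
            [
                _device_clearance_l_h(adsorption, circuit, a) if device_on else 0.0
                for a in out[_ADSORBED, in_session]
            ]
        )
        conc_outlet[in_session] = conc[in_session] * (1.0 - cl_dev_at / FL)

    return Profile(
        times=times,
        A_depot=out[_DEPOT],
        A_central=out[_CENTRAL],
        A_peripheral=out[_PERIPH],
        A_adsorbed=out[_ADSORBED],
        A_eliminated=out[_ELIM],
        conc_systemic=conc,
        conc_inlet=conc.copy(),
        conc_outlet=conc_outlet,
        dosed_in=dosed,
    )


def cumulative_adsorbed(profile: Profile) -> float:
    """Total amount (mg) bound to the cartridge at the end of the profile."""
    return float(profile.A_adsorbed[-1])
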