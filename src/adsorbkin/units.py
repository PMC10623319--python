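"""Unit conventions and conversions.

The package works in a single coherent internal unit system:

* amounts in mg
* volumes in L
* time in hours
* concentrations in mg/L
* clearances and flows in L/h

Drug-native concentration units (ng/mL for tacrolimus and everolimus
whole-blood levels, µg/L, ...) are handled only at I/O boundaries.
Circuit flows are conventionally quoted in mL/min (the pump setting) and
converted on entry.
"""

from __future__ import annotations

#: multiply a flow in mL/min by this to obtain L/h (120 mL/min ≡ 7.2 L/h)
ML_PER_MIN_TO_L_PER_H = 0.06

#: conversion factors: 1 <unit> = <factor> mg/L
_CONC_TO_MG_PER_L = {
    "mg/L": 1.0,
    "mg/l": 1.0,
    "ug/mL": 1.0,
    "µg/mL": 1.0,
    "g/L": 1000.0,
    "ug/L": 1e-3,
    "µg/L": 1e-3,
    "ng/mL": 1e-3,
    "ng/L": 1e-6,
    "pg/mL": 1e-6,
}


def flow_l_per_h(flow_ml_per_min: float) -> float:
    """Convert a circuit flow from mL/min to L/h."""
    return flow_ml_per_min * ML_PER_MIN_TO_L_PER_H


def plasma_flow(blood_flow: float, hematocrit: float) -> float:
    """Plasma (serum) flow through the device: blood flow × (1 − hematocrit).

    Units follow the input flow (mL/min in, mL/min out).
    """
    if not 0.0 < hematocrit < 1.0:
        raise ValueError(f"hematocrit must be in (0, 1), got {hematocrit}")
    return blood_flow * (1.0 - hematocrit)


def concentration_to_mg_per_l(value: float, unit: str) -> float:
    """Convert a concentration from ``unit`` to the internal mg/L."""
    try:
        return value * _CONC_TO_MG_PER_L[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; "
            f"known: {sorted(_CONC_TO_MG_PER_L)}"
        ) from None


def concentration_from_mg_per_l(value: float, unit: str) -> float:
    """Convert a concentration from internal mg/L back to ``unit``."""
    try:
        return value / _CONC_TO_MG_PER_L[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; "
            f"known: {sorted(_CONC_TO_MG_PER_L)}"
        ) from None
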