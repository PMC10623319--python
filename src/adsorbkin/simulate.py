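"""Synthetic-study generator mirroring the sheep hemoperfusion design.

The generator draws individual structural parameters from log-normal
inter-individual distributions around population typical values,
simulates each animal's full trajectory (7-day oral run-in, then the 6-h
circuit session), samples the circuit ports at the design times and
perturbs the true concentrations with port-specific residual error
(proportional for the oral drugs; combined proportional + additive for
methylprednisolone).

``default_population`` supplies per-drug generating models. The device
sub-model truths (A_max, CL_max) and absorption lag times are the
published sheep estimates; systemic disposition typical values are
synthetic conventions chosen so that steady-state troughs land inside
the therapeutic target bands of the study protocol — they are NOT
reported estimates.

Random-number streams: one master seed spawns one substream per subject
(plus one for residual error per subject), so enlarging a study never
perturbs existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import (
    COLUMNS,
    Drug,
    PKDataset,
    Port,
    Route,
    StudyDesign,
)
from .pkmodels import (
    AdsorptionConstantParams,
    AdsorptionSaturableParams,
    OneCompartmentOralParams,
    TwoCompartmentIVParams,
    solve_profile,
)

__all__ = [
    "RandomEffectsSpec",
    "PopulationModelSpec",
    "sample_individual",
    "apply_residual_error",
    "simulate_study",
    "default_population",
    "ADSORPTION_TRUTHS",
    "LAG_TRUTHS",
]


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Inter-individual and residual variability structure.

    ``omega`` maps structural parameter names to the SD of their
    log-normal inter-individual deviation. Residual error is proportional
    with separate CVs before (plasma side: systemic and inlet samples)
    and after the cartridge, plus an additive SD (mg/L) for the combined
    model (methylprednisolone; 0 otherwise).
    """

    omega: Mapping[str, float] = field(default_factory=dict)
    sigma_prop_pre: float = 0.20
    sigma_prop_post: float = 0.20
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.omega.values()):
            raise ValueError("omega SDs must be >= 0")
        if min(self.sigma_prop_pre, self.sigma_prop_post, self.sigma_add) < 0:
            raise ValueError("residual components must be >= 0")


@dataclass(frozen=True)
class PopulationModelSpec:
    """A fully specified population model for one drug.

    ``structural`` holds the typical-value parameter set;
    ``adsorption`` the device sub-model (or None); ``estimated_flags``
    marks which parameters an estimation run should estimate rather than
    fix (parameters absent from the map follow the estimator defaults).
    """

    drug: Drug
    structural: OneCompartmentOralParams | TwoCompartmentIVParams
    adsorption: AdsorptionConstantParams | AdsorptionSaturableParams | None
    random_effects: RandomEffectsSpec
    estimated_flags: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = {
            f
            for f in (
                "CL_F V_F KA ALAG"
                if isinstance(self.structural, OneCompartmentOralParams)
                else "CL V1 V2 Q"
            ).split()
        }
        for name in self.random_effects.omega:
            if name not in valid:
                raise ValueError(
                    f"IIV on {name!r} but the structural model has no such "
                    f"parameter (valid: {sorted(valid)})"
                )

    @property
    def structural_kind(self) -> str:
        return (
            "one_cpt"
            if isinstance(self.structural, OneCompartmentOralParams)
            else "two_cpt_iv"
        )


def sample_individual(
    pop: PopulationModelSpec, seed: int | np.random.Generator
):
    """Draw one individual parameter set: param_i = typical · exp(eta_i).

    Returns ``(params, etas)`` where ``etas`` maps parameter name to the
    drawn normal deviate. Reproducible under a fixed seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    etas = {
        name: float(rng.normal(0.0, sd)) if sd > 0 else 0.0
        for name, sd in pop.random_effects.omega.items()
    }
    updates = {
        name: getattr(pop.structural, name) * np.exp(eta)
        for name, eta in etas.items()
    }
    return replace(pop.structural, **updates), etas


def apply_residual_error(
    true_conc: float | np.ndarray,
    port: Port,
    spec: RandomEffectsSpec,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Observed = true·(1 + ε_prop) + ε_add with the port-specific CV.

    Pre-cartridge ports (systemic, inlet) use ``sigma_prop_pre``; the
    outlet uses ``sigma_prop_post``. Negative draws are floored at 0.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    true_conc = np.asarray(true_conc, float)
    cv = (
        spec.sigma_prop_post if port is Port.outlet else spec.sigma_prop_pre
    )
    eps_p = rng.normal(0.0, cv, size=true_conc.shape) if cv > 0 else 0.0
    eps_a = (
        rng.normal(0.0, spec.sigma_add, size=true_conc.shape)
        if spec.sigma_add > 0
        else 0.0
    )
    return np.maximum(0.0, true_conc * (1.0 + eps_p) + eps_a)


def _simulate_subject(
    subject_id: int,
    design: StudyDesign,
    pop: PopulationModelSpec,
    device: bool,
    rng: np.random.Generator,
    noise: bool = True,
) -> list[dict]:
    """Rows (dose + observation) for one subject."""
    params, _etas = sample_individual(pop, rng)
    circuit = replace(design.circuit, device_present=device)
    if device:
        port_times = design.observation_times
    else:
        port_times = {Port.systemic: tuple(
            design.circuit.session_start + t for t in design.control_sampling_times
        )}
    all_times = sorted({t for ts in port_times.values() for t in ts})
    profile = solve_profile(
        params,
        pop.adsorption if device else None,
        design.dose_events,
        circuit,
        all_times,
    )
    t_index = {round(t, 12): i for i, t in enumerate(all_times)}
    rows = [
        {
            "ID": subject_id,
            "TIME": d.time,
            "AMT": d.amount,
            "DV": np.nan,
            "EVID": 1,
            "PORT": Port.systemic.value,
            "DRUG": d.drug.value,
        }
        for d in design.dose_events
    ]
    for port, times in port_times.items():
        for t in times:
            i = t_index[round(t, 12)]
            if port is Port.outlet:
                true = profile.conc_outlet[i]
            else:
                true = profile.conc_systemic[i]
            obs = (
                float(apply_residual_error(true, port, pop.random_effects, rng))
                if noise
                else max(0.0, float(true))
            )
            rows.append(
                {
                    "ID": subject_id,
                    "TIME": t,
                    "AMT": np.nan,
                    "DV": obs,
                    "EVID": 0,
                    "PORT": port.value,
                    "DRUG": design.drug.value,
                }
            )
    return rows


def simulate_study(
    design: StudyDesign,
    pop: PopulationModelSpec,
    seed: int,
    noise: bool = True,
) -> PKDataset:
    """Simulate one full study arm pair under the generating model.

    Intervention subjects (ids 1..n_intervention) carry the device and
    get paired inlet/outlet observations during the session; control
    subjects (following ids) run the sham circuit, sampled at the same
    clock times from a single circuit port treated as systemic.
    ``noise=False`` skips residual error while keeping the IIV draws
    (set all omegas to 0 in the spec for fully deterministic output).
    """
    if design.drug is not pop.drug:
        raise ValueError(
            f"design is for {design.drug}, population model for {pop.drug}"
        )
    oral_doses = any(d.route is Route.oral for d in design.dose_events)
    if oral_doses and pop.structural_kind != "one_cpt":
        raise ValueError("oral dosing requires the one-compartment model")
    master = np.random.SeedSequence(seed)
    n_total = design.n_intervention + design.n_control
    streams = master.spawn(n_total)
    rows: list[dict] = []
    for i in range(n_total):
        device = i < design.n_intervention
        rng = np.random.default_rng(streams[i])
        rows.extend(
            _simulate_subject(i + 1, design, pop, device, rng, noise=noise)
        )
    records = pd.DataFrame(rows, columns=COLUMNS)
    return PKDataset(records=records, design=design)


# --------------------------------------------------------------------------
# Default generating models
# --------------------------------------------------------------------------

#: published sheep device-submodel estimates used as generating truths:
#: drug -> (A_max mg, CL_max L/h)
ADSORPTION_TRUTHS = {
    Drug.TAC: (0.040, 4.02),
    Drug.CYA: (1.15, 2.80),
    Drug.MMF: (4.17, 3.71),
    Drug.EVER: (0.0163, 3.23),
    Drug.MP: (53.4, 8.21),
}

#: absorption lag times (h) reported for the oral drugs
LAG_TRUTHS = {Drug.TAC: 15.3, Drug.MMF: 4.7, Drug.EVER: 4.1, Drug.PRED: 0.0}

#: synthetic systemic disposition conventions (apparent, sheep oral dosing),
#: chosen so steady-state troughs sit inside the protocol target bands;
#: drug -> dict of structural typical values
SYNTHETIC_DISPOSITION = {
    Drug.TAC: dict(CL_F=115.0, V_F=2500.0, KA=0.5, ALAG=15.3),
    Drug.CYA: dict(CL_F=500.0, V_F=12000.0, KA=0.5, ALAG=0.0),
    Drug.EVER: dict(CL_F=50.0, V_F=1200.0, KA=0.5, ALAG=4.1),
    Drug.MMF: dict(CL_F=40.0, V_F=400.0, KA=0.5, ALAG=4.7),
    Drug.PRED: dict(CL_F=20.0, V_F=100.0, KA=1.0, ALAG=0.0),
    Drug.BAS: dict(CL_F=0.05, V_F=4.0, KA=0.5, ALAG=0.0),  # IV antibody
    Drug.MP: dict(CL=25.0, V1=35.0, V2=40.0, Q=30.0),
}


def default_population(drug: Drug | str) -> PopulationModelSpec:
    """The default generating model for one drug.

    Saturable adsorption truths and lag times are the published sheep
    estimates; disposition typical values are synthetic conventions (see
    module docstring). Basiliximab and prednisolone return no-adsorption
    specs (negligible device clearance).
    """
    drug = Drug(drug)
    disp = SYNTHETIC_DISPOSITION[drug]
    if drug is Drug.MP:
        structural = TwoCompartmentIVParams(**disp)
        re_spec = RandomEffectsSpec(
            omega={"CL": 0.3},
            sigma_prop_pre=0.20,
            sigma_prop_post=0.20,
            sigma_add=0.5,
        )
    else:
        structural = OneCompartmentOralParams(**disp)
        omega = {"CL_F": 0.3}
        if drug is Drug.TAC:
            omega["V_F"] = 0.3
        re_spec = RandomEffectsSpec(
            omega=omega, sigma_prop_pre=0.20, sigma_prop_post=0.20
        )
    if drug in ADSORPTION_TRUTHS:
        a_max, cl_max = ADSORPTION_TRUTHS[drug]
        adsorption = AdsorptionSaturableParams(CL_max=cl_max, A_max=a_max)
    else:
        adsorption = None  # negligible-clearance drugs (BAS, PRED)
    return PopulationModelSpec(
        drug=drug,
        structural=structural,
        adsorption=adsorption,
        random_effects=re_spec,
    )
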