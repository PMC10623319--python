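"""Longitudinal PK records, circuit configuration and study designs.

Datasets use a NONMEM-inspired CSV dialect with columns

``ID, TIME, AMT, DV, EVID, PORT, DRUG``

where ``EVID=1`` marks a dose row (``AMT`` in mg populated) and ``EVID=0``
an observation row (``DV`` populated). ``PORT`` locates the sample in the
extracorporeal circuit: ``SYS`` (systemic / sham circuit), ``IN``
(pre-cartridge inlet) or ``OUT`` (post-cartridge outlet). Missing cells are
written as ``"."``. Concentrations are stored internally in mg/L; native
units (ng/mL etc.) are converted on read via a per-drug unit map.

The builtin study designs reproduce a sheep hemoperfusion experiment:
groups of 5 intervention + 3 control animals on twice-daily oral
immunosuppressants (tacrolimus, cyclosporin A, mycophenolate mofetil,
everolimus), a single-dose antibody group (basiliximab) and an IV
methylprednisolone group, each undergoing a 6-h extracorporeal session at
120 mL/min blood flow with paired inlet/outlet sampling.
"""

from __future__ import annotations

import enum
import io
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import units

__all__ = [
    "Drug",
    "Route",
    "Port",
    "StudyGroup",
    "DoseEvent",
    "ObservationRecord",
    "CircuitConfig",
    "StudyDesign",
    "PKDataset",
    "read_dataset",
    "write_dataset",
    "builtin_design",
    "DatasetFormatError",
    "DatasetValidationError",
]

COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "PORT", "DRUG"]


class DatasetFormatError(ValueError):
    """A file does not conform to the dataset CSV dialect."""


class DatasetValidationError(ValueError):
    """Rows violate the dataset invariants (with the offending row number)."""


class Drug(str, enum.Enum):
    TAC = "TAC"  # tacrolimus
    CYA = "CYA"  # cyclosporin A
    MMF = "MMF"  # mycophenolate mofetil
    EVER = "EVER"  # everolimus
    MP = "MP"  # methylprednisolone
    BAS = "BAS"  # basiliximab
    PRED = "PRED"  # prednisolone


class Route(str, enum.Enum):
    oral = "oral"
    iv_bolus = "iv_bolus"


class Port(str, enum.Enum):
    systemic = "SYS"
    inlet = "IN"
    outlet = "OUT"


class StudyGroup(str, enum.Enum):
    G1_TAC = "G1_TAC"
    G2_CYA = "G2_CYA"
    G3_EVER = "G3_EVER"
    G4_BAS = "G4_BAS"
    G5_MP = "G5_MP"


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: ``amount`` mg given at ``time`` h."""

    time: float
    amount: float
    route: Route
    drug: Drug

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")


@dataclass(frozen=True)
class ObservationRecord:
    """A measured concentration (mg/L) at a circuit port."""

    subject_id: int
    time: float
    port: Port
    concentration: float
    drug: Drug

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(
                f"concentration must be >= 0, got {self.concentration}"
            )


@dataclass(frozen=True)
class CircuitConfig:
    """Extracorporeal circuit settings.

    ``blood_flow`` is the pump setting in mL/min; plasma flow through the
    cartridge is ``blood_flow × (1 − hematocrit)``. The session covers
    ``[session_start, session_start + session_duration]`` hours.
    ``device_present`` distinguishes a hemoperfusion circuit from a sham
    circuit without cartridge.
    """

    blood_flow: float = 120.0
    hematocrit: float = 0.33
    session_start: float = 0.0
    session_duration: float = 6.0
    device_present: bool = True

    def __post_init__(self) -> None:
        if self.blood_flow <= 0:
            raise ValueError("blood_flow must be > 0")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must be in (0, 1)")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be > 0")

    @property
    def session_end(self) -> float:
        return self.session_start + self.session_duration

    @property
    def blood_flow_l_h(self) -> float:
        return units.flow_l_per_h(self.blood_flow)

    @property
    def plasma_flow_l_h(self) -> float:
        """Plasma flow in L/h (internal units)."""
        return units.flow_l_per_h(
            units.plasma_flow(self.blood_flow, self.hematocrit)
        )


@dataclass(frozen=True)
class StudyDesign:
    """One study arm pair: intervention (device) and sham control.

    ``sampling_times`` maps each circuit port to sampling times in hours
    relative to session start, for intervention subjects. Control subjects
    are sampled from the sham circuit at the union of those clock times and
    the samples are treated as systemic (single circuit port).
    """

    group_id: StudyGroup
    drug: Drug
    n_intervention: int
    n_control: int
    dose_events: tuple[DoseEvent, ...]
    sampling_times: Mapping[Port, tuple[float, ...]]
    circuit: CircuitConfig

    def __post_init__(self) -> None:
        if not self.dose_events:
            raise ValueError("a design needs at least one dose event")
        for port, times in self.sampling_times.items():
            if list(times) != sorted(times):
                raise ValueError(f"sampling times for {port} not ascending")
        out = self.sampling_times.get(Port.outlet, ())
        for t in out:
            # sampling times are relative to session start
            if not (0.0 <= t <= self.circuit.session_duration):
                raise ValueError(
                    f"outlet sampling time {t} h outside the circuit session"
                )

    @property
    def control_sampling_times(self) -> tuple[float, ...]:
        """Sham-circuit sampling times (single port, treated as systemic)."""
        all_times: set[float] = set()
        for times in self.sampling_times.values():
            all_times.update(times)
        return tuple(sorted(all_times))

    @property
    def daily_dose(self) -> float:
        """Dosed amount (mg) in the final 24-h window of the schedule."""
        tmax = max(d.time for d in self.dose_events)
        return float(
            sum(d.amount for d in self.dose_events if d.time > tmax - 24.0 + 1e-9)
        )

    @property
    def observation_times(self) -> dict[Port, tuple[float, ...]]:
        """Absolute sampling times (h from study origin) per port."""
        s0 = self.circuit.session_start
        return {
            p: tuple(s0 + t for t in times)
            for p, times in self.sampling_times.items()
        }

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id.value,
            "drug": self.drug.value,
            "n_intervention": self.n_intervention,
            "n_control": self.n_control,
            "dose_events": [
                {
                    "time": d.time,
                    "amount": d.amount,
                    "route": d.route.value,
                    "drug": d.drug.value,
                }
                for d in self.dose_events
            ],
            "sampling_times": {
                p.value: list(t) for p, t in self.sampling_times.items()
            },
            "circuit": {
                "blood_flow": self.circuit.blood_flow,
                "hematocrit": self.circuit.hematocrit,
                "session_start": self.circuit.session_start,
                "session_duration": self.circuit.session_duration,
                "device_present": self.circuit.device_present,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyDesign":
        return cls(
            group_id=StudyGroup(d["group_id"]),
            drug=Drug(d["drug"]),
            n_intervention=int(d["n_intervention"]),
            n_control=int(d["n_control"]),
            dose_events=tuple(
                DoseEvent(
                    time=float(e["time"]),
                    amount=float(e["amount"]),
                    route=Route(e["route"]),
                    drug=Drug(e["drug"]),
                )
                for e in d["dose_events"]
            ),
            sampling_times={
                Port(p): tuple(float(t) for t in times)
                for p, times in d["sampling_times"].items()
            },
            circuit=CircuitConfig(**d["circuit"]),
        )

    def save(self, path: str | Path) -> None:
        """Write the design as JSON (or YAML for .yaml/.yml paths)."""
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StudyDesign":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))


def _canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    """Sort rows by (subject, time, dose-before-observation)."""
    out = df.sort_values(
        ["ID", "TIME", "EVID"], ascending=[True, True, False], kind="mergesort"
    ).reset_index(drop=True)
    return out[COLUMNS]


@dataclass
class PKDataset:
    """Longitudinal dose/observation records for one study arm.

    ``records`` is a canonical-sorted DataFrame in the CSV dialect columns
    with concentrations already in mg/L. ``design`` optionally carries the
    generating study design (kept by the simulator; file round-trips drop
    it unless a design file travels alongside).
    """

    records: pd.DataFrame
    design: StudyDesign | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise DatasetFormatError(f"missing mandatory column(s): {missing}")
        self.records = _canonical_sort(self.records)
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def subject_ids(self) -> list[int]:
        return sorted(self.records["ID"].unique().tolist())

    @property
    def n_subjects(self) -> int:
        return self.records["ID"].nunique()

    def doses(self, subject_id: int | None = None) -> pd.DataFrame:
        df = self.records[self.records["EVID"] == 1]
        if subject_id is not None:
            df = df[df["ID"] == subject_id]
        return df

    def observations(self, subject_id: int | None = None) -> pd.DataFrame:
        df = self.records[self.records["EVID"] == 0]
        if subject_id is not None:
            df = df[df["ID"] == subject_id]
        return df

    def intervention_ids(self) -> list[int]:
        """Subjects with any outlet sample, i.e. the device arm."""
        out = self.records[
            (self.records["EVID"] == 0) & (self.records["PORT"] == Port.outlet.value)
        ]
        return sorted(out["ID"].unique().tolist())

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.records
        for i, row in enumerate(df.itertuples(index=False)):
            has_amt = not pd.isna(row.AMT)
            has_dv = not pd.isna(row.DV)
            if has_amt and has_dv:
                raise DatasetValidationError(
                    f"row {i}: AMT and DV are mutually exclusive"
                )
            if row.EVID == 1:
                if not has_amt:
                    raise DatasetValidationError(f"row {i}: dose row without AMT")
                if row.AMT <= 0:
                    raise DatasetValidationError(
                        f"row {i}: dose amount must be > 0, got {row.AMT}"
                    )
            elif row.EVID == 0:
                if not has_dv:
                    raise DatasetValidationError(
                        f"row {i}: observation row without DV"
                    )
                if row.DV < 0:
                    raise DatasetValidationError(
                        f"row {i}: negative concentration {row.DV}"
                    )
            else:
                raise DatasetValidationError(
                    f"row {i}: EVID must be 0 or 1, got {row.EVID}"
                )
            if row.TIME < 0:
                raise DatasetValidationError(
                    f"row {i}: negative time {row.TIME}"
                )
        for sid in self.subject_ids:
            if (self.doses(sid)).empty:
                raise DatasetValidationError(
                    f"subject {sid} has no dose event"
                )

    def equals(self, other: "PKDataset") -> bool:
        a = self.records.reset_index(drop=True)
        b = other.records.reset_index(drop=True)
        return a.equals(b)


def read_dataset(
    path: str | Path | io.IOBase,
    unit_map: Mapping[Drug | str, str] | None = None,
    design: StudyDesign | None = None,
) -> PKDataset:
    """Read a dataset in the CSV dialect, converting concentrations to mg/L.

    ``unit_map`` maps drug → native concentration unit of the DV column
    (e.g. ``{Drug.TAC: "ng/mL"}``); drugs not listed are assumed mg/L.
    """
    df = pd.read_csv(
        path, na_values=["."], keep_default_na=False, float_precision="round_trip"
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing mandatory column(s): {missing}")
    df = df[COLUMNS].copy()
    for col in ("TIME", "AMT", "DV"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["ID"] = df["ID"].astype(int)
    df["EVID"] = df["EVID"].astype(int)
    if (df["TIME"] != df["TIME"]).any():
        raise DatasetValidationError("TIME must be populated on every row")
    if unit_map:
        umap = {Drug(k).value: v for k, v in unit_map.items()}
        for drug_code, unit in umap.items():
            sel = (df["EVID"] == 0) & (df["DRUG"] == drug_code)
            df.loc[sel, "DV"] = df.loc[sel, "DV"].map(
                lambda v: units.concentration_to_mg_per_l(v, unit)
            )
    return PKDataset(records=df, design=design)


def write_dataset(dataset: PKDataset, path: str | Path) -> None:
    """Write a dataset to the CSV dialect (canonical order, mg/L, '.' = NA).

    The written file round-trips: ``read_dataset(write_dataset(d))`` equals
    ``d`` after canonical sorting.
    """
    df = dataset.records.copy()
    # str(float) round-trips exactly in Python 3
    for col in ("TIME", "AMT", "DV"):
        df[col] = df[col].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Builtin study designs
# --------------------------------------------------------------------------

#: Range-dosed drugs use the range minimum by default (config override via
#: dose_override); amounts in mg per administration.
DEFAULT_DOSE_MG = {
    Drug.TAC: 10.0,  # 2 × 10–12 mg
    Drug.CYA: 600.0,  # 2 × 600–1000 mg
    Drug.MMF: 1000.0,  # 2 × 1 g
    Drug.EVER: 3.0,  # 2 × 3–8.25 mg
    Drug.BAS: 20.0,  # single 20 mg
    Drug.PRED: 10.0,  # 10 mg daily
    Drug.MP: 1500.0,  # 1 × 1.5 g (alternative scenario: 2 × 1 g)
}

#: dosing interval (h) for repeat-dosed drugs
DOSING_INTERVAL_H = {
    Drug.TAC: 12.0,
    Drug.CYA: 12.0,
    Drug.MMF: 12.0,
    Drug.EVER: 12.0,
    Drug.PRED: 24.0,
}

#: oral run-in before the session so it starts near steady state
RUN_IN_DAYS = 7

_GROUP_PRIMARY_DRUG = {
    StudyGroup.G1_TAC: Drug.TAC,
    StudyGroup.G2_CYA: Drug.CYA,
    StudyGroup.G3_EVER: Drug.EVER,
    StudyGroup.G4_BAS: Drug.BAS,
    StudyGroup.G5_MP: Drug.MP,
}

#: circuit sampling times (h from session start) for the oral groups
ORAL_SAMPLING_H = (0.0, 30 / 60, 90 / 60, 250 / 60, 330 / 60)
#: methylprednisolone sampling times (h from first dose = session start)
MP_SAMPLING_H = (10 / 60, 30 / 60, 60 / 60, 90 / 60, 120 / 60, 180 / 60)


def _repeat_oral_doses(drug: Drug, amount: float) -> tuple[DoseEvent, ...]:
    """Run-in doses from the study origin; the last dose falls at session
    start (t = RUN_IN_DAYS × 24 h)."""
    tau = DOSING_INTERVAL_H[drug]
    n = int(RUN_IN_DAYS * 24 / tau) + 1
    times = [i * tau for i in range(n)]
    return tuple(
        DoseEvent(time=t, amount=amount, route=Route.oral, drug=drug)
        for t in times
    )


def builtin_design(
    group_id: StudyGroup | str,
    drug: Drug | str | None = None,
    mp_scenario: str = "single_high",
    dose_override: float | None = None,
) -> StudyDesign:
    """The builtin sheep-study design for one group.

    Oral groups (G1–G3): twice-daily dosing with a 7-day run-in, last dose
    at session start, 6-h circuit session, paired inlet/outlet sampling at
    0, 30, 90, 250 and 330 min. G4: single 20 mg IV antibody dose, no
    control arm. G5: IV methylprednisolone, sampled at 10–180 min;
    ``mp_scenario`` selects ``"single_high"`` (1 × 1.5 g) or ``"split"``
    (2 × 1 g, second dose at 1.5 h).

    ``drug`` selects a co-administered drug of the same group to model
    (e.g. MMF within groups 1–3); defaults to the group's primary drug.
    """
    group = StudyGroup(group_id)
    drug = Drug(drug) if drug is not None else _GROUP_PRIMARY_DRUG[group]
    # oral groups: session begins after the 7-day run-in; the study origin
    # (t = 0) is the first run-in dose so all record times are non-negative
    circuit = CircuitConfig(session_start=RUN_IN_DAYS * 24.0, device_present=True)

    if group in (StudyGroup.G1_TAC, StudyGroup.G2_CYA, StudyGroup.G3_EVER):
        if drug not in (_GROUP_PRIMARY_DRUG[group], Drug.MMF, Drug.PRED):
            raise ValueError(f"{drug} is not administered in {group.value}")
        amount = dose_override or DEFAULT_DOSE_MG[drug]
        doses = _repeat_oral_doses(drug, amount)
        sampling = {Port.inlet: ORAL_SAMPLING_H, Port.outlet: ORAL_SAMPLING_H}
        return StudyDesign(
            group_id=group,
            drug=drug,
            n_intervention=5,
            n_control=3,
            dose_events=doses,
            sampling_times=sampling,
            circuit=circuit,
        )
    circuit = replace(circuit, session_start=0.0)  # single-dose groups
    if group is StudyGroup.G4_BAS:
        amount = dose_override or DEFAULT_DOSE_MG[Drug.BAS]
        doses = (
            DoseEvent(time=0.0, amount=amount, route=Route.iv_bolus, drug=Drug.BAS),
        )
        sampling = {Port.inlet: ORAL_SAMPLING_H, Port.outlet: ORAL_SAMPLING_H}
        return StudyDesign(
            group_id=group,
            drug=Drug.BAS,
            n_intervention=3,
            n_control=0,
            dose_events=doses,
            sampling_times=sampling,
            circuit=circuit,
        )
    if group is StudyGroup.G5_MP:
        if mp_scenario == "single_high":
            doses = (
                DoseEvent(
                    time=0.0,
                    amount=dose_override or 1500.0,
                    route=Route.iv_bolus,
                    drug=Drug.MP,
                ),
            )
        elif mp_scenario == "split":
            amt = dose_override or 1000.0
            doses = (
                DoseEvent(time=0.0, amount=amt, route=Route.iv_bolus, drug=Drug.MP),
                DoseEvent(time=1.5, amount=amt, route=Route.iv_bolus, drug=Drug.MP),
            )
        else:
            raise ValueError(
                f"unknown mp_scenario {mp_scenario!r}; use 'single_high' or 'split'"
            )
        sampling = {Port.inlet: MP_SAMPLING_H, Port.outlet: MP_SAMPLING_H}
        return StudyDesign(
            group_id=group,
            drug=Drug.MP,
            n_intervention=2,
            n_control=2,
            dose_events=doses,
            sampling_times=sampling,
            circuit=circuit,
        )
    raise ValueError(f"unknown group {group_id!r}")
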