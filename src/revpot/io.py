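"""Configuration, serialization and tabular I/O.

Concentrations in config files carry explicit unit suffixes ("199 mM",
"1 uM"); internally everything is mol/L.  Time-course tables are plain CSV
with columns ``experiment_id, voltage_mV, time_s, replicate, cpm``.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import FluxTimeCourse, KineticParams, VesiclePopulation
from .thermo import GradientSet, SpeciesTerm, TransportCycle

__all__ = [
    "TimeCourseParseError",
    "RunConfig",
    "parse_quantity",
    "format_quantity",
    "cycle_to_dict",
    "cycle_from_dict",
    "gradients_to_dict",
    "gradients_from_dict",
    "load_run_config",
    "config_hash",
    "time_courses_to_frame",
    "write_time_courses",
    "parse_time_course_table",
    "write_results",
    "read_results",
]

TIME_COURSE_COLUMNS = ("experiment_id", "voltage_mV", "time_s", "replicate", "cpm")

_UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # µM
    "nM": 1e-9,
}
_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([A-Za-zµ]+)?\s*$")


class TimeCourseParseError(ValueError):
    """A time-course CSV failed validation (the message names the issue)."""


def parse_quantity(value) -> float:
    """Parse a concentration into mol/L.

    Accepts a bare number (taken as mol/L) or a string with unit suffix:
    ``"199 mM"``, ``"1 uM"``, ``"1 µM"``, ``"2e-6 M"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _QUANTITY_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse concentration {value!r}")
    number, unit = m.groups()
    factor = 1.0
    if unit is not None:
        if unit not in _UNIT_FACTORS:
            raise ValueError(f"unknown concentration unit {unit!r} in {value!r}")
        factor = _UNIT_FACTORS[unit]
    return float(number) * factor


def format_quantity(mol_per_l: float) -> str:
    """Render mol/L with the most readable of M/mM/uM/nM."""
    for unit, factor in (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9)):
        scaled = mol_per_l / factor
        if abs(scaled) >= 1:
            return f"{scaled:g} {unit}"
    return f"{mol_per_l / 1e-9:g} nM"


def cycle_to_dict(cycle: TransportCycle) -> dict:
    return {
        "label": cycle.label,
        "species": [
            {
                "name": t.name,
                "valence": int(t.valence),
                "stoichiometry": t.stoichiometry,
                "role": t.role,
            }
            for t in cycle.terms
        ],
    }


def cycle_from_dict(data: dict) -> TransportCycle:
    terms = tuple(
        SpeciesTerm(
            name=s["name"],
            valence=int(s["valence"]),
            stoichiometry=float(s["stoichiometry"]),
            role=s.get("role", "coupling_ion"),
        )
        for s in data["species"]
    )
    return TransportCycle(terms=terms, label=data.get("label", ""))


def gradients_to_dict(gradients: GradientSet) -> dict:
    return {
        name: {"in": format_quantity(c_in), "out": format_quantity(c_out)}
        for name, (c_in, c_out) in gradients.concentrations.items()
    }


def gradients_from_dict(data: dict) -> GradientSet:
    conc = {}
    for name, pair in data.items():
        if isinstance(pair, dict):
            conc[name] = (parse_quantity(pair["in"]), parse_quantity(pair["out"]))
        else:
            c_in, c_out = pair
            conc[name] = (parse_quantity(c_in), parse_quantity(c_out))
    return GradientSet(conc)


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``revpot demo --write-config``
    for a worked example of the YAML schema)."""

    cycle: TransportCycle
    gradients: GradientSet
    candidates: list[tuple[int, int]]
    voltages_mv: list[float]
    timepoints_s: list[float]
    n_replicates: int
    population: VesiclePopulation
    params: KineticParams
    analysis: dict = field(default_factory=dict)
    label: str = ""
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def seed(self) -> int:
        return self.params.seed


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return run_config_from_dict(data)


def run_config_from_dict(data: dict) -> RunConfig:
    try:
        cycle = cycle_from_dict(data["cycle"])
        gradients = gradients_from_dict(data["gradients"])
    except KeyError as exc:
        raise ValueError(f"run config missing required section {exc}") from None
    missing = [t.name for t in cycle.terms if t.name not in gradients]
    if missing:
        raise ValueError(f"gradients missing cycle species: {missing}")
    sim = dict(data.get("simulator", {}))
    if "seed" not in sim:
        raise ValueError("simulator.seed is mandatory for a stochastic run")
    pop_keys = {"diameter_nm", "vesicle_count", "lipid_mg"}
    pop = VesiclePopulation(**{k: sim.pop(k) for k in list(sim) if k in pop_keys})
    params = KineticParams(**sim)
    return RunConfig(
        cycle=cycle,
        gradients=gradients,
        candidates=[tuple(int(x) for x in c) for c in data.get("candidates", [])],
        voltages_mv=[float(v) for v in data.get("voltages_mV", [])],
        timepoints_s=[float(t) for t in data.get("timepoints_s", [0, 5, 15, 30, 60, 120])],
        n_replicates=int(data.get("replicates", 3)),
        population=pop,
        params=params,
        analysis=dict(data.get("analysis", {})),
        label=data.get("label", ""),
        raw=data,
    )


def config_hash(data: dict) -> str:
    """Short stable hash of a config dict, recorded in every manifest."""
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def time_courses_to_frame(
    courses: list[FluxTimeCourse], experiment_id: str = "exp"
) -> pd.DataFrame:
    rows = []
    for course in courses:
        for i, t in enumerate(course.timepoints):
            for r in range(course.n_replicates):
                rows.append(
                    {
                        "experiment_id": experiment_id,
                        "voltage_mV": course.voltage_mv,
                        "time_s": float(t),
                        "replicate": r + 1,
                        "cpm": course.cpm[i, r],
                    }
                )
    return pd.DataFrame(rows, columns=list(TIME_COURSE_COLUMNS))


def write_time_courses(
    courses: list[FluxTimeCourse], path, experiment_id: str = "exp"
) -> pd.DataFrame:
    frame = time_courses_to_frame(courses, experiment_id)
    frame.to_csv(path, index=False)
    return frame


def parse_time_course_table(path_or_buffer) -> list[FluxTimeCourse]:
    """Parse a time-course CSV into validated, sorted courses.

    One course per (experiment_id, voltage) group, timepoints sorted,
    replicates ordered by their label.  Round-trips bit-exactly with
    :func:`write_time_courses`.
    """
    frame = pd.read_csv(path_or_buffer)
    missing = [c for c in TIME_COURSE_COLUMNS if c not in frame.columns]
    if missing:
        raise TimeCourseParseError(f"missing required column(s): {', '.join(missing)}")
    for col in ("voltage_mV", "time_s", "cpm"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().sum() > frame[col].isna().sum():
            bad = frame.loc[coerced.isna() & frame[col].notna(), col].iloc[0]
            raise TimeCourseParseError(f"non-numeric value {bad!r} in column {col!r}")
        frame[col] = coerced
    dup_keys = ["experiment_id", "voltage_mV", "time_s", "replicate"]
    dupes = frame.duplicated(subset=dup_keys)
    if dupes.any():
        row = frame.loc[dupes.idxmax(), dup_keys].to_dict()
        raise TimeCourseParseError(f"duplicated measurement row: {row}")
    courses = []
    for (exp_id, voltage), grp in frame.groupby(["experiment_id", "voltage_mV"], sort=True):
        pivot = grp.pivot(index="time_s", columns="replicate", values="cpm").sort_index()
        if pivot.isna().any().any():
            raise TimeCourseParseError(
                f"unequal replicate coverage for experiment {exp_id!r} at "
                f"{voltage} mV"
            )
        courses.append(
            FluxTimeCourse(
                voltage_mv=float(voltage),
                timepoints=pivot.index.to_numpy(dtype=float),
                cpm=pivot.to_numpy(dtype=float),
                metadata={"experiment_id": exp_id},
            )
        )
    return courses


def write_results(result, out_dir, manifest: dict | None = None) -> dict:
    """Write an InferenceResult as ``result.json`` plus a voltage--dCPM CSV.

    Returns the paths written.  Raises on a result with no flux calls.
    """
    if not result.calls:
        raise ValueError("refusing to write a result with no flux calls")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = result.to_dict()
    if manifest:
        payload["manifest"] = manifest
    json_path = out / "result.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    paths = {"result": str(json_path)}
    if result.delta_table is not None:
        csv_path = out / "delta_cpm.csv"
        result.delta_table.to_csv(csv_path, index=False)
        paths["delta_cpm"] = str(csv_path)
    return paths


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())
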