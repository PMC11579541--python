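"""Data model and tabular I/O for preclinical DMPK assays.

All in-vivo concentrations are canonicalized to μg/L (numerically equal to
ng/mL; tissue homogenates carry ng/g on the same scale), doses to mg/kg,
in-vivo time to hours and in-vitro incubation time to minutes.  Unit
conversion happens at the I/O boundary only, so downstream arithmetic never
mixes scales.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "ConcentrationTimeProfile",
    "SpeciesScaling",
    "DEFAULT_SCALING",
    "AnalysisReport",
    "read_profiles",
    "write_profiles",
    "profile_frame",
]

logger = logging.getLogger("dmpk")

SPECIES = ("rat", "dog", "monkey", "human")

ROUTES = ("oral", "iv")

#: conversion factors into the canonical concentration unit μg/L (= ng/mL)
_CONC_FACTORS = {
    "ug/L": 1.0,
    "ng/mL": 1.0,
    "ng/g": 1.0,      # tissue: numerically commensurate with μg/L
    "ug/mL": 1000.0,
    "mg/L": 1000.0,
    "ng/L": 1e-3,
}

_TIME_FACTORS_H = {"h": 1.0, "min": 1.0 / 60.0, "d": 24.0}


def _canon_conc(values: np.ndarray, unit: str) -> np.ndarray:
    try:
        return values * _CONC_FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


@dataclass
class ConcentrationTimeProfile:
    """One subject's analyte concentration vs time in one matrix.

    Concentrations in μg/L (tissues: ng/g), times in hours, dose in mg/kg.
    BLOQ observations are carried with an explicit flag, never dropped.
    """

    subject_id: str
    species: str
    matrix: str
    route: str
    dose: float
    times: np.ndarray
    concentrations: np.ndarray
    loq: float = 0.0
    tau: float | None = None
    bloq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("first time must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("non-monotone times")
        if np.any(self.concentrations < 0):
            raise ValueError("negative concentration")
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if self.bloq is None:
            self.bloq = self.concentrations < self.loq
        else:
            self.bloq = np.asarray(self.bloq, dtype=bool)
            if self.bloq.shape != self.times.shape:
                raise ValueError("bloq flags must match times")

    @property
    def n(self) -> int:
        return len(self.times)

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations with BLOQ points removed."""
        keep = ~self.bloq
        return self.times[keep], self.concentrations[keep]


@dataclass(frozen=True)
class SpeciesScaling:
    """Physiological scaling constants for microsome-to-liver extrapolation.

    mppgl: mg microsomal protein per g liver (one value for all species).
    liver_per_bw: g liver per kg body weight, by species.
    qh: hepatic blood flow, mL/min/kg, by species.
    """

    mppgl: float = 45.0
    liver_per_bw: Mapping[str, float] = field(
        default_factory=lambda: {"rat": 40.0, "dog": 32.0, "monkey": 30.0, "human": 25.7}
    )
    qh: Mapping[str, float] = field(
        default_factory=lambda: {"rat": 55.2, "dog": 30.9, "monkey": 43.6, "human": 20.7}
    )

    def __post_init__(self) -> None:
        if self.mppgl <= 0:
            raise ValueError("mppgl must be positive")
        for name, table in (("liver_per_bw", self.liver_per_bw), ("qh", self.qh)):
            if any(v <= 0 for v in table.values()):
                raise ValueError(f"{name} entries must be positive")

    def liver_weight(self, species: str) -> float:
        try:
            return self.liver_per_bw[species]
        except KeyError:
            raise KeyError(f"no liver weight for species {species!r}") from None

    def hepatic_flow(self, species: str) -> float:
        try:
            return self.qh[species]
        except KeyError:
            raise KeyError(f"no hepatic blood flow for species {species!r}") from None


DEFAULT_SCALING = SpeciesScaling()


# ---------------------------------------------------------------------------
# Reports


@dataclass
class AnalysisReport:
    """Serializable result of one assay analysis.

    Every parameter carries a value, units and flags; provenance records the
    input digests and the configuration actually used.
    """

    assay: str
    parameters: dict[str, dict[str, Any]] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def add(self, name: str, value: Any, units: str, **flags: Any) -> None:
        if isinstance(value, (np.floating, np.integer)):
            value = value.item()
        self.parameters[name] = {"value": value, "units": units, "flags": flags}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": k, "value": v["value"], "units": v["units"],
             "flags": ";".join(f"{fk}={fv}" for fk, fv in v["flags"].items())}
            for k, v in self.parameters.items()
        ]
        return pd.DataFrame(rows, columns=["parameter", "value", "units", "flags"])


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Long-format concentration-time tables

_MANDATORY = ["subject_id", "species", "matrix", "route", "dose_mg_per_kg",
              "time", "time_unit", "conc", "conc_unit"]


def read_profiles(path: str | Path) -> list[ConcentrationTimeProfile]:
    """Read long-format concentration-time CSV/TSV into profiles.

    One profile per (subject_id, matrix) group.  ``loq`` and ``tau_h``
    columns are optional; concentrations below LOQ are flagged BLOQ but kept.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    profiles: list[ConcentrationTimeProfile] = []
    for (subject, matrix), grp in df.groupby(["subject_id", "matrix"], sort=False):
        times = np.array([t * _TIME_FACTORS_H[u] for t, u in
                          zip(grp["time"], grp["time_unit"])])
        concs = np.array([c * _CONC_FACTORS[u] for c, u in
                          zip(grp["conc"], grp["conc_unit"])])
        loq = float(grp["loq"].iloc[0]) if "loq" in grp else 0.0
        tau = float(grp["tau_h"].iloc[0]) if "tau_h" in grp and not pd.isna(grp["tau_h"].iloc[0]) else None
        profiles.append(ConcentrationTimeProfile(
            subject_id=str(subject),
            species=str(grp["species"].iloc[0]),
            matrix=str(matrix),
            route=str(grp["route"].iloc[0]),
            dose=float(grp["dose_mg_per_kg"].iloc[0]),
            times=times,
            concentrations=concs,
            loq=loq,
            tau=tau,
        ))
    logger.info("read %d profile(s) from %s", len(profiles), path)
    return profiles


def profile_frame(profiles: Iterable[ConcentrationTimeProfile]) -> pd.DataFrame:
    """Long-format DataFrame in canonical units (inverse of read_profiles)."""
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            row = {"subject_id": p.subject_id, "species": p.species,
                   "matrix": p.matrix, "route": p.route,
                   "dose_mg_per_kg": p.dose, "time": t, "time_unit": "h",
                   "conc": c, "conc_unit": "ug/L", "loq": p.loq}
            if p.tau is not None:
                row["tau_h"] = p.tau
            rows.append(row)
    return pd.DataFrame(rows)


def write_profiles(profiles: Sequence[ConcentrationTimeProfile],
                   path: str | Path) -> None:
    # %.17g keeps float64 values bitwise round-trippable through text
    profile_frame(profiles).to_csv(path, index=False, float_format="%.17g")
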