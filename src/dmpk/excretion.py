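"""Mass-balance excretion analysis: per-interval and cumulative % of dose.

Each record holds the excreta amount (urine/bile volume in mL, or dry fecal
mass in g measured as a diluted homogenate) and the analyte concentration in
that matrix.  The recovered amount is conc × matrix amount × dilution
factor, expressed as % of the administered dose; cumulative curves per route
are running sums, and total recovery is the sum of route finals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ExcretionRecord",
    "interval_pct_dose",
    "cumulative_curve",
    "total_recovery",
    "EXTENSIVE_METABOLISM_BOUND",
]

logger = logging.getLogger("dmpk.excretion")

ROUTES = ("urine", "feces", "bile")

#: total recovery below this % of dose indicates extensive metabolism
EXTENSIVE_METABOLISM_BOUND = 5.0

#: matrices measured as diluted homogenates need an explicit dilution factor
HOMOGENATE_ROUTES = ("feces",)


@dataclass
class ExcretionRecord:
    """One collection interval for one excretion route.

    ``conc`` is the analyte concentration in the measured matrix (μg/mL);
    ``matrix_amount`` is urine/bile volume (mL) or dry fecal mass (g).  For
    homogenate matrices the dilution factor converts homogenate volume back
    to the source amount (10 for a 10% homogenate).
    """

    route: str
    interval: tuple[float, float]      # (start h, end h)
    matrix_amount: float
    conc: float
    dilution_factor: float | None = None
    pct_dose: float | None = None

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        start, end = self.interval
        if not (0 <= start < end):
            raise ValueError("interval must satisfy 0 <= start < end")
        if self.matrix_amount < 0 or self.conc < 0:
            raise ValueError("amounts and concentrations must be >= 0")
        if self.route in HOMOGENATE_ROUTES and self.dilution_factor is None:
            raise ValueError(
                f"{self.route} is measured as a homogenate; dilution_factor required")


def interval_pct_dose(rec: ExcretionRecord, dose_mg_per_kg: float,
                      body_weight_kg: float) -> float:
    """% of administered dose recovered in one interval.

    amount(μg) = conc(μg/mL) × matrix amount × dilution factor;
    dose(μg) = dose(mg/kg) × BW(kg) × 1000.
    """
    if dose_mg_per_kg <= 0 or body_weight_kg <= 0:
        raise ValueError("dose and body weight must be > 0")
    dilution = rec.dilution_factor if rec.dilution_factor is not None else 1.0
    amount_ug = rec.conc * rec.matrix_amount * dilution
    dose_ug = dose_mg_per_kg * body_weight_kg * 1000.0
    rec.pct_dose = 100.0 * amount_ug / dose_ug
    return rec.pct_dose


def cumulative_curve(pct_per_interval: Sequence[float]) -> np.ndarray:
    """Running cumulative % of dose per interval end; monotone non-decreasing."""
    arr = np.asarray(pct_per_interval, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative interval excretion")
    return np.cumsum(arr)


def total_recovery(route_finals: Mapping[str, float]) -> tuple[float, bool]:
    """Total % of dose recovered over all routes.

    Returns (total %, extensive-metabolism flag); the flag is set when less
    than 5% of the dose is recovered as parent drug.
    """
    if not route_finals:
        raise ValueError("at least one route required")
    total = float(sum(route_finals.values()))
    extensive = total < EXTENSIVE_METABOLISM_BOUND
    if extensive:
        logger.info("total recovery %.3f%% of dose: extensive metabolism", total)
    return total, extensive
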