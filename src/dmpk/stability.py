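"""Microsomal depletion kinetics and well-stirred IVIVE scaling.

Parent-drug depletion in liver microsomes is treated as mono-exponential:
the elimination rate constant k_e is minus the slope of ln(remaining) vs
incubation time, and t1/2 = 0.693 / k_e.  Intrinsic clearance scales the
in-vitro half-life to the whole body,

    CL_int = (0.693 / t1/2) * (mL incubation / mg microsomes)
             * (mg microsomes / g liver) * (g liver / kg BW),

and the well-stirred liver model caps hepatic clearance at hepatic blood
flow Q_h:

    CL_h = Q_h * CL_int / (Q_h + CL_int).

The 0.693 constant is used as printed by convention; pass
``use_exact_ln2=True`` to switch to ln 2 at full precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import DEFAULT_SCALING, SpeciesScaling

__all__ = [
    "DepletionSeries",
    "StabilityResult",
    "fit_depletion",
    "detect_linear_window",
    "intrinsic_clearance",
    "hepatic_clearance",
    "species_rank",
    "analyze_depletion",
]

logger = logging.getLogger("dmpk.stability")

LN2_PRINTED = 0.693


@dataclass
class DepletionSeries:
    """Remaining parent drug vs incubation time for one replicate.

    Times in minutes; remaining as concentration or % of t=0 (the ratio is
    all that matters).  ``incubation_protein`` is the microsomal protein
    concentration in mg/mL.
    """

    species: str
    times: np.ndarray
    remaining: np.ndarray
    incubation_protein: float = 0.2
    linear_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.remaining = np.asarray(self.remaining, dtype=float)
        if self.times.min() < 0 or 0.0 not in self.times:
            raise ValueError("times must include 0 and be non-negative")
        if self.remaining[np.argmin(self.times)] <= 0:
            raise ValueError("remaining at t=0 must be > 0")
        if self.incubation_protein <= 0:
            raise ValueError("incubation_protein must be > 0")


@dataclass
class StabilityResult:
    species: str
    ke: float            # 1/min
    t_half: float        # min (inf when stable)
    r2: float
    window_used: tuple[float, float]
    cl_int: float | None = None   # mL/min/kg
    cl_h: float | None = None     # mL/min/kg

    @property
    def stable(self) -> bool:
        return not math.isfinite(self.t_half)


def detect_linear_window(times: np.ndarray, remaining: np.ndarray,
                         r2_min: float = 0.95) -> tuple[float, float]:
    """Longest prefix of the series over which ln(remaining) is linear.

    Scans prefixes of length >= 3 and returns the longest one whose
    ln-linear r² stays at or above ``r2_min``; falls back to the first three
    points when none qualifies.
    """
    order = np.argsort(times)
    t, r = times[order], remaining[order]
    pos = r > 0
    t, r = t[pos], r[pos]
    if len(t) < 3:
        raise ValueError("need >= 3 positive points for window detection")
    best_end = 2
    for end in range(2, len(t)):
        fit = stats.linregress(t[: end + 1], np.log(r[: end + 1]))
        if fit.rvalue ** 2 >= r2_min or end == 2:
            best_end = end   # longest qualifying prefix wins
    return (float(t[0]), float(t[best_end]))


def fit_depletion(series: DepletionSeries,
                  use_exact_ln2: bool = False) -> StabilityResult:
    """k_e, t1/2 and r² from the ln-linear depletion slope.

    Uses the explicit ``linear_window`` when set, otherwise auto-detects the
    longest ln-linear prefix.  A non-negative slope yields an infinite
    half-life flagged as metabolically stable.
    """
    ln2 = math.log(2.0) if use_exact_ln2 else LN2_PRINTED
    window = series.linear_window or detect_linear_window(series.times, series.remaining)
    lo, hi = window
    mask = (series.times >= lo) & (series.times <= hi)
    t = series.times[mask]
    r = series.remaining[mask]
    if np.any(r <= 0):
        raise ValueError("non-positive remaining inside the linear window")
    if len(t) < 3:
        raise ValueError("need >= 3 points inside the linear window")
    fit = stats.linregress(t, np.log(r))
    slope = fit.slope
    r2 = fit.rvalue ** 2
    if slope >= 0:
        logger.info("%s: non-negative depletion slope; flagged stable", series.species)
        return StabilityResult(series.species, ke=0.0, t_half=math.inf,
                               r2=r2, window_used=window)
    ke = -slope
    return StabilityResult(series.species, ke=ke, t_half=ln2 / ke,
                           r2=r2, window_used=window)


def intrinsic_clearance(t_half: float, incubation_protein: float,
                        species: str,
                        scaling: SpeciesScaling = DEFAULT_SCALING,
                        use_exact_ln2: bool = False) -> float:
    """Scale a microsomal half-life (min) to intrinsic clearance, mL/min/kg."""
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    if math.isinf(t_half):
        return 0.0
    ln2 = math.log(2.0) if use_exact_ln2 else LN2_PRINTED
    return (ln2 / t_half) * (1.0 / incubation_protein) \
        * scaling.mppgl * scaling.liver_weight(species)


def hepatic_clearance(cl_int: float, species: str,
                      scaling: SpeciesScaling = DEFAULT_SCALING) -> float:
    """Well-stirred hepatic clearance, mL/min/kg; bounded by Q_h."""
    if cl_int < 0:
        raise ValueError("cl_int must be >= 0")
    qh = scaling.hepatic_flow(species)
    return qh * cl_int / (qh + cl_int)


def species_rank(results: Mapping[str, StabilityResult]) -> list[tuple[str, float]]:
    """Species ordered by descending elimination rate constant.

    Returns (species, ke) pairs; exact ties keep input order and are logged.
    """
    if len(results) < 1:
        raise ValueError("at least one species required")
    items = [(sp, res.ke) for sp, res in results.items()]
    ranked = sorted(items, key=lambda kv: -kv[1])
    kes = [ke for _, ke in ranked]
    if len(set(kes)) < len(kes):
        logger.warning("ties present in species ranking by k_e")
    return ranked


def analyze_depletion(replicates: Sequence[DepletionSeries],
                      scaling: SpeciesScaling = DEFAULT_SCALING,
                      use_exact_ln2: bool = False) -> StabilityResult:
    """Per-replicate fits, then arithmetic mean of the derived parameters.

    Replicate-wise estimation (rather than a pooled fit) matches how
    triplicate microsomal assays are conventionally summarized.
    """
    if not replicates:
        raise ValueError("no replicates supplied")
    species = replicates[0].species
    fits = [fit_depletion(s, use_exact_ln2=use_exact_ln2) for s in replicates]
    if any(f.stable for f in fits):
        ke = float(np.mean([f.ke for f in fits]))
        return StabilityResult(species, ke=ke, t_half=math.inf,
                               r2=float(np.mean([f.r2 for f in fits])),
                               window_used=fits[0].window_used, cl_int=0.0,
                               cl_h=0.0)
    cl_ints = [intrinsic_clearance(f.t_half, s.incubation_protein, species,
                                   scaling, use_exact_ln2)
               for f, s in zip(fits, replicates)]
    cl_hs = [hepatic_clearance(ci, species, scaling) for ci in cl_ints]
    return StabilityResult(
        species,
        ke=float(np.mean([f.ke for f in fits])),
        t_half=float(np.mean([f.t_half for f in fits])),
        r2=float(np.mean([f.r2 for f in fits])),
        window_used=fits[0].window_used,
        cl_int=float(np.mean(cl_ints)),
        cl_h=float(np.mean(cl_hs)),
    )
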