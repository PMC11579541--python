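"""Bidirectional MDCK-MDR1 monolayer transport and MTT cytotoxicity analysis.

The apparent permeability coefficient is the regression slope of the
cumulative amount transported into the receiver chamber against time,
normalized by monolayer area and donor loading concentration:

    Papp = (dQ/dt) / (A * C0)        [cm/s]

Periodic receiver sampling with buffer replacement removes analyte; the
cumulative amount is reconstructed as

    Q(t_n) = C_n * V_receiver + sum_{i<n} C_i * V_sample.

The efflux ratio ER = Papp(B->A) / Papp(A->B) flags P-glycoprotein
substrates when it exceeds 1.5; an A->B Papp above 3e-6 cm/s marks facile
blood-brain-barrier passage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TransportExperiment",
    "PappResult",
    "CytotoxicityCurve",
    "cumulative_receiver_amount",
    "apparent_permeability",
    "efflux_ratio",
    "inhibitor_effect",
    "fit_tc50",
    "BBB_PERMEABILITY_THRESHOLD",
    "EFFLUX_SUBSTRATE_THRESHOLD",
]

logger = logging.getLogger("dmpk.transport")

#: A->B Papp above which a compound crosses the blood-brain barrier readily (cm/s)
BBB_PERMEABILITY_THRESHOLD = 3e-6
#: efflux ratio above which active (P-gp) efflux is indicated
EFFLUX_SUBSTRATE_THRESHOLD = 1.5
#: receiver concentration above this fraction of donor C0 violates sink conditions
SINK_FRACTION = 0.10


@dataclass
class TransportExperiment:
    """One direction of a bidirectional monolayer transport run.

    Concentrations in μg/mL, volumes in μL, times in minutes, area in cm².
    """

    direction: str                       # "AtoB" or "BtoA"
    c0: float                            # donor concentration at t=0, μg/mL
    samples: Sequence[tuple[float, float]]  # (time min, receiver conc μg/mL)
    area: float = 0.33
    donor_volume: float = 400.0
    receiver_volume: float = 1200.0
    sample_volume: float = 50.0
    inhibitor: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("AtoB", "BtoA"):
            raise ValueError(f"direction must be AtoB or BtoA, got {self.direction!r}")
        if self.c0 <= 0:
            raise ValueError("donor c0 must be > 0")
        if self.area <= 0:
            raise ValueError("area must be > 0")
        if self.sample_volume >= self.receiver_volume:
            raise ValueError("sample_volume must be smaller than receiver_volume")
        t = np.array([s[0] for s in self.samples], dtype=float)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing and > 0")

    @property
    def times(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples], dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples], dtype=float)


@dataclass
class PappResult:
    papp: float                    # cm/s
    slope_r2: float
    direction: str
    er: float | None = None
    flags: dict = field(default_factory=dict)


@dataclass
class CytotoxicityCurve:
    """MTT relative-growth-rate curve: RGR(%) vs compound concentration."""

    concentrations: np.ndarray     # μg/mL
    rgr: np.ndarray                # % of blank control, replicate means
    tc50: float | None = None
    tc50_ci: tuple[float, float] | None = None
    censored: bool = False
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rgr = np.asarray(self.rgr, dtype=float)
        if not np.all(np.isfinite(self.rgr)):
            raise ValueError("RGR values must be finite")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")


def cumulative_receiver_amount(
    exp: TransportExperiment, correct_sampling: bool = True
) -> list[tuple[float, float]]:
    """Cumulative amount (μg) transported into the receiver per time point.

    With ``correct_sampling`` the analyte removed by each prior aliquot is
    added back; with sample_volume = 0 (or correction off) this reduces to
    C_n * V_receiver.
    """
    v_r = exp.receiver_volume / 1000.0   # μL -> mL; conc μg/mL * mL = μg
    v_s = (exp.sample_volume / 1000.0) if correct_sampling else 0.0
    out: list[tuple[float, float]] = []
    removed = 0.0
    for t, c in exp.samples:
        out.append((t, c * v_r + removed))
        removed += c * v_s
    return out


def apparent_permeability(
    exp: TransportExperiment, correct_sampling: bool = True
) -> PappResult:
    """Papp from the least-squares slope of cumulative Q(t) vs time.

    Needs at least three sampled time points.  A non-positive slope is
    floored at Papp = 0 with a warning flag.  The BBB-permeability flag is
    set for the apical-to-basolateral direction only.
    """
    if len(exp.samples) < 3:
        raise ValueError("apparent_permeability requires >= 3 sampled time points")
    q = cumulative_receiver_amount(exp, correct_sampling=correct_sampling)
    t_sec = np.array([p[0] for p in q]) * 60.0
    amounts = np.array([p[1] for p in q])
    flags: dict = {}
    if np.allclose(amounts, 0.0):
        flags["zero_flux"] = True
        return PappResult(papp=0.0, slope_r2=float("nan"),
                          direction=exp.direction, flags=flags)
    fit = stats.linregress(t_sec, amounts)
    slope = fit.slope                     # μg/s
    r2 = fit.rvalue ** 2
    if slope <= 0:
        logger.warning("non-positive flux slope (%.3g μg/s); Papp floored at 0", slope)
        flags["nonpositive_slope"] = True
        papp = 0.0
    else:
        papp = slope / (exp.area * exp.c0)   # μg/s / (cm² · μg/cm³) = cm/s
    if exp.concentrations.max() > SINK_FRACTION * exp.c0:
        flags["sink_violation"] = True
    if exp.direction == "AtoB":
        flags["bbb_permeable"] = papp > BBB_PERMEABILITY_THRESHOLD
    return PappResult(papp=papp, slope_r2=r2, direction=exp.direction, flags=flags)


def efflux_ratio(ab: PappResult, ba: PappResult) -> PappResult:
    """Pair both directions into an efflux ratio ER = Papp(B->A)/Papp(A->B)."""
    if ab.direction != "AtoB" or ba.direction != "BtoA":
        raise ValueError("efflux_ratio expects an (AtoB, BtoA) pair")
    flags = dict(ab.flags)
    if ab.papp == 0:
        flags["er_censored"] = True
        return PappResult(papp=ab.papp, slope_r2=ab.slope_r2,
                          direction="paired", er=None, flags=flags)
    er = ba.papp / ab.papp
    flags["pgp_substrate"] = er > EFFLUX_SUBSTRATE_THRESHOLD
    return PappResult(papp=ab.papp, slope_r2=ab.slope_r2,
                      direction="paired", er=er, flags=flags)


def inhibitor_effect(
    base: Sequence[TransportExperiment],
    inhibited: Sequence[TransportExperiment],
    correct_sampling: bool = True,
) -> pd.DataFrame:
    """Per-(direction, concentration) Papp with/without efflux inhibitor.

    Returns a table with Papp fold-change per matched design cell, plus an
    ER-collapse summary row when both directions are present in both arms.
    """
    if not base or not inhibited:
        raise ValueError("both base and inhibited experiment sets are required")

    def _index(exps: Sequence[TransportExperiment]) -> dict:
        return {(e.direction, round(e.c0, 9)): e for e in exps}

    base_ix, inh_ix = _index(base), _index(inhibited)
    if set(base_ix) != set(inh_ix):
        raise ValueError("unmatched designs: base and inhibited (direction, c0) sets differ")

    rows = []
    papps: dict[tuple, dict[str, float]] = {}
    for key in sorted(base_ix):
        direction, c0 = key
        p0 = apparent_permeability(base_ix[key], correct_sampling)
        p1 = apparent_permeability(inh_ix[key], correct_sampling)
        fold = p1.papp / p0.papp if p0.papp > 0 else math.inf
        papps.setdefault(c0, {})[direction + "_base"] = p0.papp
        papps[c0][direction + "_inh"] = p1.papp
        rows.append({"direction": direction, "c0_ug_per_mL": c0,
                     "papp_base": p0.papp, "papp_inhibited": p1.papp,
                     "fold_change": fold})
    table = pd.DataFrame(rows)
    er_rows = []
    for c0, d in papps.items():
        if {"AtoB_base", "BtoA_base", "AtoB_inh", "BtoA_inh"} <= set(d):
            er_rows.append({
                "c0_ug_per_mL": c0,
                "er_base": d["BtoA_base"] / d["AtoB_base"] if d["AtoB_base"] else math.nan,
                "er_inhibited": d["BtoA_inh"] / d["AtoB_inh"] if d["AtoB_inh"] else math.nan,
            })
    if er_rows:
        table.attrs["er_summary"] = pd.DataFrame(er_rows)
    return table


# ---------------------------------------------------------------------------
# MTT cytotoxicity


def _logistic4(x: np.ndarray, bottom: float, top: float, x50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (x - x50)))


def fit_tc50(curve: CytotoxicityCurve) -> CytotoxicityCurve:
    """Fit a 4-parameter logistic of RGR vs ln(concentration) and locate TC50.

    TC50 is the concentration at which the fitted relative growth rate
    crosses 50%.  When the curve never reaches 50% inside the tested range
    the result is censored as "> max tested concentration".  Bottom and top
    asymptotes are bounded to [0, 120]% to keep shallow curves identifiable.
    """
    if len(curve.concentrations) < 5:
        raise ValueError("fit_tc50 requires >= 5 concentrations")
    x = np.log(curve.concentrations)
    y = curve.rgr
    cmax = float(curve.concentrations.max())

    if y.min() > 50.0:
        return CytotoxicityCurve(curve.concentrations, y, tc50=cmax,
                                 censored=True,
                                 flags={"note": f"> {cmax:g} ug/mL (max tested)"})
    p0 = (max(y.min(), 0.0), min(y.max(), 120.0), float(np.median(x)), 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            _logistic4, x, y, p0=p0,
            bounds=([0.0, 0.0, x.min() - 10, 0.05], [120.0, 120.0, x.max() + 10, 20.0]),
            maxfev=20000,
        )
    except RuntimeError:
        return CytotoxicityCurve(curve.concentrations, y, censored=True,
                                 flags={"note": "fit did not converge"})
    bottom, top, x50, hill = popt
    if not (bottom < 50.0 < top):
        return CytotoxicityCurve(curve.concentrations, y, tc50=cmax, censored=True,
                                 flags={"note": f"> {cmax:g} ug/mL (50% outside asymptotes)"})
    # invert the fitted logistic at RGR = 50%
    x_at_50 = x50 + math.log((top - 50.0) / (50.0 - bottom)) / hill
    tc50 = math.exp(x_at_50)
    if tc50 > cmax:
        return CytotoxicityCurve(curve.concentrations, y, tc50=cmax, censored=True,
                                 flags={"note": f"> {cmax:g} ug/mL (midpoint beyond range)"})
    # delta-method CI on ln TC50 via the midpoint parameter variance
    se_x50 = math.sqrt(max(pcov[2, 2], 0.0))
    ci = (math.exp(x_at_50 - 1.96 * se_x50), math.exp(x_at_50 + 1.96 * se_x50))
    return CytotoxicityCurve(curve.concentrations, y, tc50=tc50, tc50_ci=ci,
                             flags={"hill": hill, "top": top, "bottom": bottom})
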