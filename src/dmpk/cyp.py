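"""CYP phenotyping transformation ratios and cocktail-inhibition IC50 fits.

Phenotyping compares the parent drug remaining after incubation with a
single recombinant CYP isoform against a zero-time control; the transformed
fraction is 100·(1 − remaining/control).

Cocktail inhibition fits a 4-parameter logistic of % residual marker
activity against log10 inhibitor concentration.  When the observed maximum
inhibition never reaches 50%, the IC50 is censored as "> top tested
concentration" rather than extrapolated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "PHENOTYPING_ISOFORMS",
    "COCKTAIL_ISOFORMS",
    "PhenotypingResult",
    "InhibitionSeries",
    "IC50Result",
    "transformation_ratio",
    "fit_ic50",
    "classify_inhibition",
]

logger = logging.getLogger("dmpk.cyp")

PHENOTYPING_ISOFORMS = ("1A2", "2C9", "2C19", "2D6", "3A4")
COCKTAIL_ISOFORMS = ("1A2", "2A6", "2B6", "2C8", "2C9", "2C19", "2D6", "2E1", "3A4")

#: IC50 class bounds, μmol/L: <=10 potent, <=50 moderate, else weak
POTENT_BOUND = 10.0
MODERATE_BOUND = 50.0
#: minimum inhibition at top concentration for a censored result to count as weak
WEAK_CENSORED_INHIBITION = 25.0


@dataclass
class PhenotypingResult:
    isoform: str
    residual_pct: float
    transformed_pct: float
    significant: bool = False

    def __post_init__(self) -> None:
        # small negative / >100 values can arise from assay noise only
        if not (-5.0 <= self.transformed_pct <= 105.0):
            raise ValueError(
                f"transformed fraction {self.transformed_pct:.1f}% outside noise guard")


@dataclass
class InhibitionSeries:
    """Residual marker activity vs inhibitor concentration for one isoform.

    ``activity_pct`` has shape (n_conc,) or (n_conc, n_replicates); the
    inhibitor-free blank control defines 100% and is not a fitted point.
    """

    isoform: str
    inhibitor_conc: np.ndarray        # μmol/L, increasing
    activity_pct: np.ndarray          # % of blank control
    substrate: str = ""
    substrate_conc: float | None = None

    def __post_init__(self) -> None:
        self.inhibitor_conc = np.asarray(self.inhibitor_conc, dtype=float)
        self.activity_pct = np.asarray(self.activity_pct, dtype=float)
        if np.any(self.inhibitor_conc <= 0):
            raise ValueError("inhibitor concentrations must be > 0 (blank is the normalizer)")
        if np.any(np.diff(self.inhibitor_conc) <= 0):
            raise ValueError("inhibitor concentrations must be increasing")
        if self.activity_pct.shape[0] != len(self.inhibitor_conc):
            raise ValueError("activity rows must match concentrations")

    def mean_activity(self) -> np.ndarray:
        a = self.activity_pct
        return a if a.ndim == 1 else a.mean(axis=1)


@dataclass
class IC50Result:
    isoform: str
    ic50: float                      # μmol/L; censoring bound when censored
    censored: bool = False
    hill: float | None = None
    ci: tuple[float, float] | None = None
    max_inhibition_pct: float = 0.0
    flags: dict = field(default_factory=dict)

    def __str__(self) -> str:
        if self.censored:
            return f"CYP{self.isoform}: IC50 > {self.ic50:g} umol/L"
        return f"CYP{self.isoform}: IC50 = {self.ic50:.3g} umol/L"


def transformation_ratio(parent_remaining: float, zero_time_control: float,
                         isoform: str = "", significant: bool = False,
                         nadph_free_remaining: float | None = None) -> PhenotypingResult:
    """Transformed fraction of parent drug for one recombinant CYP isoform.

    When the NADPH-free negative control is supplied, a run losing more than
    5% of parent without cofactor is rejected as invalid.
    """
    if zero_time_control <= 0:
        raise ValueError("zero-time control must be > 0")
    if nadph_free_remaining is not None:
        drift = 100.0 * (1.0 - nadph_free_remaining / zero_time_control)
        if abs(drift) > 5.0:
            raise ValueError(
                f"NADPH-free control shows {drift:.1f}% loss; run invalid")
    residual = 100.0 * parent_remaining / zero_time_control
    return PhenotypingResult(isoform=isoform, residual_pct=residual,
                             transformed_pct=100.0 - residual,
                             significant=significant)


def _logistic4(logc: np.ndarray, bottom: float, top: float,
               log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_ic50(series: InhibitionSeries) -> IC50Result:
    """4-parameter logistic IC50 with top constrained to [90, 110]%.

    The IC50 is the fitted midpoint on the log10 concentration axis.  The
    result is censored at the highest tested concentration when the observed
    maximum inhibition stays below 50% or the fitted midpoint lies beyond
    the tested range.
    """
    if len(series.inhibitor_conc) < 4:
        raise ValueError("fit_ic50 requires >= 4 inhibitor concentrations")
    logc = np.log10(series.inhibitor_conc)
    mean = series.mean_activity()
    top_conc = float(series.inhibitor_conc[-1])
    max_inh = float(100.0 - mean.min())

    if max_inh < 50.0:
        return IC50Result(series.isoform, ic50=top_conc, censored=True,
                          max_inhibition_pct=max_inh,
                          flags={"note": f"> {top_conc:g} umol/L (max inhibition "
                                         f"{max_inh:.1f}% < 50%)"})
    # replicate-aware fit: flatten replicates against repeated x
    if series.activity_pct.ndim == 2:
        nrep = series.activity_pct.shape[1]
        x = np.repeat(logc, nrep)
        y = series.activity_pct.ravel()
    else:
        x, y = logc, mean
    try:
        popt, pcov = optimize.curve_fit(
            _logistic4, x, y,
            p0=(max(mean.min(), 0.0), 100.0, float(np.median(logc)), 1.0),
            bounds=([0.0, 90.0, logc.min() - 3, 0.1],
                    [90.0, 110.0, logc.max() + 3, 10.0]),
            maxfev=20000,
        )
    except RuntimeError:
        return IC50Result(series.isoform, ic50=top_conc, censored=True,
                          max_inhibition_pct=max_inh,
                          flags={"note": "fit did not converge"})
    bottom, top, log_ic50, hill = popt
    ic50 = 10.0 ** log_ic50
    if ic50 > top_conc:
        return IC50Result(series.isoform, ic50=top_conc, censored=True,
                          hill=hill, max_inhibition_pct=max_inh,
                          flags={"note": f"> {top_conc:g} umol/L (midpoint beyond range)"})
    se = math.sqrt(max(pcov[2, 2], 0.0))
    ci = (10.0 ** (log_ic50 - 1.96 * se), 10.0 ** (log_ic50 + 1.96 * se))
    return IC50Result(series.isoform, ic50=float(ic50), hill=float(hill),
                      ci=ci, max_inhibition_pct=max_inh,
                      flags={"bottom": float(bottom), "top": float(top)})


def classify_inhibition(result: IC50Result) -> str:
    """Classify an IC50 as negligible, weak, moderate or potent.

    Censored results are negligible unless inhibition at the top tested
    concentration reached 25%, in which case they are weak; numeric IC50s
    use the 10/50 μmol/L convention.
    """
    if result.censored:
        return "weak" if result.max_inhibition_pct >= WEAK_CENSORED_INHIBITION \
            else "negligible"
    if result.ic50 <= POTENT_BOUND:
        return "potent"
    if result.ic50 <= MODERATE_BOUND:
        return "moderate"
    return "weak"
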