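"""Plasma protein binding and tissue-distribution exposure analysis.

Protein binding from ultrafiltration pairs: bound fraction
100·(C_total − C_free)/C_total.

Tissue distribution under destructive sampling uses the composite method:
trapezoidal AUC(0→t) on per-time-point mean concentrations, tissue-to-blood
AUC ratios, and each matrix's share of the summed exposure.  Tissue
concentrations (ng/g) and blood (μg/L) are treated as numerically
commensurate for ratio purposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PPBMeasurement",
    "TissuePanel",
    "ppb_rate",
    "composite_tissue_auc",
    "peak_profile_summary",
]

logger = logging.getLogger("dmpk.binding")

#: last/peak concentration above this fraction flags possible accumulation
ACCUMULATION_FRACTION = 0.20


@dataclass
class PPBMeasurement:
    """One ultrafiltration total/free concentration pair (ng/mL)."""

    species: str
    nominal_conc: float
    ct: float          # total plasma concentration
    cf: float          # free (ultrafiltrate) concentration
    binding_pct: float | None = None

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("total concentration must be > 0")
        if self.cf < 0:
            raise ValueError("free concentration must be >= 0")
        if self.cf > self.ct:
            raise ValueError(
                "free exceeds total concentration (pre-saturation or "
                "nonspecific binding artifact)")


@dataclass
class TissuePanel:
    """Mean concentration per time point per matrix under destructive sampling.

    ``profiles`` maps matrix name ("blood" plus tissue names) to (times h,
    mean concentrations).  Derived exposure columns are filled by
    ``composite_tissue_auc``.
    """

    profiles: Mapping[str, tuple[np.ndarray, np.ndarray]]
    n_per_timepoint: int = 6
    auc_0t: dict[str, float] = field(default_factory=dict)
    ratio_to_blood: dict[str, float] = field(default_factory=dict)
    fraction_of_total: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, (t, c) in self.profiles.items():
            t = np.asarray(t, dtype=float)
            c = np.asarray(c, dtype=float)
            if len(t) != len(c):
                raise ValueError(f"{name}: times and concentrations differ in length")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{name}: non-monotone times")
            if np.any(c < 0):
                raise ValueError(f"{name}: negative concentration")
            clean[name] = (t, c)
        self.profiles = clean


def ppb_rate(m: PPBMeasurement) -> float:
    """Plasma-protein binding rate, % = 100·(Ct − Cf)/Ct, clipped to [0, 100]."""
    return float(np.clip(100.0 * (m.ct - m.cf) / m.ct, 0.0, 100.0))


def composite_tissue_auc(panel: TissuePanel) -> TissuePanel:
    """Fill per-matrix AUC(0→t), tissue-to-blood ratios and exposure shares.

    Requires a "blood" reference profile and at least two time points per
    matrix.  Fractions are percentages of the summed AUC over all matrices
    and sum to 100 exactly.
    """
    if "blood" not in panel.profiles:
        raise ValueError("panel must include a 'blood' reference profile")
    for name, (t, _) in panel.profiles.items():
        if len(t) < 2:
            raise ValueError(f"{name}: need >= 2 time points")
    aucs = {name: float(np.trapezoid(c, t))
            for name, (t, c) in panel.profiles.items()}
    blood = aucs["blood"]
    if blood <= 0:
        raise ValueError("blood AUC must be positive")
    total = sum(aucs.values())
    panel.auc_0t = aucs
    panel.ratio_to_blood = {name: a / blood for name, a in aucs.items()
                            if name != "blood"}
    panel.fraction_of_total = {name: 100.0 * a / total for name, a in aucs.items()}
    return panel


def peak_profile_summary(panel: TissuePanel) -> pd.DataFrame:
    """Observed peak time/value per matrix and a terminal accumulation screen.

    ``terminal_pct_of_peak`` is the last-time-point concentration as % of
    the peak; values above 20% flag possible tissue accumulation.
    """
    rows = []
    for name, (t, c) in panel.profiles.items():
        i = int(np.argmax(c))
        peak = float(c[i])
        terminal_pct = 100.0 * float(c[-1]) / peak if peak > 0 else 0.0
        rows.append({
            "matrix": name,
            "tmax_obs": float(t[i]),
            "cmax_obs": peak,
            "terminal_pct_of_peak": terminal_pct,
            "accumulation_flag": terminal_pct > 100.0 * ACCUMULATION_FRACTION,
        })
    df = pd.DataFrame(rows)
    df.attrs["no_tissue_accumulation"] = bool(~df["accumulation_flag"].any())
    return df
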