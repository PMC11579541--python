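"""Non-compartmental pharmacokinetic analysis.

Single-dose parameters (AUC, AUMC, MRT, λz, t1/2z, Cmax/Tmax, CL/F, Vz/F),
absolute bioavailability, steady-state metrics over a dosing interval, and
dose-proportionality ratios.

Conventions
-----------
* Trapezoidal AUC is linear by default ("linear up / log down" available).
* λz comes from a log-linear regression of the terminal phase; the point set
  is chosen to maximize adjusted r² over the last 3..k quantifiable points,
  excluding Cmax for extravascular profiles, with ties broken toward more
  points.
* BLOQ values before the first quantifiable point count as 0 in trapezoids;
  BLOQ values embedded after Cmax are excluded from the λz fit but retained
  (as 0) for trapezoids.
* Units: dose mg/kg over AUC μg/L·h gives clearance in L/h/kg after the
  mg→μg factor of 1000.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ConcentrationTimeProfile

__all__ = [
    "NCAResult",
    "SteadyStateResult",
    "auc_trapezoid",
    "fit_lambda_z",
    "single_dose_nca",
    "bioavailability",
    "steady_state_metrics",
    "dose_proportionality",
]

logger = logging.getLogger("dmpk.nca")

EXTRAPOLATION_WARN_PCT = 20.0


@dataclass
class NCAResult:
    """Single-dose NCA parameter set for one profile."""

    subject_id: str
    dose: float                     # mg/kg
    route: str
    auc_0t: float                   # μg/L·h
    aumc_0t: float                  # μg/L·h²
    cmax: float                     # μg/L
    tmax: float                     # h
    mrt_0t: float                   # h
    lambda_z: float | None = None   # 1/h
    t_half_z: float | None = None   # h
    lambda_r2adj: float | None = None
    n_lambda: int = 0
    auc_0inf: float | None = None
    aumc_0inf: float | None = None
    mrt_0inf: float | None = None
    cl_f: float | None = None       # L/h/kg
    vz_f: float | None = None       # L/kg
    extrap_pct: float | None = None
    flags: dict = field(default_factory=dict)


@dataclass
class SteadyStateResult:
    auc_ss: float                   # μg/L·h over one τ
    c_av: float                     # μg/L
    c_min: float
    c_max: float
    df: float                       # degree of fluctuation
    accumulation_index: float | None = None
    troughs_flat: bool | None = None
    flags: dict = field(default_factory=dict)


def _working_concentrations(profile: ConcentrationTimeProfile) -> np.ndarray:
    """Concentrations with the BLOQ policy applied for trapezoid use."""
    c = profile.concentrations.copy()
    c[profile.bloq] = 0.0
    return c


def auc_trapezoid(profile: ConcentrationTimeProfile,
                  t_end: float | None = None,
                  method: str = "linear") -> tuple[float, float]:
    """(AUC, AUMC) by the trapezoidal rule up to ``t_end``.

    ``method`` is "linear" or "linear_up_log_down"; the log-down rule applies
    the logarithmic trapezoid on strictly decreasing positive segments.
    Interpolates linearly (or log-linearly) when ``t_end`` falls between
    sampling times.
    """
    if method not in ("linear", "linear_up_log_down"):
        raise ValueError(f"unknown method {method!r}")
    t = profile.times
    c = _working_concentrations(profile)
    if np.count_nonzero(~profile.bloq) < 2 or not np.any(c > 0):
        raise ValueError("need >= 2 quantifiable points for AUC")
    if t_end is None:
        t_end = float(t[-1])
    if t_end < t[1]:
        raise ValueError("t_end precedes the second time point")
    # truncate / interpolate at t_end
    if t_end < t[-1]:
        keep = t <= t_end
        tt = t[keep]
        cc = c[keep]
        if tt[-1] < t_end:
            j = int(np.searchsorted(t, t_end))
            c_interp = _interp(t[j - 1], c[j - 1], t[j], c[j], t_end, method)
            tt = np.append(tt, t_end)
            cc = np.append(cc, c_interp)
    else:
        tt, cc = t, c

    auc = 0.0
    aumc = 0.0
    for i in range(1, len(tt)):
        dt = tt[i] - tt[i - 1]
        c1, c2 = cc[i - 1], cc[i]
        if method == "linear_up_log_down" and c1 > c2 > 0:
            k = math.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (tt[i - 1] * c1 - tt[i] * c2) / k + (c1 - c2) / k**2
        else:
            auc += 0.5 * dt * (c1 + c2)
            aumc += 0.5 * dt * (tt[i - 1] * c1 + tt[i] * c2)
    return float(auc), float(aumc)


def _interp(t1: float, c1: float, t2: float, c2: float, t: float, method: str) -> float:
    if method == "linear_up_log_down" and c1 > c2 > 0:
        k = math.log(c1 / c2) / (t2 - t1)
        return c1 * math.exp(-k * (t - t1))
    return c1 + (c2 - c1) * (t - t1) / (t2 - t1)


def fit_lambda_z(profile: ConcentrationTimeProfile,
                 points: Sequence[int] | None = None
                 ) -> tuple[float | None, float | None, int]:
    """Terminal elimination rate constant by log-linear regression.

    Returns (lambda_z, adjusted r², n points used); (None, None, 0) when no
    acceptable fit exists.  Candidate sets are the last 3..k quantifiable
    points after Tmax (Cmax itself excluded for extravascular routes); the
    set maximizing adjusted r² wins, ties toward more points.  ``points``
    (indices into the profile) overrides the automatic choice.
    """
    t = profile.times
    c = profile.concentrations
    usable = (~profile.bloq) & (c > 0)

    if points is not None:
        idx = np.asarray(points, dtype=int)
        if len(idx) < 3:
            raise ValueError("manual λz selection needs >= 3 points")
        return _loglin(t[idx], c[idx])

    pos = np.flatnonzero(usable)
    if len(pos) == 0:
        return None, None, 0
    i_cmax = pos[np.argmax(c[pos])]
    after = pos[pos > i_cmax] if profile.route == "oral" else pos[pos >= i_cmax]
    if len(after) < 3:
        return None, None, 0

    best: tuple[float, float, int] | None = None
    for k in range(3, len(after) + 1):
        sel = after[-k:]
        lam, r2adj, n = _loglin(t[sel], c[sel])
        if lam is None:
            continue
        # strict improvement required, so larger sets win ties
        if best is None or r2adj > best[1] + 1e-12:
            best = (lam, r2adj, n)
    if best is None:
        return None, None, 0
    return best


def _loglin(t: np.ndarray, c: np.ndarray) -> tuple[float | None, float | None, int]:
    if np.all(c == c[0]):
        return None, None, 0
    fit = stats.linregress(t, np.log(c))
    if fit.slope >= 0:
        return None, None, 0
    n = len(t)
    r2 = fit.rvalue ** 2
    r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return -fit.slope, r2adj, n


def single_dose_nca(profile: ConcentrationTimeProfile,
                    method: str = "linear",
                    lambda_points: Sequence[int] | None = None) -> NCAResult:
    """Full single-dose NCA parameter set for one profile.

    Extrapolated (*_0inf) quantities use the tail terms C_last/λz (AUC) and
    C_last·t_last/λz + C_last/λz² (AUMC); they are flagged missing when no
    λz can be estimated.
    """
    t = profile.times
    c = profile.concentrations
    usable = (~profile.bloq) & (c > 0)
    if not np.any(usable):
        raise ValueError("no quantifiable data")
    pos = np.flatnonzero(usable)
    i_cmax = pos[np.argmax(c[pos])]
    cmax = float(c[i_cmax])
    tmax = float(t[i_cmax])

    auc_0t, aumc_0t = auc_trapezoid(profile, method=method)
    mrt_0t = aumc_0t / auc_0t
    res = NCAResult(subject_id=profile.subject_id, dose=profile.dose,
                    route=profile.route, auc_0t=auc_0t, aumc_0t=aumc_0t,
                    cmax=cmax, tmax=tmax, mrt_0t=mrt_0t)

    lam, r2adj, n_lam = fit_lambda_z(profile, points=lambda_points)
    if lam is None:
        res.flags["lambda_z_missing"] = True
        return res

    i_last = pos[-1]
    c_last, t_last = float(c[i_last]), float(t[i_last])
    res.lambda_z = lam
    res.t_half_z = math.log(2.0) / lam
    res.lambda_r2adj = r2adj
    res.n_lambda = n_lam
    res.auc_0inf = auc_0t + c_last / lam
    res.aumc_0inf = aumc_0t + c_last * t_last / lam + c_last / lam**2
    res.mrt_0inf = res.aumc_0inf / res.auc_0inf
    res.extrap_pct = 100.0 * (res.auc_0inf - auc_0t) / res.auc_0inf
    if res.extrap_pct > EXTRAPOLATION_WARN_PCT:
        res.flags["high_extrapolation"] = True
    # dose mg/kg -> μg/kg over μg/L·h -> L/h/kg
    res.cl_f = profile.dose * 1000.0 / res.auc_0inf
    res.vz_f = res.cl_f / lam
    return res


def bioavailability(po: Sequence[NCAResult], iv: Sequence[NCAResult],
                    pairing: str = "by_subject",
                    metric: str = "auc_0t") -> float:
    """Absolute bioavailability F (%) from oral and intravenous arms.

    Dose-normalized AUC ratio × 100.  ``by_subject`` averages per-subject
    ratios matched on subject_id (crossover design); ``ratio_of_means``
    divides the group mean dose-normalized AUCs.
    """
    if not iv:
        raise ValueError("missing iv arm")
    if not po:
        raise ValueError("missing oral arm")

    def _dn(r: NCAResult) -> float:
        value = getattr(r, metric)
        if value is None:
            raise ValueError(f"{metric} missing for subject {r.subject_id}")
        return value / r.dose

    if pairing == "ratio_of_means":
        return 100.0 * float(np.mean([_dn(r) for r in po])) / float(np.mean([_dn(r) for r in iv]))
    if pairing == "by_subject":
        iv_by_id = {r.subject_id: r for r in iv}
        ratios = []
        for r in po:
            if r.subject_id not in iv_by_id:
                raise ValueError(f"no iv match for subject {r.subject_id}")
            ratios.append(_dn(r) / _dn(iv_by_id[r.subject_id]))
        return 100.0 * float(np.mean(ratios))
    raise ValueError(f"unknown pairing {pairing!r}")


def steady_state_metrics(profile: ConcentrationTimeProfile,
                         troughs: Sequence[float] | None = None,
                         first_dose_auc_0tau: float | None = None,
                         method: str = "linear") -> SteadyStateResult:
    """Steady-state metrics over one dosing interval from a last-dose profile.

    AUC_ss is the trapezoid over [0, τ]; C_av = AUC_ss/τ; the degree of
    fluctuation DF = (Cmax − Cmin)/C_av.  With pre-dose trough values a
    flatness check (regression slope p ≥ 0.05) confirms steady state; with a
    first-dose AUC_0τ the accumulation index AUC_ss/AUC_0τ is added.
    """
    if profile.tau is None:
        raise ValueError("dosing interval tau missing")
    tau = profile.tau
    if profile.times[-1] < tau:
        raise ValueError("profile does not cover one full dosing interval")
    auc_ss, _ = auc_trapezoid(profile, t_end=tau, method=method)
    c_av = auc_ss / tau
    within = profile.times <= tau
    c = _working_concentrations(profile)[within]
    c_max = float(c.max())
    c_min = float(c.min())
    df = (c_max - c_min) / c_av if c_av > 0 else 0.0
    res = SteadyStateResult(auc_ss=auc_ss, c_av=c_av, c_min=c_min,
                            c_max=c_max, df=df)
    if first_dose_auc_0tau is not None:
        res.accumulation_index = auc_ss / first_dose_auc_0tau
    if troughs is not None and len(troughs) >= 3:
        fit = stats.linregress(np.arange(len(troughs)), np.asarray(troughs, float))
        res.troughs_flat = bool(fit.pvalue >= 0.05)
        if not res.troughs_flat:
            res.flags["trough_trend"] = True
    return res


def dose_proportionality(results: Mapping[float, Sequence[NCAResult]],
                         metric: str = "auc_0t"
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dose-normalized exposure ratios across dose groups.

    Returns (doses, metric ratios, dose ratios), each normalized to the
    lowest dose group.  Ratios exceeding the dose ratios indicate
    supra-proportional exposure (saturable elimination).
    """
    if len(results) < 2:
        raise ValueError("need >= 2 dose groups")
    doses = np.array(sorted(results))
    means = []
    for d in doses:
        group = results[d]
        if not group:
            raise ValueError(f"empty group at dose {d}")
        vals = [getattr(r, metric) for r in group]
        if any(v is None for v in vals):
            raise ValueError(f"{metric} missing in dose group {d}")
        means.append(float(np.mean(vals)))
    means = np.array(means)
    return doses, means / means[0], doses / doses[0]
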