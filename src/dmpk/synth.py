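"""Synthetic assay-data generators with known ground truth.

Every analysis stage in the package can be exercised against data whose
true parameters are chosen up front, so each estimator can be checked by
inversion: at zero noise the analysis must recover the generator's inputs.

Models
------
* one-compartment oral / IV-bolus / multiple-dose kinetics with
  multiplicative log-normal residual noise (default CV 5%) and log-normal
  between-subject variability on ka, ke and V (default CV 20%)
* mono-exponential microsomal depletion with an optional post-window plateau
* linear receiver-flux monolayer transport with periodic
  sampling-and-replacement applied to the emitted concentrations
* 4-parameter logistic CYP inhibition curves
* Kp-scaled tissue panels over a sparse destructive-sampling design
* fractional excretion records over the standard five collection intervals

Default designs mirror the package's reference study conditions: rat
sampling at 0, 2, 5, 15, 30 min and 1–24 h, dog sampling at 0, 5–45 min and
1–24 h, transport sampling at 15–120 min with 50 μL aliquots, depletion at
0–120 min, inhibitor concentrations 0.1–100 μmol/L, tissue sampling at
0.25/2/6/24 h, and excretion intervals 0–5, 5–12, 12–24, 24–48, 48–72 h.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .binding import TissuePanel
from .cyp import InhibitionSeries
from .excretion import ExcretionRecord
from .io import ConcentrationTimeProfile
from .stability import DepletionSeries
from .transport import TransportExperiment

__all__ = [
    "SimConfig",
    "RAT_PK_TIMES_H",
    "DOG_PK_TIMES_H",
    "TRANSPORT_TIMES_MIN",
    "DEPLETION_TIMES_MIN",
    "INHIBITOR_CONCS_UMOL",
    "TISSUE_TIMES_H",
    "EXCRETION_INTERVALS_H",
    "simulate",
    "simulate_pk",
    "simulate_depletion",
    "simulate_transport",
    "simulate_inhibition",
    "simulate_tissue",
    "simulate_excretion",
]

logger = logging.getLogger("dmpk.synth")

RAT_PK_TIMES_H = np.array([0, 2 / 60, 5 / 60, 15 / 60, 30 / 60, 1, 2, 4, 6, 8, 12, 24.0])
DOG_PK_TIMES_H = np.array([0, 5 / 60, 15 / 60, 30 / 60, 45 / 60, 1, 2, 4, 6, 8, 12, 24.0])
TRANSPORT_TIMES_MIN = np.array([15.0, 30, 45, 60, 90, 120])
DEPLETION_TIMES_MIN = np.array([0.0, 2, 5, 10, 15, 30, 60, 90, 120])
INHIBITOR_CONCS_UMOL = np.array([0.1, 1.0, 10.0, 50.0, 100.0])
TISSUE_TIMES_H = np.array([0.25, 2.0, 6.0, 24.0])
EXCRETION_INTERVALS_H = [(0.0, 5.0), (5.0, 12.0), (12.0, 24.0), (24.0, 48.0), (48.0, 72.0)]

_MODELS = ("oral_1cmt", "iv_1cmt", "multidose_1cmt", "depletion",
           "transport", "inhibition", "tissue_panel", "excretion")


@dataclass
class SimConfig:
    """Seeded configuration for one synthetic-data model."""

    seed: int
    model: str
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {_MODELS}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        if self.parameters.get("noise_cv", 0.0) < 0:
            raise ValueError("noise_cv must be >= 0")


def _rng(cfg: SimConfig) -> np.random.Generator:
    return np.random.default_rng(cfg.seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Unit-median multiplicative noise with the requested CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def simulate(cfg: SimConfig):
    """Dispatch a configuration to its generator."""
    return {
        "oral_1cmt": simulate_pk, "iv_1cmt": simulate_pk,
        "multidose_1cmt": simulate_pk, "depletion": simulate_depletion,
        "transport": simulate_transport, "inhibition": simulate_inhibition,
        "tissue_panel": simulate_tissue, "excretion": simulate_excretion,
    }[cfg.model](cfg)


# ---------------------------------------------------------------------------
# One-compartment kinetics


def oral_1cmt_conc(t: np.ndarray, dose: float, ka: float, ke: float,
                   v: float, f: float = 1.0) -> np.ndarray:
    """First-order absorption concentration, μg/L (dose mg/kg, V L/kg).

    Falls back to the ka→ke limiting form F·D·ka·t·e^(−ka·t)/V when the two
    rate constants coincide.
    """
    t = np.asarray(t, dtype=float)
    if np.isclose(ka, ke, rtol=1e-9):
        c = f * dose * ka * t * np.exp(-ka * t) / v
    else:
        c = f * dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    return 1000.0 * np.maximum(c, 0.0)   # mg/L -> μg/L


def iv_1cmt_conc(t: np.ndarray, dose: float, ke: float, v: float) -> np.ndarray:
    """IV-bolus concentration, μg/L."""
    return 1000.0 * (dose / v) * np.exp(-ke * np.asarray(t, dtype=float))


def simulate_pk(cfg: SimConfig) -> list[ConcentrationTimeProfile]:
    """Simulate concentration-time profiles for a cohort of subjects.

    Parameters (cfg.parameters): dose mg/kg, ka 1/h (oral), ke 1/h, v L/kg,
    f fraction (oral), species, times h, n_subjects, noise_cv, bsv_cv,
    loq μg/L; multidose additionally tau h and n_doses (times are then
    measured from the last dose).
    """
    p = cfg.parameters
    rng = _rng(cfg)
    species = p.get("species", "rat")
    times = np.asarray(p.get("times", RAT_PK_TIMES_H if species == "rat"
                             else DOG_PK_TIMES_H), dtype=float)
    dose = float(p.get("dose", 20.0))
    ke = float(p.get("ke", 0.18))
    v = float(p.get("v", 8.0))
    ka = float(p.get("ka", 2.0))
    f = float(p.get("f", 0.42))
    n_subjects = int(p.get("n_subjects", 6))
    noise_cv = float(p.get("noise_cv", 0.05))
    bsv_cv = float(p.get("bsv_cv", 0.20))
    loq = float(p.get("loq", 0.0))
    tau = float(p.get("tau", 12.0))
    n_doses = int(p.get("n_doses", 8))

    profiles = []
    for i in range(n_subjects):
        eta = _lognormal_factor(rng, bsv_cv, size=3)
        ka_i, ke_i, v_i = ka * eta[0], ke * eta[1], v * eta[2]
        if cfg.model == "iv_1cmt":
            conc = iv_1cmt_conc(times, dose, ke_i, v_i)
            route = "iv"
            tau_out = None
        elif cfg.model == "oral_1cmt":
            conc = oral_1cmt_conc(times, dose, ka_i, ke_i, v_i, f)
            route = "oral"
            tau_out = None
        else:  # multidose_1cmt: superposition over prior doses every tau
            conc = np.zeros_like(times)
            for j in range(n_doses):
                conc += oral_1cmt_conc(times + j * tau, dose, ka_i, ke_i, v_i, f)
            route = "oral"
            tau_out = tau
        conc = conc * _lognormal_factor(rng, noise_cv, size=len(times))
        if cfg.model == "oral_1cmt" and times[0] == 0:
            conc[0] = 0.0   # pre-dose sample
        profiles.append(ConcentrationTimeProfile(
            subject_id=f"S{i + 1:02d}", species=species, matrix="plasma",
            route=route, dose=dose, times=times, concentrations=conc,
            loq=loq, tau=tau_out))
    return profiles


# ---------------------------------------------------------------------------
# Microsomal depletion


def simulate_depletion(cfg: SimConfig) -> list[DepletionSeries]:
    """Mono-exponential depletion replicates, remaining % of t=0.

    Parameters: ke 1/min, times min, n_replicates, noise_cv,
    plateau_after min (concentration freezes past this time, emulating
    saturating early kinetics), incubation_protein mg/mL, species.
    """
    p = cfg.parameters
    rng = _rng(cfg)
    ke = float(p.get("ke", 0.693 / 249.30))
    times = np.asarray(p.get("times", DEPLETION_TIMES_MIN), dtype=float)
    n_rep = int(p.get("n_replicates", 3))
    noise_cv = float(p.get("noise_cv", 0.0))
    plateau_after = p.get("plateau_after")
    protein = float(p.get("incubation_protein", 0.2))
    species = p.get("species", "human")

    out = []
    for _ in range(n_rep):
        remaining = 100.0 * np.exp(-ke * times)
        if plateau_after is not None:
            level = 100.0 * np.exp(-ke * float(plateau_after))
            remaining = np.where(times > plateau_after, level, remaining)
        noisy = remaining * _lognormal_factor(rng, noise_cv, size=len(times))
        noisy[times == 0] = remaining[times == 0]
        out.append(DepletionSeries(species=species, times=times,
                                   remaining=noisy,
                                   incubation_protein=protein))
    return out


# ---------------------------------------------------------------------------
# Monolayer transport


def simulate_transport(cfg: SimConfig) -> tuple[TransportExperiment, TransportExperiment]:
    """Paired A→B / B→A transport runs under linear (sink) flux.

    The passive permeability ``papp`` is split asymmetrically by the efflux
    factor: Papp(A→B) = papp/√ef and Papp(B→A) = papp·√ef, so the true
    efflux ratio equals ``efflux_factor``.  ``inhibitor`` mode sets ef = 1
    (efflux fully blocked), which raises the A→B permeability.  Sampling
    aliquots are removed and replaced with blank buffer in the forward
    model, so emitted receiver concentrations require the replacement
    correction to reconstruct cumulative flux.
    """
    p = cfg.parameters
    rng = _rng(cfg)
    papp = float(p.get("papp", 1.0e-5))              # passive, cm/s
    ef = 1.0 if p.get("inhibitor") else float(p.get("efflux_factor", 1.9))
    c0 = float(p.get("c0", 1.0))                      # μg/mL
    times = np.asarray(p.get("times", TRANSPORT_TIMES_MIN), dtype=float)
    area = float(p.get("area", 0.33))
    noise_cv = float(p.get("noise_cv", 0.0))
    geom = {
        "AtoB": (float(p.get("donor_ab", 400.0)), float(p.get("receiver_ab", 1200.0))),
        "BtoA": (float(p.get("donor_ba", 1200.0)), float(p.get("receiver_ba", 400.0))),
    }
    sample_volume = float(p.get("sample_volume", 50.0))
    inhibitor = "verapamil" if p.get("inhibitor") else None

    def _run(direction: str, papp_true: float) -> TransportExperiment:
        donor_v, receiver_v = geom[direction]
        v_r = receiver_v / 1000.0
        v_s = sample_volume / 1000.0
        q = 0.0                                       # μg in receiver
        t_prev = 0.0
        samples = []
        for t in times:
            q += papp_true * area * c0 * (t - t_prev) * 60.0
            c_meas = (q / v_r) * _lognormal_factor(rng, noise_cv)
            samples.append((float(t), float(c_meas)))
            q -= (q / v_r) * v_s                      # aliquot removed, buffer replaced
            t_prev = t
        return TransportExperiment(direction=direction, c0=c0, samples=samples,
                                   area=area, donor_volume=donor_v,
                                   receiver_volume=receiver_v,
                                   sample_volume=sample_volume,
                                   inhibitor=inhibitor)

    return _run("AtoB", papp / np.sqrt(ef)), _run("BtoA", papp * np.sqrt(ef))


# ---------------------------------------------------------------------------
# CYP inhibition


def simulate_inhibition(cfg: SimConfig) -> InhibitionSeries:
    """Logistic residual-activity series for one isoform.

    Parameters: ic50 μmol/L, hill, top %, bottom %, concs μmol/L,
    n_replicates, noise_cv, isoform.
    """
    p = cfg.parameters
    rng = _rng(cfg)
    ic50 = float(p.get("ic50", 25.0))
    hill = float(p.get("hill", 1.0))
    top = float(p.get("top", 100.0))
    bottom = float(p.get("bottom", 0.0))
    concs = np.asarray(p.get("concs", INHIBITOR_CONCS_UMOL), dtype=float)
    n_rep = int(p.get("n_replicates", 3))
    noise_cv = float(p.get("noise_cv", 0.03))
    activity = bottom + (top - bottom) / (1.0 + (concs / ic50) ** hill)
    reps = activity[:, None] * _lognormal_factor(rng, noise_cv, size=(len(concs), n_rep))
    return InhibitionSeries(isoform=p.get("isoform", "2D6"),
                            inhibitor_conc=concs, activity_pct=reps,
                            substrate=p.get("substrate", "probe"),
                            substrate_conc=p.get("substrate_conc"))


# ---------------------------------------------------------------------------
# Tissue distribution


#: tissue-to-blood partition defaults emulating a lipophilic CNS compound
DEFAULT_KP = {
    "lung": 155.0, "liver": 81.0, "intestine": 76.0, "stomach": 49.0,
    "spleen": 46.0, "kidney": 38.0, "testis": 27.0, "brain": 23.0,
    "heart": 17.0, "fat": 14.0, "muscle": 9.3,
}


def simulate_tissue(cfg: SimConfig) -> TissuePanel:
    """Sparse tissue panel: Kp-scaled copies of a blood oral profile.

    Parameters: kp (matrix→partition map), dose mg/kg, ka/ke 1/h, v L/kg,
    f, times h, noise_cv.  Default kinetics put the blood peak at ~2 h.
    """
    p = cfg.parameters
    rng = _rng(cfg)
    kp = dict(p.get("kp", DEFAULT_KP))
    times = np.asarray(p.get("times", TISSUE_TIMES_H), dtype=float)
    blood = oral_1cmt_conc(times, dose=float(p.get("dose", 20.0)),
                           ka=float(p.get("ka", 1.0)), ke=float(p.get("ke", 0.2)),
                           v=float(p.get("v", 8.0)), f=float(p.get("f", 0.42)))
    noise_cv = float(p.get("noise_cv", 0.0))
    profiles = {"blood": (times, blood * _lognormal_factor(rng, noise_cv, len(times)))}
    for tissue, k in kp.items():
        profiles[tissue] = (times, blood * k * _lognormal_factor(rng, noise_cv, len(times)))
    return TissuePanel(profiles=profiles, n_per_timepoint=int(p.get("n", 6)))


# ---------------------------------------------------------------------------
# Excretion


#: per-interval excretion as % of dose, by route (study-condition defaults)
DEFAULT_INTERVAL_PCT = {
    "feces": [0.010, 0.206, 0.145, 0.019, 0.002],
    "urine": [0.116, 0.107, 0.050, 0.014, 0.005],
    "bile": [0.089, 0.182, 0.149, 0.000, 0.016],
}


def simulate_excretion(cfg: SimConfig) -> list[ExcretionRecord]:
    """Excretion records whose programmed % of dose is exactly recoverable.

    Parameters: interval_pct (route→list of % per interval), dose mg/kg,
    body_weight_kg, noise_cv, dilution_factor (feces homogenate).  Matrix
    amounts use typical rat urine volumes, fecal dry masses and bile
    volumes; concentrations are back-calculated so that
    ``interval_pct_dose`` inverts the programmed fractions.
    """
    p = cfg.parameters
    rng = _rng(cfg)
    interval_pct = p.get("interval_pct", DEFAULT_INTERVAL_PCT)
    dose = float(p.get("dose", 20.0))
    bw = float(p.get("body_weight_kg", 0.2))
    noise_cv = float(p.get("noise_cv", 0.0))
    dilution = float(p.get("dilution_factor", 10.0))
    amounts = {"urine": 5.0, "feces": 1.5, "bile": 3.0}   # mL, g, mL per interval

    dose_ug = dose * bw * 1000.0
    records = []
    for route, pcts in interval_pct.items():
        if len(pcts) != len(EXCRETION_INTERVALS_H):
            raise ValueError(f"{route}: expected {len(EXCRETION_INTERVALS_H)} intervals")
        for (start, end), pct in zip(EXCRETION_INTERVALS_H, pcts):
            matrix_amount = amounts[route]
            dil = dilution if route == "feces" else None
            target_ug = pct / 100.0 * dose_ug
            conc = target_ug / (matrix_amount * (dil or 1.0))
            conc *= _lognormal_factor(rng, noise_cv)
            records.append(ExcretionRecord(route=route, interval=(start, end),
                                           matrix_amount=matrix_amount,
                                           conc=conc, dilution_factor=dil))
    return records
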