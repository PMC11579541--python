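"""Assay dispatch: structured config in, serializable report out.

Each assay has a small documented CSV schema (see the reader functions) and
a runner that turns the parsed inputs into an :class:`~dmpk.io.AnalysisReport`
whose every numeric parameter carries units and flags.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .binding import PPBMeasurement, TissuePanel, composite_tissue_auc, \
    peak_profile_summary, ppb_rate
from .cyp import InhibitionSeries, classify_inhibition, fit_ic50, \
    transformation_ratio
from .excretion import ExcretionRecord, cumulative_curve, interval_pct_dose, \
    total_recovery
from .io import AnalysisReport, DEFAULT_SCALING, file_digest, read_profiles
from .nca import bioavailability, single_dose_nca, steady_state_metrics
from .stability import DepletionSeries, analyze_depletion
from .transport import TransportExperiment, apparent_permeability, efflux_ratio

__all__ = ["run_pipeline", "ASSAYS"]

logger = logging.getLogger("dmpk.pipeline")


# ---------------------------------------------------------------------------
# Assay-specific table readers


def read_transport(path: str | Path) -> list[TransportExperiment]:
    """Schema: direction, c0, area_cm2, donor_ul, receiver_ul, sample_ul,
    time_min, conc[, inhibitor] — one row per sampled time point."""
    df = pd.read_csv(path)
    exps = []
    keys = ["direction", "c0"] + (["inhibitor"] if "inhibitor" in df.columns else [])
    for key, grp in df.groupby(keys, sort=False, dropna=False):
        grp = grp.sort_values("time_min")
        first = grp.iloc[0]
        inhibitor = None
        if "inhibitor" in grp.columns and not pd.isna(first["inhibitor"]):
            inhibitor = str(first["inhibitor"])
        exps.append(TransportExperiment(
            direction=str(first["direction"]), c0=float(first["c0"]),
            samples=list(zip(grp["time_min"].astype(float),
                             grp["conc"].astype(float))),
            area=float(first.get("area_cm2", 0.33)),
            donor_volume=float(first.get("donor_ul", 400.0)),
            receiver_volume=float(first.get("receiver_ul", 1200.0)),
            sample_volume=float(first.get("sample_ul", 50.0)),
            inhibitor=inhibitor))
    return exps


def read_depletion(path: str | Path, species: str,
                   incubation_protein: float = 0.2) -> list[DepletionSeries]:
    """Schema: species, replicate, time_min, remaining — % of t=0 or conc."""
    df = pd.read_csv(path)
    df = df[df["species"] == species]
    if df.empty:
        raise ValueError(f"no depletion rows for species {species!r}")
    return [
        DepletionSeries(species=species,
                        times=grp["time_min"].to_numpy(float),
                        remaining=grp["remaining"].to_numpy(float),
                        incubation_protein=incubation_protein)
        for _, grp in df.groupby("replicate", sort=True)
    ]


def read_inhibition(path: str | Path) -> list[InhibitionSeries]:
    """Schema: isoform, inhibitor_conc, replicate, activity_pct."""
    df = pd.read_csv(path)
    out = []
    for isoform, grp in df.groupby("isoform", sort=False):
        wide = grp.pivot_table(index="inhibitor_conc", columns="replicate",
                               values="activity_pct").sort_index()
        out.append(InhibitionSeries(isoform=str(isoform),
                                    inhibitor_conc=wide.index.to_numpy(float),
                                    activity_pct=wide.to_numpy(float)))
    return out


def read_ppb(path: str | Path) -> list[PPBMeasurement]:
    """Schema: species, nominal_conc, ct, cf — one row per replicate."""
    df = pd.read_csv(path)
    return [PPBMeasurement(species=r.species, nominal_conc=float(r.nominal_conc),
                           ct=float(r.ct), cf=float(r.cf))
            for r in df.itertuples()]


def read_tissue_panel(path: str | Path) -> TissuePanel:
    """Schema: matrix, time_h, conc — mean concentration per time point."""
    df = pd.read_csv(path)
    profiles = {
        str(matrix): (grp.sort_values("time_h")["time_h"].to_numpy(float),
                      grp.sort_values("time_h")["conc"].to_numpy(float))
        for matrix, grp in df.groupby("matrix", sort=False)
    }
    return TissuePanel(profiles=profiles)


def read_excretion(path: str | Path) -> list[ExcretionRecord]:
    """Schema: route, start_h, end_h, matrix_amount, conc[, dilution_factor]."""
    df = pd.read_csv(path)
    records = []
    for r in df.itertuples():
        dil = getattr(r, "dilution_factor", None)
        dil = None if dil is None or pd.isna(dil) else float(dil)
        records.append(ExcretionRecord(route=str(r.route),
                                       interval=(float(r.start_h), float(r.end_h)),
                                       matrix_amount=float(r.matrix_amount),
                                       conc=float(r.conc), dilution_factor=dil))
    return records


# ---------------------------------------------------------------------------
# Assay runners


def _provenance(config: Mapping[str, Any]) -> dict[str, Any]:
    digests = {}
    for key, value in config.items():
        if isinstance(value, str) and Path(value).is_file():
            digests[key] = file_digest(value)
    return {"software_version": __version__, "config": dict(config),
            "input_digests": digests}


def _run_stability(config: Mapping[str, Any]) -> AnalysisReport:
    species = config["species"]
    reps = read_depletion(config["input"], species,
                          float(config.get("incubation_protein", 0.2)))
    res = analyze_depletion(reps, scaling=DEFAULT_SCALING,
                            use_exact_ln2=bool(config.get("use_exact_ln2", False)))
    report = AnalysisReport(assay="stability", provenance=_provenance(config))
    report.add("t_half", res.t_half, "min", stable=res.stable,
               window=list(res.window_used))
    report.add("ke", res.ke, "1/min")
    report.add("r2", res.r2, "unitless")
    report.add("cl_int", res.cl_int, "mL/min/kg")
    report.add("cl_h", res.cl_h, "mL/min/kg",
               qh=DEFAULT_SCALING.hepatic_flow(species))
    return report


def _run_nca(config: Mapping[str, Any]) -> AnalysisReport:
    profiles = read_profiles(config["input"])
    method = config.get("auc_method", "linear")
    report = AnalysisReport(assay="nca", provenance=_provenance(config))
    results = [single_dose_nca(p, method=method) for p in profiles]
    fields = [("auc_0t", "ug/L*h"), ("auc_0inf", "ug/L*h"), ("mrt_0t", "h"),
              ("mrt_0inf", "h"), ("t_half_z", "h"), ("tmax", "h"),
              ("cl_f", "L/h/kg"), ("vz_f", "L/kg"), ("cmax", "ug/L")]
    for name, units in fields:
        vals = [getattr(r, name) for r in results]
        known = [v for v in vals if v is not None]
        if not known:
            report.add(name, None, units, missing=True)
            continue
        report.add(name, float(np.mean(known)), units,
                   n=len(known), sd=float(np.std(known, ddof=1)) if len(known) > 1 else 0.0,
                   extrapolation_flagged=any(r.flags.get("high_extrapolation")
                                             for r in results))
    return report


def _run_bioavailability(config: Mapping[str, Any]) -> AnalysisReport:
    po = [single_dose_nca(p) for p in read_profiles(config["po"])]
    iv = [single_dose_nca(p) for p in read_profiles(config["iv"])]
    pairing = config.get("pairing", "by_subject")
    report = AnalysisReport(assay="bioavailability", provenance=_provenance(config))
    for metric in ("auc_0t", "auc_0inf"):
        report.add(f"f_{metric}", bioavailability(po, iv, pairing=pairing,
                                                  metric=metric),
                   "%", pairing=pairing)
    return report


def _run_steadystate(config: Mapping[str, Any]) -> AnalysisReport:
    profiles = read_profiles(config["input"])
    tau = config.get("tau")
    report = AnalysisReport(assay="steadystate", provenance=_provenance(config))
    per = []
    for p in profiles:
        if tau is not None:
            p.tau = float(tau)
        per.append(steady_state_metrics(p, troughs=config.get("troughs")))
    report.add("auc_ss", float(np.mean([r.auc_ss for r in per])), "ug/L*h")
    report.add("c_av", float(np.mean([r.c_av for r in per])), "ug/L")
    report.add("c_max", float(np.mean([r.c_max for r in per])), "ug/L")
    report.add("c_min", float(np.mean([r.c_min for r in per])), "ug/L")
    report.add("df", float(np.mean([r.df for r in per])), "unitless")
    return report


def _run_transport(config: Mapping[str, Any]) -> AnalysisReport:
    exps = read_transport(config["input"])
    correct = bool(config.get("correct_sampling", True))
    report = AnalysisReport(assay="transport", provenance=_provenance(config))
    by_dir = {}
    for exp in exps:
        res = apparent_permeability(exp, correct_sampling=correct)
        by_dir[exp.direction] = res
        report.add(f"papp_{exp.direction}_c0_{exp.c0:g}", res.papp, "cm/s",
                   r2=res.slope_r2, **res.flags)
    if {"AtoB", "BtoA"} <= set(by_dir):
        paired = efflux_ratio(by_dir["AtoB"], by_dir["BtoA"])
        report.add("efflux_ratio", paired.er, "unitless", **paired.flags)
    return report


def _run_ppb(config: Mapping[str, Any]) -> AnalysisReport:
    measurements = read_ppb(config["input"])
    report = AnalysisReport(assay="ppb", provenance=_provenance(config))
    df = pd.DataFrame([{"species": m.species, "nominal": m.nominal_conc,
                        "binding_pct": ppb_rate(m)} for m in measurements])
    for (species, nominal), grp in df.groupby(["species", "nominal"]):
        report.add(f"binding_{species}_{nominal:g}",
                   float(grp["binding_pct"].mean()), "%",
                   n=len(grp), sd=float(grp["binding_pct"].std(ddof=1))
                   if len(grp) > 1 else 0.0)
    return report


def _run_tissue(config: Mapping[str, Any]) -> AnalysisReport:
    panel = composite_tissue_auc(read_tissue_panel(config["input"]))
    peaks = peak_profile_summary(panel)
    report = AnalysisReport(assay="tissue", provenance=_provenance(config))
    for matrix, auc in panel.auc_0t.items():
        units = "ug/L*h" if matrix == "blood" else "ng/g*h"
        report.add(f"auc_0t_{matrix}", auc, units,
                   fraction_of_total_pct=panel.fraction_of_total[matrix])
    for matrix, ratio in panel.ratio_to_blood.items():
        report.add(f"ratio_{matrix}", ratio, "unitless")
    report.add("no_tissue_accumulation",
               peaks.attrs["no_tissue_accumulation"], "flag")
    return report


def _run_excretion(config: Mapping[str, Any]) -> AnalysisReport:
    records = read_excretion(config["input"])
    dose = float(config["dose_mg_per_kg"])
    bw = float(config["body_weight_kg"])
    report = AnalysisReport(assay="excretion", provenance=_provenance(config))
    finals = {}
    for route in sorted({r.route for r in records}):
        recs = sorted((r for r in records if r.route == route),
                      key=lambda r: r.interval[0])
        pcts = [interval_pct_dose(r, dose, bw) for r in recs]
        cum = cumulative_curve(pcts)
        finals[route] = float(cum[-1])
        report.add(f"cumulative_{route}", float(cum[-1]), "% of dose",
                   per_interval=pcts, cumulative=list(cum))
    total, extensive = total_recovery(finals)
    report.add("total_recovery", total, "% of dose",
               extensive_metabolism=extensive)
    return report


def _run_inhibition(config: Mapping[str, Any]) -> AnalysisReport:
    series = read_inhibition(config["input"])
    report = AnalysisReport(assay="inhibition", provenance=_provenance(config))
    for s in series:
        res = fit_ic50(s)
        report.add(f"ic50_{s.isoform}", res.ic50, "umol/L",
                   censored=res.censored,
                   classification=classify_inhibition(res),
                   max_inhibition_pct=res.max_inhibition_pct, **res.flags)
    return report


def _run_phenotyping(config: Mapping[str, Any]) -> AnalysisReport:
    """Schema: isoform, remaining, control[, nadph_free_remaining]."""
    df = pd.read_csv(config["input"])
    report = AnalysisReport(assay="phenotyping", provenance=_provenance(config))
    for r in df.itertuples():
        nadph_free = getattr(r, "nadph_free_remaining", None)
        nadph_free = None if nadph_free is None or pd.isna(nadph_free) else float(nadph_free)
        res = transformation_ratio(float(r.remaining), float(r.control),
                                   isoform=str(r.isoform),
                                   nadph_free_remaining=nadph_free)
        report.add(f"transformed_{res.isoform}", res.transformed_pct, "%")
    return report


ASSAYS = {
    "stability": _run_stability,
    "nca": _run_nca,
    "f": _run_bioavailability,
    "steadystate": _run_steadystate,
    "transport": _run_transport,
    "ppb": _run_ppb,
    "tissue": _run_tissue,
    "excretion": _run_excretion,
    "inhibition": _run_inhibition,
    "phenotyping": _run_phenotyping,
}


def run_pipeline(config: Mapping[str, Any]) -> AnalysisReport:
    """Dispatch a structured config to its assay runner.

    ``config`` must contain an ``assay`` key naming one of :data:`ASSAYS`;
    the remaining keys are assay-specific (input paths, species, dose
    metadata).  Returns a report with units and flags on every parameter.
    """
    try:
        assay = config["assay"]
    except KeyError:
        raise ValueError("config must name an assay") from None
    try:
        runner = ASSAYS[assay]
    except KeyError:
        raise ValueError(
            f"unknown assay {assay!r}; choose from {sorted(ASSAYS)}") from None
    logger.info("running assay %s", assay)
    return runner(config)
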