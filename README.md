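# dmpk

A preclinical drug-metabolism-and-pharmacokinetics (DMPK) analysis toolkit
for discovery-stage scientists who need to turn raw assay tables —
bidirectional monolayer transport time courses, microsomal depletion
series, CYP cocktail-inhibition plates, ultrafiltration pairs,
concentration–time profiles, tissue panels and excreta collections — into
the standard derived parameters of a candidate-nomination data package.

## What it computes

**Permeability and efflux** (MDCK-MDR1 style assays). The apparent
permeability coefficient is the regression slope of cumulative receiver
amount against time, normalized by monolayer area and donor concentration:

    Papp = (dQ/dt) / (A · C0)          [cm/s]

with the sampling-and-replacement correction
Q(tₙ) = Cₙ·V_receiver + Σ_{i<n} Cᵢ·V_sample applied by default. The efflux
ratio ER = Papp(B→A)/Papp(A→B) flags P-glycoprotein substrates at ER > 1.5;
A→B Papp above 3×10⁻⁶ cm/s marks ready blood–brain-barrier passage. MTT
cytotoxicity curves are fit by a four-parameter logistic of relative growth
rate against ln(concentration) to yield a TC₅₀.

**Microsomal stability and IVIVE.** Parent depletion is fit log-linearly
(k_e, t½ = 0.693/k_e) over an automatically detected linear window, scaled
to intrinsic clearance

    CL_int = (0.693/t½) · (incubation mL / microsomal protein mg)
             · (mg microsomes / g liver) · (g liver / kg BW)

and capped by hepatic blood flow through the well-stirred liver model
CL_h = Q_h·CL_int/(Q_h + CL_int). Physiological constants (45 mg microsomal
protein per g liver; liver weights 40/32/30/25.7 g/kg and hepatic flows
55.2/30.9/43.6/20.7 mL/min/kg for rat/dog/monkey/human) ship as validated
defaults.

**CYP phenotyping and inhibition.** Transformation ratios against zero-time
controls for recombinant isoforms, and censored four-parameter-logistic
IC₅₀ fits for cocktail inhibition plates — curves that never reach 50%
inhibition are reported as "> top tested concentration", never
extrapolated.

**Non-compartmental PK.** Trapezoidal AUC/AUMC (linear or
linear-up/log-down), terminal λz by best-adjusted-r² log-linear regression,
Cmax/Tmax, MRT, CL/F and Vz/F with explicit unit handling, absolute
bioavailability F = AUC_po/AUC_iv × 100 (per-subject crossover or
ratio-of-means), steady-state metrics (AUC_ss, C_av = AUC_ss/τ, degree of
fluctuation), and dose-proportionality ratio vectors.

**Distribution and excretion.** Plasma protein binding
100·(C_t − C_f)/C_t from ultrafiltration pairs; composite
(destructive-sampling) tissue AUCs with tissue-to-blood ratios and
exposure fractions; interval and cumulative excretion as % of dose per
route with a total-recovery mass balance.

**Synthetic data.** Every assay has a seeded generator with known ground
truth (one-compartment kinetics, mono-exponential depletion, linear
receiver flux with sampling replacement, logistic inhibition, Kp-scaled
tissue panels, fractional excretion), so the whole pipeline is testable
end to end without animal data.

## Worked example

Simulate a human microsomal depletion series with a 249.3 min half-life
and run the stability analysis on it:

```bash
dmpk simulate --model depletion --seed 7 --out fixtures/
dmpk stability --input fixtures/depletion.csv --species human --out report.json
```

`report.json` contains (values abridged):

```json
{
  "assay": "stability",
  "parameters": {
    "t_half": {"value": 249.3, "units": "min", "flags": {"stable": false, "window": [0.0, 120.0]}},
    "ke":     {"value": 0.00278, "units": "1/min", "flags": {}},
    "cl_int": {"value": 16.07, "units": "mL/min/kg", "flags": {}},
    "cl_h":   {"value": 9.05, "units": "mL/min/kg", "flags": {"qh": 20.7}}
  }
}
```

Read: the compound depletes with a 249 min half-life in human liver
microsomes, scaling to an intrinsic clearance of 16.1 mL/min/kg and a
predicted hepatic clearance of 9.1 mL/min/kg — well below hepatic blood
flow (20.7 mL/min/kg), i.e. a low-extraction compound in human.

The same pattern works for every assay (`dmpk nca`, `dmpk f`,
`dmpk steadystate`, `dmpk transport`, `dmpk ppb`, `dmpk tissue`,
`dmpk excretion`, `dmpk inhibition`, `dmpk phenotyping`), or from Python:

```python
from dmpk import intrinsic_clearance, hepatic_clearance
cl_int = intrinsic_clearance(t_half=249.30, incubation_protein=0.2, species="human")
cl_h = hepatic_clearance(cl_int, species="human")   # 16.07 -> 9.05 mL/min/kg
```

## Layout

- `src/dmpk/io.py` — data model, unit canonicalization, CSV/JSON I/O
- `src/dmpk/transport.py` — Papp, efflux ratio, inhibitor comparison, TC₅₀
- `src/dmpk/stability.py` — depletion kinetics and well-stirred IVIVE
- `src/dmpk/nca.py` — non-compartmental PK engine
- `src/dmpk/cyp.py` — phenotyping ratios and censored IC₅₀ fits
- `src/dmpk/binding.py` — protein binding and tissue distribution
- `src/dmpk/excretion.py` — excretion mass balance
- `src/dmpk/synth.py` — seeded synthetic-data generators
- `src/dmpk/pipeline.py`, `src/dmpk/cli.py` — assay dispatch and the
  `dmpk` command

See `docs/methods.md` for the models, assumptions and numerical choices.
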