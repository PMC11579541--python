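# Methods

This note documents the models behind each analysis module, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that were genuinely open.

## Units and data model

All in-vivo concentrations are canonicalized to μg/L (numerically identical
to ng/mL; tissue homogenate data in ng/g ride on the same numeric scale),
doses to mg/kg, in-vivo time to hours and in-vitro incubation time to
minutes. Conversion happens once, at the I/O boundary, because published PK
tables routinely mix μg/L·h with L/h/kg and a single internal system is the
only reliable defence against silent 1000× errors. Time units are a
mandatory column in every input table and are never inferred.

Below-limit-of-quantification (BLOQ) observations are flagged and carried,
never dropped: values before the first quantifiable point enter trapezoids
as 0; BLOQ values embedded after Cmax are excluded from terminal-slope fits
but retained (as 0) for trapezoids. This is the common NCA convention; with
a LOQ of 0 the policy is inert.

## Monolayer transport

The forward model is linear (sink-condition) flux: dQ/dt = Papp·A·C0.
Estimation inverts this by ordinary least squares of cumulative receiver
amount against time in seconds, so a 6-point design is used in full rather
than a two-point difference — regression is the noise-robust reading of the
defining equation. Periodic receiver sampling with blank-buffer replacement
removes analyte; the cumulative amount is reconstructed as
Q(tₙ) = Cₙ·V_r + Σ_{i<n} Cᵢ·V_s. The correction is on by default (typical
assays replace 50 μL aliquots out of 400–1200 μL wells, a 4–12% distortion
per sample) and can be toggled off for comparison; with V_s = 0 it reduces
to the naive Cₙ·V_r.

A receiver concentration exceeding 10% of donor C0 triggers a
sink-violation warning, since the linear-flux reading of Papp assumes an
effectively infinite gradient. Non-positive slopes floor Papp at 0 with a
flag rather than reporting a negative permeability.

The efflux ratio uses the >1.5 substrate convention and the
3×10⁻⁶ cm/s brain-permeability threshold; both are constants at the top of
`transport.py`. TC₅₀ is fit as a four-parameter logistic of relative growth
rate against ln(concentration) with both asymptotes bounded to [0, 120]% —
blank-normalized viability cannot meaningfully exceed ~120%, and an
unconstrained top makes shallow curves non-identifiable. TC₅₀ is reported
where the fitted curve crosses 50% absolute; if that point lies beyond the
tested range the result is censored as "> max tested".

## Microsomal stability and IVIVE

Depletion is treated as first-order: k_e is minus the slope of
ln(remaining) vs time, t½ = 0.693/k_e. The 0.693 constant (rather than ln 2
to machine precision) is the deliberate default because published scaling
uses the printed constant; `use_exact_ln2=True` switches to full precision
(the difference is 2×10⁻⁴ relative — irrelevant in practice, but the
reported numbers should be reproducible as printed).

Species with saturating early kinetics show ln-linear decay only over an
initial window. The automatic rule takes the **longest prefix of the series
whose ln-linear r² is ≥ 0.95** (minimum three points); an explicit window
always overrides. On a series linear to 15 min and flat after, the rule
recovers (0, 15); on a fully linear series it uses all points.

Scaling is the standard microsome-to-body chain:
CL_int = (0.693/t½)·(1/protein)·MPPGL·(liver weight/BW), with MPPGL
45 mg/g for all species and liver weights 40/32/30/25.7 g/kg for
rat/dog/monkey/human; the well-stirred model CL_h = Q_h·CL_int/(Q_h+CL_int)
uses hepatic flows 55.2/30.9/43.6/20.7 mL/min/kg. No binding correction
(fu_mic, fu_p) is applied and no parallel-tube or dispersion alternative is
offered — the scope is the basic well-stirred chain. A lookup for an
unknown species raises; nothing defaults silently.

Replicates are fit individually and the derived parameters averaged
(arithmetic mean ± SD), not pooled into one regression: triplicate
microsomal assays are conventionally summarized per replicate, and the two
approaches differ by ~0.5% (ratio of means vs mean of ratios), which is why
round-trip checks against published tables use a 1% tolerance.

## Non-compartmental analysis

AUC and AUMC use the linear trapezoid by default, with linear-up/log-down
available by flag (the log rule is exact on mono-exponential segments).
λz comes from log-linear regression over candidate sets of the last 3..k
quantifiable points after Tmax, excluding Cmax itself for extravascular
profiles; the set maximizing adjusted r² wins and ties break toward more
points. This is the dominant convention among NCA tools; manual point
selection is supported for audit parity.

Extrapolated quantities use the standard tail terms: AUC_0∞ = AUC_0t +
C_last/λz and AUMC_0∞ = AUMC_0t + C_last·t_last/λz + C_last/λz². MRT_0t is
strictly truncated; MRT_0∞ includes the tails. An extrapolated fraction
above 20% raises a quality flag. CL/F = dose/AUC_0∞ and Vz/F = CL/(F·λz)
with the mg→μg factor applied explicitly, so clearances emerge in L/h/kg.

Bioavailability defaults to the per-subject crossover mean of
dose-normalized AUC ratios (matching how crossover studies report F);
ratio-of-group-means is available and differs from the per-animal mean by
well under 1% in the reference data. Steady-state metrics over one dosing
interval: AUC_ss by trapezoid over [0, τ], C_av = AUC_ss/τ,
DF = (Cmax−Cmin)/C_av, an optional accumulation index against first-dose
AUC_0τ, and a trough-flatness check (regression slope p ≥ 0.05 across
pre-dose troughs). Dose-proportionality returns the metric ratios
normalized to the lowest dose group alongside the dose ratios, so
supra-proportional exposure (saturable elimination) is read off directly.

## CYP phenotyping and inhibition

Phenotyping is arithmetic — transformed % = 100·(1 − remaining/control) —
with two guards: the zero-time control must be positive, and when an
NADPH-free negative control is supplied, more than 5% parent loss without
cofactor invalidates the run. A ±5% noise guard brackets the transformed
fraction.

IC₅₀ fits a four-parameter logistic on log₁₀(inhibitor concentration). The
top asymptote is constrained to [90, 110]% because the blank control
defines 100% by construction and a free top makes shallow inhibition curves
non-identifiable; the bottom is bounded at 0. The zero-concentration blank
is the normalizer, not a fitted point. Censoring comes **before** fitting:
if observed maximum inhibition never reaches 50%, the result is "> top
tested concentration" — a monotone curve staying above 50% activity can
never receive a numeric IC₅₀ inside the tested range. Classification uses
the 10/50 μmol/L potent/moderate/weak convention; censored results are
negligible unless inhibition at the top concentration reached 25%, in which
case they are called weak.

The fitter-recovery validation (IC₅₀ ∈ {1, 10, 50} μmol/L × hill ∈
{0.8, 1, 1.5} at 3% noise) uses a nine-point log design spanning
0.1–316 μmol/L: a recovery study must place concentrations around every
tested midpoint, which the five-point screening design (0.1–100 μmol/L)
deliberately does not do — the screening design exists to establish
censoring, and remains the generator default.

## Binding, distribution, excretion

Protein binding is 100·(C_t−C_f)/C_t, clipped to [0, 100]; a free
concentration exceeding total is rejected as a device artifact
(pre-saturation failure or nonspecific binding).

Tissue distribution under destructive sampling uses the composite method:
trapezoidal AUC on per-time-point mean concentrations. Per-animal AUCs do
not exist in such a design, so ratios are ratios of composite AUCs; tissue
ng/g and blood μg/L are treated as numerically commensurate for ratio
purposes, as is conventional for homogenate panels. Exposure fractions are
percentages of the summed AUC over all matrices and sum to 100 exactly. The
accumulation screen flags any matrix whose terminal concentration exceeds
20% of its peak.

Excretion mass balance converts matrix concentration × amount × dilution
factor to recovered drug, as % of dose (dose × body weight). The fecal
homogenate dilution factor is an explicit input (default 10, i.e. a 10%
homogenate) rather than hard-coded. Cumulative curves are running sums,
monotone by construction; total recovery below 5% of dose raises an
"extensive metabolism" interpretation flag. Body weights are a required
input; the synthetic fixtures use 0.2 kg rats.

## Synthetic-data generators

One-compartment kinetics with first-order absorption was chosen as the
minimal model consistent with mono-exponential terminal phases; no claim is
made that any real compound is one-compartment. Multiple dosing is built by
superposition. Residual noise is multiplicative log-normal (unit median)
with default CV 5%, the standard bioanalytical error model; between-subject
variability applies log-normal factors (default CV 20%) to ka, ke and V.
These defaults are fixture conventions, not estimates of any study's
variance structure. The degenerate oral case ka = ke uses the limiting form
F·D·ka·t·e^(−ka·t)/V.

The transport generator splits a passive permeability asymmetrically by the
efflux factor (A→B = p/√ef, B→A = p·√ef) so the true ER equals the factor
and inhibitor mode (ef = 1) raises A→B permeability, as P-gp blockade does.
It applies sampling-and-replacement to the emitted concentrations, so the
analysis-side correction is genuinely exercised. The tissue generator
scales one blood profile by per-tissue partition coefficients, with
kinetics placing the blood peak near 2 h. The excretion generator
back-calculates matrix concentrations from programmed per-interval dose
fractions, so the analysis inverts it exactly at zero noise.

What the generators do **not** emulate: enterohepatic recirculation,
saturable (Michaelis–Menten) elimination, time-dependent CYP inactivation,
inter-occasion variability, LOQ-censoring mechanisms tied to assay
chemistry, or correlated tissue kinetics. Passing the inversion suite
therefore demonstrates estimator correctness under the stated models — not
robustness to every pathology of real bioanalytical data.

## Problem sizes

Simulation-based checks use 200 profiles for λz/AUC recovery, 36 fits for
the IC₅₀ grid, and dense grids (Δt = 0.01 h over 100 h) for
trapezoid-vs-closed-form comparisons; these sizes give stable pass/fail
behaviour at fixed seeds while keeping the whole suite around a few
seconds.

## Known limitations

- No binding-corrected IVIVE, no compartmental or population PK fitting,
  no PBPK, no Kp prediction, no metabolite quantification, no group
  hypothesis testing (per-animal data are required for p-values and are
  typically unpublished).
- The λz selection and trapezoid flavor of legacy NCA software are not
  fully documented anywhere; round-trip comparisons against published
  parameter tables should allow ~2% slack for convention mismatch.
- Composite-design tissue SDs cannot be derived from composite means;
  only means are modeled.
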