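# Methods

This note records the model, its assumptions, the defaults that matter, and
the design decisions taken where the design was genuinely open.

## Scope and strategy

The package simulates a single oral dose of doxepin in an adult, tracks the
parent and its active metabolite N-desmethyldoxepin, scales CYP2D6 metabolism
by metabolizer phenotype, and implements the evaluation arithmetic used to
qualify such models (fold error, GMFE, twofold coverage), local sensitivity
analysis, and least-squares parameter identification. Multiple dosing,
stereoisomer-resolved kinetics, CYP2C19 genotype scaling, renal elimination,
pharmacodynamics and drug–drug interactions are out of scope.

## Whole-body model

**Topology.** 13 perfusion-limited, well-stirred organ compartments (lung,
brain, heart, kidney, liver, gut, spleen, stomach, muscle, adipose, skin,
bone, rest) plus arterial and venous blood. The lung carries the whole
cardiac output in series; gut, spleen and stomach drain into the liver
(portal vein); all other organs return to venous blood. Flows balance at the
venous and arterial nodes by construction of the bundled physiology table.
Sub-organ permeability-limited structure is not reconstructed: with the
reported specific organ permeabilities (0.30–0.33 cm/min) the well-mixed
approximation is adequate at this scale, and numerical reproduction of any
particular proprietary simulator is explicitly not a goal.

**Physiology.** A 70 kg reference adult (ICRP-style rounded organ volumes and
regional flows, cardiac output 5.36 L/min) is bundled as package data. Virtual
individuals scale volumes by (weight/70) and flows by (weight/70)^0.75 —
standard allometry, chosen because the original demographic sampling
algorithm is proprietary-in-detail. Age and weight are drawn uniformly within
the printed study ranges and sex by the group's female fraction; height and
BMI are not modelled (the study groups report only age/weight/sex ranges).

**Distribution.** Tissue:plasma partition coefficients are composition-based.
For doxepin (moderate-to-strong base, pKa 9.76) the Rodgers–Rowland
equations are used, with the acidic-phospholipid association constant
derived from the blood:plasma ratio (default 1.0, not reported for either
compound; exposed in configuration) at hematocrit 0.45. For nordoxepin a
Schmitt-style scheme is used: neutral-species affinities P (neutral lipid)
and 0.3P + 0.7 (phospholipid), with ion-partitioning factors 1e-3 (neutral
lipid), 0.3 (neutral phospholipid) and 20 (acidic phospholipid,
cation–anion attraction). The exact constants of the published Schmitt
method are not reproducible from open sources; these factors give
plausible magnitudes for a lipophilic amine (liver Kp ~ 60, whole-body
Vss ~ 15–20 L/kg) and preserve the properties that matter downstream:
positivity, determinism, and monotonicity in log P of the lipid terms.
Note that for the blood-cell-calibrated Rodgers–Rowland base equations,
total Kp need *not* be monotone in log P: the calibration re-derives the
electrostatic constant from the fixed blood:plasma ratio, deliberately
offsetting the lipid increase.

**Absorption.** The tablet dissolves by a Weibull curve parameterized by the
50%-dissolution time (t50 = 12 min, shape b = 0.80); the scale parameter is
therefore λ = t50/ln(2)^(1/b), stated explicitly because the textbook Weibull
uses the 63.2% time. Dissolution is implemented in hazard form
(rate = f/(1−F) × remaining solid) so mass is conserved when the solubility
cap binds. Dissolved drug sits in a 0.25 L luminal volume capped at the
compound's printed solubility (31.60 mg/L at pH 7); for a 75 mg dose this cap
binds (max ~7.9 mg in solution), making absorption dissolution/solubility-
limited — a deliberate, documented modelling decision (the printed solubility
is taken at face value rather than corrected for luminal pH ionization, which
would lift the cap entirely). Absorption into the portal circulation is first
order with ka = Peff · (2/r) · A, using the printed specific intestinal
permeability, a cylindrical lumen of radius 1.25 cm, and an effective
surface-area amplification A = 40 (villi/microvilli), chosen once to give an
absorption half-time of ~15 min, typical of an immediate-release oral dose.
The immediate-release capsule formulation is modelled as the same Weibull
with t50 halved (no capsule dissolution parameters are published). Multi-
segment gut transit, gut-wall metabolism and food effects are not modelled.

**Metabolism.** All clearance is hepatic, driven by the unbound liver water
concentration Cu = C_liver·fu/Kp_liver (well-stirred convention):

- doxepin → nordoxepin by CYP2C19 (Km 5 µM, kcat 28 min⁻¹, reference enzyme
  concentration 0.76 µmol/L), mole-for-mole into the liver metabolite pool;
- doxepin → inactive by CYP2D6 (Km 88 µM, reference 0.40 µmol/L);
- nordoxepin → inactive by CYP2D6 (Km 40 µM) plus a linear "total hepatic
  clearance" of 2.50 L/min lumping the remaining routes. The reference value
  does not state whether that clearance refers to plasma, blood or unbound
  concentration; it is interpreted here as an intrinsic clearance on the
  unbound liver concentration, because a plasma clearance of 2.5 L/min would
  exceed hepatic blood flow. Flow limitation then emerges from the topology.

Minor doxepin pathways (CYP1A2/3A4/2C9) carry no published parameters and are
omitted; renal clearance is excluded (<3% urinary excretion).

**Genotype scaling.** Only the CYP2D6 kcat varies by phenotype (Km held
constant): doxepin 260 (non-genotyped), 505/299/85/0 min⁻¹ for UM/NM/IM/PM;
nordoxepin 160 and 505/165/30/0. Phenotypes follow the 2019 CPIC/DPWG
consensus activity-score bins; the printed rule leaves (2.25, 2.5]
unassigned, and such scores are classified NM with a warning rather than
inventing a fifth category. Inter-individual enzyme abundance is a lognormal
multiplier with median 1 and geometric SD 1.4 (the reference material is
silent; exposed in configuration) applied to the reference enzyme
concentrations.

## Numerics

Amounts are in nmol, concentrations nmol/L, time minutes internally and hours
at interfaces. Integration is LSODA with rtol 1e-8 and atol 1e-10 nmol by
default (configurable); because the cumulative-elimination states integrate
the same fluxes as the compartments, mass balance closes to near machine
precision (~1e-15 relative, far inside the 1e-6 requirement). A state more
negative than tolerance is a hard error; sub-tolerance negatives are clipped
at output. The Weibull hazard diverges as t^(b−1) at t = 0 for b < 1; it is
evaluated at max(t, 1e-9 min). The solubility cap uses a 0.5 min relaxation
toward saturation headroom to keep the right-hand side solver-friendly.
Population percentiles are empirical order statistics with linear
interpolation; bands from fewer than 20 individuals trigger a warning. The
degenerate zero-dose regimen is admitted and yields identically zero
profiles.

**NCA.** Cmax/Tmax are the sampled maximum; AUC to the last point uses the
linear-up/log-down trapezoid; λz comes from an unweighted log-linear fit over
the last 3–5 post-peak points chosen by best adjusted r²; AUC extrapolation
is C_last/λz, with a flag above 20% extrapolated fraction.

**Sensitivity.** S = (ΔPK/PK)/(Δp/p) by forward difference at Δp/p = +0.10
(the interpretive convention: +1.0 means a +10% input change gives +10% in
the metric). Forward, not central, to mirror the definition; |S| > 0.5 is
flagged influential.

**Fitting.** Residuals on log concentrations (uniform weights) by default;
parameters are log-transformed, so positivity holds by construction and
bounds transfer to the optimizer (scipy trust-region reflective least
squares, the bounded relative of Levenberg–Marquardt). Standard errors come
from the Jacobian via the delta method. Non-convergence is reported, not
raised, with the best iterate retained.

## Synthetic data

The generator emulates the study conditions: demographic groups matching the
printed study table (e.g. the development group: n = 30, 63% female, age
22–50, weight 55–90 kg; virtual evaluation populations of n = 100), and
synthetic "observed" profiles built as model output times lognormal
proportional noise with a stated CV (σ = sqrt(ln(1+cv²)), mean-1 noise), as a
stand-in for unpublished raw concentration data. It does not emulate real
assay error structure (additive floors, LLOQ censoring), demographic
covariance (height/BMI), disease physiology, or model misspecification —
so parameter-recovery results show identifiability under the stated noise
model, not robustness to structural error. The recovery study uses 12
sampling times spanning 1–96 h; the late points carry most of the
information about the metabolite's elimination turnover because terminal-
slope sensitivity grows with time.

## Problem sizes

Default test and analysis runs use a 96 h horizon (≥5 terminal half-lives
for the parent; the metabolite's terminal phase is longer, so its
extrapolated AUC fraction is reported and flagged), 144 h for genotype
ordering, n = 100 for population summaries, and 50 seeded replicates for the
noisy recovery study, at rtol 1e-6 for repeated-simulation studies. These
sizes were chosen as the package's own desk-scale defaults.

## Known limitations

Kp magnitudes and hence absolute predicted concentrations are not expected
to match simulators with proprietary physiology/composition databases; the
package's quantitative claims are the evaluation arithmetic, conservation
properties, analytic-oracle agreement, genotype orderings, and recovery
behavior, all of which the test suite computes. Healthy-adult physiology
only; single dose only; total (E+Z) isomer mixture kinetics.
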