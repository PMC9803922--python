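# Methods

## Speciation chemistry

All chemistry is ideal-solution: activities equal concentrations, and the
two equilibrium constants are fixed numbers — pKa 9.24 for boric
acid/borate and pKw 14.0 for water (configurable; the pKa is treated as
independent of temperature and ionic strength because the downstream
thermodynamics uses a single recording temperature of 18 °C and
physiological salines). "Total boric acid" always means
[B(OH)₃] + [B(OH)₄⁻]; the split is the Henderson–Hasselbalch fraction
1/(1+10^(pKa−pH)). Polyborates, which appear at high concentration and
alkaline pH, are ignored — at the ≤ 33 mM, pH ≤ 8.5 range of interest
they are negligible. Internal units are mol/L, volts, amperes and
kelvin; mM/mV/μA appear only in I/O layers, and nothing is rounded
internally (a separate formatting layer reproduces display rounding:
one decimal for mM species, nearest mV, two significant figures for
fold changes).

## Transport thermodynamics

The three candidate cycles (B(OH)₄⁻ uniport, B(OH)₃–OH⁻ cotransport,
B(OH)₃/H⁺ exchange) all move net charge −1 inward per cycle, with
cotransport/exchange stoichiometry fixed at 1:1 (not configurable). The
driving force is Δμ = RT·ln(r) − F·ΔΨ with ΔΨ = Ψᵢₙ − Ψₒᵤₜ; this sign
convention makes the worked example (1.4 mM/pH 7.1 inside vs 20 mM/
pH 7.5 outside) give ΔΨ_eq ≈ −89.5 mV at 291.15 K with the physically
expected sign (hyperpolarization drives efflux). Each mode's ratio is
computed from its own species so the Ka/Kw identity between them is a
*checked* property (equal to 1e−12 relative), not an assumption.
Mixed-ion (Goldman-style) potentials and Na⁺-coupled modes are out of
scope: the transporter is Na⁺-independent and a single-species
equilibrium potential is the right object.

## Voltage-clamp analysis

Steady-state currents are means over the terminal 25% of an epoch or
voltage step (configurable; recordings settle well within typical epoch
lengths). Elicited currents are I(substrate) − I(substrate-free) with
matched holding potentials, the reference being either a paired trace or
a pre-application baseline window. Charge integration is trapezoidal;
monitoring traces are 1 Hz, charge-accounting traces 9 Hz. The leak
charge defaults to (mean pre-application current) × (application
duration) — a cohort-mean convention — with a per-oocyte alternative via
`charge_accounting_from_trace`. Charge counts are E/e and molecule
counts ΔB·N_A; on the published accounting these land at ~9.5×10¹⁴ and
~9.4×10¹⁴ for ~152 μC and ~1.56 nmol (the exponent-free ratio ≈ 1.1 is
the meaningful quantity, and the package reports the ratio both of mean
counts and recomputed from mean charge/content, which differ slightly
because per-cell averaging does not commute with division). Reversal
potentials come from linear interpolation between the bracketing sign
change only — an I–V curve that does not cross zero has its reversal
reported as absent, never extrapolated.

Dose–response fits use scipy least squares on internally rescaled
variables (doses by their median, currents by their max magnitude) so the
optimizer sees O(1) numbers; starting values are deterministic (K_m/IC₅₀
at the median dose, I_max/I₀ at the largest-magnitude current), making
fits reproducible. K_m and IC₅₀ are constrained positive. An inhibition
fit whose IC₅₀ lands ≥ 20× the largest tested dose (< 5% inhibition at
the top dose) is reported as "no measurable inhibition" (absent) rather
than as a number. Fits are scale-equivariant: scaling all currents scales
I_max/I₀ and leaves K_m/IC₅₀ unchanged. pH drift slopes are ordinary
least squares over ≥ 10 samples.

## Flux and cohort analysis

Uptake/efflux rates are OLS slopes of per-cell boron content vs time
(influx positive). Cohort summaries are group mean ± sample SD (n−1);
fold changes are ratios of group means — matching how the published fold
figures are computed — displayed at two significant figures.
Below-detection concentrations are rejected at parse time rather than
imputed. Hypothesis testing (t-tests, ANOVA) is deliberately out of
scope. The printed cohort fixture carries only groups whose mean, SD and
n are all printed; fold figures whose printed operands do not reproduce
the printed result (the 41-, 140- and 590-fold values, which presumably
used unrounded means) are computable but not asserted anywhere.

## The synthetic oocyte

The simulator exists to give the analysis pipeline inputs with known
ground truth, not to be a biophysically complete oocyte.

**Membrane.** One capacitance (0.2 μF), one linear leak (1 μS reversing
at −30 mV — input resistance ~1 MΩ, typical of healthy oocytes), plus
the transporter.

**Transporter.** `I = I_max · [B]ₒ/(K_m+[B]ₒ) · tanh(−Δμ/(2RT))` with
K_m = 6.5 mM, I_max = 1.5 μA. The saturable factor is the measured
dose–response; the tanh factor is a modelling choice — the data constrain
only reversal at Δμ = 0, monotonicity and boundedness, and any odd
bounded function would do; tanh is the simplest. Its argument is scaled
by 2RT so the conductance near equilibrium is finite (slope
I_max·F/2RT). NMDG inhibition is empirical scaling by IC₅₀/(IC₅₀+[NMDG])
with IC₅₀ = 67 mM (the underlying chemistry is chelation of boric acid,
for which no binding constant is available). With no external substrate
the carrier is silent — the saturable factor is written in [B]ₒ only, so
the simulator does not reproduce trans-side efflux into substrate-free
media; efflux series for flux-rate analysis are generated directly.

**Bookkeeping.** Each transported charge carries one boric acid molecule
and one base equivalent: dB/dt = I_t/F into a cytoplasm of
0.7 μL × 10%, and dpHᵢ/dt = (I_t/F)/(β·V_cyto) with buffering power
β = 20 mM/pH (literature-typical for oocytes; configurable). Charge–mole
conservation therefore holds by construction and is asserted on every
simulated uptake run (analysis-side recovery to 1e−3 relative, the
limit set by trapezoidal integration of the sampled current). Which
fraction of transported base equivalents titrates the buffer in a real
oocyte is unknown; the simulator's 1:1 choice is ground truth for
tests, not a claim about cells. A consequence of the small cytoplasmic
volume is that clamped currents at negative potentials self-limit
within tens of seconds as the cell loads with boron and alkalinizes —
dose–response protocols therefore clamp at +60 mV (as the published
kinetics did), where equilibrium is far away and currents are stable.

**Integration.** Fixed-step explicit Euler, at least 100 steps per
epoch; unclamped epochs integrate C·dV/dt = −(I_leak+I_t) with the step
bounded by 0.2·C/(g_leak + I_max·F/2RT) (a conservative stability
bound on the steepest force–flux slope); an explicitly requested step
above the bound raises with a suggested step. Intracellular pH is
clipped to [1, 13] before speciation as a numerical guard. Recording
noise is additive Gaussian on current (σ = 0.02 μA default, matching
quiet two-electrode recordings) and optional on pH; all draws come from
one seeded generator, so identical seeds and scripts are bit-identical.

**Cohorts.** Group concentrations are lognormal — positive-valued and
right-skewed like real fluid measurements — moment-matched to target
mean/SD (σ² = ln(1+SD²/m²), μ = ln m − σ²/2), degenerate at SD = 0, with
a heavy-tail warning at SD ≥ 3×mean. At the small printed group sizes
(n = 3–7) sample means scatter around targets per sampling theory; the
test suite checks that property across seeds rather than asserting any
single draw.

## Problem sizes and tolerances

Monte-Carlo recovery uses 200 replicates (enough to pin the replicate
mean to a few percent while keeping runs in seconds). The end-to-end
simulator recovery is documented at 20% for K_m/I_max because the tanh
force–flux factor varies mildly across doses, so simulated dose–response
currents are only approximately Michaelis–Menten; IC₅₀ recovers within
10% because inhibition scales currents uniformly. Unclamped settling is
asserted within 3 mV of the equilibrium potential of the *final*
simulated state (the state drifts slightly while the membrane relaxes).
Equilibrium-potential agreement with the printed worked example is ±1 mV:
the printed value could come from the rounded (0.03 → −88.0 mV) or
unrounded (0.0282 → −89.5 mV) ratio, which bracket it.

## What passing tests do and do not show

The synthetic generator emulates leak + saturable transporter currents,
pHᵢ drift under a stated buffering power, and positive-valued cohort
noise — it does not emulate endogenous oocyte conductances, capacitance
transients, series resistance, electrode drift, spatial gradients, or
real biological variability in expression level. Parameter recovery on
synthetic data validates the analysis pipeline's correctness, not the
biological values themselves; quantities that depend on real cells (the
exemplar +0.27 μA elicited current, measured pH drift rates, measured
hyperpolarizations, mRNA induction) are never asserted numerically.
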