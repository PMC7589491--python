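# Methods

## The measurement being modelled

A drug dissolved in the donor chamber of a Franz diffusion cell crosses an
artificial lipid-impregnated membrane into a stirred receiver chamber.
Samples withdrawn from the receiver on a fixed schedule (0.25, 0.5, 1, 2,
3, 4, 5, 6, 10, 12 h) are assayed by HPLC; each withdrawal is replaced
with fresh buffer. The quantity of interest is the permeability
coefficient of the membrane for that drug, which in turn predicts the
fraction of an oral dose absorbed in humans and the drug's BCS
permeability class.

## Two-compartment transport model

Both chambers are treated as well mixed, connected by a membrane of area
*S* with a single lumped permeability *P*. Between sampling events the
receiver concentration obeys

    dC_r/dt = P·S·(C_d − C_r)/V_r,    C_d = (Q − C_r·V_r)/V_d

with *Q* the total dissolved mass. Because the system is linear, each
interval has the closed form implemented by `propagate_interval`:
exponential relaxation toward the well-mixed equilibrium *Q*/(*V_r*+*V_d*)
with rate constant *P·S·(1/V_r + 1/V_d)*. The closed form is verified in
the tests against step-size-refined `scipy.integrate.solve_ivp`
integration to 1×10⁻⁶ relative over *P* ∈ {10⁻⁷…10⁻⁴} cm/s and
Δt ∈ {900, 3600, 14400} s (observed agreement ≈ 10⁻¹²).

Assumptions: fully dissolved, spatially uniform donor (no solid reservoir,
no saturation kinetics); no unstirred-water-layer sub-model (stirring at
500 rpm is taken to make it negligible); no pH/ionisation dependence; no
membrane retention or lag time.

## Simulator

`simulate_permeation` iterates the closed form over the schedule. At each
sampling time it records the pre-replacement receiver concentration, then
applies the sampling event: the withdrawn mass *C_r·V_s* leaves the
system and the receiver is diluted by *f* = (*V_r* − *V_s*)/*V_r*. The
simulator always conserves mass; the test suite checks donor + receiver +
withdrawn mass against the initial donor load at every step (1×10⁻⁹
relative) with an independent two-state ODE replay.

Measurement noise is multiplicative Gaussian (mean 1, sd `noise_cv`,
truncated at zero) applied to recorded values only — HPLC error scales
roughly with concentration. The simulator does not emulate: drug-specific
assay LOQs, membrane-to-membrane variability, solid excess in the donor,
or the pre/post-replacement ambiguity of real autosamplers (recorded
values are pre-replacement by definition here). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to every artefact of real assay data.

Default study conditions mirror the reference assay: area 1.77 cm², donor
1 mL, receiver 7 mL, C₀ = 10 mg/mL, 3 replicates, the 10-point schedule
above. The sample volume is not reported for the reference assay; the
demo configuration uses 1.0 mL and flags it as an assumption — it must be
supplied, never silently defaulted, when reading real data. Simulated
noise defaults to 5% CV, the variability scale reported for permeabilities
near 10×10⁻⁶ cm/s in large PAMPA surveys (≈10%) rounded down to the
replicate-level precision a GLP HPLC assay achieves.

## Sink (flux) estimator

`cumulative_amount` reconstructs transported mass with the
sampling-replacement correction Q(t_k) = C_k·V_r + Σ_{i<k} C_i·V_s.
`find_linear_portion` then selects, among all contiguous windows of at
least 4 points, the one maximising OLS R² — the "best fit through the
linear portion" procedure. Choices:

* **minimum window 4 points**: with a 10-point schedule this leaves ≥ 2
  residual degrees of freedom, below which R² is vacuous;
* **ties** (R² within 1×10⁻⁹, e.g. exactly linear data): the longer
  window wins, then the later start (closer to steady state);
* a **constant window** is assigned R² = 1 (a zero-slope line fits it
  exactly); an all-zero experiment short-circuits to flux 0 with R²
  reported as missing;
* the window search is verified against exhaustive O(n²) enumeration in
  the tests.

Slopes are fitted per replicate and averaged, so the coefficient of
variation of flux across replicates is well defined; the reported window
and R² come from the replicate-mean curve, matching the convention of
fitting mean cumulative plots. Fitting mass (µg) rather than
concentration (µg/mL) differs only by the constant V_r absorbed into the
slope; the physics is in mass units. Papp = J/C₀ with J in µg cm⁻² s⁻¹
and C₀ in µg/cm³ gives cm/s with no conversion factors.

## Non-sink estimator

`predict_receiver_series` iterates the interval recursion with the
dilution factor applied to the previous concentration at the start of each
interval. Two bookkeeping conventions for the total mass Q are exposed:

* **mass-conserving** (default): Q is decremented by the withdrawn mass at
  every sampling event — identical dynamics to the simulator (the
  self-consistency test requires 1×10⁻⁹ relative agreement);
* **paper-literal**: Q fixed at V_d·C₀, the form in which the recursion
  is usually printed (Q carries no time index); kept for reproduction
  studies. It over-predicts late time points, since withdrawn mass is
  counted as still present.

The first interval has no preceding sampling event, so f = 1 there — the
recursion itself is silent on this boundary case.

`fit_peff` minimises the SSR against the replicate-mean series over
P ∈ [10⁻⁹, 10⁻²] cm/s: a 60-point log-spaced grid brackets the optimum,
then bounded scalar minimisation in log₁₀ P refines it to ~10⁻⁶ relative.
A single-parameter deterministic search was chosen over generic nonlinear
least squares for bit-reproducibility and immunity to local minima; the
tests cross-check it against a 10⁴-point brute-force grid and, on
monotone (no-sampling) data, against bisection on the final time point.
All-zero observations return P = 0 with a degenerate-fit flag. Replicates
are pooled by averaging before fitting (the mean-curve convention) rather
than fitted jointly; no heteroscedasticity weighting is applied.

Structural behaviour, verified in the acceptance tests: at true
P ≥ 10⁻⁵ cm/s the sink estimate falls below the non-sink fit (donor
depletion biases the flux slope low — the direction seen when comparing
the two published estimates, e.g. metoprolol 15.8 vs 59.0 ×10⁻⁶ cm/s);
at P ≤ 10⁻⁷ the two agree within 2%.

## Classification

High permeability ⇔ Papp > 0.8 × Papp(metoprolol), strictly: a drug
exactly at the threshold is low, a convention that must be documented
because the published analysis never exercises the tie. Applied to the
Franz-cell column of the reference table (threshold 0.8 × 15.8 = 12.64
×10⁻⁶ cm/s) this labels seven drugs high (caffeine, propranolol,
theophylline, diclofenac, ibuprofen, atenolol, cimetidine). The package
reports rule-based labels only; the published prose list of "seven highly
permeable drugs" includes naproxen (2.89 ×10⁻⁶, below threshold) and is
internally inconsistent with its own table. The dose number uses the
standard definition D₀ = (dose/250 mL)/solubility with the 250 mL
reference gastric volume.

## Correlation battery

"Log-linear" is ordinary least squares of Fa% on log₁₀ Papp (the
straight-line summary customary when permeabilities span three orders of
magnitude); a sigmoidal absorption model is out of scope. Cross-membrane
agreement is Pearson correlation, computed on both log₁₀ and linear
scales because the published analysis does not state its scale; drugs
with zero permeability in a column are excluded from log-scale statistics.
Every battery row records the exact drug subset used.

Which published statistics regenerate from the packaged reference table,
and which do not:

* **regenerate**: Fa vs Corti membrane, linear — R² 0.9043 vs published
  0.904 (all 14 drugs with Corti data) and 0.8934 vs 0.890 (excluding the
  actively transported trio); the sink vs non-sink column correlation on
  log scale — R² 0.8757 / r 0.9358, bracketing the published 0.8984; Fa
  vs Caco-2 — the published "R² = 0.805" matches the *Pearson r* (0.8067,
  all 18 drugs) of the log-linear fit, whose R² is 0.651;
* **do not regenerate**: Fa vs the Franz-cell column (published 0.664 all
  drugs / 0.6982 excluding ranitidine, trimethoprim, verapamil; the table
  yields 0.232 / 0.276), the Franz vs Caco-2 R² (published 0.826; table
  yields 0.181 log-scale), and the Franz vs literature-PAMPA r (published
  0.7355; table yields 0.33–0.53). An exhaustive search over drug-subset
  exclusions (to size 5) and transforms found no reading of the printed
  table that reproduces these, so the figure-level regressions evidently
  used inputs differing from the printed column. The battery reports the
  deviations rather than hiding them, and the corresponding acceptance
  test is left failing by design.

What the table *does* support in full: the qualitative claims — removing
the actively transported trio improves the Fa fit, and both estimators
give every drug the same BCS classification.

## Numerical and I/O conventions

Time is hours at every boundary, seconds only inside flux/permeability
arithmetic. Results are written with 6 significant digits and stable
column order (byte-deterministic). The long-format concentration CSV
(`drug,replicate,time_h,conc_ug_ml`) keeps ragged replicates
representable, though the data model requires schedule-aligned series.
Random seeds are always explicit configuration values.

## Problem sizes

The test suite and acceptance script run the full chain at the study's
own scale: 10-point schedules, 3 replicates, 100 noisy-recovery seeds,
10⁴-point oracle grids — a few seconds end to end, so nothing is
down-scaled relative to the conditions described above.
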