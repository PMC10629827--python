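# Methods

This note records the models implemented in `rohflux`, their assumptions,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical choices that matter.

## Carrier-protein speciation

Retinol partitions among five species via two sequential 1:1 equilibria:

    ROH + RBP        ⇌ ROH-RBP          K_D1 = [ROH][RBP]/[ROH-RBP]
    ROH-RBP + TTR    ⇌ ROH-RBP-TTR      K_D2 = [ROH-RBP][TTR]/[ROH-RBP-TTR]

Defaults: K_D1 = 0.10 µM and K_D2 = 0.25 µM, the measured affinities of
the recombinant proteins. Assumptions:

- **One effective RBP site per TTR tetramer.** TTR has two potential RBP
  sites, but the published speciation for the 2/2/4 µM mixture balances
  only with free TTR = total − complex, i.e. single-site stoichiometry;
  we keep that convention and do not model a second site or
  cooperativity.
- **Apo-RBP–TTR binding is neglected.** Only holo-RBP binding to TTR is
  quantified; the speciation balances without an apo arm.
- Mutants are parameter changes, not code paths: muRBP (L63R/L64S) and
  muTTR (I84A) abolish the RBP–TTR interaction, so those delivery modes
  are solved with the TTR step disabled; muRBP retains normal ROH
  affinity.

**Solver.** Outer bounded scalar root-find (Brent) on free TTR in
[0, TTR_total]; for fixed free TTR the ROH/RBP subproblem reduces to a
1:1 quadratic with apparent constant K_D1/(1 + [TTR]/K_D2), solved in
closed form using the cancellation-safe root (accurate in the
tight-binding regime). Bracketing guarantees convergence with no
initialization sensitivity; outer tolerance ~1e-14 so mass balances close
to 1e-8 relative and mass-action residuals to 1e-6 relative.

A note on the printed reference values: the exact solve of the ternary
2/2/4 µM mixture at the stated constants gives 0.1348/0.1817/1.6835 µM
(free / binary / ternary). The tabulated free-ROH value of 0.14 µM
back-computes to K_D1 ≈ 0.109 µM — inside the 100 ± 30 nM measurement
envelope — so tabulated comparisons are made at the table's printed
resolution (±0.01 µM).

## Radiotracer quantification

DPM converts to total compound linearly:
`total_µmol = DPM / (SA · 2.22e12 · 1e-3 · hot_fraction)` with SA in
Ci/mmol. Defaults: SA = 30 Ci/mmol; hot fraction 1/21 (a 1:20 hot:cold
ratio, ≈4.8%), configurable because tracer stocks are re-quantified per
batch. Cellular concentrations divide by aggregate cell volume; the
default BMEC geometry is 402 µm² × 3.4 µm = 1.37e-12 L/cell. Per-well
cell counts are a required user input — they vary with seeding density
and are not derivable from geometry. Technical counting reads are
averaged arithmetically. Dual-isotope data (³H 0–18.6 keV, ¹⁴C 0–156 keV)
are modeled as two already-separated DPM channels; crosstalk and quench
correction are instrument-side and out of scope, as are decay corrections
(³H half-life is irrelevant on a 2-h scale).

## Uptake kinetics

Model 1 treats accumulation as first-order solvent-like partitioning with
coefficient K_p (µM cell per µM fluid) and rate k₁ (min⁻¹). Model 2 adds
a second phase with its own amplitude K_p\* and rate k₁\*, triggered when
the cellular concentration crosses c\*; the trigger time is derived from
phase 1, t_lag = −ln(1 − c\*/(K_p c_f))/k₁, and the second term is
clamped to zero before t_lag, making the curve continuous there. When
c\* ≥ K_p·c_f the threshold is unreachable and the second phase is
inactive (t_lag = +∞) — this is why normalized model-1 curves are
concentration-independent while model-2 curves fan out with rising fluid
concentration. Biological reading: c\* corresponds to saturation of the
intracellular retinol-buffering capacity (CRBP1-scale), beyond which
esterification-like storage engages.

**Fitting.** Default is a single global parameter set across all
concentrations fit to normalized curves (c_cell/c_f), since one shared
threshold describes the design; per-condition fitting and raw-scale
fitting sit behind flags. k₁\* is free and distinct from k₁. The
optimizer is bounded trust-region least squares with one data-driven
start (low-concentration plateau → K_p, half-rise → k₁) plus log-uniform
multistarts under a fixed seed; lowest SSR wins, ties to first occurrence.
Standard errors come from the Gauss–Newton covariance s²(JᵀJ)⁻¹; a
condition number above 1e12 flags the parameters as unidentifiable.
Fluid concentration is held constant (bulk depletion over 2 h is
negligible at these volumes); no depletion correction is applied.

**Model comparison.** Extra-sum-of-squares F with df = (3, N − 5) for the
three added parameters, plus Gaussian-likelihood AIC (constant terms
omitted; only differences are meaningful). Operating characteristics
under the study design (measured by the acceptance tests): median
absolute error ≈4% for c\*, <2% for K_p and k₁; power >90% against
biphasic truth; empirical size ≈3–5% under single-phase truth. Note the
size is evaluated with all parameters on bounds (K_p\* ≥ 0), where the
nominal F reference is approximate but empirically close.

The c\* estimator deserves a caveat: c\* enters the likelihood only
through the lag of conditions whose plateau exceeds it (~4.5 min at 2 µM
under the defaults), so single-experiment estimates are heavy-tailed even
though the ensemble median is tight. Recovery claims are therefore stated
as medians.

## Transwell permeability

Pe_app = slope(Q vs t) / (A · C_apical,0), reported in cm/s for the
monolayer + filter in series (filter deconvolution,
1/Pe_cell = 1/Pe_total − 1/Pe_filter, is available but optional since
filter-only blanks are rarely run). Sink conditions justify the linear
form — the receiver never exceeds ~1.5% of the donor concentration in
these assays. The cumulative amount credits back analyte removed by
earlier draws: Q(t_k) = C_b(t_k)·V_b + Σ_{j<k} C_b(t_j)·V_sample, with
concentrations read immediately before each draw and replacement assumed
analyte-free (replacement only dilutes). The regression keeps a free
intercept and by default starts the window at 15 min so the short initial
lag does not bias the slope; results are annotated with the window used.
Pe is invariant to the DPM↔µM unit choice (scales cancel). Defaults:
A = 1.12 cm², 550 µL apical / 1500 µL basolateral, 30 µL draws every
15 min (five draws ≈ 10% of the chamber volume, matching the protocol's
sampling cap). QC: sucrose Pe threshold 1e-6 cm/s (configurable);
TEER × 1.12 cm² area normalization.

## Binding assays

Because protein concentrations sit near or above K_D, titrations are fit
with the depletion-corrected (Morrison) isotherm — the same quadratic
root as the speciation binary solve — inside an affine signal model
s = s₀ + (s_max − s₀)·bound/P. Affinity and amplitude therefore decouple:
halving the energy-transfer efficiency halves s_max and leaves K_D
untouched. Standard errors come from the fit covariance; 95% CIs use
t(n−3). Non-saturating curves are flagged rather than rejected.
Anisotropy is predicted as the species-fraction-weighted mean r with
equal quantum yields assumed across species — an approximation;
intensity-weighted averaging would shift predictions where brightness
differs between free and complexed retinol.

## qPCR expression

Technical Cq triplicates are averaged per biological replicate; ΔCq is
taken against ACTB, ΔΔCq against the mean ΔCq of the buffer (HBSS)
control across its replicates — the natural reading of "the control value
was used as the reference" at n = 4 — so the control's mean log2 fold
change is exactly 0. Fold = 2^(−ΔΔCq) assumes 100% efficiency
(efficiency-corrected models are out of scope). Statistics run on log2
fold changes: one-way ANOVA, then Dunnett's many-to-one comparisons at
α = 0.05 using the multivariate-t formulation (scipy's implementation),
which is exact at small n. ΔΔCq is invariant to plate-wide Cq shifts, and
adjusted p-values never fall below the matching pooled-variance
unadjusted p.

## Synthetic data

Generators reproduce the study designs with known truth: accumulation at
0.1/0.4/2 µM on a 0–120 min grid at 5-min cadence with 3 biological
replicates; Transwell transport at the geometry above with 15-min
sampling and 4 replicates; 12-point titrations at 100 nM truth; Cq tables
with 4×3 replication and a +1.5 log2 fold LRAT effect confined to the
TTR-containing conditions (σ_bio = 0.4, σ_tech = 0.15, housekeeping
carries technical noise only). Uptake truth defaults to
(K_p, k₁, K_p\*, k₁\*, c\*) = (90, 0.05, 90, 0.02, 36), which reproduces
the observed plateaus (~9 µM at 0.1 µM fluid, threshold crossing only at
2 µM). Titrations default to 0.25 µM protein — a few times K_D — because
the binding assay's identifiability, not the cell assay's 2 µM
composition, sets that choice; at 2 µM protein the curve is nearly
piecewise-linear and K_D is poorly determined at 3% noise.

Replicate noise is multiplicative Gaussian (CV-parameterized, clipped at
zero) because published error bars report SDs without a stated noise
model; optional Poisson noise applies at the DPM layer, where counting
statistics are physical. The Transwell simulator integrates the linear
two-compartment ODE dQ_b/dt = Pe·A·(C_a − C_b) with the exact piecewise
closed-form solution between sampling events (the concentration
difference decays as exp(−Pe·A·(1/V_a + 1/V_b)·t) with total analyte
conserved), so the pre-noise mass balance closes to machine precision and
the conservation checks are meaningful; measurement noise never feeds
back into the state.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: no cellular compartment in the Transwell
simulator (no lag, no lysate pool, no efflux asymmetry), no unstirred
water layers, no bulk depletion during accumulation, no spectral
crosstalk between isotope channels, no amplification-efficiency
heterogeneity in qPCR, and no single-cell heterogeneity anywhere. The
tests establish that the estimators recover what the models generate at
the study's noise scale, not that the models capture every feature of the
biological system.

## Problem sizes

The statistical studies run at the sizes that make their comparisons
meaningful while staying desk-scale: 100 simulated experiments for
parameter recovery and power, 400 for the F-test size, 100 titrations for
K_D spread and CI coverage, 1000 null and 500 alternative simulations for
the Dunnett operating characteristics. The full suite completes in a few
minutes on one CPU.

## Known limitations

- The ternary equilibrium is specific to this 1:1:1 system; no general
  n-component solver, no albumin or non-specific binding.
- The F-test's nominal reference is approximate under boundary-null
  conditions (K_p\* = 0); its empirical size is verified by simulation
  instead.
- Anisotropy additivity ignores per-species brightness differences.
- Pe_app conflates monolayer and filter unless a filter-only blank is
  supplied.
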