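# rohflux

Quantitative analysis of retinol (vitamin A) transport across in vitro
blood–brain-barrier (BBB) models built from brain microvascular
endothelial-like cell (BMEC) monolayers.

Retinol (ROH) circulates bound to retinol-binding protein (RBP), whose
holo form is in turn bound by transthyretin (TTR). How much ROH a barrier
cell takes up, and how fast retinoid crosses into the "brain" compartment
of a Transwell assay, depends on the equilibrium split of ROH among its
free, RBP-bound, and RBP–TTR-bound states, on threshold-triggered
intracellular storage kinetics, and on careful radiotracer bookkeeping.
`rohflux` packages that entire analysis chain for experimentalists running
radiolabeled accumulation and permeability assays:

- **`rohflux.speciation`** — coupled mass-action equilibria
  `ROH + RBP ⇌ ROH-RBP` (K_D1 = 0.10 µM) and
  `ROH-RBP + TTR ⇌ ROH-RBP-TTR` (K_D2 = 0.25 µM), solved exactly
  (closed-form quadratic inside a bracketed root-find), including the
  TTR-binding-deficient mutant delivery modes.
- **`rohflux.tracer`** — scintillation DPM → µmol via specific activity
  (30 Ci/mmol, 1 Ci = 2.22×10¹² DPM) and hot fraction (1:20 hot:cold),
  cellular concentrations via the measured BMEC volume
  (402 µm² × 3.4 µm = 1.37×10⁻¹² L/cell), and mass-balance closure.
- **`rohflux.uptake`** — the partitioning model
  `c_cell/c_f = K_p (1 − e^{−k₁ t})` and its biphasic extension with a
  second phase triggered once `c_cell` crosses a threshold `c*`
  (lag `t_lag = −ln(1 − c*/(K_p c_f))/k₁`); global least-squares fitting
  and extra-sum-of-squares F-test / AIC model comparison.
- **`rohflux.transwell`** — apparent permeability
  `Pe_app = (dQ/dt)/(A·C_apical,0)` in cm/s with exact correction for
  periodic basolateral sampling-and-replacement, sucrose paracellular QC,
  and TEER area normalization.
- **`rohflux.binding`** — depletion-corrected (Morrison) K_D fits to
  fluorescence titrations, and species-weighted anisotropy prediction.
- **`rohflux.qpcr`** — ΔΔCq relative expression with one-way ANOVA and
  Dunnett's many-to-one test against the buffer control.
- **`rohflux.synthetic`** — generators for every input above with known
  ground truth (accumulation, Transwell transport, titrations, Cq tables).

## Worked example

Solve the serum speciation for the assay conditions (2 µM ROH, 2 µM RBP,
4 µM TTR where present):

```python
import pandas as pd
from rohflux import speciation

conds = pd.DataFrame({
    "label": ["0.1 Free", "2 ROH-RBP", "2 ROH-RBP-TTR", "2 ROH-RBP-muTTR"],
    "mode":  ["Free", "ROH-RBP", "ROH-RBP-TTR", "ROH-RBP-muTTR"],
    "roh_uM": [0.1, 2, 2, 2], "rbp_uM": [0, 2, 2, 2], "ttr_uM": [0, 0, 4, 4],
})
print(speciation.build_speciation_table(conds).round(2).to_string(index=False))
```

```
          label          mode  roh_total_uM  free_roh_uM  roh_rbp_uM  roh_rbp_ttr_uM  apo_rbp_uM  free_ttr_uM
       0.1 Free          Free           0.1         0.10        0.00            0.00        0.00         0.00
      2 ROH-RBP       ROH-RBP           2.0         0.40        1.60            0.00        0.40         0.00
  2 ROH-RBP-TTR   ROH-RBP-TTR           2.0         0.13        0.18            1.68        0.13         2.32
2 ROH-RBP-muTTR ROH-RBP-muTTR           2.0         0.40        1.60            0.00        0.40         4.00
```

With RBP alone, 20% of ROH stays free (0.40 of 2 µM); adding TTR pulls
most ROH into the ternary complex and drops free ROH to ~0.13 µM. The
I84A TTR mutant cannot bind RBP, so that row reduces to the RBP-only
split.

Simulate a three-concentration accumulation experiment and recover the
biphasic kinetics:

```python
from rohflux import synthetic, uptake

tcs, _ = synthetic.simulate_accumulation(seed=7)       # 0.1/0.4/2 µM, 3 reps
fit2 = uptake.fit_uptake(tcs, model=2, seed=0)
fit1 = uptake.fit_uptake(tcs, model=1, seed=0)
cmp_ = uptake.compare_models(fit1, fit2)
print(fit2.params, fit2.t_lag, cmp_.f_stat, cmp_.aic1 - cmp_.aic2)
```

This prints `Kp ≈ 88.9`, `k1 ≈ 0.051 min⁻¹`, `Kp* ≈ 91.7`,
`k1* ≈ 0.019 min⁻¹`, and a triggering threshold `c* ≈ 35.5 µM`
(truth 36 µM), with a lag of ~4.3 min at 2 µM fluid ROH and no trigger at
0.1 µM; the F-test (F ≈ 2705, p ≈ 10⁻¹⁷³) and ΔAIC ≈ 812 decisively favor
the biphasic model, mirroring the concentration-dependent fan-out of
normalized uptake curves that motivates it.

A CLI wraps each stage (`rohflux speciate`, `quantify`, `fit-uptake`,
`permeability`, `binding-fit`, `qpcr`, `simulate`, `run`); see
`rohflux --help`.

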