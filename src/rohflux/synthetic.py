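"""Synthetic-data generators emulating the study's experimental designs.

Every analysis stage in this package has a generator here that produces
its input with known ground truth: accumulation time courses, two-chamber
Transwell transport series, ligand-depletion binding titrations, and qPCR
Cq tables.  Defaults reproduce the study conditions — fluid retinol at
0.1/0.4/2 µM, 0–120 min sampling at 5-min cadence with 3 biological
replicates for accumulation; 12-well Transwell geometry with 15-min
basolateral sampling-and-replacement and 4 replicates; Kd = 100 nM
titrations; and 4 biological x 3 technical qPCR replicates with a
TTR-driven LRAT effect.

Replicate noise is multiplicative Gaussian (parameterized by CV) because
published error bars report SDs without a stated noise model; Poisson
counting noise can additionally be applied at the DPM layer, where
counting statistics are physical.  All generators are deterministic for a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd

from .tracer import CellGeometry, TracerSpec, total_umol_to_dpm
from .transwell import PermeabilitySeries, TranswellSetup
from .uptake import Timecourse, UptakeParams1, UptakeParams2, model1_predict, model2_predict

__all__ = [
    "SimulationConfig",
    "DEFAULT_UPTAKE_TRUTH",
    "simulate_accumulation",
    "simulate_transwell",
    "simulate_titration",
    "simulate_cq",
    "accumulation_to_frame",
    "transwell_series",
]

#: Biphasic ground truth matching the fitted study-scale kinetics:
#: low-concentration plateau ~90 µM/µM, threshold c* = 36 µM.
DEFAULT_UPTAKE_TRUTH = UptakeParams2(Kp=90.0, k1=0.05, Kp_star=90.0, k1_star=0.02, c_star=36.0)

_DESIGNS = ("accumulation", "transwell", "titration", "qpcr")


@dataclass
class SimulationConfig:
    """Declarative simulation request: design name, seed, and overrides."""

    seed: int
    design: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in _DESIGNS:
            raise ValueError(f"design must be one of {_DESIGNS}, got {self.design!r}")

    def run(self):
        fn: Callable = {
            "accumulation": simulate_accumulation,
            "transwell": simulate_transwell,
            "titration": simulate_titration,
            "qpcr": simulate_cq,
        }[self.design]
        return fn(seed=self.seed, **self.params)


# ---------------------------------------------------------------------------
# Accumulation


def simulate_accumulation(
    seed: int,
    truth: UptakeParams1 | UptakeParams2 = DEFAULT_UPTAKE_TRUTH,
    c_fluids: tuple[float, ...] = (0.1, 0.4, 2.0),
    t_max_min: float = 120.0,
    t_step_min: float = 5.0,
    n_rep: int = 3,
    cv: float = 0.05,
    poisson_dpm: bool = False,
    tracer: TracerSpec = TracerSpec(),
    geometry: CellGeometry = CellGeometry(),
    cell_count: float = 1e5,
) -> tuple[list[Timecourse], dict]:
    """Accumulation time courses from the chosen uptake model.

    Replicate curves are the model mean times ``(1 + cv*eps)`` with
    standard-normal eps, clipped at zero.  With ``poisson_dpm`` the noisy
    concentration is additionally routed through the scintillation layer:
    converted to well DPM, Poisson-resampled, and converted back.
    Returns ``(timecourses, truth_record)``.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max_min + 0.5 * t_step_min, t_step_min)
    predict = model2_predict if isinstance(truth, UptakeParams2) else model1_predict
    tcs = []
    for cf in c_fluids:
        mu = predict(times, cf, truth)
        reps = np.clip(mu[None, :] * (1.0 + cv * rng.standard_normal((n_rep, times.size))), 0.0, None)
        if poisson_dpm:
            umol = reps * cell_count * geometry.volume_L  # µM * L = µmol
            dpm = total_umol_to_dpm(umol, tracer)
            dpm = rng.poisson(dpm).astype(float)
            reps = dpm / tracer.dpm_per_umol_total / (cell_count * geometry.volume_L)
        tcs.append(Timecourse(label=f"{cf:g} uM", c_fluid=cf, times=times, c_cell=reps))
    record = {
        "model": 2 if isinstance(truth, UptakeParams2) else 1,
        "params": truth.__dict__.copy(),
        "cv": cv,
        "n_rep": n_rep,
        "seed": seed,
    }
    return tcs, record


def accumulation_to_frame(timecourses: list[Timecourse]) -> pd.DataFrame:
    """Tidy CSV schema ``label,c_fluid_uM,time_min,rep,c_cell_uM``."""
    rows = []
    for tc in timecourses:
        for r in range(tc.c_cell.shape[0]):
            for j, t in enumerate(tc.times):
                rows.append((tc.label, tc.c_fluid, t, r + 1, tc.c_cell[r, j]))
    return pd.DataFrame(rows, columns=["label", "c_fluid_uM", "time_min", "rep", "c_cell_uM"])


# ---------------------------------------------------------------------------
# Transwell


def _integrate_two_compartment(
    pe_cm_s: float,
    setup: TranswellSetup,
    c_apical0_uM: float,
    sample_times_min: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact piecewise solution of the two-compartment transfer ODE.

    dQ_b/dt = Pe*A*(C_a - C_b) is linear, so between sampling events the
    concentration difference decays as exp(-Pe*A*(1/V_a + 1/V_b)*t) and
    total analyte is conserved; this closed form replaces numerical
    integration exactly.  Sampling events read C_b, then remove
    ``sample_volume_L`` (bookkept) and replace with analyte-free buffer.

    Returns (C_a at sample times, C_b at sample times (pre-draw), total
    withdrawn amount in µmol, post-draw final C_b).
    """
    va = setup.v_apical_L * 1e3  # cm³
    vb = setup.v_basolateral_L * 1e3
    kappa = pe_cm_s * setup.area_cm2 * (1.0 / va + 1.0 / vb)  # 1/s
    ca, cb = c_apical0_uM, 0.0
    withdrawn_umol = 0.0
    out_a, out_b = [], []
    prev_t = sample_times_min[0]
    for i, t in enumerate(sample_times_min):
        dt_s = (t - prev_t) * 60.0
        if dt_s > 0:
            m = ca * setup.v_apical_L + cb * setup.v_basolateral_L  # µmol
            vtot = setup.v_apical_L + setup.v_basolateral_L
            ceq = m / vtot
            d = (ca - cb) * math.exp(-kappa * dt_s)
            cb = ceq - d * setup.v_apical_L / vtot
            ca = ceq + d * setup.v_basolateral_L / vtot
        out_a.append(ca)
        out_b.append(cb)
        if setup.sample_volume_L > 0 and i < len(sample_times_min):
            withdrawn_umol += cb * setup.sample_volume_L
            if setup.replace_after_sampling:
                cb *= (setup.v_basolateral_L - setup.sample_volume_L) / setup.v_basolateral_L
            # without replacement the chamber volume would shrink; the
            # protocol always replaces, so that branch is not modeled
        prev_t = t
    # cb now holds the post-draw concentration, which is what remains in
    # the chamber after the final sample; report it for exact bookkeeping
    return np.array(out_a), np.array(out_b), withdrawn_umol, cb


def simulate_transwell(
    seed: int,
    pe_roh: float = 5e-6,
    pe_sucrose: float = 0.6e-6,
    setup: TranswellSetup = TranswellSetup(),
    c_apical_roh_uM: float = 2.0,
    c_apical_sucrose_uM: float = 10.0,
    t_max_min: float = 60.0,
    t_step_min: float = 15.0,
    n_rep: int = 4,
    cv: float = 0.05,
    loss_fraction: float = 0.0,
    tracer: TracerSpec = TracerSpec(),
) -> tuple[pd.DataFrame, dict]:
    """Two-channel (³H-retinol + ¹⁴C-sucrose) Transwell transport series.

    The transport state evolves by the exact two-compartment solution with
    sampling/replacement events every ``t_step_min``; measurement noise is
    multiplicative on the read concentrations and does not feed back into
    the state, so the underlying bookkeeping conserves mass exactly.
    ``loss_fraction`` removes that fraction of the initial dose from the
    ledger (emulating unaccounted losses) without altering transport.

    Returns a tidy frame ``rep,time_min,chamber,channel,conc_uM,dpm,
    volume_uL`` plus a truth record with exact withdrawn amounts.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max_min + 0.5 * t_step_min, t_step_min)
    sucrose_dpm_per_umol = 1.0e6  # nominal ¹⁴C calibration; cancels in Pe
    channels = {
        "3H": (pe_roh, c_apical_roh_uM, tracer.dpm_per_umol_total),
        "14C": (pe_sucrose, c_apical_sucrose_uM, sucrose_dpm_per_umol),
    }
    rows = []
    truth: dict[str, Any] = {
        "pe_roh": pe_roh, "pe_sucrose": pe_sucrose, "seed": seed,
        "loss_fraction": loss_fraction, "withdrawn_umol": {}, "final_state": {},
    }
    for channel, (pe, c0, dpm_per_umol) in channels.items():
        # unaccounted loss comes off the top before transport; the recorded
        # dose is the full charged amount, so recovery reads (1-loss)*100%
        ca, cb, withdrawn, cb_final = _integrate_two_compartment(
            pe, setup, c0 * (1.0 - loss_fraction), times)
        truth["withdrawn_umol"][channel] = withdrawn
        truth["final_state"][channel] = {
            "apical_uM": ca[-1], "basolateral_uM": cb_final,
            "initial_umol": c0 * setup.v_apical_L,
        }
        for rep in range(1, n_rep + 1):
            noise_b = 1.0 + cv * rng.standard_normal(times.size)
            meas_b = np.clip(cb * noise_b, 0.0, None)
            for t, c in zip(times, meas_b):
                dpm = c * setup.sample_volume_L * dpm_per_umol
                rows.append((rep, t, "basolateral", channel, c, dpm,
                             setup.sample_volume_L * 1e6))
            for t, c_true in ((times[0], ca[0]), (times[-1], ca[-1])):
                c = max(c_true * (1.0 + cv * rng.standard_normal()), 0.0)
                rows.append((rep, t, "apical", channel, c,
                             c * setup.sample_volume_L * dpm_per_umol,
                             setup.sample_volume_L * 1e6))
    frame = pd.DataFrame(
        rows, columns=["rep", "time_min", "chamber", "channel", "conc_uM", "dpm", "volume_uL"]
    )
    return frame, truth


def transwell_series(
    frame: pd.DataFrame, channel: str, rep: int, analyte: str = "ROH"
) -> PermeabilitySeries:
    """Extract one replicate/channel as a :class:`PermeabilitySeries`."""
    sub = frame[(frame["channel"] == channel) & (frame["rep"] == rep)]
    baso = sub[sub["chamber"] == "basolateral"].sort_values("time_min")
    apical0 = sub[(sub["chamber"] == "apical")].sort_values("time_min")["conc_uM"].iloc[0]
    return PermeabilitySeries(
        times=baso["time_min"].to_numpy(),
        basolateral_conc=baso["conc_uM"].to_numpy(),
        apical_conc_t0=float(apical0),
        analyte=analyte,
    )


# ---------------------------------------------------------------------------
# Titration


def simulate_titration(
    seed: int,
    kd_nM: float = 100.0,
    protein_uM: float = 0.25,
    ligand_max_uM: float = 2.5,
    n_points: int = 12,
    s0: float = 0.05,
    s_max: float = 1.0,
    noise_frac: float = 0.03,
    amplitude_scale: float = 1.0,
):
    """Depletion-corrected fluorescence titration with known Kd.

    Additive Gaussian noise with SD ``noise_frac * (s_max - s0)``.
    ``amplitude_scale`` shrinks the saturation signal without touching the
    Kd (the reduced-energy-transfer mutant case).  Protein is held at
    0.25 µM — a few times Kd — which keeps the dissociation constant
    identifiable while still requiring the depletion correction.
    """
    from .binding import TitrationCurve, fraction_bound_quadratic

    rng = np.random.default_rng(seed)
    kd_uM = kd_nM * 1e-3
    ligand = np.linspace(0.0, ligand_max_uM, n_points)
    smax_eff = s0 + amplitude_scale * (s_max - s0)
    bound = fraction_bound_quadratic(ligand, protein_uM, kd_uM)
    signal = s0 + (smax_eff - s0) * bound / protein_uM
    signal = signal + noise_frac * (s_max - s0) * rng.standard_normal(ligand.size)
    curve = TitrationCurve(protein_total=protein_uM, ligand_totals=ligand, signal=signal)
    truth = {"kd_nM": kd_nM, "s_max": smax_eff, "s0": s0, "seed": seed}
    return curve, truth


# ---------------------------------------------------------------------------
# qPCR


def simulate_cq(
    seed: int,
    genes: tuple[str, ...] = ("STRA6", "CRBP1", "LRAT"),
    housekeeping: str = "ACTB",
    conditions: tuple[str, ...] = (
        "HBSS", "ROH", "ROH-RBP", "ROH-muRBP", "ROH-RBP-TTR", "ROH-RBP-muTTR",
    ),
    effects: dict[str, dict[str, float]] | None = None,
    baselines: dict[str, float] | None = None,
    sigma_bio: float = 0.4,
    sigma_tech: float = 0.15,
    n_bio: int = 4,
    n_tech: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Cq table with per-gene, per-condition log2 fold-change effects.

    Default effects inject a +1.5 log2 fold change of LRAT in the two
    TTR-containing conditions and nothing elsewhere (the observed
    expression pattern: TTR upregulates LRAT whether or not it can bind
    RBP).  Target-gene Cq = baseline − log2FC + biological noise (shared
    across technical reads) + technical noise; the housekeeping gene
    carries technical noise only.
    """
    if effects is None:
        effects = {"LRAT": {"ROH-RBP-TTR": 1.5, "ROH-RBP-muTTR": 1.5}}
    if baselines is None:
        baselines = {housekeeping: 18.0, **{g: 24.0 for g in genes}}
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        for b in range(1, n_bio + 1):
            bio_eps = {g: rng.normal(0.0, sigma_bio) for g in genes}
            for gene in (*genes, housekeeping):
                if gene == housekeeping:
                    mu = baselines[gene]
                else:
                    fc = effects.get(gene, {}).get(cond, 0.0)
                    mu = baselines[gene] - fc + bio_eps[gene]
                for tch in range(1, n_tech + 1):
                    cq = mu + rng.normal(0.0, sigma_tech)
                    rows.append((gene, cond, b, tch, cq))
    frame = pd.DataFrame(rows, columns=["gene", "condition", "bio_rep", "tech_rep", "cq"])
    truth = {
        "effects": effects, "sigma_bio": sigma_bio, "sigma_tech": sigma_tech,
        "n_bio": n_bio, "n_tech": n_tech, "seed": seed,
    }
    return frame, truth
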