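"""Equilibrium speciation of retinol among its serum carriers.

Retinol (ROH) in serum partitions between a free-lipid state and two
protein-bound states: the binary complex with retinol-binding protein
(ROH-RBP) and the ternary complex with transthyretin (ROH-RBP-TTR).
Given total concentrations and the two dissociation constants

    Kd1 = [ROH][RBP] / [ROH-RBP]
    Kd2 = [ROH-RBP][TTR] / [ROH-RBP-TTR]

this module solves the coupled mass-action equilibria for all five
species.  A single effective RBP site per TTR tetramer is assumed
(1:1:1 stoichiometry), and binding of ligand-free apo-RBP to TTR is
neglected; both choices are consistent with measured serum speciation.

All concentrations are µM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "BindingConstants",
    "MixtureTotals",
    "Speciation",
    "SpeciationError",
    "solve_two_component",
    "solve_speciation",
    "build_speciation_table",
    "DELIVERY_MODES",
]


class SpeciationError(ValueError):
    """Invalid speciation input or failed equilibrium solve."""


@dataclass(frozen=True)
class BindingConstants:
    """Dissociation constants for the two sequential binding steps (µM).

    Defaults are the measured values for recombinant human proteins:
    ROH·RBP Kd = 100 nM and (ROH-RBP)·TTR Kd = 250 nM.
    """

    kd_roh_rbp: float = 0.10
    kd_rohrbp_ttr: float = 0.25

    def __post_init__(self) -> None:
        for name in ("kd_roh_rbp", "kd_rohrbp_ttr"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise SpeciationError(f"{name} must be strictly positive and finite, got {v}")


@dataclass(frozen=True)
class MixtureTotals:
    """Total (free + bound) concentrations of the three components (µM)."""

    roh_total: float
    rbp_total: float
    ttr_total: float = 0.0

    def __post_init__(self) -> None:
        for name in ("roh_total", "rbp_total", "ttr_total"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise SpeciationError(f"{name} must be non-negative and finite, got {v}")


@dataclass(frozen=True)
class Speciation:
    """Equilibrium concentrations of the five species (µM) plus diagnostics."""

    free_roh: float
    apo_rbp: float
    roh_rbp: float
    free_ttr: float
    roh_rbp_ttr: float
    residuals: dict = field(default_factory=dict, compare=False)

    @property
    def roh_total(self) -> float:
        return self.free_roh + self.roh_rbp + self.roh_rbp_ttr

    @property
    def rbp_total(self) -> float:
        return self.apo_rbp + self.roh_rbp + self.roh_rbp_ttr

    @property
    def ttr_total(self) -> float:
        return self.free_ttr + self.roh_rbp_ttr

    def roh_fractions(self) -> tuple[float, float, float]:
        """Fractions of total ROH that are free, RBP-bound, and TTR-complexed."""
        tot = self.roh_total
        if tot <= 0:
            raise SpeciationError("no ROH present; fractions undefined")
        return (self.free_roh / tot, self.roh_rbp / tot, self.roh_rbp_ttr / tot)


def solve_two_component(roh_total: float, rbp_total: float, kd: float) -> tuple[float, float]:
    """Closed-form 1:1 binding equilibrium.

    Returns ``(free_roh, roh_rbp)`` for the physical root of the binding
    quadratic.  Uses the cancellation-safe form of the root so that tight
    binding (kd much smaller than the totals) stays accurate.
    """
    if roh_total < 0 or rbp_total < 0:
        raise SpeciationError("totals must be non-negative")
    if not kd > 0:
        raise SpeciationError("kd must be strictly positive")
    if roh_total == 0 or rbp_total == 0:
        return roh_total, 0.0
    s = roh_total + rbp_total + kd
    disc = s * s - 4.0 * roh_total * rbp_total
    # disc >= kd^2 > 0 analytically; guard against rounding
    root = math.sqrt(max(disc, 0.0))
    bound = 2.0 * roh_total * rbp_total / (s + root)
    bound = min(bound, roh_total, rbp_total)
    return roh_total - bound, bound


def solve_speciation(
    totals: MixtureTotals,
    constants: BindingConstants = BindingConstants(),
    *,
    xtol: float = 1e-14,
) -> Speciation:
    """Solve the coupled ROH/RBP/TTR equilibria.

    The outer problem is a bounded scalar root-find on the free TTR
    concentration ``y`` in [0, ttr_total].  For fixed ``y`` the ROH/RBP
    subproblem collapses to a 1:1 binding quadratic with the apparent
    constant ``Kd1 / (1 + y/Kd2)`` (TTR pulls the RBP equilibrium toward
    the bound side), solved in closed form.  Bracketing guarantees
    convergence with no initialization sensitivity.
    """
    kd1, kd2 = constants.kd_roh_rbp, constants.kd_rohrbp_ttr
    R, P, T = totals.roh_total, totals.rbp_total, totals.ttr_total

    def split(y: float) -> tuple[float, float, float]:
        """Given free TTR, return (free_roh, roh_rbp, roh_rbp_ttr)."""
        amp = 1.0 + y / kd2
        free, bound = solve_two_component(R, P, kd1 / amp)
        rp = bound / amp
        return free, rp, bound - rp

    if T == 0 or R == 0 or P == 0:
        free, bound = solve_two_component(R, P, kd1)
        y, rpt = T, 0.0
        rp = bound
    else:
        def residual(y: float) -> float:
            return y + split(y)[2] - T

        try:
            y = brentq(residual, 0.0, T, xtol=xtol, rtol=8.9e-16, maxiter=200)
        except Exception as exc:  # pragma: no cover - bracketing makes this unreachable
            raise SpeciationError(
                f"TTR equilibrium did not converge: residual(0)={residual(0.0):.3g}, "
                f"residual(T)={residual(T):.3g}"
            ) from exc
        free, rp, rpt = split(y)

    apo = P - rp - rpt
    diag = {
        "mass_roh": free + rp + rpt - R,
        "mass_rbp": apo + rp + rpt - P,
        "mass_ttr": y + rpt - T,
        "kd1_rel": (free * apo / rp - kd1) / kd1 if rp > 0 else 0.0,
        "kd2_rel": (rp * y / rpt - kd2) / kd2 if rpt > 0 else 0.0,
    }
    return Speciation(free, max(apo, 0.0), rp, y, rpt, residuals=diag)


# Delivery modes of the accumulation/permeability assays.  Mutants change
# binding parameters, not code paths: muRBP binds ROH normally but not TTR,
# and muTTR (I84A) does not bind ROH-RBP, so both reduce to the RBP-only solve.
DELIVERY_MODES = {
    "free": "free",
    "roh-rbp": "rbp",
    "rbp": "rbp",
    "roh-murbp": "rbp",
    "murbp": "rbp",
    "roh-rbp-ttr": "rbp+ttr",
    "rbp+ttr": "rbp+ttr",
    "roh-rbp-muttr": "rbp",
    "rbp+muttr": "rbp",
}


def build_speciation_table(
    conditions: pd.DataFrame,
    constants: BindingConstants = BindingConstants(),
) -> pd.DataFrame:
    """Solve speciation for a table of labelled assay conditions.

    ``conditions`` needs columns ``label, mode, roh_uM, rbp_uM, ttr_uM``.
    Mode is one of the delivery labels (case-insensitive): free, ROH-RBP,
    ROH-muRBP, ROH-RBP-TTR, ROH-RBP-muTTR.  TTR-binding-incompetent modes
    are solved with the TTR step disabled.
    """
    required = {"label", "mode", "roh_uM", "rbp_uM", "ttr_uM"}
    missing = required - set(conditions.columns)
    if missing:
        raise SpeciationError(f"conditions table missing columns: {sorted(missing)}")
    rows = []
    for rec in conditions.itertuples(index=False):
        key = str(rec.mode).strip().lower()
        if key not in DELIVERY_MODES:
            raise SpeciationError(
                f"unknown delivery mode {rec.mode!r} for condition {rec.label!r}; "
                f"expected one of {sorted(set(DELIVERY_MODES))}"
            )
        canonical = DELIVERY_MODES[key]
        if canonical == "free":
            totals = MixtureTotals(rec.roh_uM, 0.0, 0.0)
        elif canonical == "rbp":
            totals = MixtureTotals(rec.roh_uM, rec.rbp_uM, 0.0)
        else:
            totals = MixtureTotals(rec.roh_uM, rec.rbp_uM, rec.ttr_uM)
        sp = solve_speciation(totals, constants)
        rows.append(
            {
                "label": rec.label,
                "mode": rec.mode,
                "roh_total_uM": rec.roh_uM,
                "free_roh_uM": sp.free_roh,
                "roh_rbp_uM": sp.roh_rbp,
                "roh_rbp_ttr_uM": sp.roh_rbp_ttr,
                "apo_rbp_uM": sp.apo_rbp,
                "free_ttr_uM": sp.free_ttr if canonical == "rbp+ttr" else rec.ttr_uM,
            }
        )
    columns = [
        "label", "mode", "roh_total_uM", "free_roh_uM", "roh_rbp_uM",
        "roh_rbp_ttr_uM", "apo_rbp_uM", "free_ttr_uM",
    ]
    return pd.DataFrame(rows, columns=columns)
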