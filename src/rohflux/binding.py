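"""Equilibrium binding fits from fluorescence titrations, and anisotropy.

Retinol binds RBP tightly (Kd ~ 100 nM) relative to the protein
concentrations used in titrations, so the free-ligand approximation fails
and the depletion-corrected (Morrison) isotherm is required:

    bound = [(P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)] / 2

The fluorescence readout (retinol emission at 460 nm via resonance energy
transfer from protein tryptophans) is modeled as affine in the bound
fraction:  signal = s0 + (s_max - s0) * bound / P.  Binding amplitude and
affinity decouple: a mutant with half the energy-transfer efficiency
halves s_max without moving Kd.

Fluorescence anisotropy of bound retinol increases with complex size; the
population anisotropy is predicted as the species-fraction-weighted mean,
assuming equal quantum yield across species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .speciation import Speciation, solve_two_component

__all__ = [
    "TitrationCurve",
    "BindingFit",
    "BindingError",
    "fraction_bound_quadratic",
    "fit_kd",
    "anisotropy_predict",
]


class BindingError(ValueError):
    """Invalid binding-assay input."""


@dataclass
class TitrationCurve:
    """Fluorescence titration at fixed protein, varying total ligand (µM)."""

    protein_total: float
    ligand_totals: np.ndarray
    signal: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ligand_totals = np.asarray(self.ligand_totals, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if not self.protein_total > 0:
            raise BindingError("protein_total must be positive")
        if np.any(self.ligand_totals < 0):
            raise BindingError("ligand_totals must be non-negative")
        if np.any(np.diff(self.ligand_totals) < 0):
            raise BindingError("ligand_totals must be sorted ascending")
        if not np.all(np.isfinite(self.signal)):
            raise BindingError("signal must be finite")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)


@dataclass(frozen=True)
class BindingFit:
    """Fitted dissociation constant with uncertainty (Kd reported in nM)."""

    kd_nM: float
    s_max: float
    s0: float
    se_kd_nM: float
    ci95_kd_nM: tuple[float, float]
    wide_ci: bool = False

    @property
    def kd_uM(self) -> float:
        return self.kd_nM * 1e-3


def fraction_bound_quadratic(ligand_total, protein_total: float, kd: float):
    """Bound complex concentration (µM) under 1:1 binding with depletion.

    Same physical root as the speciation two-component solve; exposed here
    in the (ligand, protein) orientation of a titration.
    """
    ligand_total = np.asarray(ligand_total, dtype=float)
    if np.any(ligand_total < 0) or protein_total < 0:
        raise BindingError("concentrations must be non-negative")
    if not kd > 0:
        raise BindingError("kd must be positive")
    s = ligand_total + protein_total + kd
    disc = np.maximum(s * s - 4.0 * ligand_total * protein_total, 0.0)
    bound = 2.0 * ligand_total * protein_total / (s + np.sqrt(disc))
    bound = np.minimum(bound, np.minimum(ligand_total, protein_total))
    return float(bound) if bound.ndim == 0 else bound


def _signal_model(L, kd, s_max, s0, P):
    return s0 + (s_max - s0) * fraction_bound_quadratic(L, P, kd) / P


def fit_kd(curve: TitrationCurve, *, wide_ci_factor: float = 1.0) -> BindingFit:
    """Fit (Kd, s_max, s0) to a depletion-corrected titration curve.

    Requires at least 6 points spanning sub- to super-stoichiometric
    ligand.  Standard errors come from the Jacobian covariance; the 95% CI
    uses the t distribution with n - 3 degrees of freedom.  A CI wider
    than the estimate itself sets ``wide_ci`` (non-saturating curve).
    """
    L, y, P = curve.ligand_totals, curve.signal, curve.protein_total
    if L.size < 6:
        raise BindingError("need at least 6 titration points")
    if L.max() <= P:
        raise BindingError("titration must extend beyond stoichiometric ligand")
    s0_guess = float(y[0])
    smax_guess = float(y[-1])
    kd_guess = max(0.1 * P, 1e-4)
    popt, pcov = curve_fit(
        lambda l, kd, smax, s0: _signal_model(l, kd, smax, s0, P),
        L, y, p0=[kd_guess, smax_guess, s0_guess],
        bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    kd, s_max, s0 = popt
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    dof = max(L.size - 3, 1)
    tcrit = stats.t.ppf(0.975, dof)
    ci = (kd - tcrit * se[0], kd + tcrit * se[0])
    wide = (ci[1] - ci[0]) > wide_ci_factor * 2.0 * kd
    if wide:
        import warnings

        warnings.warn("titration poorly saturating: Kd confidence interval is wide",
                      stacklevel=2)
    return BindingFit(
        kd_nM=kd * 1e3, s_max=float(s_max), s0=float(s0),
        se_kd_nM=float(se[0] * 1e3),
        ci95_kd_nM=(float(ci[0] * 1e3), float(ci[1] * 1e3)),
        wide_ci=bool(wide),
    )


def anisotropy_predict(
    spec: Speciation, r_free: float, r_rbp: float, r_ttr_complex: float
) -> float:
    """Population anisotropy of retinol as the species-weighted mean.

    Weights are the fractions of total retinol in the free, RBP-bound, and
    TTR-complexed states; anisotropies must lie in the physical [0, 0.4]
    range.  Equal brightness across species is assumed.
    """
    for name, r in (("r_free", r_free), ("r_rbp", r_rbp), ("r_ttr_complex", r_ttr_complex)):
        if not (0.0 <= r <= 0.4):
            raise BindingError(f"{name} must be in [0, 0.4], got {r}")
    try:
        fracs = spec.roh_fractions()
    except ValueError as exc:
        raise BindingError(str(exc)) from exc
    if not math.isclose(sum(fracs), 1.0, rel_tol=1e-9):
        raise BindingError("species fractions do not sum to 1")
    return fracs[0] * r_free + fracs[1] * r_rbp + fracs[2] * r_ttr_complex
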