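"""Apparent permeability from Transwell time series.

A solute charged to the apical chamber crosses the cell monolayer plus
filter into the basolateral chamber.  Under sink conditions (receiver
concentration a small fraction of the donor's) the cumulative transported
amount Q grows linearly and the combined apparent permeability is

    Pe_app = (dQ/dt) / (A * C_apical,0)        [cm/s]

with membrane area A (cm²) and initial donor concentration C_apical,0.
Periodic basolateral sampling with buffer replacement removes analyte, so
Q must credit earlier draws back:

    Q(t_k) = C_b(t_k) * V_b + sum_{j<k} C_b(t_j) * V_sample

Barrier integrity is checked by a co-dosed paracellular marker (sucrose)
and by area-normalized transendothelial electrical resistance (TEER).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TranswellSetup",
    "PermeabilitySeries",
    "PermeabilityResult",
    "TranswellError",
    "cumulative_amount",
    "apparent_permeability",
    "teer_area_normalize",
    "paracellular_qc",
    "deconvolve_filter",
]

#: (µmol/min) / (cm² · µM·(mol/cm³ per µM)) → cm/s conversion:
#: 1 µmol/min = 1e-6/60 mol/s and 1 µM = 1e-9 mol/cm³.
_UMOL_MIN_TO_CM_S = (1e-6 / 60.0) / 1e-9


class TranswellError(ValueError):
    """Invalid Transwell series or setup."""


@dataclass(frozen=True)
class TranswellSetup:
    """Geometry and sampling protocol of the Transwell assay.

    Defaults follow the 12-well format: 1.12 cm² insert, 550 µL apical and
    1500 µL basolateral volumes.  The basolateral chamber is sampled
    periodically; withdrawn volume is replaced with analyte-free buffer,
    and total sampling stays within 10% of the chamber volume (30 µL per
    draw across five draws by default).
    """

    area_cm2: float = 1.12
    v_apical_L: float = 550e-6
    v_basolateral_L: float = 1.5e-3
    sample_volume_L: float = 30e-6
    replace_after_sampling: bool = True

    def __post_init__(self) -> None:
        if min(self.area_cm2, self.v_apical_L, self.v_basolateral_L) <= 0:
            raise TranswellError("area and chamber volumes must be positive")
        if self.sample_volume_L < 0:
            raise TranswellError("sample volume must be non-negative")
        if self.sample_volume_L > self.v_basolateral_L:
            raise TranswellError("sample volume exceeds basolateral chamber volume")


@dataclass
class PermeabilitySeries:
    """Basolateral concentration readings for one analyte in one well."""

    times: np.ndarray
    basolateral_conc: np.ndarray  # µM, measured just before each draw
    apical_conc_t0: float
    analyte: str = "ROH"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.basolateral_conc = np.asarray(self.basolateral_conc, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise TranswellError("times must be strictly increasing")
        if np.any(self.basolateral_conc < 0):
            raise TranswellError("concentrations must be non-negative")
        if not self.apical_conc_t0 > 0:
            raise TranswellError("apical_conc_t0 must be positive")


@dataclass(frozen=True)
class PermeabilityResult:
    """Apparent permeability with regression diagnostics and QC flags."""

    pe_app: float  # cm/s
    slope_umol_per_min: float
    intercept_umol: float
    r_squared: float
    fit_window: tuple[float, float]
    n_points: int
    qc: dict = field(default_factory=dict, compare=False)


def cumulative_amount(series: PermeabilitySeries, setup: TranswellSetup) -> np.ndarray:
    """Sampling-corrected cumulative transported amount Q(t), µmol.

    Each measured concentration is assumed taken immediately before that
    time point's draw; all earlier draws removed ``C_b(t_j) * V_sample``
    of analyte, which is credited back.  With zero sampling volume this
    reduces to ``C_b * V_b``.
    """
    c = series.basolateral_conc
    q = c * setup.v_basolateral_L
    if setup.sample_volume_L > 0:
        withdrawn = np.concatenate([[0.0], np.cumsum(c[:-1] * setup.sample_volume_L)])
        q = q + withdrawn
    return q


def apparent_permeability(
    times_min: np.ndarray,
    q_umol: np.ndarray,
    apical_conc_t0_uM: float,
    area_cm2: float,
    fit_window: tuple[float, float] = (15.0, 60.0),
) -> PermeabilityResult:
    """Apparent permeability (cm/s) from a cumulative-amount series.

    A free-intercept least-squares line is fit to Q(t) inside
    ``fit_window`` (minutes); the default window starts at 15 min to skip
    the short initial lag before the basolateral rise turns linear, and
    the free intercept keeps any residual lag from biasing the slope.  A
    negative fitted slope is reported as Pe_app = 0 with a warning flag.
    """
    times_min = np.asarray(times_min, dtype=float)
    q_umol = np.asarray(q_umol, dtype=float)
    if not apical_conc_t0_uM > 0:
        raise TranswellError("apical_conc_t0_uM must be positive")
    if not area_cm2 > 0:
        raise TranswellError("area_cm2 must be positive")
    lo, hi = fit_window
    mask = (times_min >= lo) & (times_min <= hi)
    if mask.sum() < 3:
        raise TranswellError(
            f"fit window {fit_window} contains {int(mask.sum())} points; need >= 3"
        )
    res = stats.linregress(times_min[mask], q_umol[mask])
    slope = float(res.slope)
    qc = {"negative_slope": False}
    if slope < 0:
        warnings.warn("negative transport slope; reporting Pe_app = 0", stacklevel=2)
        qc["negative_slope"] = True
        pe = 0.0
    else:
        pe = slope * _UMOL_MIN_TO_CM_S / (area_cm2 * apical_conc_t0_uM)
    return PermeabilityResult(
        pe_app=pe,
        slope_umol_per_min=slope,
        intercept_umol=float(res.intercept),
        r_squared=float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0,
        fit_window=(lo, hi),
        n_points=int(mask.sum()),
        qc=qc,
    )


def teer_area_normalize(resistance_ohm: float, area_cm2: float) -> float:
    """Area-normalized TEER (Ω·cm²)."""
    if resistance_ohm < 0 or area_cm2 <= 0:
        raise TranswellError("resistance must be >= 0 and area > 0")
    return resistance_ohm * area_cm2


def paracellular_qc(pe_sucrose: float, threshold: float = 1e-6) -> bool:
    """Barrier-integrity check: sucrose permeability at or below threshold passes."""
    if pe_sucrose < 0:
        raise TranswellError("pe_sucrose must be non-negative")
    return pe_sucrose <= threshold


def deconvolve_filter(pe_total: float, pe_filter: float) -> float:
    """Monolayer-only permeability from series resistances:
    1/Pe_cell = 1/Pe_total - 1/Pe_filter.  Optional — the combined
    monolayer+filter value is what is normally reported."""
    if not (0 < pe_total < pe_filter):
        raise TranswellError("requires 0 < pe_total < pe_filter")
    return 1.0 / (1.0 / pe_total - 1.0 / pe_filter)
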