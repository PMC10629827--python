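"""Radiotracer quantification: DPM to moles and cellular concentrations.

Scintillation counters report disintegrations per minute (DPM).  With the
tracer's specific activity (Ci per mmol of labeled compound) and the hot
fraction (mole fraction of labeled compound in the tracer-diluted stock),
DPM converts linearly to total micromoles of compound:

    total_umol = dpm / (SA * 2.22e12 * 1e-3 * hot_fraction)

where 1 Ci = 2.22e12 DPM.  Dividing by the aggregate cell volume of a well
yields the accumulated intracellular concentration in µM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DPM_PER_CI",
    "TracerSpec",
    "CellGeometry",
    "TracerError",
    "cell_volume",
    "dpm_to_total_umol",
    "total_umol_to_dpm",
    "cellular_concentration_uM",
    "mass_balance_fraction",
    "quantify_table",
]

#: Disintegrations per minute in one curie (physical constant).
DPM_PER_CI = 2.22e12


class TracerError(ValueError):
    """Invalid tracer specification or measurement."""


@dataclass(frozen=True)
class TracerSpec:
    """Radiotracer stock description.

    specific_activity: Ci per mmol of *labeled* compound (³H-retinol ships
        at 30 Ci/mmol).
    hot_fraction: labeled/(labeled+unlabeled) mole fraction.  A 1:20
        hot:cold dilution gives 1/21 ≈ 4.8%; re-quantified per batch in
        practice, hence configurable.
    """

    specific_activity: float = 30.0
    hot_fraction: float = 1.0 / 21.0

    def __post_init__(self) -> None:
        if not self.specific_activity > 0:
            raise TracerError("specific_activity must be > 0")
        if not (0.0 < self.hot_fraction <= 1.0):
            raise TracerError("hot_fraction must be in (0, 1]")

    @property
    def dpm_per_umol_total(self) -> float:
        """DPM produced by 1 µmol of total (labeled + unlabeled) compound."""
        return self.specific_activity * DPM_PER_CI * 1e-3 * self.hot_fraction


@dataclass(frozen=True)
class CellGeometry:
    """Mean single-cell geometry of the barrier-forming monolayer.

    Defaults are the measured brain microvascular endothelial-like cell
    footprint (402 µm²) and monolayer height (3.4 µm), giving a cell
    volume of 1.37e-12 L.
    """

    area_um2: float = 402.0
    height_um: float = 3.4

    def __post_init__(self) -> None:
        if not (self.area_um2 > 0 and self.height_um > 0):
            raise TracerError("cell geometry dimensions must be positive")

    @property
    def volume_L(self) -> float:
        return cell_volume(self.area_um2, self.height_um)


def cell_volume(area_um2: float, height_um: float) -> float:
    """Per-cell volume in liters from footprint area (µm²) and height (µm)."""
    if not (area_um2 > 0 and height_um > 0):
        raise TracerError("area and height must be positive")
    return area_um2 * height_um * 1e-15  # 1 µm³ = 1e-15 L


def dpm_to_total_umol(dpm: float, spec: TracerSpec = TracerSpec()) -> float:
    """Total µmol of compound (labeled + unlabeled) represented by ``dpm``."""
    dpm = np.asarray(dpm, dtype=float)
    if np.any(dpm < 0):
        raise TracerError("dpm must be non-negative")
    out = dpm / spec.dpm_per_umol_total
    return float(out) if out.ndim == 0 else out


def total_umol_to_dpm(umol: float, spec: TracerSpec = TracerSpec()) -> float:
    """Inverse of :func:`dpm_to_total_umol`."""
    umol = np.asarray(umol, dtype=float)
    if np.any(umol < 0):
        raise TracerError("umol must be non-negative")
    out = umol * spec.dpm_per_umol_total
    return float(out) if out.ndim == 0 else out


def cellular_concentration_uM(
    dpm: float,
    spec: TracerSpec,
    cell_count: float,
    cell_volume_L: float,
) -> float:
    """Accumulated concentration (µM) inside the aggregate cell volume."""
    if not cell_count > 0:
        raise TracerError("cell_count must be positive")
    if not cell_volume_L > 0:
        raise TracerError("cell_volume_L must be positive")
    return dpm_to_total_umol(dpm, spec) / (cell_count * cell_volume_L)


def mass_balance_fraction(
    initial_dose_dpm: float,
    apical_final_dpm: float,
    basolateral_dpm: Iterable[float] | float,
    lysate_dpm: float = 0.0,
) -> float:
    """Percent of the initial radioactive dose recovered at assay end.

    ``basolateral_dpm`` covers everything that reached the receiver side:
    the final chamber contents plus all previously withdrawn samples.  A
    lossless experiment (or noise-free simulation) closes at 100%.
    """
    if not initial_dose_dpm > 0:
        raise TracerError("initial dose must be positive")
    baso = np.atleast_1d(np.asarray(basolateral_dpm, dtype=float))
    parts = np.concatenate([[apical_final_dpm, lysate_dpm], baso])
    if np.any(parts < 0):
        raise TracerError("DPM measurements must be non-negative")
    return float(parts.sum() / initial_dose_dpm * 100.0)


def quantify_table(
    table: pd.DataFrame,
    spec: TracerSpec = TracerSpec(),
    geometry: CellGeometry = CellGeometry(),
    cell_count: float | None = None,
) -> pd.DataFrame:
    """Add molar columns to a tidy DPM table.

    Input schema: ``well,label,time_min,channel,dpm,volume_uL``.  Replicate
    counting reads for the same (well, label, time_min, channel) are first
    averaged (arithmetic mean of technical reads).  Adds ``total_umol`` and,
    for lysate rows when ``cell_count`` is given, ``conc_uM`` (per cell
    volume); for fluid rows ``conc_uM`` is per sampled fluid volume.
    """
    required = {"well", "label", "time_min", "channel", "dpm", "volume_uL"}
    missing = required - set(table.columns)
    if missing:
        raise TracerError(f"missing columns: {sorted(missing)}")
    keys = ["well", "label", "time_min", "channel"]
    agg = table.groupby(keys, as_index=False).agg(
        dpm=("dpm", "mean"), volume_uL=("volume_uL", "first")
    )
    agg["total_umol"] = dpm_to_total_umol(agg["dpm"].to_numpy(), spec)
    is_lysate = agg["label"].astype(str).str.lower().eq("lysate")
    conc = np.full(len(agg), np.nan)
    fluid = ~is_lysate & (agg["volume_uL"] > 0)
    conc[fluid] = agg.loc[fluid, "total_umol"] / (agg.loc[fluid, "volume_uL"] * 1e-6)
    if cell_count is not None:
        conc[is_lysate] = agg.loc[is_lysate, "total_umol"] / (cell_count * geometry.volume_L)
    agg["conc_uM"] = conc
    return agg
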