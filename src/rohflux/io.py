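"""Shared table readers, run configuration, and the pipeline driver.

Unit conventions, asserted at the I/O boundary: concentrations µM, volumes
L (µL only in column names suffixed ``_uL``), times min, permeabilities
cm/s.  CSV dialect: comma-separated, UTF-8, ``.`` decimal, mandatory
header row.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .speciation import BindingConstants
from .tracer import CellGeometry, TracerSpec
from .transwell import TranswellSetup

__all__ = [
    "SCHEMAS",
    "IOError_",
    "RunConfig",
    "read_table",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger("rohflux")


class IOError_(ValueError):
    """Malformed input file (named row/column in the message)."""


#: column -> (dtype, non_negative) per input kind
SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "conditions": {
        "label": ("str", False), "mode": ("str", False),
        "roh_uM": ("float", True), "rbp_uM": ("float", True), "ttr_uM": ("float", True),
    },
    "timecourse": {
        "label": ("str", False), "c_fluid_uM": ("float", True),
        "time_min": ("float", True), "rep": ("int", True), "c_cell_uM": ("float", True),
    },
    "transwell": {
        "rep": ("int", True), "time_min": ("float", True), "chamber": ("str", False),
        "channel": ("str", False), "dpm": ("float", True), "volume_uL": ("float", True),
    },
    "titration": {
        "ligand_total_uM": ("float", True), "signal": ("float", False),
    },
    "cq": {
        "gene": ("str", False), "condition": ("str", False),
        "bio_rep": ("int", True), "tech_rep": ("int", True), "cq": ("float", True),
    },
    "dpm_wells": {
        "well": ("str", False), "label": ("str", False), "time_min": ("float", True),
        "channel": ("str", False), "dpm": ("float", True), "volume_uL": ("float", True),
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against one of the named schemas.

    Header order is irrelevant; extra columns pass through.  Missing
    columns, non-numeric cells, and negative values in non-negative
    columns raise :class:`IOError_` naming the offending row/column.
    """
    if schema not in SCHEMAS:
        raise IOError_(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise IOError_(f"file not found: {path}")
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise IOError_(f"{path}: empty file") from exc
    spec = SCHEMAS[schema]
    missing = set(spec) - set(table.columns)
    if missing:
        raise IOError_(f"{path}: missing column(s) {sorted(missing)}")
    if len(table) == 0:
        raise IOError_(f"{path}: no data rows")
    for col, (dtype, non_negative) in spec.items():
        if dtype in ("float", "int"):
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = coerced.isna() & table[col].notna()
            if bad.any() or table[col].isna().any():
                row = int(table.index[bad | table[col].isna()][0])
                raise IOError_(f"{path}: non-numeric value in column {col!r}, row {row}")
            table[col] = coerced.astype(float if dtype == "float" else int)
            if non_negative and (table[col] < 0).any():
                row = int(table.index[table[col] < 0][0])
                raise IOError_(f"{path}: negative value in column {col!r}, row {row}")
        else:
            table[col] = table[col].astype(str)
    logger.info("read %s: %d rows (%s schema)", path, len(table), schema)
    return table


@dataclass
class RunConfig:
    """Validated run configuration (YAML on disk, units in key names)."""

    binding_constants: BindingConstants = field(default_factory=BindingConstants)
    tracer: TracerSpec = field(default_factory=TracerSpec)
    geometry: CellGeometry = field(default_factory=CellGeometry)
    transwell: TranswellSetup = field(default_factory=TranswellSetup)
    seed: int = 0
    cell_count: float = 1e5
    binding_protein_uM: float = 2.0
    housekeeping: str = "ACTB"
    control_condition: str = "HBSS"
    paths: dict[str, str] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = {
            "binding_constants": asdict(self.binding_constants),
            "tracer": asdict(self.tracer),
            "geometry": asdict(self.geometry),
            "transwell": asdict(self.transwell),
            "seed": self.seed,
            "cell_count": self.cell_count,
            "binding_protein_uM": self.binding_protein_uM,
            "housekeeping": self.housekeeping,
            "control_condition": self.control_condition,
            "paths": self.paths,
            "stages": self.stages,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


_CONFIG_BLOCKS = {
    "binding_constants": (BindingConstants, {"kd_roh_rbp_uM": "kd_roh_rbp",
                                             "kd_rohrbp_ttr_uM": "kd_rohrbp_ttr"}),
    "tracer": (TracerSpec, {"specific_activity_ci_per_mmol": "specific_activity",
                            "hot_fraction": "hot_fraction"}),
    "geometry": (CellGeometry, {"area_um2": "area_um2", "height_um": "height_um"}),
    "transwell": (TranswellSetup, {"area_cm2": "area_cm2", "v_apical_L": "v_apical_L",
                                   "v_basolateral_L": "v_basolateral_L",
                                   "sample_volume_L": "sample_volume_L",
                                   "replace_after_sampling": "replace_after_sampling"}),
}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration with located error messages."""
    path = Path(path)
    if not path.exists():
        raise IOError_(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise IOError_(f"{path}: top level must be a mapping")
    kwargs: dict[str, Any] = {}
    for block, (cls, key_map) in _CONFIG_BLOCKS.items():
        if block in raw:
            sub = raw[block]
            unknown = set(sub) - set(key_map)
            if unknown:
                raise IOError_(f"{path}: unknown key(s) {sorted(unknown)} in block {block!r}")
            try:
                kwargs[block] = cls(**{key_map[k]: v for k, v in sub.items()})
            except ValueError as exc:
                raise IOError_(f"{path}: block {block!r}: {exc}") from exc
    for scalar in ("seed", "cell_count", "binding_protein_uM", "housekeeping",
                   "control_condition", "paths", "stages", "log_level"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    return RunConfig(**kwargs)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured analysis stages and write a manifest.

    Stage names: ``speciate``, ``fit-uptake``, ``permeability``,
    ``binding-fit``, ``qpcr``.  Each stage reads its input from
    ``config.paths[stage]``, writes its outputs under ``out_dir``, and a
    stage failure halts the run with a stage-scoped message.  The manifest
    records the seed, the config hash, and the package version, so a rerun
    with the same config and seed is byte-identical.
    """
    from . import __version__, binding, qpcr, speciation, transwell, uptake

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }

    for stage in config.stages:
        try:
            if stage == "speciate":
                conditions = read_table(config.paths[stage], "conditions")
                table = speciation.build_speciation_table(conditions, config.binding_constants)
                table.to_csv(out_dir / "speciation.csv", index=False)
                manifest["stages"][stage] = {"rows": len(table)}
            elif stage == "fit-uptake":
                frame = read_table(config.paths[stage], "timecourse")
                tcs = _frame_to_timecourses(frame)
                fit1 = uptake.fit_uptake(tcs, model=1, seed=config.seed)
                fit2 = uptake.fit_uptake(tcs, model=2, seed=config.seed)
                cmp_ = uptake.compare_models(fit1, fit2)
                report = {
                    "model1": {"params": fit1.params, "se": fit1.se, "ssr": fit1.ssr},
                    "model2": {"params": fit2.params, "se": fit2.se, "ssr": fit2.ssr,
                               "t_lag_min": fit2.t_lag},
                    "comparison": {"F": cmp_.f_stat, "p": cmp_.p_value, "df": cmp_.df,
                                   "aic1": cmp_.aic1, "aic2": cmp_.aic2},
                }
                (out_dir / "uptake_fit.json").write_text(json.dumps(report, indent=2))
                manifest["stages"][stage] = {"p_model2": cmp_.p_value}
            elif stage == "permeability":
                frame = read_table(config.paths[stage], "transwell")
                results = _permeability_stage(frame, config)
                (out_dir / "permeability.json").write_text(json.dumps(results, indent=2))
                manifest["stages"][stage] = {"wells": len(results)}
            elif stage == "binding-fit":
                frame = read_table(config.paths[stage], "titration")
                curve = binding.TitrationCurve(
                    protein_total=config.binding_protein_uM,
                    ligand_totals=frame["ligand_total_uM"].to_numpy(),
                    signal=frame["signal"].to_numpy(),
                )
                fit = binding.fit_kd(curve)
                (out_dir / "binding_fit.json").write_text(json.dumps({
                    "kd_nM": fit.kd_nM, "se_kd_nM": fit.se_kd_nM,
                    "ci95_kd_nM": fit.ci95_kd_nM, "s_max": fit.s_max, "s0": fit.s0,
                }, indent=2))
                manifest["stages"][stage] = {"kd_nM": fit.kd_nM}
            elif stage == "qpcr":
                frame = read_table(config.paths[stage], "cq")
                collapsed = qpcr.collapse_technical(frame)
                expr = qpcr.delta_delta_cq(collapsed, config.housekeeping,
                                           config.control_condition)
                expr.to_csv(out_dir / "expression.csv", index=False)
                stats = qpcr.anova_dunnett(expr, config.control_condition)
                (out_dir / "expression_stats.json").write_text(json.dumps({
                    g: {"anova_f": s.anova_f, "anova_p": s.anova_p,
                        "dunnett": s.comparisons.to_dict(orient="records")}
                    for g, s in stats.items()
                }, indent=2))
                manifest["stages"][stage] = {"genes": len(stats)}
            else:
                raise IOError_(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _frame_to_timecourses(frame: pd.DataFrame):
    from .uptake import Timecourse

    tcs = []
    for (label, cf), sub in frame.groupby(["label", "c_fluid_uM"], sort=False):
        wide = sub.pivot_table(index="rep", columns="time_min", values="c_cell_uM")
        tcs.append(Timecourse(label=str(label), c_fluid=float(cf),
                              times=wide.columns.to_numpy(float), c_cell=wide.to_numpy()))
    return tcs


def _permeability_stage(frame: pd.DataFrame, config: RunConfig) -> list[dict]:
    from .synthetic import transwell_series
    from .transwell import apparent_permeability, cumulative_amount

    results = []
    frame = frame.copy()
    if "conc_uM" not in frame.columns:
        # DPM route: per-sample concentration from DPM and sampled volume
        from .tracer import dpm_to_total_umol

        frame["conc_uM"] = dpm_to_total_umol(frame["dpm"].to_numpy(), config.tracer) / (
            frame["volume_uL"].to_numpy() * 1e-6
        )
    for (rep, channel), _ in frame.groupby(["rep", "channel"]):
        series = transwell_series(frame, channel=channel, rep=rep,
                                  analyte="ROH" if channel == "3H" else "sucrose")
        q = cumulative_amount(series, config.transwell)
        res = apparent_permeability(series.times, q, series.apical_conc_t0,
                                    config.transwell.area_cm2)
        results.append({"rep": int(rep), "channel": str(channel),
                        "pe_app_cm_s": res.pe_app, "r_squared": res.r_squared,
                        "slope_umol_per_min": res.slope_umol_per_min})
    return results
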