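"""Relative expression from qPCR Cq tables: ΔΔCq, ANOVA, Dunnett.

Technical-replicate Cq values are averaged per biological replicate; each
target gene is normalized to a housekeeping gene (ΔCq = Cq_target −
Cq_housekeeping), then to a reference condition (ΔΔCq = ΔCq − mean ΔCq of
the reference).  At 100% amplification efficiency, fold change = 2^(−ΔΔCq)
and log2 fold change = −ΔΔCq.  Per-gene statistics are a one-way ANOVA on
log2 fold changes followed by Dunnett's many-to-one comparisons against
the control condition (multivariate-t critical values, α = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrError",
    "ExpressionStats",
    "collapse_technical",
    "delta_delta_cq",
    "anova_dunnett",
]

_CQ_COLUMNS = ["gene", "condition", "bio_rep", "tech_rep", "cq"]


class QpcrError(ValueError):
    """Invalid Cq table or analysis request."""


def _validate_cq(table: pd.DataFrame, needed: set[str]) -> None:
    missing = needed - set(table.columns)
    if missing:
        raise QpcrError(f"Cq table missing columns: {sorted(missing)}")
    cq = table["cq"]
    if not ((cq > 0) & (cq < 50)).all():
        bad = table.loc[~((cq > 0) & (cq < 50))]
        raise QpcrError(f"Cq values outside (0, 50) in rows: {list(bad.index[:5])}")


def collapse_technical(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic-mean Cq over technical replicates.

    Input columns ``gene, condition, bio_rep, tech_rep, cq``; output one
    row per (gene, condition, bio_rep).  Unbalanced technical replication
    is tolerated with a warning.
    """
    _validate_cq(table, set(_CQ_COLUMNS))
    counts = table.groupby(["gene", "condition", "bio_rep"])["cq"].size()
    if counts.nunique() > 1:
        import warnings

        warnings.warn(
            f"unbalanced technical replicates (counts {sorted(counts.unique())})",
            stacklevel=2,
        )
    return (
        table.groupby(["gene", "condition", "bio_rep"], as_index=False)["cq"].mean()
    )


def delta_delta_cq(
    collapsed: pd.DataFrame,
    housekeeping: str = "ACTB",
    reference: str = "HBSS",
) -> pd.DataFrame:
    """Per-biological-replicate ΔCq, ΔΔCq, and fold changes.

    ΔΔCq for each replicate is taken against the mean ΔCq of the reference
    condition (so the reference's mean log2 fold change is exactly 0).
    Raises when the housekeeping gene or reference condition is absent, or
    when a (gene, condition, bio_rep) cell lacks a housekeeping partner.
    """
    _validate_cq(collapsed, {"gene", "condition", "bio_rep", "cq"})
    genes = collapsed["gene"].unique()
    if housekeeping not in genes:
        raise QpcrError(f"housekeeping gene {housekeeping!r} not in table")
    if reference not in collapsed["condition"].unique():
        raise QpcrError(f"reference condition {reference!r} not in table")

    hk = collapsed[collapsed["gene"] == housekeeping].set_index(["condition", "bio_rep"])["cq"]
    targets = collapsed[collapsed["gene"] != housekeeping].copy()
    idx = pd.MultiIndex.from_frame(targets[["condition", "bio_rep"]])
    missing = idx.difference(hk.index)
    if len(missing):
        raise QpcrError(
            f"housekeeping Cq missing for (condition, bio_rep) cells: {list(missing[:5])}"
        )
    targets["dcq"] = targets["cq"].to_numpy() - hk.loc[idx].to_numpy()

    ref_mean = (
        targets[targets["condition"] == reference].groupby("gene")["dcq"].mean()
    )
    gaps = set(targets["gene"].unique()) - set(ref_mean.index)
    if gaps:
        raise QpcrError(f"reference condition lacks genes: {sorted(gaps)}")
    targets["ddcq"] = targets["dcq"] - targets["gene"].map(ref_mean).to_numpy()
    targets["log2_fold"] = -targets["ddcq"]
    targets["fold"] = 2.0 ** targets["log2_fold"]
    return targets.reset_index(drop=True)


@dataclass
class ExpressionStats:
    """Per-gene ANOVA and Dunnett many-to-one results."""

    gene: str
    anova_f: float
    anova_p: float
    control: str
    comparisons: pd.DataFrame = field(repr=False)  # condition, mean_log2_fold, p_adj


def anova_dunnett(
    expression: pd.DataFrame,
    control: str = "HBSS",
    value_col: str = "log2_fold",
) -> dict[str, ExpressionStats]:
    """One-way ANOVA + Dunnett's test vs control, per gene.

    ``expression`` is the output of :func:`delta_delta_cq` (or any frame
    with ``gene, condition`` and a value column).  Requires at least two
    conditions and two biological replicates per condition.  Dunnett
    adjusted p-values are never smaller than the unadjusted two-sided
    t-test p-values.
    """
    if control not in expression["condition"].unique():
        raise QpcrError(f"control condition {control!r} not in table")
    out: dict[str, ExpressionStats] = {}
    for gene, sub in expression.groupby("gene"):
        groups = {c: g[value_col].to_numpy() for c, g in sub.groupby("condition")}
        if len(groups) < 2:
            raise QpcrError(f"gene {gene!r} has a single condition; ANOVA undefined")
        if any(len(v) < 2 for v in groups.values()):
            raise QpcrError(f"gene {gene!r} has a condition with < 2 replicates")
        others = [c for c in groups if c != control]
        f, p = stats.f_oneway(*groups.values())
        res = stats.dunnett(*(groups[c] for c in others), control=groups[control])
        comp = pd.DataFrame(
            {
                "condition": others,
                "mean_log2_fold": [groups[c].mean() for c in others],
                "p_adj": res.pvalue,
            }
        )
        out[str(gene)] = ExpressionStats(
            gene=str(gene), anova_f=float(f), anova_p=float(p),
            control=control, comparisons=comp,
        )
    return out
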