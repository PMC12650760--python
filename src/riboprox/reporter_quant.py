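"""qPCR and RIP-qPCR normalization chains for reporter and binding assays.

Inputs are relative quantities (post delta-Ct); amplification-efficiency
modelling is out of scope.  Ratios are computed per replicate and summarized
as mean +/- sd over replicate-wise values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd


@dataclass(frozen=True)
class QpcrMeasurement:
    """One amplicon's pulldown/input relative quantities in one replicate."""

    target_id: str
    condition: str
    pulldown_quantity: float
    input_quantity: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not (self.pulldown_quantity > 0 and self.input_quantity > 0):
            raise ValueError(f"{self.target_id}: qPCR quantities must be positive")


def amplicon_enrichment(m: QpcrMeasurement) -> float:
    """Pulldown-to-input quantity ratio for one amplicon."""
    return m.pulldown_quantity / m.input_quantity


def reporter_percent_of_control(
    reporter_enr: float,
    endogenous_ref_enr: float,
    control_reporter_enr: float,
    control_endogenous_ref_enr: float,
) -> float:
    """Reporter enrichment as a percentage of the positive-control reporter.

    Each reporter's enrichment is first normalized to the endogenously
    expressed reference gene measured in the same sample, then expressed as a
    percentage of the identically normalized positive-control reporter.
    """
    for v in (reporter_enr, endogenous_ref_enr, control_reporter_enr, control_endogenous_ref_enr):
        if not v > 0:
            raise ValueError("all enrichment values must be positive")
    return 100.0 * (reporter_enr / endogenous_ref_enr) / (
        control_reporter_enr / control_endogenous_ref_enr
    )


def internal_control_normalize(
    enr_map: Mapping[str, float], control_gene: str
) -> dict[str, float]:
    """Divide every enrichment by the internal-control gene's enrichment.

    An endogenously expressed non-target gene (e.g. a histone) run in the
    same batch absorbs batch effects; the control itself normalizes to 1.
    """
    if control_gene not in enr_map:
        raise KeyError(f"internal control {control_gene!r} missing from enrichment map")
    control = enr_map[control_gene]
    if not control > 0:
        raise ValueError(f"internal control {control_gene!r} has non-positive enrichment")
    return {gene: value / control for gene, value in enr_map.items()}


def rip_log2_enrichment(sample_enr: float, mcherry_control_enr: float) -> float:
    """log2 binding enrichment relative to the inert-protein (mCherry) control."""
    if not (sample_enr > 0 and mcherry_control_enr > 0):
        raise ValueError("enrichment values must be positive")
    return math.log2(sample_enr / mcherry_control_enr)


# ---------------------------------------------------------------------------
# table-level helpers
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ("target_id", "condition", "replicate", "pulldown_quantity", "input_quantity")


def read_qpcr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: qPCR table missing columns {sorted(missing)}")
    if (df["pulldown_quantity"] <= 0).any() or (df["input_quantity"] <= 0).any():
        raise ValueError(f"{path}: qPCR quantities must be positive")
    return df


def add_enrichment(df: pd.DataFrame) -> pd.DataFrame:
    """Append the per-row pulldown/input enrichment column."""
    out = df.copy()
    out["enrichment"] = out["pulldown_quantity"] / out["input_quantity"]
    return out


def normalize_by_internal_control(
    df: pd.DataFrame, control_target: str, batch_col: Optional[str] = None
) -> pd.DataFrame:
    """Normalize enrichment within each (replicate, batch) to the control target.

    Every batch must contain exactly one control measurement per replicate.
    """
    if "enrichment" not in df.columns:
        df = add_enrichment(df)
    group_cols = ["replicate"] + ([batch_col] if batch_col else [])

    def _norm(group: pd.DataFrame) -> pd.DataFrame:
        control = group.loc[group["target_id"] == control_target, "enrichment"]
        if len(control) != 1:
            raise ValueError(
                f"expected exactly one {control_target!r} control per batch/replicate, "
                f"found {len(control)}"
            )
        out = group.copy()
        out["normalized_enrichment"] = out["enrichment"] / float(control.iloc[0])
        return out

    parts = [_norm(g) for _, g in df.groupby(group_cols, sort=False)]
    return pd.concat(parts).sort_index()


def replicate_summary(df: pd.DataFrame, value_col: str = "normalized_enrichment") -> pd.DataFrame:
    """Mean and sd of a per-replicate value for each target/condition."""
    grouped = df.groupby(["target_id", "condition"], sort=True)[value_col]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out
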