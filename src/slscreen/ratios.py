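"""Lane normalization, control-lane read floor, and log2 ratios.

Counts in each lane are normalized to the lane's average read count so
that differing sequencing depths cancel; constructs with fewer than
``min_reads`` reads (default 100) in the *control* lane are excluded as
unreliable, and each surviving construct gets
``log2(norm_treat / norm_ctrl)`` — negative values mean depletion under
treatment (the candidate synthetic-lethal signal), positive values mean
enrichment (candidate rescue).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from slscreen.io import CountTable, LibraryDesign, ScreenConfigError

logger = logging.getLogger(__name__)

RATIO_COLUMNS = (
    "construct_id",
    "gene",
    "module",
    "is_control",
    "count_ctrl",
    "count_treat",
    "norm_ctrl",
    "norm_treat",
    "passes_filter",
    "log2_ratio",
)


def normalize_lane(counts: CountTable) -> pd.Series:
    """Divide each count by the lane's mean count; output mean is 1.

    Scale-invariant: multiplying every count in the lane by a constant
    leaves the result unchanged.
    """
    total = counts.total_reads
    if len(counts.counts) == 0:
        raise ScreenConfigError(f"lane {counts.lane_label!r} has no constructs")
    if total == 0:
        raise ScreenConfigError(
            f"lane {counts.lane_label!r} has zero total reads; cannot normalize"
        )
    return counts.counts / counts.counts.mean()


def apply_read_floor(
    table: pd.DataFrame, min_reads: int = 100
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Flag constructs below the control-lane read floor.

    ``passes_filter`` is False iff ``count_ctrl < min_reads`` (strict
    "less than", so a construct at exactly ``min_reads`` passes).
    Returns the table plus an exclusion report: per module,
    ``100 * excluded / all constructs in the module`` rounded to one
    decimal.
    """
    if min_reads < 0:
        raise ScreenConfigError("min_reads must be >= 0")
    table = table.copy()
    table["passes_filter"] = table["count_ctrl"] >= min_reads
    report = {}
    for module, grp in table.groupby("module"):
        pct = 100.0 * (~grp["passes_filter"]).sum() / len(grp)
        report[int(module)] = round(float(pct), 1)
    return table, report


def compute_log2_ratios(
    table: pd.DataFrame,
    treat_lane_mean: pd.Series | float,
    zero_guard: float = 1.0,
) -> pd.DataFrame:
    """Fill ``log2_ratio`` for passing constructs.

    For a passing construct with ``count_treat = 0`` (complete dropout —
    maximal depletion, which must stay callable) a pseudo-count of
    ``zero_guard`` raw reads is substituted before normalization, i.e.
    its normalized treatment abundance becomes
    ``zero_guard / treat_lane_mean``.  Excluded constructs carry NaN.
    """
    if zero_guard <= 0:
        raise ScreenConfigError("zero_guard must be > 0")
    table = table.copy()
    norm_treat = table["norm_treat"].astype(float)
    zero_mask = table["count_treat"] == 0
    if np.ndim(treat_lane_mean) == 0:
        guard = zero_guard / float(treat_lane_mean)
        norm_treat = norm_treat.mask(zero_mask, guard)
    else:
        norm_treat = norm_treat.mask(zero_mask, zero_guard / treat_lane_mean)
    with np.errstate(divide="ignore"):
        ratio = np.log2(norm_treat / table["norm_ctrl"])
    table["log2_ratio"] = ratio.where(table["passes_filter"], np.nan)
    return table


def build_ratio_table(
    design: LibraryDesign,
    ctrl: CountTable,
    treat: CountTable,
    min_reads: int = 100,
    zero_guard: float = 1.0,
    normalization: str = "lane",
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Full ratio stage: normalize, filter, compute log2 ratios.

    Parameters
    ----------
    normalization
        ``"lane"`` (default): normalize each condition across all
        modules jointly, matching a design where both modules were
        sequenced in one lane per condition.  ``"module"``: normalize
        within each (module, condition) group instead.

    Returns
    -------
    (ratio_table, exclusion_report)
        Ratio table with one row per library construct (columns
        :data:`RATIO_COLUMNS`) and the per-module excluded percentage.
    """
    if normalization not in ("lane", "module"):
        raise ScreenConfigError(f"unknown normalization scope {normalization!r}")
    ctrl = ctrl.reindex_to(design)
    treat = treat.reindex_to(design)
    t = design.table
    df = pd.DataFrame(
        {
            "construct_id": t["construct_id"].values,
            "gene": t["gene"].values,
            "module": t["module"].values,
            "is_control": t["is_control"].values,
            "count_ctrl": ctrl.counts.values,
            "count_treat": treat.counts.values,
        }
    )
    if normalization == "lane":
        df["norm_ctrl"] = df["count_ctrl"] / df["count_ctrl"].mean()
        df["norm_treat"] = df["count_treat"] / df["count_treat"].mean()
        treat_lane_mean: pd.Series | float = float(df["count_treat"].mean())
        if df["count_ctrl"].sum() == 0 or df["count_treat"].sum() == 0:
            raise ScreenConfigError("a lane has zero total reads")
    else:
        module_mean_c = df.groupby("module")["count_ctrl"].transform("mean")
        module_mean_t = df.groupby("module")["count_treat"].transform("mean")
        if (module_mean_c == 0).any() or (module_mean_t == 0).any():
            raise ScreenConfigError("a module-lane has zero total reads")
        df["norm_ctrl"] = df["count_ctrl"] / module_mean_c
        df["norm_treat"] = df["count_treat"] / module_mean_t
        treat_lane_mean = module_mean_t

    df, report = apply_read_floor(df, min_reads)
    df = compute_log2_ratios(df, treat_lane_mean, zero_guard)
    logger.info(
        "ratio table: %d constructs, excluded per module: %s", len(df), report
    )
    return df[list(RATIO_COLUMNS)], report
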