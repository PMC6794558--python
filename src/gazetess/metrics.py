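"""Relative fixation duration (RFD) per AOI label and table export.

RFD is each participant's time fixating an AOI divided by that
participant's total on-screen fixation time for the stimulus, so the values
over all labels (including Background, excluding off-screen time) sum to 1.
The long-format table this module writes is the hand-off point to group
statistics (mixed ANOVAs etc.), which are deliberately out of scope here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tessellation import AOIMap, OFF_SCREEN_LABEL

__all__ = ["compute_rfd", "export_long_table", "summarize_by_group"]

RFD_COLUMNS = ["participant", "group", "stimulus", "condition", "aoi_label", "rfd", "total_ms"]


def compute_rfd(
    labeled_fixations: pd.DataFrame,
    aoi: AOIMap | list,
    conditions: dict | None = None,
) -> pd.DataFrame:
    """Relative fixation duration per participant x stimulus x AOI label.

    ``labeled_fixations`` is the output of
    :func:`gazetess.tessellation.assign_fixations` (possibly concatenated
    over traces).  Every label present in the AOI map gets a row for every
    participant x stimulus, zero-filled where unfixated; off-screen
    fixations enter neither numerator nor denominator.  Participants whose
    on-screen fixation time is zero get rows with ``total_ms = 0`` and
    missing (NaN) rfd.

    ``conditions`` optionally maps stimulus id -> condition
    ("static"/"dynamic"); unmapped stimuli get an empty condition.
    """
    if isinstance(aoi, AOIMap):
        label_universe = sorted(set(aoi.labels))
    else:
        label_universe = sorted(set(aoi))
    df = labeled_fixations
    required = {"participant", "group", "stimulus", "aoi_label", "duration_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"labeled fixations lack columns {sorted(missing)}")
    keys = ["participant", "group", "stimulus"]
    units = df[keys].drop_duplicates()
    on = df[df["aoi_label"] != OFF_SCREEN_LABEL]
    per_label = (
        on.groupby(keys + ["aoi_label"], sort=True)["duration_ms"].sum().reset_index()
    )
    # complete grid: every unit x every AOI label
    grid = units.merge(pd.DataFrame({"aoi_label": label_universe}), how="cross")
    full = grid.merge(per_label, on=keys + ["aoi_label"], how="left")
    full["duration_ms"] = full["duration_ms"].fillna(0.0)
    totals = full.groupby(keys)["duration_ms"].transform("sum")
    full["total_ms"] = totals
    with np.errstate(invalid="ignore", divide="ignore"):
        full["rfd"] = np.where(totals > 0, full["duration_ms"] / totals, np.nan)
    full["condition"] = full["stimulus"].map(conditions or {}).fillna("")
    out = full[RFD_COLUMNS].sort_values(
        ["participant", "stimulus", "aoi_label"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def export_long_table(records: pd.DataFrame, path, missing_marker: str = "NA") -> None:
    """Write the long-format RFD table as TSV with a stable row/column order.

    Missing rfd values (zero on-screen time) are written as
    ``missing_marker`` so downstream statistics can distinguish "never
    looked on screen" from "looked, but not here".  Re-export of the same
    records is byte-identical.
    """
    if records.empty:
        raise ValueError("no RFD records to export")
    out = records[RFD_COLUMNS].sort_values(
        ["participant", "stimulus", "aoi_label"], kind="mergesort"
    )
    out = out.copy()
    out["rfd"] = out["rfd"].map(lambda v: missing_marker if pd.isna(v) else repr(float(v)))
    out["total_ms"] = out["total_ms"].map(lambda v: repr(float(v)))
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def summarize_by_group(
    records: pd.DataFrame, by: list | None = None, sd_zero_for_singleton: bool = False
) -> pd.DataFrame:
    """Descriptive summary (mean, SD, n) of rfd within each key combination.

    The mean is unweighted over records (one per participant within a cell);
    SD uses the n-1 denominator and is NaN for singleton cells unless
    ``sd_zero_for_singleton``.  Missing rfd values are excluded.
    """
    if records.empty:
        raise ValueError("no RFD records to summarize")
    by = by or ["group", "aoi_label"]
    valid = records.dropna(subset=["rfd"])
    agg = valid.groupby(by, sort=True)["rfd"].agg(
        mean="mean", sd=lambda s: s.std(ddof=1), n="count"
    )
    if sd_zero_for_singleton:
        agg.loc[agg["n"] == 1, "sd"] = 0.0
    return agg.reset_index()
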