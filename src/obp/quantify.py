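"""Per-cell intensity quantification and organoid-level summaries.

The platform's core image readouts:

* **ACI** (average cytoplasmic intensity): each cell contributes its *maximum*
  cytoplasmic voxel intensity for a channel; the ACI is the arithmetic mean of
  those per-cell maxima over all cells.
* **ANI** (average nuclear intensity): per-nucleus mean Ki-67 intensity,
  averaged over cells.
* **Concordance**: agreement between the enumerated nucleus and cell counts,
  ``100 * min / max``, reported to one decimal.
* **Depth profiles**: mean foreground intensity in z-bins, for verifying
  antibody penetration through thick (40–120 μm) organoid sections.
* **Group comparisons**: Welch t-test for two groups, one-way ANOVA beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import CYTOPLASMIC_CHANNELS, KI67, LabelVolume, OrganoidVolume

__all__ = [
    "build_cell_table",
    "compute_aci",
    "compute_ani",
    "concordance",
    "depth_signal_profile",
    "compare_groups",
    "organoid_summary",
    "OrganoidSummary",
    "UndefinedValueError",
]


class UndefinedValueError(ValueError):
    """Raised when a summary statistic is requested for empty input."""


def build_cell_table(
    volume: OrganoidVolume, nuclei: LabelVolume, cells: LabelVolume
) -> pd.DataFrame:
    """Per-cell intensity records from label volumes.

    One row per cell label with the maximum intensity over the cell's voxels
    for every cytoplasmic channel (``max_<channel>`` columns), the mean Ki-67
    over the matched nucleus' voxels (``ki67_nuclear_mean``, NaN for anucleate
    cells), the matched ``nucleus_id`` (pandas NA when anucleate) and the cell
    volume in μm³. Empty labels yield an empty table.
    """
    if cells.labels.shape != volume.shape_zyx or nuclei.labels.shape != volume.shape_zyx:
        raise ValueError("label volumes must match the intensity volume shape")
    n_cells = cells.n_objects
    cols = ["cell_id", "nucleus_id", "cell_volume_um3", "ki67_nuclear_mean"] + [
        f"max_{c}" for c in CYTOPLASMIC_CHANNELS if volume.has_channel(c)
    ]
    if n_cells == 0:
        return pd.DataFrame(columns=cols)

    idx = np.arange(1, n_cells + 1)
    table: dict[str, np.ndarray] = {"cell_id": idx}

    # nucleus matched to each cell: the nucleus label whose seed the cell contains
    nucleus_ids = np.full(n_cells, 0, dtype=np.int64)
    if nuclei.n_objects > 0:
        # majority nucleus label inside each cell (a cell contains voxels of at
        # most one nucleus by construction of the seeded watershed)
        nuc_in_cell = ndimage.maximum(nuclei.labels, labels=cells.labels, index=idx)
        nucleus_ids = np.asarray(nuc_in_cell, dtype=np.int64)
    table["nucleus_id"] = nucleus_ids

    counts = ndimage.sum_labels(np.ones_like(cells.labels, dtype=np.uint8), cells.labels, idx)
    table["cell_volume_um3"] = counts * cells.voxel_volume_um3

    for ch in CYTOPLASMIC_CHANNELS:
        if volume.has_channel(ch):
            table[f"max_{ch}"] = np.asarray(
                ndimage.maximum(volume.channel(ch), labels=cells.labels, index=idx),
                dtype=float,
            )

    ki67 = np.full(n_cells, np.nan)
    if volume.has_channel(KI67) and nuclei.n_objects > 0:
        nuc_idx = np.arange(1, nuclei.n_objects + 1)
        nuc_means = np.asarray(
            ndimage.mean(volume.channel(KI67), labels=nuclei.labels, index=nuc_idx),
            dtype=float,
        )
        has = nucleus_ids > 0
        ki67[has] = nuc_means[nucleus_ids[has] - 1]
    table["ki67_nuclear_mean"] = ki67

    df = pd.DataFrame(table)
    df["nucleus_id"] = df["nucleus_id"].astype("Int64")
    df.loc[df["nucleus_id"] == 0, "nucleus_id"] = pd.NA
    return df[cols]


def compute_aci(table: pd.DataFrame, channel: str) -> float:
    """Average cytoplasmic intensity: mean over cells of per-cell channel maxima."""
    col = f"max_{channel}" if f"max_{channel}" in table.columns else channel
    if len(table) == 0:
        raise UndefinedValueError("ACI is undefined for an empty cell table")
    if col not in table.columns:
        raise KeyError(f"no column for channel {channel!r}")
    return float(table[col].mean())


def compute_ani(table: pd.DataFrame, column: str = "ki67_nuclear_mean") -> float:
    """Average nuclear intensity: mean over cells of per-nucleus Ki-67 means."""
    if len(table) == 0:
        raise UndefinedValueError("ANI is undefined for an empty cell table")
    vals = table[column].dropna()
    if len(vals) == 0:
        raise UndefinedValueError("no nucleated cells with Ki-67 measurements")
    return float(vals.mean())


def concordance(n_nuclei: int, n_cells: int) -> float:
    """Percent agreement between nucleus and cell counts, to one decimal.

    ``100 * min(n_nuclei, n_cells) / max(n_nuclei, n_cells)``; symmetric in its
    arguments and at most 100.
    """
    if n_nuclei <= 0 or n_cells <= 0:
        raise UndefinedValueError("concordance requires positive counts")
    return round(100.0 * min(n_nuclei, n_cells) / max(n_nuclei, n_cells), 1)


def depth_signal_profile(
    volume: OrganoidVolume,
    channel: str,
    step_um: float = 5.0,
    foreground_floor: float = 0.0,
    low_signal_floor: float | None = None,
) -> pd.DataFrame:
    """Mean foreground intensity per depth bin.

    Foreground voxels are those strictly above ``foreground_floor``. Bins with
    mean signal below ``low_signal_floor`` (when given) are flagged; empty bins
    carry NaN. ``step_um`` must be a positive multiple of the z voxel size.
    """
    sz = volume.voxel_size_um[2]
    ratio = step_um / sz
    if step_um <= 0 or abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"step_um must be a multiple of the z-step ({sz} μm)")
    planes_per_bin = int(round(ratio))
    data = volume.channel(channel)
    n_z = data.shape[0]
    rows = []
    for start in range(0, n_z, planes_per_bin):
        chunk = data[start : start + planes_per_bin]
        fg = chunk[chunk > foreground_floor]
        mean = float(fg.mean()) if fg.size else np.nan
        rows.append(
            {
                "depth_um": start * sz,
                "mean_intensity": mean,
                "n_foreground_voxels": int(fg.size),
                "low_signal": bool(
                    low_signal_floor is not None
                    and (np.isnan(mean) or mean < low_signal_floor)
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Result of a two-group Welch t-test or multi-group one-way ANOVA."""

    statistic: float
    p_value: float
    difference: float  # mean(b) - mean(a) for two groups; range of means beyond
    test: str


def compare_groups(*groups: np.ndarray) -> GroupComparison:
    """Welch two-sided t-test for two groups, one-way ANOVA for more.

    Degenerate input (all groups constant with equal means) returns p = 1 by
    convention rather than NaN.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    means = [a.mean() for a in arrays]
    degenerate = all(a.std() == 0 for a in arrays) and len(set(means)) == 1
    if len(arrays) == 2:
        diff = means[1] - means[0]
        if degenerate:
            return GroupComparison(0.0, 1.0, diff, "welch_t")
        stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        return GroupComparison(float(stat), float(p), float(diff), "welch_t")
    diff = max(means) - min(means)
    if degenerate:
        return GroupComparison(0.0, 1.0, diff, "anova")
    stat, p = stats.f_oneway(*arrays)
    return GroupComparison(float(stat), float(p), float(diff), "anova")


@dataclass
class OrganoidSummary:
    """Organoid-level readout: counts, concordance, ACIs, ANI, stroma/tumor ratio."""

    n_nuclei: int
    n_cells: int
    concordance_pct: float
    aci: dict[str, float]
    ani_ki67: float | None
    sma_ck19_ratio: float | None

    def to_dict(self) -> dict:
        return {
            "n_nuclei": self.n_nuclei,
            "n_cells": self.n_cells,
            "concordance_pct": self.concordance_pct,
            "aci": self.aci,
            "ani_ki67": self.ani_ki67,
            "sma_ck19_ratio": self.sma_ck19_ratio,
        }


def organoid_summary(
    table: pd.DataFrame, nuclei: LabelVolume, cells: LabelVolume
) -> OrganoidSummary:
    """Summarize one organoid from its cell table and label volumes.

    The alpha-SMA/CK-19 ratio (stroma over tumor marker ACI) is reported to two
    decimals; percentages to one decimal.
    """
    n_nuc, n_cell = nuclei.n_objects, cells.n_objects
    aci = {}
    for col in table.columns:
        if col.startswith("max_"):
            ch = col[len("max_") :]
            aci[ch] = compute_aci(table, ch) if len(table) else float("nan")
    try:
        ani = compute_ani(table)
    except (UndefinedValueError, KeyError):
        ani = None
    ratio = None
    if "aSMA" in aci and "CK19" in aci and aci["CK19"] > 0:
        ratio = round(aci["aSMA"] / aci["CK19"], 2)
    return OrganoidSummary(
        n_nuclei=n_nuc,
        n_cells=n_cell,
        concordance_pct=concordance(n_nuc, n_cell) if n_nuc > 0 and n_cell > 0 else float("nan"),
        aci=aci,
        ani_ki67=ani,
        sma_ck19_ratio=ratio,
    )
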