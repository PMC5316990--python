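"""Population-level analysis: viability filtering, proportional activation,
amplitude distributions and granule-cell-layer position statistics.

The unit of analysis for group comparisons is the per-slice activation
percentage, computed over viable cells only.  Viability follows the
saturating-picrotoxin check: a cell that never responds in any condition,
including PTX, is assumed deafferented or dead and excluded; a slice in
which ≥ 70% of ROIs fail to activate under PTX is considered damaged and
excluded outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import stats as _stats

__all__ = [
    "CellRecord",
    "SliceSummary",
    "GroupSummary",
    "viability_filter",
    "slice_exclusion",
    "proportional_activation",
    "amplitude_summary",
    "compare_position_distributions",
    "inner_outer_contingency",
    "PTX_LABEL",
]

PTX_LABEL = "PTX"


class DataError(ValueError):
    pass


@dataclass
class CellRecord:
    """Per-ROI bookkeeping across conditions.

    ``position_pct`` is the soma's % distance from the inner (hilar) to the
    outer (molecular-layer) border of the granule cell layer.  ``responded``
    maps condition label → whether a stimulus-evoked transient was detected;
    ``peak_dff`` optionally holds the measured amplitude per condition.
    """

    slice_id: str
    roi_id: str
    position_pct: float
    responded: dict[str, bool]
    viable: bool = True
    peak_dff: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.position_pct <= 100.0:
            raise DataError("position_pct must lie in [0, 100]")


@dataclass
class SliceSummary:
    slice_id: str
    n_viable: int
    pct_active: dict[str, float]
    excluded: bool = False
    reason: str = ""


@dataclass
class GroupSummary:
    group: str
    pct_active_per_slice: dict[str, list[float]]
    amplitudes: dict[str, list[float]]
    amplitude_median: dict[str, float]
    amplitude_iqr: dict[str, tuple[float, float]]


def viability_filter(
    cells: Sequence[CellRecord], ptx_label: str = PTX_LABEL
) -> tuple[list[CellRecord], dict[str, int]]:
    """Drop cells inactive in every condition including PTX.

    Returns the retained cells (with ``viable`` set) and a per-slice count
    of exclusions.  A cell that responded anywhere is never removed.
    """
    removed: dict[str, int] = {}
    kept: list[CellRecord] = []
    for cell in cells:
        if ptx_label not in cell.responded:
            raise DataError(f"cell {cell.roi_id} lacks a {ptx_label} condition entry")
        if any(cell.responded.values()):
            cell.viable = True
            kept.append(cell)
        else:
            cell.viable = False
            removed[cell.slice_id] = removed.get(cell.slice_id, 0) + 1
    return kept, removed


def slice_exclusion(
    slice_cells: Sequence[CellRecord],
    ptx_label: str = PTX_LABEL,
    threshold: float = 0.70,
) -> bool:
    """True if the slice is damaged/deafferented: ≥ 70% of its ROIs
    (all ROIs, before viability filtering) fail to activate under PTX."""
    if not slice_cells:
        raise DataError("slice has no ROIs")
    inactive = sum(not c.responded.get(ptx_label, False) for c in slice_cells)
    return inactive / len(slice_cells) >= threshold


def proportional_activation(
    viable_cells: Sequence[CellRecord], condition: str
) -> float | None:
    """Percent of viable cells with a detected response in ``condition``.

    Returns None (with a warning) when the slice has no viable cells.
    """
    if not viable_cells:
        warnings.warn("no viable cells; slice skipped", stacklevel=2)
        return None
    responding = sum(bool(c.responded.get(condition, False)) for c in viable_cells)
    return 100.0 * responding / len(viable_cells)


def amplitude_summary(
    amplitudes: Sequence[float],
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Median, interquartile range and ECDF of a group's peak amplitudes.

    The ECDF is returned as an (n, 2) array of sorted (value, cumulative
    fraction) pairs with the final fraction exactly 1.
    """
    if len(amplitudes) == 0:
        raise DataError("amplitude summary of an empty group")
    vals = np.sort(np.asarray(amplitudes, dtype=float))
    median = float(np.median(vals))
    iqr = (float(np.percentile(vals, 25)), float(np.percentile(vals, 75)))
    ecdf = np.column_stack([vals, np.arange(1, len(vals) + 1) / len(vals)])
    return median, iqr, ecdf


def compare_position_distributions(
    active_positions: Sequence[float], all_positions: Sequence[float]
):
    """Two-sample Kolmogorov-Smirnov comparison of responsive-cell positions
    against the positions of every imaged cell."""
    if len(active_positions) == 0 or len(all_positions) == 0:
        raise DataError("position samples must be non-empty")
    a = np.asarray(active_positions, dtype=float)
    b = np.asarray(all_positions, dtype=float)
    if a.min() < 0 or a.max() > 100 or b.min() < 0 or b.max() > 100:
        raise DataError("positions must lie in [0, 100]")
    return _stats.ks_two_sample(a, b)


def inner_outer_contingency(
    positions_a: Sequence[float],
    positions_b: Sequence[float],
    boundary: float = 50.0,
) -> tuple[np.ndarray, float]:
    """2×2 inner/outer GCL table between two groups plus Fisher's exact p.

    Inner = position strictly below ``boundary`` (% of the inner→outer
    distance).  Rows are groups, columns (inner, outer).
    """
    if len(positions_a) == 0 or len(positions_b) == 0:
        raise DataError("both groups must be non-empty")
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    table = np.array([
        [int((a < boundary).sum()), int((a >= boundary).sum())],
        [int((b < boundary).sum()), int((b >= boundary).sum())],
    ])
    p = _stats.fisher_exact(table)
    return table, p


def summarize_slices(
    cells: Sequence[CellRecord],
    conditions: Sequence[str],
    ptx_label: str = PTX_LABEL,
    exclusion_threshold: float = 0.70,
) -> list[SliceSummary]:
    """Per-slice activation percentages with the full exclusion cascade.

    Applies slice exclusion on the raw ROI set, then the per-cell viability
    filter, then computes proportional activation per condition.
    """
    by_slice: dict[str, list[CellRecord]] = {}
    for c in cells:
        by_slice.setdefault(c.slice_id, []).append(c)
    out: list[SliceSummary] = []
    for slice_id in sorted(by_slice):
        group = by_slice[slice_id]
        if slice_exclusion(group, ptx_label, exclusion_threshold):
            out.append(SliceSummary(slice_id, 0, {}, excluded=True,
                                    reason="≥70% of ROIs inactive under PTX"))
            continue
        viable, _ = viability_filter(group, ptx_label)
        pct = {}
        for cond in conditions:
            val = proportional_activation(viable, cond)
            if val is not None:
                pct[cond] = val
        out.append(SliceSummary(slice_id, len(viable), pct))
    return out
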