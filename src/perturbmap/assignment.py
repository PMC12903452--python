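"""Guide assignment from relative UMI abundance.

A cell is assigned to its most abundant guide when that guide accounts for a
large enough share of the cell's guide UMIs. The cutoff on the share is not
fixed: within each inlet, the distribution of top-guide relative abundances
is bimodal (a low mode of ambient/ambiguous cells and an upper mode of clean
single-guide cells), and the threshold is placed at the density valley
between the two modes inside the window [0.5, 1.0]. When no valley can be
found the threshold falls back to 0.75, the median inlet threshold observed
in practice. Cells also need a minimum of 3 UMIs for the top guide; all
other cells are left unassigned and act as controls downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .simulate import GuideUmiTable

__all__ = [
    "compute_relative_abundance",
    "detect_inlet_threshold",
    "assign_guides",
    "FALLBACK_THRESHOLD",
]

logger = logging.getLogger(__name__)

FALLBACK_THRESHOLD = 0.75
DEFAULT_WINDOW = (0.5, 1.0)


def compute_relative_abundance(guide_umis: dict[str, int]):
    """Top guide, its UMI count, and its share of the cell's guide UMIs.

    Ties for the top guide are broken lexicographically by guide id. A cell
    with no guide UMIs returns ``(None, 0, nan)`` and is flagged unassigned.
    """
    for g, c in guide_umis.items():
        if c < 0:
            raise ValueError(f"negative UMI count for guide {g!r}")
    total = sum(guide_umis.values())
    if total == 0:
        return None, 0, float("nan")
    top_count = max(guide_umis.values())
    top_guide = min(g for g, c in guide_umis.items() if c == top_count)
    return top_guide, top_count, top_count / total


def detect_inlet_threshold(
    relative_abundances,
    window: tuple[float, float] = DEFAULT_WINDOW,
    bandwidth: float = 0.02,
    min_cells: int = 100,
    fallback: float = FALLBACK_THRESHOLD,
    grid_size: int = 501,
) -> float:
    """Place the assignment cutoff at the KDE valley below the upper mode.

    A Gaussian KDE (absolute bandwidth ``bandwidth``) is evaluated on a grid
    over ``window``; the threshold is the minimum-density point between the
    two highest local maxima in the window. Falls back to ``fallback`` when
    there are too few cells, the data are (near-)constant, or no interior
    valley exists.
    """
    x = np.asarray(relative_abundances, dtype=float)
    x = x[np.isfinite(x)]
    lo, hi = window
    if len(x) < min_cells:
        logger.warning(
            "only %d cells with guide UMIs (< %d); using fallback threshold %.2f",
            len(x), min_cells, fallback,
        )
        return fallback
    if np.std(x) < 1e-9:
        return fallback
    kde = gaussian_kde(x, bw_method=bandwidth / np.std(x, ddof=1))
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    modes = interior[is_max]
    # treat the window edges as modes if density is rising toward them, so a
    # single interior valley between a low and an upper mode is still found
    if dens[0] > dens[1]:
        modes = np.concatenate([[0], modes])
    if dens[-1] > dens[-2]:
        modes = np.concatenate([modes, [grid_size - 1]])
    if len(modes) < 2:
        return fallback
    top_two = modes[np.argsort(dens[modes])[-2:]]
    a, b = np.sort(top_two)
    if b - a < 2:
        return fallback
    valley = a + 1 + int(np.argmin(dens[a + 1 : b]))
    return float(grid[valley])


def assign_guides(
    table: GuideUmiTable,
    inlet_of_cell: pd.Series | dict,
    thresholds: dict[str, float],
    min_umis: int = 3,
) -> pd.DataFrame:
    """Assign each cell to at most one guide.

    Assignment requires the top guide to have at least ``min_umis`` UMIs and
    a relative abundance at or above the cell's inlet threshold. Returns a
    DataFrame indexed by cell with columns ``assigned_guide`` (empty string
    when unassigned), ``top_guide``, ``top_guide_umis``,
    ``relative_abundance``, ``inlet_threshold_used`` and ``status``.
    """
    inlet_of_cell = pd.Series(inlet_of_cell)
    missing = set(pd.unique(inlet_of_cell.loc[table.cell_ids])) - set(thresholds)
    if missing:
        raise ValueError(f"no threshold supplied for inlet(s): {sorted(missing)}")

    counts = table.counts.tocsr()
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("guide UMI counts must be non-negative")
    records = []
    guide_ids = np.asarray(table.guide_ids)
    for i, cell in enumerate(table.cell_ids):
        row = counts.getrow(i)
        thr = thresholds[inlet_of_cell[cell]]
        if row.nnz == 0:
            records.append((cell, "", "", 0, np.nan, thr, "no_guide_umis"))
            continue
        data, idx = row.data, row.indices
        top_count = int(data.max())
        ties = idx[data == top_count]
        top_guide = min(guide_ids[t] for t in ties) if len(ties) > 1 else guide_ids[ties[0]]
        if len(ties) > 1:
            logger.info("cell %s: tie for top guide broken lexicographically", cell)
        rel = top_count / float(data.sum())
        if top_count >= min_umis and rel >= thr:
            records.append((cell, top_guide, top_guide, top_count, rel, thr, "assigned"))
        else:
            reason = "below_min_umis" if top_count < min_umis else "below_threshold"
            records.append((cell, "", top_guide, top_count, rel, thr, reason))
    out = pd.DataFrame(
        records,
        columns=[
            "cell", "assigned_guide", "top_guide", "top_guide_umis",
            "relative_abundance", "inlet_threshold_used", "status",
        ],
    ).set_index("cell")
    return out


def detect_thresholds_per_inlet(
    table: GuideUmiTable,
    inlet_of_cell: pd.Series | dict,
    **kwargs,
) -> dict[str, float]:
    """Convenience: compute relative abundances and a threshold per inlet."""
    inlet_of_cell = pd.Series(inlet_of_cell)
    counts = table.counts.tocsr()
    totals = np.asarray(counts.sum(axis=1)).ravel()
    tops = counts.max(axis=1).toarray().ravel() if counts.nnz else np.zeros(len(table.cell_ids))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, tops / totals, np.nan)
    inlets = inlet_of_cell.loc[table.cell_ids].to_numpy()
    return {
        inlet: detect_inlet_threshold(rel[inlets == inlet], **kwargs)
        for inlet in np.unique(inlets)
    }
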