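"""Co-regulation networks from perturbation-profile similarity.

Two targets are co-regulating when the Pearson correlation of their
trans-effect profiles (LFC across all expressed genes) is high; two
expressed genes are co-regulated when their response profiles across
knockdowns correlate. Edges are drawn at |r| strictly greater than a
threshold (default 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SimilarityMatrix", "profile_correlation", "threshold_network", "lfc_matrix"]

MIN_OVERLAP = 20


@dataclass
class SimilarityMatrix:
    axis: str  # "targets" or "genes"
    corr: pd.DataFrame
    n_pairs: int


def lfc_matrix(effects: pd.DataFrame) -> pd.DataFrame:
    """Pivot a target-level effect table into a targets x genes LFC matrix."""
    return effects.pivot(index="unit", columns="gene", values="lfc")


def profile_correlation(
    effects: pd.DataFrame,
    axis: str = "targets",
    min_overlap: int = MIN_OVERLAP,
) -> SimilarityMatrix:
    """Pearson correlation of LFC profiles between targets or between genes.

    Missing LFCs are excluded pairwise; pairs with fewer than ``min_overlap``
    shared features are flagged missing (NaN), as are zero-variance
    profiles. The diagonal is 1 by definition.
    """
    if axis not in ("targets", "genes"):
        raise ValueError("axis must be 'targets' or 'genes'")
    mat = lfc_matrix(effects)
    frame = mat.T if axis == "targets" else mat  # columns = the compared units
    corr = frame.corr(min_periods=min_overlap)
    np.fill_diagonal(corr.values, 1.0)
    m = corr.shape[0]
    return SimilarityMatrix(axis=axis, corr=corr, n_pairs=m * (m - 1) // 2)


def threshold_network(sim: SimilarityMatrix, min_abs_r: float = 0.2) -> pd.DataFrame:
    """Undirected edges where |r| exceeds ``min_abs_r`` (strictly).

    Returns a DataFrame with columns ``a``, ``b``, ``r``; self-pairs and
    missing correlations are excluded.
    """
    corr = sim.corr
    names = corr.index.to_numpy()
    vals = corr.to_numpy()
    iu, ju = np.triu_indices(len(names), k=1)
    r = vals[iu, ju]
    keep = np.isfinite(r) & (np.abs(r) > min_abs_r)
    return pd.DataFrame({"a": names[iu[keep]], "b": names[ju[keep]], "r": r[keep]})
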