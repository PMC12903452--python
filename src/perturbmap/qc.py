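"""Cell quality control, log-normalization, gene selection, cell-cycle scores.

Cells are retained when they clear three criteria: a per-inlet minimum UMI
count (the UMI distributions are multi-modal per inlet, so thresholds are
supplied per inlet), a minimum number of detected features (default 2,000)
and a maximum mitochondrial fraction (default 10%). Counts are normalized by
total-sum scaling to 10,000 and log-transformed with a pseudocount of 1
(natural log), so downstream log-fold changes are natural-log differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse

__all__ = [
    "QcThresholds",
    "filter_cells",
    "lognormalize",
    "select_expressed_genes",
    "select_hvg",
    "cell_cycle_scores",
    "SCALE_FACTOR",
]

logger = logging.getLogger(__name__)

SCALE_FACTOR = 10_000.0


@dataclass
class QcThresholds:
    min_features: int = 2000
    max_mito_fraction: float = 0.10
    min_umis_per_inlet: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.min_features < 1:
            raise ValueError("min_features must be positive")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        for inlet, v in self.min_umis_per_inlet.items():
            if v < 1:
                raise ValueError(f"min UMI threshold for inlet {inlet!r} must be positive")


def filter_cells(adata: ad.AnnData, thresholds: QcThresholds) -> ad.AnnData:
    """Keep cells passing all three QC criteria.

    Requires ``obs`` columns ``inlet``, ``mito_fraction``, ``total_umis``
    and ``n_features``. Per-cell removal reasons are recorded in
    ``uns["qc_filter_report"]`` of the returned object. Idempotent.
    """
    thresholds.validate()
    for col in ("inlet", "mito_fraction", "total_umis", "n_features"):
        if col not in adata.obs:
            raise ValueError(f"obs is missing required column {col!r}")
    inlets = set(adata.obs["inlet"].unique())
    missing = inlets - set(thresholds.min_umis_per_inlet)
    if missing:
        raise ValueError(f"no UMI threshold for inlet(s): {sorted(missing)}")

    umi_thr = adata.obs["inlet"].map(thresholds.min_umis_per_inlet).to_numpy(float)
    fail_umi = adata.obs["total_umis"].to_numpy() < umi_thr
    fail_feat = adata.obs["n_features"].to_numpy() < thresholds.min_features
    fail_mito = adata.obs["mito_fraction"].to_numpy() > thresholds.max_mito_fraction
    keep = ~(fail_umi | fail_feat | fail_mito)

    reasons = []
    for i, cell in enumerate(adata.obs_names):
        if keep[i]:
            continue
        why = [
            r
            for r, f in (("low_umis", fail_umi), ("low_features", fail_feat), ("high_mito", fail_mito))
            if f[i]
        ]
        reasons.append((cell, ";".join(why)))
    report = pd.DataFrame(reasons, columns=["cell", "reason"])
    logger.info("QC removed %d / %d cells", (~keep).sum(), adata.n_obs)
    out = adata[keep].copy()
    out.uns["qc_filter_report"] = report
    return out


def lognormalize(adata: ad.AnnData, scale_factor: float = SCALE_FACTOR) -> ad.AnnData:
    """Add layer ``lognorm`` = ln(1 + count / cell_total x scale_factor).

    Zero counts map to zero exactly; a zero-total cell is rejected because it
    should have been removed by QC.
    """
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        bad = list(adata.obs_names[totals <= 0])
        raise ValueError(f"cells with zero total counts: {bad[:5]}")
    if sparse.issparse(X):
        norm = X.multiply(scale_factor / totals[:, None]).tocsr()
        norm.data = np.log1p(norm.data)
    else:
        norm = np.log1p(np.asarray(X) * (scale_factor / totals[:, None]))
    adata.layers["lognorm"] = norm
    return adata


def _lognorm_dense(adata: ad.AnnData) -> np.ndarray:
    if "lognorm" not in adata.layers:
        raise ValueError("run lognormalize first (no 'lognorm' layer)")
    L = adata.layers["lognorm"]
    return L.toarray() if sparse.issparse(L) else np.asarray(L)


def select_expressed_genes(adata: ad.AnnData, min_mean: float = 0.1) -> list[str]:
    """Genes whose mean log-normalized expression exceeds ``min_mean``."""
    L = adata.layers.get("lognorm")
    if L is None:
        raise ValueError("run lognormalize first (no 'lognorm' layer)")
    means = np.asarray(L.mean(axis=0)).ravel()
    return [g for g, m in zip(adata.var_names, means) if m > min_mean]


def select_hvg(adata: ad.AnnData, k: int = 2000) -> list[str]:
    """Top-``k`` genes by variance of log-normalized expression.

    Ties are broken by gene id so the selection is deterministic.
    """
    if k > adata.n_vars:
        raise ValueError(f"k={k} exceeds the number of genes ({adata.n_vars})")
    L = _lognorm_dense(adata)
    var = L.var(axis=0, ddof=1)
    order = sorted(zip(-var, adata.var_names))
    return [g for _, g in order[:k]]


def cell_cycle_scores(
    adata: ad.AnnData,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 24,
    ctrl_size: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell S and G2M module scores and a discrete phase call.

    A module score is the mean log-normalized expression of the gene set
    minus the mean of an expression-matched background (genes binned by mean
    expression into ``n_bins`` bins; ``ctrl_size`` background genes drawn per
    bin). Phase is S or G2M for whichever positive score is larger, G1 when
    neither is positive. Scores are added to ``adata.obs`` as ``s_score``,
    ``g2m_score`` and ``phase``.
    """
    s_set = [g for g in s_genes if g in adata.var_names]
    g2m_set = [g for g in g2m_genes if g in adata.var_names]
    if not s_set or not g2m_set:
        raise ValueError("cell-cycle gene sets do not intersect the genes present")
    sc.tl.score_genes(
        adata, s_set, score_name="s_score", ctrl_size=ctrl_size,
        n_bins=n_bins, random_state=seed, layer="lognorm",
    )
    sc.tl.score_genes(
        adata, g2m_set, score_name="g2m_score", ctrl_size=ctrl_size,
        n_bins=n_bins, random_state=seed, layer="lognorm",
    )
    s = adata.obs["s_score"].to_numpy()
    g2m = adata.obs["g2m_score"].to_numpy()
    phase = np.where((s <= 0) & (g2m <= 0), "G1", np.where(s > g2m, "S", "G2M"))
    adata.obs["phase"] = phase
    return adata.obs[["s_score", "g2m_score", "phase"]].copy()
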