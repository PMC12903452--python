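"""Perturbation-effect estimation against a control-cell covariate model.

Control cells (unassigned cells plus carriers of non-targeting guides) are
used to fit, per expressed gene, a least-squares model of log-normalized
expression on technical and biological covariates: cell line, inlet,
mitochondrial fraction, S and G2M cell-cycle scores and total UMIs. The
perturbation effect of a cell on a gene is the observed minus the predicted
expression, so a knockdown yields negative values. Per-cell effects are
averaged within guides, targets or target x line pairings; significance
comes from a z-test whose standard error is the control-fit residual SD
divided by sqrt(cells), with Benjamini-Hochberg control across the whole
family of tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ControlFit",
    "build_design",
    "fit_control_model",
    "per_cell_effects",
    "aggregate_effects",
    "bh_adjust",
    "estimate_cis_effect",
    "test_universe_size",
    "percent",
    "DEFAULT_MIN_CELLS",
    "FDR_THRESHOLD",
]

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.1
DEFAULT_MIN_CELLS = {"guide": 5, "target": 10, "target_by_line": 10}

CATEGORICAL_COVARIATES = ("cell_line", "inlet")
CONTINUOUS_COVARIATES = ("mito_fraction", "s_score", "g2m_score", "total_umis")


@dataclass
class ControlFit:
    """Per-gene least-squares fit on control cells."""

    genes: list[str]
    design_columns: list[str]
    reference_levels: dict[str, str]
    coef: np.ndarray  # (p, n_genes)
    residual_sd: np.ndarray  # (n_genes,)
    n_control_cells: int
    rank: int


def build_design(
    obs: pd.DataFrame,
    categorical: tuple[str, ...] = CATEGORICAL_COVARIATES,
    continuous: tuple[str, ...] = CONTINUOUS_COVARIATES,
    reference_levels: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Intercept + one-hot categoricals (first level reference) + continuous.

    ``reference_levels`` fixes the dropped level per categorical so that a
    design built for new cells is compatible with the control fit.
    """
    cols = [np.ones(len(obs))]
    names = ["intercept"]
    refs: dict[str, str] = {}
    for cov in categorical:
        if cov not in obs:
            raise ValueError(f"missing covariate {cov!r}")
        levels = sorted(map(str, obs[cov].unique()))
        ref = (reference_levels or {}).get(cov, levels[0])
        refs[cov] = ref
        for lev in levels:
            if lev == ref:
                continue
            cols.append((obs[cov].astype(str) == lev).to_numpy(float))
            names.append(f"{cov}[{lev}]")
    for cov in continuous:
        if cov not in obs:
            raise ValueError(f"missing covariate {cov!r}")
        cols.append(obs[cov].to_numpy(float))
        names.append(cov)
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite covariate values")
    return X, names, refs


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Greedy rank selection in column order, so the intercept and early
    covariates win over later collinear ones."""
    n = X.shape[0]
    Q = np.zeros((n, 0))
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        r = v - Q @ (Q.T @ v)
        if np.linalg.norm(r) > max(np.linalg.norm(v), 1.0) * 1e-10:
            Q = np.column_stack([Q, r / np.linalg.norm(r)])
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        logger.warning("dropping collinear design column(s): %s", dropped)
    if not keep:
        raise ValueError("design matrix has no usable columns")
    return X[:, keep], [names[j] for j in keep]


def fit_control_model(
    adata: ad.AnnData,
    control_cells,
    genes: list[str] | None = None,
) -> ControlFit:
    """Fit the per-gene covariate model on control cells only.

    Residual SDs use denominator ``n - rank`` (the unbiased choice).
    """
    control_cells = list(control_cells)
    if not control_cells:
        raise ValueError("control cell set is empty")
    genes = list(genes) if genes is not None else list(adata.var_names)
    ctrl = adata[control_cells, genes]
    X, names, refs = build_design(ctrl.obs)
    X, names = _drop_collinear(X, names)
    Y = ctrl.layers["lognorm"]
    Y = Y.toarray() if hasattr(Y, "toarray") else np.asarray(Y)
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    df = len(control_cells) - rank
    if df <= 0:
        raise ValueError("not enough control cells for the design")
    residual_sd = np.sqrt((resid**2).sum(axis=0) / df)
    return ControlFit(
        genes=genes,
        design_columns=names,
        reference_levels=refs,
        coef=coef,
        residual_sd=residual_sd,
        n_control_cells=len(control_cells),
        rank=int(rank),
    )


def _design_for(adata: ad.AnnData, cells, fit: ControlFit) -> np.ndarray:
    obs = adata.obs.loc[list(cells)]
    X, names, _ = build_design(obs, reference_levels=fit.reference_levels)
    idx = {n: j for j, n in enumerate(names)}
    out = np.zeros((len(obs), len(fit.design_columns)))
    for j, name in enumerate(fit.design_columns):
        if name in idx:
            out[:, j] = X[:, idx[name]]
        # a control-fit column absent here (e.g. a line level not present)
        # contributes zero, which is the reference coding
    return out


def per_cell_effects(adata: ad.AnnData, cells, fit: ControlFit) -> pd.DataFrame:
    """Observed minus predicted log-normalized expression, cells x genes."""
    cells = list(cells)
    X = _design_for(adata, cells, fit)
    sub = adata[cells, fit.genes]
    Y = sub.layers["lognorm"]
    Y = Y.toarray() if hasattr(Y, "toarray") else np.asarray(Y)
    return pd.DataFrame(Y - X @ fit.coef, index=cells, columns=fit.genes)


def _summarize_group(effect_rows: np.ndarray, residual_sd: np.ndarray):
    """Mean LFC, SE, z and two-sided normal p for one group of cells.

    This is the single code path shared by the main aggregation and the
    bootstrap power analysis.
    """
    n = effect_rows.shape[0]
    lfc = effect_rows.mean(axis=0)
    se = residual_sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return lfc, n, se, z, p


def aggregate_effects(
    effects: pd.DataFrame,
    groups: pd.Series,
    fit: ControlFit,
    level: str,
    min_cells: int | None = None,
    fdr: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Average per-cell effects within units and attach z-test inference.

    ``groups`` maps each cell (index of ``effects``) to its unit id (guide,
    target, or "target|line"). Units with fewer than ``min_cells`` cells are
    omitted. BH adjustment is applied across all rows of the returned table.
    """
    if min_cells is None:
        min_cells = DEFAULT_MIN_CELLS.get(level, 10)
    groups = groups.loc[effects.index]
    rows = []
    for unit, cells in groups.groupby(groups).groups.items():
        if len(cells) < min_cells:
            continue
        lfc, n, se, z, p = _summarize_group(
            effects.loc[cells].to_numpy(), fit.residual_sd
        )
        rows.append(
            pd.DataFrame(
                {
                    "level": level,
                    "unit": unit,
                    "gene": fit.genes,
                    "lfc": lfc,
                    "n_cells": n,
                    "se": se,
                    "z": z,
                    "p": p,
                }
            )
        )
    if not rows:
        logger.warning("no unit at level %r passed the %d-cell minimum", level, min_cells)
        return pd.DataFrame(
            columns=["level", "unit", "gene", "lfc", "n_cells", "se", "z", "p", "p_adj", "significant"]
        )
    table = pd.concat(rows, ignore_index=True)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < fdr
    return table


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_cis_effect(
    adata: ad.AnnData,
    control_cells,
    gene: str,
    genotype_dosage: dict[str, int],
) -> float:
    """Additive cis-variant effect on ``gene`` from control cells.

    The control covariate model is refit with the cell-line term replaced by
    the donor's alternate-allele dosage (0/1/2); the returned coefficient is
    the per-allele effect on log-normalized expression.
    """
    control_cells = list(control_cells)
    obs = adata.obs.loc[control_cells]
    missing = set(obs["donor"].unique()) - set(genotype_dosage)
    if missing:
        raise ValueError(f"no genotype dosage for donor(s): {sorted(missing)}")
    dosage = obs["donor"].map(genotype_dosage).to_numpy(float)
    if np.unique(dosage).size < 2:
        raise ValueError("monomorphic dosage: cis effect unidentifiable")
    X, names, _ = build_design(obs, categorical=("inlet",))
    X = np.column_stack([X, dosage])
    names = names + ["dosage"]
    X, names = _drop_collinear(X, names)
    y = adata[control_cells, [gene]].layers["lognorm"]
    y = np.asarray(y.todense()).ravel() if hasattr(y, "todense") else np.asarray(y).ravel()
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[names.index("dosage")])


def test_universe_size(n_units: int, n_genes: int) -> int:
    """Number of (unit, expressed gene) tests a run defines."""
    if n_units < 0 or n_genes < 0:
        raise ValueError("counts must be non-negative")
    return int(n_units) * int(n_genes)


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """A fraction as a percentage rounded for reporting."""
    if denominator == 0:
        raise ValueError("denominator is zero")
    return round(100.0 * numerator / denominator, ndigits)
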