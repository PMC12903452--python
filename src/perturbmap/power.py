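"""Detection power and estimator variance by bootstrap down-sampling.

For a target with many assigned cells, cells are resampled with replacement
to simulated datasets of 5, 10, 25, 50, 100, 250, 500 and 1000 cells, 25
times each, and the trans-effect estimates are recomputed on every resample
through the identical code path as the main pipeline (the control model is
not refit: controls are untouched by the resampling). The spread of the LFC
across replicates measures estimator noise at each cell count; the fraction
of replicates reaching BH significance measures detection power.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .effects import ControlFit, _summarize_group, bh_adjust, FDR_THRESHOLD

__all__ = ["DEFAULT_SIZES", "bootstrap_downsample", "summarize_power", "sd_scaling_slope"]

DEFAULT_SIZES = (5, 10, 25, 50, 100, 250, 500, 1000)
DEFAULT_REPS = 25


def bootstrap_downsample(
    profiles: pd.DataFrame,
    target_cells,
    target: str,
    fit: ControlFit,
    sizes=DEFAULT_SIZES,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-estimate one target's effects on bootstrap resamples of its cells.

    ``profiles`` holds per-cell effects (cells x genes) from the main
    pipeline; resampling is with replacement so sizes may exceed the number
    of assigned cells. Seeding derives one independent stream per
    (size, replicate), so the grid is reproducible and insensitive to
    evaluation order. Returns a long-form frame (target, gene, size, rep,
    lfc, se, z, p).
    """
    cells = [c for c in target_cells if c in profiles.index]
    if not cells:
        raise ValueError(f"target {target!r} has no assigned cells with effect profiles")
    sizes = tuple(sizes)
    if any(s <= 0 for s in sizes) or list(sizes) != sorted(sizes):
        raise ValueError("sizes must be positive and ascending")
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    mat = profiles.loc[cells].to_numpy()
    genes = profiles.columns.to_numpy()
    root = np.random.SeedSequence(seed)
    frames = []
    for size, child in zip(sizes, root.spawn(len(sizes))):
        for rep, grand in enumerate(child.spawn(reps)):
            rng = np.random.default_rng(grand)
            idx = rng.integers(0, len(cells), size=size)
            lfc, n, se, z, p = _summarize_group(mat[idx], fit.residual_sd)
            frames.append(
                pd.DataFrame(
                    {
                        "target": target,
                        "gene": genes,
                        "size": size,
                        "rep": rep,
                        "lfc": lfc,
                        "se": se,
                        "z": z,
                        "p": p,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def summarize_power(
    grid: pd.DataFrame,
    true_pairs=None,
    fdr: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Per (target, gene, size): LFC spread and detection rate.

    BH adjustment is applied within each (size, rep) family across genes,
    mirroring the main pipeline; the detection rate is the fraction of
    replicates significant at ``fdr``. ``true_pairs`` (set of (target, gene))
    marks which rows carry an injected effect, when truth is known.
    """
    grid = grid.copy()
    grid["p_adj"] = grid.groupby(["target", "size", "rep"])["p"].transform(
        lambda p: bh_adjust(p.to_numpy())
    )
    grid["hit"] = grid["p_adj"] < fdr
    out = (
        grid.groupby(["target", "gene", "size"], sort=True)
        .agg(sd_lfc=("lfc", lambda x: x.std(ddof=1)), mean_lfc=("lfc", "mean"), detection_rate=("hit", "mean"))
        .reset_index()
    )
    if true_pairs is not None:
        tp = set(map(tuple, true_pairs))
        out["is_true_effect"] = [
            (t, g) in tp for t, g in zip(out["target"], out["gene"])
        ]
    return out


def sd_scaling_slope(summary: pd.DataFrame) -> float:
    """Slope of log sd(LFC) against log size (expected about -1/2).

    Pools all (target, gene) pairs with positive sd at every size.
    """
    sub = summary[summary["sd_lfc"] > 0]
    x = np.log(sub["size"].to_numpy(float))
    y = np.log(sub["sd_lfc"].to_numpy(float))
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)
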