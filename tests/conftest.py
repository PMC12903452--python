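"""Shared fixtures: small simulated screens built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from perturbmap import (
    PipelineConfig,
    SimConfig,
    random_trans_effects,
)
from perturbmap.effects import fit_control_model, per_cell_effects, aggregate_effects
from perturbmap.qc import lognormalize
from perturbmap.simulate import generate_dataset


def analyze(adata, guide_table, library, truth, threshold: float = 0.75, min_umis: int = 3):
    """Run assignment (fixed threshold), normalization, control fit, effects.

    Returns a dict with the intermediate objects the tests poke at.
    """
    from perturbmap.assignment import assign_guides

    inlets = adata.obs["inlet"]
    thresholds = {i: threshold for i in inlets.unique()}
    assign = assign_guides(guide_table, inlets, thresholds, min_umis=min_umis)
    target_of_guide = dict(zip(library.guide_id, library.target))
    adata.obs["assigned_guide"] = assign["assigned_guide"].reindex(adata.obs_names).fillna("")
    adata.obs["target"] = adata.obs["assigned_guide"].map(target_of_guide).fillna("")
    adata.obs["s_score"] = 0.0
    adata.obs["g2m_score"] = 0.0
    lognormalize(adata)
    is_control = (adata.obs["assigned_guide"] == "") | (adata.obs["target"] == "non-targeting")
    control_cells = list(adata.obs_names[is_control])
    fit = fit_control_model(adata, control_cells)
    assigned = list(adata.obs_names[~is_control])
    profiles = per_cell_effects(adata, assigned, fit)
    obs_assigned = adata.obs.loc[assigned]
    return {
        "adata": adata,
        "assign": assign,
        "control_cells": control_cells,
        "assigned": assigned,
        "fit": fit,
        "profiles": profiles,
        "obs": obs_assigned,
        "truth": truth,
        "library": library,
    }


@pytest.fixture(scope="session")
def effect_screen():
    """Screen with injected on-target and trans effects, paired planted
    co-regulation blocks (targets 0/1 and 2/3 share trans signatures)."""
    n_targets, n_genes = 6, 150
    rng = np.random.default_rng(42)
    trans: dict[tuple[int, int], float] = {}
    # two co-regulating blocks sharing signatures, plus idiosyncratic targets
    shared_a = rng.choice(np.arange(n_targets, n_genes), 6, replace=False)
    shared_b = rng.choice(np.arange(n_targets, n_genes), 6, replace=False)
    for j in shared_a:
        for t in (0, 1):
            trans[(t, int(j))] = 0.6
    for j in shared_b:
        for t in (2, 3):
            trans[(t, int(j))] = -0.6
    for t in (4, 5):
        for j in rng.choice(np.arange(n_targets, n_genes), 4, replace=False):
            trans[(t, int(j))] = float(rng.choice([-0.5, 0.5]))
    cfg = SimConfig(
        n_donors=2,
        cells_per_line_per_guide=20,
        n_genes=n_genes,
        n_targets=n_targets,
        guides_per_target=3,
        n_nontargeting=20,
        baseline_logmean_dist=(2.3, 0.4),
        trans_effect_matrix=trans,
        seed=11,
    )
    data = generate_dataset(cfg)
    out = analyze(*data)
    out["config"] = cfg
    return out


@pytest.fixture(scope="session")
def effect_tables(effect_screen):
    s = effect_screen
    return {
        "guide": aggregate_effects(s["profiles"], s["obs"]["assigned_guide"], s["fit"], "guide", 5),
        "target": aggregate_effects(s["profiles"], s["obs"]["target"], s["fit"], "target", 10),
        "target_by_line": aggregate_effects(
            s["profiles"],
            s["obs"]["target"] + "|" + s["obs"]["cell_line"].astype(str),
            s["fit"],
            "target_by_line",
            10,
        ),
    }


@pytest.fixture(scope="session")
def heritable_screen():
    """5-donor screen with donor-modulated trans effects: gamma SD 0.5 on
    20 planted (target, gene) pairs, ~51 cells per line per target."""
    n_targets, n_genes = 5, 100
    trans = {}
    modulated = []
    for t in range(n_targets):
        for j in range(n_targets + t * 4, n_targets + t * 4 + 4):
            trans[(t, j)] = 0.5
            modulated.append((t, j))
    cfg = SimConfig(
        n_donors=5,
        cells_per_line_per_guide=17,  # 3 guides -> 51 cells/line/target
        n_genes=n_genes,
        n_targets=n_targets,
        guides_per_target=3,
        n_nontargeting=15,
        baseline_logmean_dist=(2.3, 0.4),
        trans_effect_matrix=trans,
        donor_trans_sd=0.5,
        donor_modulated_pairs=modulated,
        donor_baseline_sd=0.4,
        heritable_baseline_fraction=0.15,
        seed=23,
    )
    data = generate_dataset(cfg)
    out = analyze(*data)
    out["config"] = cfg
    out["modulated"] = modulated
    return out
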