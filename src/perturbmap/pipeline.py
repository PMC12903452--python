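"""End-to-end orchestration of the screen analysis on one configuration.

``run_pipeline`` wires the stages together in their natural order —
simulate (or load) -> guide assignment -> QC and normalization -> control
model and per-cell effects -> guide/target/target x line aggregation ->
co-regulation -> off-target annotation -> donor heritability -> power — and
writes every result table as TSV with a provenance header carrying the
package version and a hash of the effective configuration. A single root
seed feeds named substreams for every stochastic stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assignment as asg
from . import effects as eff
from . import heritability as her
from . import io as pio
from . import power as pow_
from .coregulation import profile_correlation, threshold_network
from .qc import QcThresholds, cell_cycle_scores, filter_cells, lognormalize, select_expressed_genes
from .simulate import DonorDesign, SimConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage toggles and thresholds; defaults are the reference screen's values."""

    sim: SimConfig = field(default_factory=SimConfig)
    min_guide_umis: int = 3
    assignment_window: tuple[float, float] = (0.5, 1.0)
    assignment_fallback: float = 0.75
    assignment_threshold: float | None = None  # fixed threshold; None = detect per inlet
    qc_min_features: int = 2000
    qc_max_mito: float = 0.10
    qc_umi_threshold: int = 500  # applied to every inlet unless overridden
    qc_umi_thresholds: dict[str, int] = field(default_factory=dict)
    expressed_min_mean: float = 0.1
    min_cells_guide: int = 5
    min_cells_target: int = 10
    min_cells_target_line: int = 10
    fdr: float = 0.1
    coreg_min_abs_r: float = 0.2
    run_coregulation: bool = True
    run_heritability: bool = True
    heritability_early_stop: int = 10
    heritability_cap: int = 10_000
    max_heritability_pairs: int | None = None
    run_power: bool = False
    power_sizes: tuple[int, ...] = pow_.DEFAULT_SIZES
    power_reps: int = 25
    power_targets: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        data = dict(data)
        if "sim" in data and isinstance(data["sim"], dict):
            sim = dict(data["sim"])
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            bad = set(sim) - sim_known
            if bad:
                raise ValueError(f"unknown sim configuration key(s): {sorted(bad)}")
            if "trans_effect_matrix" in sim and isinstance(sim["trans_effect_matrix"], dict):
                sim["trans_effect_matrix"] = {
                    tuple(map(int, k.split(","))) if isinstance(k, str) else tuple(k): v
                    for k, v in sim["trans_effect_matrix"].items()
                }
            data["sim"] = SimConfig(**sim)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["trans_effect_matrix"] = {
            f"{t},{j}": v for (t, j), v in self.sim.trans_effect_matrix.items()
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def validate(self) -> None:
        self.sim.validate()
        if self.run_heritability and self.sim.n_donors < 2:
            raise ValueError("heritability stage requires at least 2 donors")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all toggled stages on a simulated screen; write result tables.

    Returns a dict of the in-memory results keyed by stage name.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"perturbmap_version": __version__, "config_hash": config.config_hash()}
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    logger.info("effective config hash %s", prov["config_hash"])
    results: dict = {}

    # -- simulate ----------------------------------------------------------
    adata, guide_table, library, truth = generate_dataset(config.sim)
    truth.to_json(outdir / "truth.json")
    pio.write_library(library, outdir / "library.tsv")
    results["truth"] = truth

    # -- guide assignment --------------------------------------------------
    inlet_of_cell = adata.obs["inlet"]
    if config.assignment_threshold is not None:
        thresholds = {
            inlet: config.assignment_threshold for inlet in inlet_of_cell.unique()
        }
    else:
        thresholds = asg.detect_thresholds_per_inlet(
            guide_table, inlet_of_cell,
            window=config.assignment_window, fallback=config.assignment_fallback,
        )
    assign = asg.assign_guides(guide_table, inlet_of_cell, thresholds, config.min_guide_umis)
    pio.write_table(assign.reset_index(), outdir / "assignments.tsv", prov)
    target_of_guide = dict(zip(library.guide_id, library.target))
    adata.obs["assigned_guide"] = assign["assigned_guide"].reindex(adata.obs_names).fillna("")
    adata.obs["target"] = adata.obs["assigned_guide"].map(target_of_guide).fillna("")
    results["assignments"] = assign

    # -- QC + normalization ------------------------------------------------
    umi_thr = {
        inlet: config.qc_umi_thresholds.get(inlet, config.qc_umi_threshold)
        for inlet in adata.obs["inlet"].unique()
    }
    adata = filter_cells(
        adata,
        QcThresholds(config.qc_min_features, config.qc_max_mito, umi_thr),
    )
    lognormalize(adata)
    expressed = select_expressed_genes(adata, config.expressed_min_mean)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    pool = [g for g in expressed]
    if len(pool) >= 10:
        picks = rng.choice(pool, size=min(40, len(pool)), replace=False)
        cell_cycle_scores(adata, list(picks[: len(picks) // 2]), list(picks[len(picks) // 2 :]))
    else:
        adata.obs["s_score"] = 0.0
        adata.obs["g2m_score"] = 0.0
    results["adata"] = adata
    results["expressed_genes"] = expressed

    # -- control model and effects ----------------------------------------
    is_control = (adata.obs["assigned_guide"] == "") | (
        adata.obs["target"] == "non-targeting"
    )
    control_cells = list(adata.obs_names[is_control])
    fit = eff.fit_control_model(adata, control_cells, genes=expressed)
    assigned = list(adata.obs_names[~is_control])
    profiles = eff.per_cell_effects(adata, assigned, fit)
    results["control_fit"] = fit
    results["profiles"] = profiles

    obs_assigned = adata.obs.loc[assigned]
    tables = {}
    tables["guide"] = eff.aggregate_effects(
        profiles, obs_assigned["assigned_guide"], fit, "guide", config.min_cells_guide, config.fdr
    )
    tables["target"] = eff.aggregate_effects(
        profiles, obs_assigned["target"], fit, "target", config.min_cells_target, config.fdr
    )
    tables["target_by_line"] = eff.aggregate_effects(
        profiles,
        obs_assigned["target"] + "|" + obs_assigned["cell_line"].astype(str),
        fit,
        "target_by_line",
        config.min_cells_target_line,
        config.fdr,
    )
    for level, tab in tables.items():
        pio.write_table(tab, outdir / f"effects_{level}.tsv", prov)
    results["effects"] = tables

    # -- co-regulation -----------------------------------------------------
    if config.run_coregulation and len(tables["target"]):
        for axis in ("targets", "genes"):
            sim = profile_correlation(tables["target"], axis=axis)
            edges = threshold_network(sim, config.coreg_min_abs_r)
            pio.write_table(edges, outdir / f"coregulation_{axis}_edges.tsv", prov)
            results[f"coregulation_{axis}"] = (sim, edges)

    # -- heritability ------------------------------------------------------
    if config.run_heritability and len(tables["target_by_line"]):
        design = DonorDesign(dict(truth.design))
        candidates = her.candidate_pairs(tables["target_by_line"], fdr=config.fdr)
        if config.max_heritability_pairs is not None:
            candidates = candidates[: config.max_heritability_pairs]
        target_expr = pd.DataFrame(
            np.asarray(
                adata[assigned, [g for g in adata.var_names if g in set(t for t, _ in candidates)]]
                .layers["lognorm"]
                .todense()
            ),
            index=assigned,
            columns=[g for g in adata.var_names if g in set(t for t, _ in candidates)],
        ) if candidates else pd.DataFrame(index=assigned)
        obs_h = obs_assigned.rename(columns={"assigned_guide": "guide"})
        records = her.heritability_scan(
            profiles,
            obs_h,
            target_expr,
            candidates,
            design,
            obs_assigned["target"],
            early_stop=config.heritability_early_stop,
            cap=config.heritability_cap,
            seed=config.seed,
        )
        records = her.classify_records(
            records,
            adata,
            design,
            control_cells,
            obs_assigned["target"],
            tables["target_by_line"],
            fdr=config.fdr,
            early_stop=config.heritability_early_stop,
            cap=config.heritability_cap,
            seed=config.seed,
        )
        pio.write_table(records, outdir / "heritability.tsv", prov)
        results["heritability"] = records

    # -- power -------------------------------------------------------------
    if config.run_power:
        grids = []
        targets = config.power_targets or tuple(
            t for t in tables["target"]["unit"].unique()[:3]
        )
        for t in targets:
            cells = obs_assigned.index[obs_assigned["target"] == t]
            grids.append(
                pow_.bootstrap_downsample(
                    profiles, cells, t, fit,
                    sizes=config.power_sizes, reps=config.power_reps, seed=config.seed,
                )
            )
        grid = pd.concat(grids, ignore_index=True)
        summary = pow_.summarize_power(grid, fdr=config.fdr)
        pio.write_table(grid, outdir / "power_grid.tsv", prov)
        pio.write_table(summary, outdir / "power_summary.tsv", prov)
        results["power"] = (grid, summary)

    return results
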