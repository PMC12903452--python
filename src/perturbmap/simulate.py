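"""Synthetic pooled CRISPRi screens with single-cell readout and known truth.

The generator emulates the structure of a multi-donor CRISPRi screen: donors
each contribute two replicate iPSC lines, cells carry one guide from a
library of targeting and non-targeting guides, and UMI counts follow a
negative binomial with gene-specific means and a common dispersion. Injected
signal consists of an on-target knockdown (a natural-log fold change on the
NB mean), sparse trans effects on downstream genes, optional donor-specific
modulations of those trans effects (shared by both replicate lines of a
donor — the structure the constrained permutation test is built to detect),
and donor offsets on the baseline expression of a subset of genes
("heritable" baseline expression).

Guide-capture UMIs are simulated separately: each cell receives UMIs for its
true guide around ``true_guide_umi_mean`` plus Poisson ambient contamination
spread over random other guides, creating exactly the ambiguity the
relative-abundance assignment rule resolves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "SimConfig",
    "DonorDesign",
    "SyntheticTruth",
    "GuideUmiTable",
    "generate_donor_design",
    "generate_dataset",
    "sample_guide_umis",
    "random_trans_effects",
]


@dataclass
class DonorDesign:
    """Mapping of replicate cell lines to donors (two lines per donor)."""

    line_to_donor: dict[str, str]

    @property
    def donors(self) -> list[str]:
        return sorted(set(self.line_to_donor.values()))

    @property
    def lines(self) -> list[str]:
        return sorted(self.line_to_donor)

    def donor_pairs(self) -> list[tuple[str, str]]:
        """The original (line, line) pair of each donor, sorted."""
        by_donor: dict[str, list[str]] = {}
        for line, donor in self.line_to_donor.items():
            by_donor.setdefault(donor, []).append(line)
        return [tuple(sorted(v)) for _, v in sorted(by_donor.items())]


def generate_donor_design(n_donors: int, lines_per_donor: int = 2) -> DonorDesign:
    """Create the paired-line design: ``n_donors`` donors, two lines each.

    The donor-label permutation scheme requires swapping lines between
    donors, so at least two donors are needed.
    """
    if n_donors < 2:
        raise ValueError("n_donors must be >= 2 (permutation scheme undefined)")
    if lines_per_donor != 2:
        raise ValueError("the paired design requires exactly 2 lines per donor")
    mapping = {}
    for d in range(n_donors):
        for r in range(lines_per_donor):
            mapping[f"donor{d}_line{r}"] = f"donor{d}"
    return DonorDesign(mapping)


@dataclass
class SimConfig:
    """All knobs of the simulated screen; ``seed`` fully determines output.

    Log-fold changes are on the natural-log scale and act multiplicatively on
    the NB mean, so they are commensurate with differences of log1p-normalized
    expression downstream. ``trans_effect_matrix`` maps (target index, gene
    index) to an LFC; target index t corresponds to gene index t (the first
    ``n_targets`` genes are the targets) and on-target entries are forbidden
    there because the on-target knockdown is injected separately.
    """

    n_donors: int = 5
    lines_per_donor: int = 2
    cells_per_line_per_guide: int = 10
    n_genes: int = 300
    n_targets: int = 20
    guides_per_target: int = 3
    n_nontargeting: int = 40
    baseline_logmean_dist: tuple[float, float] = (1.0, 1.0)
    nb_dispersion: float = 10.0
    libsize_logmean: float = 0.0
    libsize_logsd: float = 0.25
    on_target_lfc: float = -0.5
    trans_effect_matrix: dict[tuple[int, int], float] = field(default_factory=dict)
    donor_baseline_sd: float = 0.0
    heritable_baseline_fraction: float = 0.1
    donor_trans_sd: float = 0.0
    donor_modulated_pairs: list[tuple[int, int]] | None = None
    ambient_guide_rate: float = 1.0
    true_guide_umi_mean: float = 10.0
    mito_beta_params: tuple[float, float] = (2.0, 38.0)
    n_unassigned_per_line: int = 20
    n_inlets: int = 2
    dpi: int = 10
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_donors": self.n_donors,
            "lines_per_donor": self.lines_per_donor,
            "cells_per_line_per_guide": self.cells_per_line_per_guide,
            "n_genes": self.n_genes,
            "n_targets": self.n_targets,
            "guides_per_target": self.guides_per_target,
            "n_inlets": self.n_inlets,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.n_nontargeting < 0 or self.n_unassigned_per_line < 0:
            raise ValueError("n_nontargeting and n_unassigned_per_line must be >= 0")
        if self.n_targets > self.n_genes:
            raise ValueError("n_targets cannot exceed n_genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for name in ("donor_baseline_sd", "donor_trans_sd", "ambient_guide_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.true_guide_umi_mean <= 0:
            raise ValueError("true_guide_umi_mean must be > 0")
        if not 0 <= self.heritable_baseline_fraction <= 1:
            raise ValueError("heritable_baseline_fraction must be in [0, 1]")
        for (t, j), lfc in self.trans_effect_matrix.items():
            if not (0 <= t < self.n_targets):
                raise ValueError(f"trans_effect_matrix target index {t} out of range")
            if not (0 <= j < self.n_genes):
                raise ValueError(f"trans_effect_matrix gene index {j} out of range")
            if t == j:
                raise ValueError(
                    "trans_effect_matrix must not contain on-target entries "
                    f"(target {t}); on-target knockdown is set via on_target_lfc"
                )
            if not np.isfinite(lfc):
                raise ValueError("trans effect LFCs must be finite")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated screen; JSON-serializable."""

    guide_of_cell: dict[str, str]
    lfc_true: dict[str, dict[str, float]]  # target gene -> {gene: lfc}
    donor_modulation: dict[str, float]  # "target|gene|donor" -> gamma
    heritable_baseline_genes: dict[str, dict[str, float]]  # gene -> donor offsets
    control_cells: list[str]
    line_of_cell: dict[str, str]
    design: dict[str, str]  # line -> donor

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GuideUmiTable:
    """Sparse guide-capture UMI counts, cells x guides."""

    counts: sparse.csr_matrix
    cell_ids: list[str]
    guide_ids: list[str]

    def to_long(self) -> pd.DataFrame:
        coo = self.counts.tocoo()
        return pd.DataFrame(
            {
                "cell": [self.cell_ids[i] for i in coo.row],
                "guide": [self.guide_ids[j] for j in coo.col],
                "umis": coo.data.astype(int),
            }
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame, cell_ids=None, guide_ids=None):
        cells = list(cell_ids) if cell_ids is not None else sorted(df["cell"].unique())
        guides = list(guide_ids) if guide_ids is not None else sorted(df["guide"].unique())
        ci = {c: i for i, c in enumerate(cells)}
        gi = {g: i for i, g in enumerate(guides)}
        mat = sparse.coo_matrix(
            (
                df["umis"].to_numpy(),
                (df["cell"].map(ci).to_numpy(), df["guide"].map(gi).to_numpy()),
            ),
            shape=(len(cells), len(guides)),
        ).tocsr()
        return cls(mat, cells, guides)


def random_trans_effects(
    n_targets: int,
    n_genes: int,
    effects_per_target: int = 5,
    lfc_scale: float = 0.5,
    seed: int = 0,
    gene_pool: np.ndarray | None = None,
) -> dict[tuple[int, int], float]:
    """Draw a sparse target x gene trans-effect matrix.

    Downstream genes are sampled from ``gene_pool`` (default: all non-target
    genes) and LFC magnitudes from ±``lfc_scale`` x Uniform(0.5, 1.5).
    """
    rng = np.random.default_rng(seed)
    pool = (
        np.asarray(gene_pool)
        if gene_pool is not None
        else np.arange(n_targets, n_genes)
    )
    out: dict[tuple[int, int], float] = {}
    for t in range(n_targets):
        genes = rng.choice(pool[pool != t], size=min(effects_per_target, len(pool)), replace=False)
        for j in genes:
            sign = rng.choice([-1.0, 1.0])
            out[(t, int(j))] = float(sign * lfc_scale * rng.uniform(0.5, 1.5))
    return out


def _gene_names(n: int) -> list[str]:
    return [f"gene{i:04d}" for i in range(n)]


def _build_library(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = _gene_names(config.n_genes)
    rows = []
    bases = np.array(list("ACGT"))
    for t in range(config.n_targets):
        for g in range(config.guides_per_target):
            seq = "".join(rng.choice(bases, size=20))
            rows.append((f"{genes[t]}_g{g + 1}", genes[t], seq, False))
    for k in range(config.n_nontargeting):
        seq = "".join(rng.choice(bases, size=20))
        rows.append((f"NTC_g{k + 1}", "non-targeting", seq, True))
    return pd.DataFrame(rows, columns=["guide_id", "target", "sequence", "is_control"])


def generate_dataset(
    config: SimConfig,
) -> tuple[ad.AnnData, GuideUmiTable, pd.DataFrame, SyntheticTruth]:
    """Simulate a full screen: counts, guide UMIs, library and ground truth.

    Returns an AnnData (cells x genes, raw UMI counts in ``X``), the sparse
    guide-UMI table, the guide library table and the :class:`SyntheticTruth`.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    design = generate_donor_design(config.n_donors, config.lines_per_donor)
    genes = _gene_names(config.n_genes)
    library = _build_library(config, rng)

    loc, scale = config.baseline_logmean_dist
    base_logmean = rng.normal(loc, scale, size=config.n_genes)
    # targets sit in the upper expression range so injected LFCs survive the
    # pseudocount; the real screen likewise targeted well-expressed genes
    base_logmean[: config.n_targets] = loc + scale * np.abs(
        rng.normal(0.8, 0.4, size=config.n_targets)
    )

    # donor offsets on baseline expression for a subset of genes
    n_herit = int(round(config.heritable_baseline_fraction * config.n_genes))
    heritable_idx = (
        rng.choice(config.n_genes, size=n_herit, replace=False)
        if config.donor_baseline_sd > 0 and n_herit > 0
        else np.array([], dtype=int)
    )
    donors = design.donors
    donor_offsets = np.zeros((len(donors), config.n_genes))
    for j in heritable_idx:
        off = rng.normal(0, config.donor_baseline_sd, size=len(donors))
        donor_offsets[:, j] = off - off.mean()

    # donor modulation of trans effects, shared by both lines of a donor
    mod_pairs = (
        list(config.trans_effect_matrix)
        if config.donor_modulated_pairs is None
        else list(config.donor_modulated_pairs)
    )
    donor_modulation: dict[tuple[int, int, str], float] = {}
    if config.donor_trans_sd > 0:
        for t, j in mod_pairs:
            if (t, j) not in config.trans_effect_matrix:
                raise ValueError(
                    f"donor_modulated_pairs entry ({t}, {j}) has no trans effect"
                )
            g = rng.normal(0, config.donor_trans_sd, size=len(donors))
            g = g - g.mean()  # zero-mean across donors by construction
            for d, donor in enumerate(donors):
                donor_modulation[(t, j, donor)] = float(g[d])

    # cell bookkeeping: per line, cells_per_line_per_guide for every guide
    # (targeting and non-targeting) plus unassigned controls
    guide_ids = library["guide_id"].tolist()
    guide_target_idx = np.full(len(guide_ids), -1)
    gene_index = {g: i for i, g in enumerate(genes)}
    for k, row in library.iterrows():
        if not row.is_control:
            guide_target_idx[k] = gene_index[row.target]

    lines = design.lines
    cell_line, cell_guide = [], []
    for line in lines:
        for gidx in range(len(guide_ids)):
            cell_line += [line] * config.cells_per_line_per_guide
            cell_guide += [gidx] * config.cells_per_line_per_guide
        cell_line += [line] * config.n_unassigned_per_line
        cell_guide += [-1] * config.n_unassigned_per_line  # unassigned control
    n_cells = len(cell_line)
    cell_ids = [f"cell{i:06d}" for i in range(n_cells)]
    cell_line = np.array(cell_line)
    cell_guide = np.array(cell_guide)
    cell_donor = np.array([design.line_to_donor[l] for l in cell_line])
    donor_idx = {d: i for i, d in enumerate(donors)}

    # per-cell log-mean offsets: depth + donor baseline + injected effects
    depth = rng.lognormal(config.libsize_logmean, config.libsize_logsd, size=n_cells)
    log_mu = np.tile(base_logmean, (n_cells, 1))
    log_mu += donor_offsets[[donor_idx[d] for d in cell_donor], :]
    is_control_guide = library["is_control"].to_numpy()
    cell_target = np.where(
        (cell_guide >= 0) & ~is_control_guide[np.maximum(cell_guide, 0)],
        guide_target_idx[np.maximum(cell_guide, 0)],
        -1,
    )
    for t in range(config.n_targets):
        mask_t = cell_target == t
        if not mask_t.any():
            continue
        log_mu[mask_t, t] += config.on_target_lfc
        for (tt, j), lfc in config.trans_effect_matrix.items():
            if tt != t:
                continue
            log_mu[mask_t, j] += lfc
            for d, donor in enumerate(donors):
                g = donor_modulation.get((t, j, donor), 0.0)
                if g:
                    log_mu[mask_t & (cell_donor == donor), j] += g

    mu = depth[:, None] * np.exp(log_mu)
    theta = float(config.nb_dispersion)
    counts = rng.poisson(rng.gamma(theta, mu / theta))
    X = sparse.csr_matrix(counts)

    mito = rng.beta(*config.mito_beta_params, size=n_cells)
    obs = pd.DataFrame(
        {
            "cell_line": cell_line,
            "donor": cell_donor,
            "inlet": rng.choice([f"inlet{i}" for i in range(config.n_inlets)], size=n_cells),
            "dpi": config.dpi,
            "mito_fraction": mito,
            "total_umis": np.asarray(X.sum(axis=1)).ravel(),
            "n_features": np.asarray((X > 0).sum(axis=1)).ravel(),
        },
        index=cell_ids,
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))

    lfc_true: dict[str, dict[str, float]] = {}
    for t in range(config.n_targets):
        row = {genes[t]: float(config.on_target_lfc)} if config.on_target_lfc != 0 else {}
        for (tt, j), lfc in config.trans_effect_matrix.items():
            if tt == t:
                row[genes[j]] = float(lfc)
        lfc_true[genes[t]] = row

    is_control_cell = cell_target < 0
    truth = SyntheticTruth(
        guide_of_cell={
            cell_ids[i]: (guide_ids[cell_guide[i]] if cell_guide[i] >= 0 else "")
            for i in range(n_cells)
        },
        lfc_true=lfc_true,
        donor_modulation={
            f"{genes[t]}|{genes[j]}|{d}": v for (t, j, d), v in donor_modulation.items()
        },
        heritable_baseline_genes={
            genes[j]: {d: float(donor_offsets[donor_idx[d], j]) for d in donors}
            for j in heritable_idx
        },
        control_cells=[cell_ids[i] for i in range(n_cells) if is_control_cell[i]],
        line_of_cell=dict(zip(cell_ids, cell_line)),
        design=dict(design.line_to_donor),
    )

    guide_table = sample_guide_umis(truth, config, cell_ids=cell_ids, guide_ids=guide_ids)
    return adata, guide_table, library, truth


def sample_guide_umis(
    truth: SyntheticTruth,
    config: SimConfig,
    cell_ids: list[str] | None = None,
    guide_ids: list[str] | None = None,
) -> GuideUmiTable:
    """Simulate guide-capture UMIs for every cell in ``truth``.

    Each cell with a true guide receives ``Poisson(true_guide_umi_mean)``
    UMIs for it (floored at 1) plus ``Poisson(ambient_guide_rate)`` ambient
    UMIs scattered uniformly over the other guides. Unassigned control cells
    (empty true guide) receive no UMIs at all.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    if cell_ids is None:
        cell_ids = sorted(truth.guide_of_cell)
    if guide_ids is None:
        guide_ids = sorted({g for g in truth.guide_of_cell.values() if g})
    gidx = {g: i for i, g in enumerate(guide_ids)}
    rows, cols, data = [], [], []
    n_guides = len(guide_ids)
    for i, cell in enumerate(cell_ids):
        true_guide = truth.guide_of_cell[cell]
        if not true_guide:
            continue
        k = max(1, rng.poisson(config.true_guide_umi_mean))
        rows.append(i)
        cols.append(gidx[true_guide])
        data.append(k)
        n_amb = rng.poisson(config.ambient_guide_rate) if config.ambient_guide_rate > 0 else 0
        if n_amb > 0 and n_guides > 1:
            others = rng.integers(0, n_guides - 1, size=n_amb)
            others = np.where(others >= gidx[true_guide], others + 1, others)
            for j, c in zip(*np.unique(others, return_counts=True)):
                rows.append(i)
                cols.append(int(j))
                data.append(int(c))
    mat = sparse.coo_matrix(
        (data, (rows, cols)), shape=(len(cell_ids), n_guides)
    ).tocsr()
    mat.sum_duplicates()
    return GuideUmiTable(mat, list(cell_ids), list(guide_ids))
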