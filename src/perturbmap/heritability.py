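"""Donor heritability of perturbation effects via a constrained permutation LMM test.

For each candidate (target, expressed gene) pair, the per-cell perturbation
effects of the target's assigned cells are fitted with a linear mixed model:
normalized target-gene expression as a fixed effect (a proxy for per-cell
knockdown efficacy) and guide, cell line and donor as independent random
intercepts, by REML. The donor contribution is measured by the likelihood
ratio between this model and the one without the donor term.

Significance comes from a permutation scheme that respects the paired-line
design: donor labels are permuted across cell lines such that the two lines
of every donor end up in different donors, preserving the line structure
while destroying the donor structure. For n donors with two lines each the
admissible relabelings are the perfect pairings of the 2n lines that avoid
every original pair — 544 of them for 5 donors. Permutations are evaluated
in seeded random order with early stopping once 10 null statistics reach the
observed one, and the empirical p-value is

    p_emp = max(10, S + 1) / (min(P, 10^4) + 1)

where S counts stronger null observations and P the permutations evaluated,
so p_emp is floored at 10 / (P + 1). The floor's conservatism is largely
offset by negative dependence inherent in the derangement constraint (null
pairings cannot reuse the observed donor pairs), leaving the test
approximately calibrated; see docs/methods.md.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import bh_adjust
from .lmm import LmmFit, RandomInterceptLMM
from .simulate import DonorDesign

__all__ = [
    "LmmSpec",
    "fit_lmm",
    "lrt_donor",
    "enumerate_donor_permutations",
    "admissible_pairing_count",
    "permutation_pvalue",
    "control_heritability",
    "candidate_pairs",
    "classify_heritability",
    "classify_records",
    "variance_decomposition",
    "heritability_scan",
]

logger = logging.getLogger(__name__)

EARLY_STOP = 10
PERMUTATION_CAP = 10_000
FDR_THRESHOLD = 0.1
MIN_ABS_LFC = 0.1


@dataclass
class LmmSpec:
    """One (target, gene) mixed-model problem.

    ``y`` holds the per-cell response (perturbation effect, or normalized
    expression for control-cell tests); ``fixed`` the per-cell fixed
    covariate (normalized target-gene expression) or None for an
    intercept-only model; ``guide``/``line``/``donor`` the per-cell labels
    (``guide`` may be None for control-cell models).
    """

    y: np.ndarray
    fixed: np.ndarray | None
    guide: np.ndarray | None
    line: np.ndarray
    donor: np.ndarray

    def design(self) -> np.ndarray:
        n = len(self.y)
        if self.fixed is None:
            return np.ones((n, 1))
        return np.column_stack([np.ones(n), np.asarray(self.fixed, float)])

    def factors(self, with_donor: bool = True) -> dict[str, np.ndarray]:
        f: dict[str, np.ndarray] = {}
        if self.guide is not None:
            f["guide"] = np.asarray(self.guide)
        f["line"] = np.asarray(self.line)
        if with_donor:
            f["donor"] = np.asarray(self.donor)
        return f

    def check(self) -> None:
        line_donor = pd.DataFrame({"line": self.line, "donor": self.donor})
        per_line = line_donor.groupby("line")["donor"].nunique()
        if (per_line > 1).any():
            raise ValueError("cell lines must nest consistently within donors")
        per_donor = line_donor.groupby("donor")["line"].nunique()
        if len(per_donor) < 2:
            raise ValueError("need >= 2 donors represented")
        if (per_donor < 2).any():
            raise ValueError("every donor needs both replicate lines represented")


def fit_lmm(spec: LmmSpec, with_donor: bool = True) -> LmmFit:
    """REML fit of the full (or donor-free) model for one pair."""
    spec.check()
    model = RandomInterceptLMM(spec.y, spec.design(), spec.factors(with_donor))
    return model.fit()


def lrt_donor(spec: LmmSpec) -> float:
    """2 x (loglik_full - loglik_without_donor), clipped at zero."""
    full = fit_lmm(spec, with_donor=True)
    reduced = fit_lmm(spec, with_donor=False)
    if full.degenerate or reduced.degenerate:
        raise ValueError("degenerate fit: response has no variance")
    lrt = 2.0 * (full.loglik - reduced.loglik)
    if lrt < 0:
        logger.debug("negative LRT %.3g clipped to 0", lrt)
    return max(0.0, float(lrt))


# -- permutation scheme ----------------------------------------------------


def admissible_pairing_count(n_donors: int) -> int:
    """Closed form: pairings of 2n lines avoiding all n original pairs.

    Inclusion-exclusion over the forbidden pairs:
    sum_k (-1)^k C(n, k) (2n - 2k - 1)!!
    """
    total = 0
    for k in range(n_donors + 1):
        m = 2 * (n_donors - k)
        dfact = math.prod(range(m - 1, 0, -2)) if m > 0 else 1
        total += (-1) ** k * math.comb(n_donors, k) * dfact
    return total


def enumerate_donor_permutations(design: DonorDesign) -> list[tuple[tuple[str, str], ...]]:
    """All admissible donor relabelings of the paired-line design.

    Each relabeling is an unlabeled partition of the lines into pairs, none
    of which is an original donor pair (labels are irrelevant to the donor
    variance component). Returned as sorted tuples of sorted line pairs.
    """
    lines = design.lines
    if len(lines) % 2:
        raise ValueError("odd number of lines: paired design required")
    forbidden = set(design.donor_pairs())

    out: list[tuple[tuple[str, str], ...]] = []

    def recurse(remaining: list[str], acc: list[tuple[str, str]]):
        if not remaining:
            out.append(tuple(acc))
            return
        first = remaining[0]
        for j in range(1, len(remaining)):
            pair = (first, remaining[j])
            if pair in forbidden:
                continue
            rest = remaining[1:j] + remaining[j + 1 :]
            acc.append(pair)
            recurse(rest, acc)
            acc.pop()

    recurse(list(lines), [])
    return out


class _PermutationEngine:
    """Fast refits of the full model under donor relabelings.

    Only the donor factor changes between permutations, and donors are
    groupings of lines, so every permuted model's cross-products derive from
    line-level aggregates of the base (guide, line) model: if Z_d = Z_l M for
    pairing indicator M, then Z_d'A = M'(Z_l'A) for any A. No per-cell work
    is done inside the loop.
    """

    def __init__(self, spec: LmmSpec):
        spec.check()
        self.spec = spec
        y = np.asarray(spec.y, float)
        X = spec.design()
        base = RandomInterceptLMM(y, X, spec.factors(with_donor=False))
        self.base = base
        self.names = base.names  # may or may not include "guide"
        self.sl = base.block_slices["line"]
        self.line_levels = base.levels["line"]
        self._X = X
        self._y = y

    def model_for(self, pairing: tuple[tuple[str, str], ...]) -> RandomInterceptLMM:
        ql = len(self.line_levels)
        nd = len(pairing)
        M = np.zeros((ql, nd))
        lidx = {l: i for i, l in enumerate(self.line_levels)}
        for g, pair in enumerate(pairing):
            for line in pair:
                M[lidx[line], g] = 1.0
        b = self.base
        Zb_Zb = b._ZtZ  # (qg+ql) square
        Zl_rows = slice(self.sl.start, self.sl.stop)
        Zl_Zb = Zb_Zb[Zl_rows, :]
        Zd_Zb = M.T @ Zl_Zb
        Zd_Zd = M.T @ Zb_Zb[Zl_rows, Zl_rows] @ M
        q0 = Zb_Zb.shape[0]
        ZtZ = np.zeros((q0 + nd, q0 + nd))
        ZtZ[:q0, :q0] = Zb_Zb
        ZtZ[q0:, :q0] = Zd_Zb
        ZtZ[:q0, q0:] = Zd_Zb.T
        ZtZ[q0:, q0:] = Zd_Zd
        ZtX = np.vstack([b._ZtX, M.T @ b._ZtX[Zl_rows]])
        Zty = np.concatenate([b._Zty, M.T @ b._Zty[Zl_rows]])
        levels = dict(b.levels)
        levels["donor"] = np.array([f"perm{g}" for g in range(nd)])
        return RandomInterceptLMM.from_crossprods(
            self.names + ["donor"],
            levels,
            ZtZ,
            ZtX,
            Zty,
            b._XtX,
            b._Xty,
            b._yty,
            b.n,
            b._ybar,
        )


def permutation_pvalue(
    observed_lrt: float,
    spec: LmmSpec,
    permutations: list[tuple[tuple[str, str], ...]],
    early_stop: int = EARLY_STOP,
    cap: int = PERMUTATION_CAP,
    seed: int = 0,
) -> tuple[int, int, float]:
    """Empirical p-value of the donor LRT under admissible relabelings.

    Permutations are consumed in seeded random order (without replacement,
    truncated at ``cap``) until ``early_stop`` null statistics >= the
    observed one are seen, the cap is hit, or the list is exhausted. Returns
    (S, P, p_emp) with p_emp = max(10, S+1) / (min(P, 1e4) + 1).
    """
    engine = _PermutationEngine(spec)
    reduced = engine.base.fit()
    if reduced.degenerate:
        raise ValueError("degenerate response: permutation test undefined")
    # warm start permuted fits from the observed full-model optimum; floored
    # away from the boundary so the gradient search is never started in the
    # flat gamma ~ 0 region (where it would terminate immediately and
    # systematically underestimate null statistics)
    obs_fit = fit_lmm(spec, with_donor=True)
    warm = np.array(
        [
            max(obs_fit.varcomp[n] / max(obs_fit.sigma2, 1e-12), 0.05)
            for n in engine.names + ["donor"]
        ]
    )
    # re-evaluate the observed statistic with the exact routine used for the
    # nulls (same engine, warm start and optimizer), and compare against the
    # smaller of the two: any optimizer shortfall then deflates both sides
    # equally instead of only the null distribution
    identity = tuple(
        sorted(
            tuple(sorted(pd.unique(np.asarray(spec.line)[np.asarray(spec.donor) == d])))
            for d in pd.unique(np.asarray(spec.donor))
        )
    )
    obs_ll = engine.model_for(identity).fit_grad(warm)
    observed_cmp = min(
        observed_lrt, max(0.0, 2.0 * (obs_ll - reduced.loglik))
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(permutations))[:cap]
    S = 0
    P = 0
    n_bad = 0
    for k in order:
        model = engine.model_for(permutations[k])
        ll = model.fit_grad(warm)
        if not np.isfinite(ll):
            n_bad += 1
            continue
        null_lrt = max(0.0, 2.0 * (ll - reduced.loglik))
        P += 1
        # numerical ties (boundary fits on both sides) count as exceedances
        if null_lrt >= observed_cmp - 1e-6:
            S += 1
            if S >= early_stop:
                break
    if n_bad:
        logger.warning("%d permutation fit(s) failed and were skipped", n_bad)
    p_emp = max(EARLY_STOP, S + 1) / (min(P, PERMUTATION_CAP) + 1)
    return S, P, float(min(p_emp, 1.0))


def control_heritability(
    adata,
    gene: str,
    control_cells,
    design: DonorDesign,
    permutations=None,
    early_stop: int = EARLY_STOP,
    cap: int = PERMUTATION_CAP,
    seed: int = 0,
) -> dict:
    """Donor heritability of a gene's expression in control cells.

    Same LMM/permutation machinery applied to normalized expression, with
    random effects line and donor only (no guide, no efficacy covariate).
    """
    control_cells = list(control_cells)
    obs = adata.obs.loc[control_cells]
    y = adata[control_cells, [gene]].layers["lognorm"]
    y = np.asarray(y.todense()).ravel() if hasattr(y, "todense") else np.asarray(y).ravel()
    spec = LmmSpec(
        y=y,
        fixed=None,
        guide=None,
        line=obs["cell_line"].to_numpy(),
        donor=obs["donor"].to_numpy(),
    )
    lrt = lrt_donor(spec)
    if permutations is None:
        permutations = enumerate_donor_permutations(design)
    S, P, p_emp = permutation_pvalue(lrt, spec, permutations, early_stop, cap, seed)
    return {"gene": gene, "lrt": lrt, "S": S, "P": P, "p_emp": p_emp}


# -- candidate selection and classification --------------------------------


def candidate_pairs(
    effects_by_line: pd.DataFrame,
    offtarget_pairs=None,
    fdr: float = FDR_THRESHOLD,
    min_abs_lfc: float = MIN_ABS_LFC,
) -> list[tuple[str, str]]:
    """(target, gene) pairs significant in at least one line and unflagged.

    ``effects_by_line`` is a target x line effect table whose ``unit`` is
    "target|line". A pair qualifies when some line has BH-adjusted p below
    ``fdr`` and |LFC| above ``min_abs_lfc``; pairs in ``offtarget_pairs``
    (off-target or cross-mapping artifacts) are removed.
    """
    tab = effects_by_line.copy()
    split = tab["unit"].str.split("|", n=1, expand=True)
    tab["target"] = split[0]
    hit = (tab["p_adj"] < fdr) & (tab["lfc"].abs() > min_abs_lfc)
    pairs = set(map(tuple, tab.loc[hit, ["target", "gene"]].to_numpy()))
    if offtarget_pairs is not None:
        pairs -= set(map(tuple, offtarget_pairs))
    return sorted(pairs)


def classify_heritability(
    donor_p_adj: float,
    control_p_adj: float | None,
    control_p_emp: float | None,
    postkd_p_adj: float | None,
    line_lfcs: dict[str, float],
    line_to_donor: dict[str, str],
    fdr: float = FDR_THRESHOLD,
) -> tuple[str, str, str | None]:
    """Classify a heritable trans effect and its direction.

    Classes: expression heritable in controls (adjusted p < 0.1) resolves to
    "loss" when heritability disappears after knockdown, else "maintenance";
    no evidence in controls (p > 0.9) resolves to "gain" when heritability
    appears after knockdown, else "no-gain"; anything in between is
    "unclassified". Direction is "up"/"down" from the line LFCs, and when a
    single donor's two lines drive an up-regulation that donor is reported
    as the carrier.
    """
    if donor_p_adj >= fdr:
        return "unclassified", _direction(line_lfcs, line_to_donor)[0], None
    if control_p_adj is None or control_p_emp is None or postkd_p_adj is None:
        return "unclassified", _direction(line_lfcs, line_to_donor)[0], None
    direction, carrier = _direction(line_lfcs, line_to_donor)
    if control_p_adj < fdr:
        cls = "loss" if postkd_p_adj >= fdr else "maintenance"
    elif control_p_emp > 0.9:
        cls = "gain" if postkd_p_adj < fdr else "no-gain"
    else:
        cls = "unclassified"
    return cls, direction, carrier


def _direction(line_lfcs: dict[str, float], line_to_donor: dict[str, str]):
    if not line_lfcs:
        return "unknown", None
    vals = pd.Series(line_lfcs, dtype=float)
    donor_mean = vals.groupby(vals.index.map(line_to_donor)).mean()
    up = donor_mean[donor_mean > 0]
    if len(up) == 1 and (donor_mean.drop(up.index) <= 0).all():
        return "up", str(up.index[0])
    return ("up" if vals.mean() > 0 else "down"), None


def variance_decomposition(
    y,
    factors: dict[str, np.ndarray],
    fixed: np.ndarray | None = None,
) -> dict[str, float]:
    """Fraction of response variance per random effect, residual and fixed.

    Components come from the REML fit; the fixed-effect share is the
    variance of the fitted fixed-effect contribution. Fractions sum to 1.
    """
    y = np.asarray(y, float)
    n = len(y)
    X = np.ones((n, 1)) if fixed is None else np.column_stack([np.ones(n), np.asarray(fixed, float)])
    fit = RandomInterceptLMM(y, X, factors).fit()
    if fit.degenerate:
        return {**{k: 0.0 for k in factors}, "fixed": 0.0, "residual": 0.0}
    parts = dict(fit.varcomp)
    parts["residual"] = fit.sigma2
    contrib = X @ fit.beta
    parts["fixed"] = float(contrib.var(ddof=0)) if X.shape[1] > 1 else 0.0
    total = sum(parts.values())
    return {k: v / total for k, v in parts.items()}


def classify_records(
    records: pd.DataFrame,
    adata,
    design: DonorDesign,
    control_cells,
    target_of_cell: pd.Series,
    line_lfcs: pd.DataFrame,
    fdr: float = FDR_THRESHOLD,
    early_stop: int = EARLY_STOP,
    cap: int = PERMUTATION_CAP,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach heritability classes and directions to scan records.

    For every donor-significant pair (p_adj < fdr) the response gene's
    expression heritability is tested in control cells and in the target's
    perturbed cells (same LMM/permutation machinery); the loss/maintenance/
    gain rules then classify the pair. ``line_lfcs`` is the target x line
    effect table (unit "target|line") supplying per-line LFC signs.
    """
    out = records.copy()
    out["class"] = "unclassified"
    out["direction"] = ""
    out["carrier_donor"] = ""
    if not len(out):
        return out
    sig = out[out["p_adj"] < fdr]
    permutations = enumerate_donor_permutations(design)
    ss = np.random.SeedSequence([seed, 7])
    # control-cell heritability once per response gene among significant pairs
    control_p: dict[str, float] = {}
    genes = sorted(sig["gene"].unique())
    for gene, child in zip(genes, ss.spawn(len(genes))):
        try:
            rec = control_heritability(
                adata, gene, control_cells, design, permutations,
                early_stop, cap, seed=int(child.generate_state(1)[0] % 2**31),
            )
            control_p[gene] = rec["p_emp"]
        except ValueError as err:
            logger.warning("control heritability for %s failed: %s", gene, err)
    control_p_adj = (
        dict(zip(genes, bh_adjust([control_p[g] for g in genes])))
        if all(g in control_p for g in genes)
        else {g: np.nan for g in genes}
    )

    split = line_lfcs["unit"].astype(str).str.split("|", n=1, expand=True)
    lfc_tab = line_lfcs.assign(_target=split[0], _line=split[1])
    l2d = dict(design.line_to_donor)

    postkd_raw = []
    for _, row in sig.iterrows():
        cells = target_of_cell.index[target_of_cell == row["target"]]
        obs = adata.obs.loc[cells]
        y = adata[list(cells), [row["gene"]]].layers["lognorm"]
        y = np.asarray(y.todense()).ravel() if hasattr(y, "todense") else np.asarray(y).ravel()
        spec = LmmSpec(
            y=y, fixed=None,
            guide=obs["assigned_guide"].to_numpy() if "assigned_guide" in obs else None,
            line=obs["cell_line"].to_numpy(), donor=obs["donor"].to_numpy(),
        )
        try:
            lrt = lrt_donor(spec)
            S, P, p = permutation_pvalue(lrt, spec, permutations, early_stop, cap, seed=seed)
            postkd_raw.append(p)
        except ValueError:
            postkd_raw.append(np.nan)
    postkd_ok = [p for p in postkd_raw if np.isfinite(p)]
    adj_iter = iter(bh_adjust(postkd_ok)) if postkd_ok else iter([])
    postkd_adj = [next(adj_iter) if np.isfinite(p) else np.nan for p in postkd_raw]

    for (idx, row), post_p in zip(sig.iterrows(), postkd_adj):
        per_line = lfc_tab[
            (lfc_tab["_target"] == row["target"]) & (lfc_tab["gene"] == row["gene"])
        ]
        lfcs = dict(zip(per_line["_line"], per_line["lfc"]))
        cp_adj = control_p_adj.get(row["gene"], np.nan)
        cp_raw = control_p.get(row["gene"], np.nan)
        cls, direction, carrier = classify_heritability(
            row["p_adj"],
            None if not np.isfinite(cp_adj) else cp_adj,
            None if not np.isfinite(cp_raw) else cp_raw,
            None if not np.isfinite(post_p) else post_p,
            lfcs,
            l2d,
            fdr=fdr,
        )
        out.loc[idx, ["class", "direction", "carrier_donor"]] = [
            cls, direction, carrier or "",
        ]
    return out


def heritability_scan(
    profiles: pd.DataFrame,
    obs: pd.DataFrame,
    target_expression: pd.DataFrame,
    candidates: list[tuple[str, str]],
    design: DonorDesign,
    target_of_cell: pd.Series,
    early_stop: int = EARLY_STOP,
    cap: int = PERMUTATION_CAP,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the donor LRT + permutation test for every candidate pair.

    ``profiles``: per-cell effect matrix (assigned cells x expressed genes);
    ``obs``: metadata with guide/cell_line/donor for those cells;
    ``target_expression``: log-normalized expression, cells x target genes
    (column per target; the fixed efficacy covariate);
    ``target_of_cell``: the assigned target per cell.
    Returns one record per pair with lrt, S, P, p_emp and BH-adjusted p.
    """
    permutations = enumerate_donor_permutations(design)
    ss = np.random.SeedSequence(seed)
    records = []
    for (target, gene), child in zip(candidates, ss.spawn(len(candidates))):
        cells = target_of_cell.index[target_of_cell == target]
        cells = cells.intersection(profiles.index)
        if len(cells) == 0:
            continue
        sub = obs.loc[cells]
        fixed = None
        if target in target_expression.columns:
            fixed = target_expression.loc[cells, target].to_numpy()
        else:
            logger.info("target %s not expressed: efficacy covariate dropped", target)
        spec = LmmSpec(
            y=profiles.loc[cells, gene].to_numpy(),
            fixed=fixed,
            guide=sub["guide"].to_numpy() if "guide" in sub else sub["assigned_guide"].to_numpy(),
            line=sub["cell_line"].to_numpy(),
            donor=sub["donor"].to_numpy(),
        )
        try:
            lrt = lrt_donor(spec)
            pair_seed = int(child.generate_state(1)[0] % (2**31))
            S, P, p_emp = permutation_pvalue(
                lrt, spec, permutations, early_stop, cap, seed=pair_seed
            )
        except ValueError as err:
            logger.warning("pair (%s, %s) skipped: %s", target, gene, err)
            continue
        records.append((target, gene, lrt, S, P, p_emp))
    out = pd.DataFrame(records, columns=["target", "gene", "lrt", "S", "P", "p_emp"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p_emp"].to_numpy())
    else:
        out["p_adj"] = []
    return out
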