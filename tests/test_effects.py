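"""Control model, per-cell effects, aggregation, BH and cis effects."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from perturbmap.effects import (
    ControlFit,
    aggregate_effects,
    bh_adjust,
    estimate_cis_effect,
    fit_control_model,
    per_cell_effects,
    percent,
)
from perturbmap.effects import test_universe_size as universe_size


def _noiseless_adata(lines=("A", "B"), cells_per_line=10, offsets=(0.5, -0.5)):
    """Expression = 1 + line offset exactly; all other covariates constant."""
    n = cells_per_line * len(lines)
    cell_line = np.repeat(lines, cells_per_line)
    vals = 1.0 + np.repeat(offsets, cells_per_line)
    L = np.column_stack([vals, np.full(n, 2.0)])  # gene0 varies, gene1 constant
    obs = pd.DataFrame(
        {
            "cell_line": cell_line,
            "inlet": "i0",
            "mito_fraction": 0.05,
            "s_score": 0.0,
            "g2m_score": 0.0,
            "total_umis": 1000.0,
            "donor": np.repeat(["d0", "d1"], cells_per_line),
        },
        index=[f"c{i}" for i in range(n)],
    )
    adata = ad.AnnData(
        X=np.exp(L), obs=obs, var=pd.DataFrame(index=["gene0", "gene1"])
    )
    adata.layers["lognorm"] = L
    return adata


class TestControlFit:
    def test_line_offsets_recovered_exactly(self):
        """Closed-form least squares on noiseless data: the line contrast
        equals the injected offset difference and residual SD is zero."""
        adata = _noiseless_adata()
        fit = fit_control_model(adata, list(adata.obs_names))
        coef = dict(zip(fit.design_columns, fit.coef[:, 0]))
        assert coef["intercept"] == pytest.approx(1.5, abs=1e-10)  # reference line A
        assert coef["cell_line[B]"] == pytest.approx(-1.0, abs=1e-10)
        assert fit.residual_sd[0] == pytest.approx(0.0, abs=1e-9)

    def test_constant_gene_flat_fit(self):
        adata = _noiseless_adata()
        fit = fit_control_model(adata, list(adata.obs_names))
        coef = dict(zip(fit.design_columns, fit.coef[:, 1]))
        assert coef["intercept"] == pytest.approx(2.0, abs=1e-10)
        assert coef["cell_line[B]"] == pytest.approx(0.0, abs=1e-10)
        assert fit.residual_sd[1] == pytest.approx(0.0, abs=1e-9)

    def test_cell_order_invariance(self):
        adata = _noiseless_adata()
        rng = np.random.default_rng(0)
        L = adata.layers["lognorm"]
        L = L + rng.normal(0, 0.1, size=L.shape)
        adata.layers["lognorm"] = L
        cells = list(adata.obs_names)
        f1 = fit_control_model(adata, cells)
        f2 = fit_control_model(adata, list(reversed(cells)))
        assert np.allclose(f1.coef, f2.coef)
        assert np.allclose(f1.residual_sd, f2.residual_sd)

    def test_empty_control_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_control_model(_noiseless_adata(), [])


class TestPerCellEffects:
    def test_effect_is_observed_minus_predicted(self):
        adata = _noiseless_adata()
        fit = fit_control_model(adata, list(adata.obs_names))
        # perturb one cell's observed value downward by 0.42
        adata.layers["lognorm"][0, 0] -= 0.42
        eff = per_cell_effects(adata, ["c0", "c1"], fit)
        assert eff.loc["c0", "gene0"] == pytest.approx(-0.42, abs=1e-9)
        assert eff.loc["c1", "gene0"] == pytest.approx(0.0, abs=1e-9)

    def test_control_cells_yield_their_residuals(self):
        adata = _noiseless_adata()
        rng = np.random.default_rng(1)
        adata.layers["lognorm"] = adata.layers["lognorm"] + rng.normal(
            0, 0.2, size=adata.layers["lognorm"].shape
        )
        cells = list(adata.obs_names)
        fit = fit_control_model(adata, cells)
        eff = per_cell_effects(adata, cells, fit)
        assert abs(eff["gene0"].mean()) < 1e-9  # residuals average zero


class TestAggregateEffects:
    def _profiles(self, n=25, mean=-0.42, genes=("gX",)):
        eff = pd.DataFrame(
            np.full((n, len(genes)), mean), index=[f"c{i}" for i in range(n)], columns=genes
        )
        fit = ControlFit(
            genes=list(genes), design_columns=["intercept"], reference_levels={},
            coef=np.zeros((1, len(genes))), residual_sd=np.ones(len(genes)),
            n_control_cells=100, rank=1,
        )
        return eff, fit

    def test_z_and_p_arithmetic(self):
        """n=25 cells, mean effect -0.42, residual SD 1: SE 0.2, z=-2.1,
        p = 2 Phi(-2.1) ~ 0.0357."""
        eff, fit = self._profiles()
        groups = pd.Series("t1", index=eff.index)
        tab = aggregate_effects(eff, groups, fit, "target", min_cells=10)
        row = tab.iloc[0]
        assert row.se == pytest.approx(0.2)
        assert row.z == pytest.approx(-2.1)
        assert row.p == pytest.approx(2 * norm.cdf(-2.1), rel=1e-9)
        assert row.p == pytest.approx(0.0357, abs=2e-4)

    def test_small_guide_groups_omitted(self):
        eff, fit = self._profiles(n=9)
        groups = pd.Series(["gA"] * 4 + ["gB"] * 5, index=eff.index)
        tab = aggregate_effects(eff, groups, fit, "guide", min_cells=5)
        assert set(tab.unit) == {"gB"}  # 4-cell guide dropped (minimum 5)

    def test_zero_effect_gives_p_one(self):
        eff, fit = self._profiles(mean=0.0)
        tab = aggregate_effects(eff, pd.Series("t", index=eff.index), fit, "target")
        assert tab.iloc[0].z == 0.0
        assert tab.iloc[0].p == 1.0

    def test_empty_grouping_returns_empty_table(self):
        eff, fit = self._profiles(n=3)
        tab = aggregate_effects(eff, pd.Series("t", index=eff.index), fit, "target", min_cells=10)
        assert len(tab) == 0

    def test_target_lfc_is_weighted_mean_of_guides(self, effect_tables):
        """Conservation: a target's LFC equals the cell-count-weighted mean
        of its guides' LFCs (same cells, same code path)."""
        guides = effect_tables["guide"]
        targets = effect_tables["target"]
        gene = targets.gene.iloc[0]
        for t in targets.unit.unique():
            g = guides[(guides.unit.str.startswith(t + "_")) & (guides.gene == gene)]
            trow = targets[(targets.unit == t) & (targets.gene == gene)]
            if len(g) == 0 or len(trow) == 0:
                continue
            if g.n_cells.sum() != trow.n_cells.iloc[0]:
                continue  # some guides fell below the guide-level minimum
            weighted = np.average(g.lfc, weights=g.n_cells)
            assert weighted == pytest.approx(trow.lfc.iloc[0], abs=1e-9)


def _bh_oracle(p):
    """Brute-force step-up: p_(i) * m / i with running minimum from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_worked_example(self):
        adj = bh_adjust([0.01, 0.02, 0.04, 0.8])
        assert np.allclose(adj, [0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_single_and_tied_pvalues(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=60)
    )
    def test_matches_bruteforce_oracle(self, pvals):
        assert np.allclose(bh_adjust(pvals), _bh_oracle(pvals), atol=1e-12)


class TestCisEffect:
    def _dosage_adata(self, beta=0.3, noise=0.0, dosages=(0, 1, 2), seed=0):
        rng = np.random.default_rng(seed)
        per = 40
        donors = np.repeat([f"d{k}" for k in range(len(dosages))], per)
        dose = np.repeat(dosages, per)
        n = len(donors)
        vals = 1.0 + beta * dose + rng.normal(0, noise, size=n)
        obs = pd.DataFrame(
            {
                "donor": donors, "inlet": "i0", "mito_fraction": 0.05,
                "s_score": 0.0, "g2m_score": 0.0, "total_umis": 1000.0,
                "cell_line": donors,
            },
            index=[f"c{i}" for i in range(n)],
        )
        adata = ad.AnnData(X=np.exp(vals)[:, None], obs=obs, var=pd.DataFrame(index=["geneC"]))
        adata.layers["lognorm"] = vals[:, None]
        return adata

    def test_additive_effect_recovered_exactly(self):
        adata = self._dosage_adata()
        est = estimate_cis_effect(adata, list(adata.obs_names), "geneC", {"d0": 0, "d1": 1, "d2": 2})
        assert est == pytest.approx(0.3, abs=1e-10)

    def test_null_dosage_effect_near_zero(self):
        adata = self._dosage_adata(beta=0.0, noise=0.5, seed=1)
        est = estimate_cis_effect(adata, list(adata.obs_names), "geneC", {"d0": 0, "d1": 1, "d2": 2})
        assert abs(est) < 0.2

    def test_monomorphic_dosage_rejected(self):
        adata = self._dosage_adata()
        with pytest.raises(ValueError, match="monomorphic"):
            estimate_cis_effect(adata, list(adata.obs_names), "geneC", {"d0": 1, "d1": 1, "d2": 1})


def test_bookkeeping_helpers():
    assert universe_size(3, 7) == 21
    assert percent(1, 8) == 12.5
    with pytest.raises(ValueError):
        percent(1, 0)
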