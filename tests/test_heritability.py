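"""Donor LRT, constrained permutations, classification, variance shares."""

import itertools

import numpy as np
import pandas as pd
import pytest

from perturbmap.heritability import (
    LmmSpec,
    admissible_pairing_count,
    candidate_pairs,
    classify_heritability,
    control_heritability,
    enumerate_donor_permutations,
    fit_lmm,
    lrt_donor,
    permutation_pvalue,
    variance_decomposition,
)
from perturbmap.simulate import generate_donor_design


def _spec(seed=0, donor_sd=0.0, line_sd=0.3, guide_sd=0.2, cells_per_line=30, n_donors=5):
    rng = np.random.default_rng(seed)
    design = generate_donor_design(n_donors)
    donors = design.donors
    u_d = dict(zip(donors, rng.normal(0, donor_sd, len(donors))))
    y, guide, line, donor_lab, x = [], [], [], [], []
    for l, d in sorted(design.line_to_donor.items()):
        u_l = rng.normal(0, line_sd)
        for g in range(3):
            u_g = rng.normal(0, guide_sd)
            for _ in range(cells_per_line // 3):
                xv = rng.normal()
                y.append(u_d[d] + u_l + u_g + 0.3 * xv + rng.normal())
                guide.append(f"g{g}")
                line.append(l)
                donor_lab.append(d)
                x.append(xv)
    return design, LmmSpec(
        y=np.array(y), fixed=np.array(x), guide=np.array(guide),
        line=np.array(line), donor=np.array(donor_lab),
    )


def _bruteforce_count(n):
    """Exhaustive oracle: pairings of 2n items avoiding the n natural pairs."""
    items = list(range(2 * n))
    forbidden = {(2 * k, 2 * k + 1) for k in range(n)}

    def pairings(rest):
        if not rest:
            yield ()
            return
        a = rest[0]
        for i in range(1, len(rest)):
            b = rest[i]
            for tail in pairings(rest[1:i] + rest[i + 1 :]):
                yield ((a, b),) + tail

    return sum(
        1
        for p in pairings(items)
        if not any(pair in forbidden for pair in p)
    )


class TestPermutationEnumeration:
    def test_five_donor_design_has_544_relabelings(self):
        design = generate_donor_design(5)
        perms = enumerate_donor_permutations(design)
        assert len(perms) == 544
        assert len(set(perms)) == 544

    @pytest.mark.parametrize("n,expected", [(2, 2), (3, 8)])
    def test_small_designs_match_exhaustive_oracle(self, n, expected):
        design = generate_donor_design(n)
        perms = enumerate_donor_permutations(design)
        assert len(perms) == expected
        assert _bruteforce_count(n) == expected

    @pytest.mark.parametrize("n", range(2, 7))
    def test_closed_form_matches_enumeration(self, n):
        assert admissible_pairing_count(n) == len(
            enumerate_donor_permutations(generate_donor_design(n))
        )

    def test_no_relabeling_contains_an_original_pair(self):
        design = generate_donor_design(4)
        originals = set(design.donor_pairs())
        for perm in enumerate_donor_permutations(design):
            assert not (set(perm) & originals)
            flat = [l for pair in perm for l in pair]
            assert sorted(flat) == design.lines


class TestLrt:
    def test_null_donor_variance_gives_small_lrt(self):
        _, spec = _spec(seed=1, donor_sd=0.0)
        assert lrt_donor(spec) < 2.0

    def test_planted_donor_effect_detected_across_seeds(self):
        """gamma_sd = 0.5 with ~100 cells/line: LRT > 0 in >= 95% of seeds
        (scaled to 20 seeds)."""
        positive = 0
        for seed in range(20):
            _, spec = _spec(seed=seed, donor_sd=0.5, cells_per_line=99)
            if lrt_donor(spec) > 0:
                positive += 1
        assert positive >= 19

    def test_constant_response_rejected(self):
        design, spec = _spec()
        spec.y = np.zeros_like(spec.y)
        with pytest.raises(ValueError, match="degenerate"):
            lrt_donor(spec)

    def test_inconsistent_nesting_rejected(self):
        _, spec = _spec()
        spec.donor = spec.donor.copy()
        spec.donor[0] = "other"
        with pytest.raises(ValueError, match="nest"):
            fit_lmm(spec)


class TestPermutationPvalue:
    def test_pvalue_formula_direct_arithmetic(self):
        """p_emp = max(10, S+1)/(min(P, 1e4)+1) at the printed examples."""
        assert max(10, 0 + 1) / (min(544, 10**4) + 1) == pytest.approx(10 / 545)
        assert max(10, 42 + 1) / (min(544, 10**4) + 1) == pytest.approx(43 / 545)

    def test_observed_zero_early_stops_at_ten(self):
        design, spec = _spec(seed=2, donor_sd=0.4, cells_per_line=30)
        perms = enumerate_donor_permutations(design)
        S, P, p = permutation_pvalue(0.0, spec, perms, seed=3)
        assert S == 10  # every null LRT >= 0
        assert p == pytest.approx(11 / (P + 1))

    def test_floor_property_and_determinism(self):
        design, spec = _spec(seed=4, donor_sd=0.8, cells_per_line=30)
        perms = enumerate_donor_permutations(design)
        obs = lrt_donor(spec)
        r1 = permutation_pvalue(obs, spec, perms, seed=5)
        r2 = permutation_pvalue(obs, spec, perms, seed=5)
        assert r1 == r2
        S, P, p = r1
        assert p >= 10 / (min(P, 10**4) + 1)
        assert p <= 1.0

    def test_strong_effect_exhausts_permutations_with_low_p(self):
        design, spec = _spec(seed=6, donor_sd=1.5, cells_per_line=60)
        perms = enumerate_donor_permutations(design)
        obs = lrt_donor(spec)
        S, P, p = permutation_pvalue(obs, spec, perms, seed=7)
        assert P == 544
        assert p == pytest.approx(10 / 545)


class TestControlHeritability:
    def _control_adata(self, offset_sd=0.0, seed=0, cells_per_line=40):
        import anndata as ad

        rng = np.random.default_rng(seed)
        design = generate_donor_design(5)
        offs = {d: rng.normal(0, offset_sd) for d in design.donors}
        rows, lines, donors = [], [], []
        for l, d in sorted(design.line_to_donor.items()):
            for _ in range(cells_per_line):
                rows.append(1.0 + offs[d] + rng.normal(0, 0.5))
                lines.append(l)
                donors.append(d)
        obs = pd.DataFrame(
            {"cell_line": lines, "donor": donors},
            index=[f"c{i}" for i in range(len(rows))],
        )
        adata = ad.AnnData(X=np.exp(np.array(rows))[:, None], obs=obs,
                           var=pd.DataFrame(index=["geneH"]))
        adata.layers["lognorm"] = np.array(rows)[:, None]
        return adata, design

    def test_planted_donor_offsets_detected(self):
        """Donor baseline offsets of SD 0.5 against noise SD 0.5 give a small
        empirical p in nearly all seeds (scaled-down Monte-Carlo)."""
        hits = 0
        for seed in range(4):
            adata, design = self._control_adata(offset_sd=0.5, seed=seed)
            rec = control_heritability(adata, "geneH", list(adata.obs_names), design, seed=seed)
            hits += rec["p_emp"] <= 0.05
        assert hits >= 3

    def test_single_donor_rejected(self):
        adata, design = self._control_adata()
        keep = adata.obs["donor"] == "donor0"
        with pytest.raises(ValueError, match="donor"):
            control_heritability(adata[keep], "geneH", list(adata.obs_names[keep]), design)


class TestCandidatesAndClassification:
    def _line_table(self):
        return pd.DataFrame(
            {
                "level": "target_by_line",
                "unit": ["tA|l1", "tA|l2", "tB|l1", "tC|l1"],
                "gene": ["gX", "gX", "gX", "gY"],
                "lfc": [0.2, 0.01, 0.05, -0.3],
                "p_adj": [0.05, 0.9, 0.05, 0.01],
            }
        )

    def test_candidate_rules(self):
        pairs = candidate_pairs(self._line_table())
        assert ("tA", "gX") in pairs      # significant and |LFC| > 0.1 in line 1
        assert ("tB", "gX") not in pairs  # |LFC| too small everywhere
        assert ("tC", "gY") in pairs

    def test_offtarget_flagged_pairs_excluded(self):
        pairs = candidate_pairs(self._line_table(), offtarget_pairs={("tC", "gY")})
        assert ("tC", "gY") not in pairs

    def test_classification_rules(self):
        l2d = {"l1": "d1", "l2": "d1", "l3": "d2", "l4": "d2"}
        down = {"l1": -0.3, "l2": -0.2, "l3": -0.4, "l4": -0.1}
        cls, direction, carrier = classify_heritability(0.05, 0.05, 0.5, 0.5, down, l2d)
        assert (cls, direction) == ("loss", "down")
        one_up = {"l1": 0.4, "l2": 0.5, "l3": -0.1, "l4": -0.2}
        cls, direction, carrier = classify_heritability(0.05, 0.95, 0.95, 0.02, one_up, l2d)
        assert (cls, direction, carrier) == ("gain", "up", "d1")
        cls, _, _ = classify_heritability(0.05, 0.5, 0.5, 0.5, down, l2d)
        assert cls == "unclassified"
        cls, _, _ = classify_heritability(0.5, 0.05, 0.5, 0.5, down, l2d)
        assert cls == "unclassified"  # donor component not significant


class TestVarianceDecomposition:
    def test_fractions_sum_to_one_and_null_is_residual(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=600)
        factors = {
            "donor": np.repeat(np.arange(6), 100),
            "line": np.repeat(np.arange(12), 50),
        }
        fracs = variance_decomposition(y, factors)
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-6)
        assert fracs["residual"] >= 0.95

    def test_planted_components_recovered(self):
        """Balanced design with donor/line/guide variances 0.3/0.2/0.1 of
        total: mean recovered fractions within 0.1 (20 seeds, scaled)."""
        got = {"donor": [], "line": [], "guide": [], "residual": []}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_d, n_l, n_g, reps = 8, 16, 24, 25
            donor = np.repeat(np.arange(n_d), n_l // n_d * n_g // (n_g // n_l) * reps // reps)
            # simple balanced layout: each donor -> 2 lines -> 3 guides x reps
            donor, line, guide, y = [], [], [], []
            for d in range(n_d):
                ud = rng.normal(0, np.sqrt(0.3))
                for li in range(2):
                    ul = rng.normal(0, np.sqrt(0.2))
                    for g in range(3):
                        ug = rng.normal(0, np.sqrt(0.1))
                        for _ in range(15):
                            y.append(ud + ul + ug + rng.normal(0, np.sqrt(0.4)))
                            donor.append(d)
                            line.append(f"{d}_{li}")
                            guide.append(f"{d}_{li}_{g}")
            fr = variance_decomposition(
                np.array(y),
                {"guide": np.array(guide), "line": np.array(line), "donor": np.array(donor)},
            )
            for k in got:
                got[k].append(fr[k])
        assert np.mean(got["donor"]) == pytest.approx(0.3, abs=0.1)
        assert np.mean(got["line"]) == pytest.approx(0.2, abs=0.1)
        assert np.mean(got["guide"]) == pytest.approx(0.1, abs=0.1)
        assert np.mean(got["residual"]) == pytest.approx(0.4, abs=0.1)
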