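"""Pruning likelihood, ML fitting, and ancestral marginals."""

import math

import numpy as np
import pytest

from decgeo import (DatedTree, DecParams, EpochGeography, OptimizerConfig,
                    StratifiedScenario, ancestral_marginals,
                    build_state_space, fit_model, model_spec, tree_likelihood)
from decgeo.errors import DataError
from tests.conftest import brute_force_lnl, random_dated_tree


def tips_for(space, assignment):
    return {lab: space.range_from_names(names) for lab, names in assignment.items()}


class TestTreeLikelihood:
    def test_single_tip_zero_branch_uniform_prior(self, space3, scen3):
        tree = DatedTree.single_tip("a", 0.0)
        tips = tips_for(space3, {"a": ["A"]})
        lnl = tree_likelihood(tree, tips, scen3, space3, DecParams(0.1, 0.1))
        assert lnl == pytest.approx(-math.log(space3.n_nonnull), abs=1e-12)

    def test_cherry_matches_exhaustive_enumeration(self, space2, geo2):
        scen = StratifiedScenario.single(geo2)
        tree = DatedTree.from_newick("(a:1.5,b:1.5);")
        tips = tips_for(space2, {"a": ["A"], "b": ["B"]})
        p = DecParams(0.05, 0.03, j=0.4)
        lnl = tree_likelihood(tree, tips, scen, space2, p)
        assert lnl == pytest.approx(brute_force_lnl(tree, tips, scen, space2, p),
                                    abs=1e-10)

    def test_pruning_equals_brute_force_on_random_instances(self):
        """Property: pruning equals joint enumeration (<=4 tips, <=3 areas)."""
        rng = np.random.default_rng(2024)
        for trial in range(25):
            n_tips = int(rng.integers(2, 5))
            n_areas = int(rng.integers(2, 4))
            space = build_state_space([chr(65 + i) for i in range(n_areas)],
                                      n_areas)
            geo = EpochGeography.uniform(n_areas,
                                         distance=float(rng.uniform(1, 500)))
            scen = StratifiedScenario.single(geo)
            tree = random_dated_tree(rng, n_tips)
            tips = {
                lab: space.states[1 + rng.integers(space.n_nonnull)]
                for lab in tree.labels
            }
            p = DecParams(
                d=float(rng.uniform(0.01, 0.5)),
                e=float(rng.uniform(0.0, 0.3)),
                j=float(rng.uniform(0.0, 1.0)),
                x=float(rng.uniform(-2.0, 0.0)),
            )
            lnl = tree_likelihood(tree, tips, scen, space, p)
            oracle = brute_force_lnl(tree, tips, scen, space, p)
            assert lnl == pytest.approx(oracle, abs=1e-10), f"trial {trial}"

    def test_stratified_pruning_matches_brute_force(self):
        old = EpochGeography(math.inf, 2.0,
                             np.array([[0.0, 120.0], [120.0, 0.0]]),
                             np.ones((2, 2)), np.array([True, False]))
        young = EpochGeography.uniform(2, start_age=2.0, distance=120.0)
        scen = StratifiedScenario((old, young))
        space = build_state_space(["A", "B"], 2)
        tree = DatedTree.from_newick("((a:1,b:1):2,c:3);")
        tips = tips_for(space, {"a": ["A"], "b": ["B"], "c": ["A"]})
        p = DecParams(0.2, 0.05, j=0.3, x=-0.5)
        lnl = tree_likelihood(tree, tips, scen, space, p)
        assert lnl == pytest.approx(brute_force_lnl(tree, tips, scen, space, p),
                                    abs=1e-10)

    def test_tip_order_permutation_invariance(self, space2, geo2):
        scen = StratifiedScenario.single(geo2)
        p = DecParams(0.1, 0.05, j=0.2)
        t1 = DatedTree.from_newick("((a:1,b:1):1,c:2);")
        t2 = DatedTree.from_newick("(c:2,(b:1,a:1):1);")
        tips = tips_for(space2, {"a": ["A"], "b": ["B"], "c": ["A"]})
        assert tree_likelihood(t1, tips, scen, space2, p) == pytest.approx(
            tree_likelihood(t2, tips, scen, space2, p), abs=1e-12
        )

    def test_newick_roundtrip_preserves_likelihood(self, space2, geo2):
        scen = StratifiedScenario.single(geo2)
        p = DecParams(0.1, 0.05)
        tree = DatedTree.from_newick("((a:1,b:1):1.5,c:2.5);")
        again = DatedTree.from_newick(tree.to_newick())
        tips = tips_for(space2, {"a": ["A"], "b": ["B"], "c": ["B"]})
        assert tree_likelihood(tree, tips, scen, space2, p) == pytest.approx(
            tree_likelihood(again, tips, scen, space2, p), abs=1e-12
        )

    def test_missing_tip_range_is_data_error(self, space2, geo2):
        scen = StratifiedScenario.single(geo2)
        tree = DatedTree.from_newick("(a:1,b:1);")
        with pytest.raises(DataError, match="absent"):
            tree_likelihood(tree, tips_for(space2, {"a": ["A"]}), scen,
                            space2, DecParams(0.1, 0.1))

    def test_tip_in_unavailable_area_is_data_error(self):
        geo = EpochGeography(math.inf, 0.0,
                             np.array([[0.0, 50.0], [50.0, 0.0]]),
                             np.ones((2, 2)), np.array([True, False]))
        scen = StratifiedScenario.single(geo)
        space = build_state_space(["A", "B"], 2)
        tree = DatedTree.from_newick("(a:1,b:1);")
        tips = tips_for(space, {"a": ["A"], "b": ["B"]})
        with pytest.raises(DataError, match="unavailable"):
            tree_likelihood(tree, tips, scen, space, DecParams(0.1, 0.1))


class TestModelStructure:
    @pytest.fixture
    def dataset(self, space3, scen3):
        tree = DatedTree.from_newick("(((a:1,b:1):1,c:2):1,d:3);")
        tips = tips_for(space3, {"a": ["A"], "b": ["B"], "c": ["A"], "d": ["C"]})
        return tree, tips

    def test_plus_j_at_zero_matches_dec_exactly(self, dataset, space3, scen3):
        tree, tips = dataset
        base = DecParams(0.07, 0.02)
        with_j = DecParams(0.07, 0.02, j=0.0)
        l1 = tree_likelihood(tree, tips, scen3, space3, base)
        l2 = tree_likelihood(tree, tips, scen3, space3, with_j)
        assert l1 == pytest.approx(l2, abs=1e-12)

    def test_zero_exponent_ignores_distance_matrix(self, dataset, space3):
        tree, tips = dataset
        p = DecParams(0.07, 0.02, j=0.3, x=0.0)
        out = []
        for dist in (1.0, 9999.0):
            scen = StratifiedScenario.single(
                EpochGeography.uniform(3, distance=dist)
            )
            out.append(tree_likelihood(tree, tips, scen, space3, p))
        assert out[0] == pytest.approx(out[1], abs=1e-12)

    def test_distance_rescaling_invariance(self, dataset, space3):
        tree, tips = dataset
        x = -1.4
        c = 37.0
        d0 = 0.05
        dist = np.array([[0.0, 120.0, 260.0], [120.0, 0.0, 140.0],
                         [260.0, 140.0, 0.0]])
        lnls = []
        for scale, d in ((1.0, d0), (c, d0 * c ** (-x))):
            geo = EpochGeography(math.inf, 0.0, dist * scale,
                                 np.ones((3, 3)), np.ones(3, dtype=bool))
            scen = StratifiedScenario.single(geo)
            lnls.append(tree_likelihood(tree, tips, scen, space3,
                                        DecParams(d, 0.02, j=0.3, x=x)))
        assert lnls[0] == pytest.approx(lnls[1], abs=1e-9)

    def test_identical_epochs_match_unstratified(self, dataset, space3, geo3):
        tree, tips = dataset
        p = DecParams(0.07, 0.02, j=0.3, x=-1.0)
        single = StratifiedScenario.single(geo3)
        geo_old = EpochGeography(math.inf, 1.5, geo3.distance_km,
                                 geo3.multiplier, geo3.allowed)
        geo_young = EpochGeography(1.5, 0.0, geo3.distance_km,
                                   geo3.multiplier, geo3.allowed)
        split = StratifiedScenario((geo_old, geo_young))
        assert tree_likelihood(tree, tips, single, space3, p) == pytest.approx(
            tree_likelihood(tree, tips, split, space3, p), abs=1e-10
        )


class TestFitModel:
    def test_no_extinction_signal_drives_e_to_bound(self, space2, geo2):
        scen = StratifiedScenario.single(geo2)
        # star-like tree, every tip in the same single area: no contraction signal
        tree = DatedTree.from_newick("((a:0.1,b:0.1):2.9,(c:0.1,d:0.1):2.9);")
        tips = tips_for(space2, {k: ["A"] for k in "abcd"})
        res = fit_model(tree, tips, scen, space2, model_spec("DEC"))
        assert res.params.e < 1e-6
        assert res.converged

    def test_nesting_dec_plus_j_never_worse(self, space3, scen3):
        tree = DatedTree.from_newick("(((a:1,b:1):1,c:2):1,d:3);")
        tips = tips_for(space3, {"a": ["A"], "b": ["B"], "c": ["C"], "d": ["A"]})
        dec = fit_model(tree, tips, scen3, space3, model_spec("DEC"))
        decj = fit_model(tree, tips, scen3, space3, model_spec("DEC+J"))
        decjx = fit_model(tree, tips, scen3, space3, model_spec("DEC+J+x"))
        assert decj.lnl >= dec.lnl - 1e-6
        assert decjx.lnl >= decj.lnl - 1e-6

    def test_fit_is_deterministic(self, space2, geo2):
        scen = StratifiedScenario.single(geo2)
        tree = DatedTree.from_newick("((a:1,b:1):1,c:2);")
        tips = tips_for(space2, {"a": ["A"], "b": ["B"], "c": ["B"]})
        r1 = fit_model(tree, tips, scen, space2, model_spec("DEC+J"))
        r2 = fit_model(tree, tips, scen, space2, model_spec("DEC+J"))
        assert r1.lnl == r2.lnl
        assert r1.estimates() == r2.estimates()

    def test_optimizer_start_grid_covers_spec(self):
        cfg = OptimizerConfig(full_grid=True)
        starts = cfg.starts(model_spec("DEC+J+x"))
        assert len(starts) == 12
        assert len(OptimizerConfig().starts(model_spec("DEC"))) == 3


class TestAncestralMarginals:
    def test_single_tip_marginal_is_observed_state(self, space3, scen3):
        tree = DatedTree.single_tip("a", 0.0)
        tips = tips_for(space3, {"a": ["B"]})
        m = ancestral_marginals(tree, tips, scen3, space3, DecParams(0.1, 0.1))
        idx = space3.index(space3.range_from_names(["B"])) - 1  # non-null offset
        assert m[0, idx] == pytest.approx(1.0)

    def test_concordant_cherry_concentrates_root_mass(self, space2, geo2):
        scen = StratifiedScenario.single(geo2)
        tree = DatedTree.from_newick("(a:1,b:1);")
        tips = tips_for(space2, {"a": ["A"], "b": ["A"]})
        m = ancestral_marginals(tree, tips, scen, space2,
                                DecParams(0.001, 0.001))
        iA = space2.index(space2.range_from_names(["A"])) - 1
        assert m[-1, iA] > 0.99

    def test_rows_sum_to_one(self, space3, scen3):
        tree = DatedTree.from_newick("(((a:1,b:1):1,c:2):1,d:3);")
        tips = tips_for(space3, {"a": ["A"], "b": ["B"], "c": ["C"], "d": ["A"]})
        m = ancestral_marginals(tree, tips, scen3, space3,
                                DecParams(0.2, 0.05, j=0.4, x=-0.5))
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-9)

    def test_marginals_match_brute_force_posterior(self, space2, geo2):
        """Root marginal equals the enumeration posterior on a cherry."""
        scen = StratifiedScenario.single(geo2)
        tree = DatedTree.from_newick("(a:1,b:1);")
        tips = tips_for(space2, {"a": ["A"], "b": ["B"]})
        p = DecParams(0.1, 0.05, j=0.3)
        m = ancestral_marginals(tree, tips, scen, space2, p)
        post = _enumeration_root_posterior(tree, tips, scen, space2, p)
        np.testing.assert_allclose(m[-1], post, atol=1e-10)


    def test_node_override_pins_marginal(self, space3, scen3):
        from decgeo import apply_node_overrides

        tree = DatedTree.from_newick("((a:1,b:1):1,c:2);")
        tips = tips_for(space3, {"a": ["A"], "b": ["B"], "c": ["C"]})
        m = ancestral_marginals(tree, tips, scen3, space3,
                                DecParams(0.1, 0.05, j=0.3))
        pinned = apply_node_overrides(m, tree, space3, {tree.root: ["A", "C"]})
        idx = space3.index(space3.range_from_names(["A", "C"])) - 1
        assert pinned[-1, idx] == 1.0 and pinned[-1].sum() == 1.0
        # other nodes untouched
        np.testing.assert_array_equal(pinned[0], m[0])


def _enumeration_root_posterior(tree, tips, scen, space, params):
    from decgeo.dec import cladogenesis_table, build_Q, branch_transition

    geo = scen.epochs[0]
    Q = build_Q(space, params, geo)
    P = branch_transition(Q, 1.0)
    tbl = cladogenesis_table(space, params, geo)
    ia = space.index(tips["a"].bits)
    ib = space.index(tips["b"].bits)
    weights = np.zeros(space.n_states)
    for s in range(space.n_states):
        if space.states[s].is_null:
            continue
        for l, r, pr in tbl.outcomes_for(s):
            weights[s] += pr * P[l, ia] * P[r, ib]
    post = weights / weights.sum()
    return post[1:]
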