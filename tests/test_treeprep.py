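"""subs2coal: CF inversion, regression, prediction intervals, smoothing."""

import warnings

import dendropy
import numpy as np
import pytest

from hemicoal import (
    CFTree,
    cf_to_coalescent_length,
    coalescent_length_to_cf,
    fit_conversion,
    predict_tips,
    smooth,
    subs2coal,
)
from hemicoal.treeprep import ConversionError, _depths


def _cf(T):
    return 1 - (2 / 3) * np.exp(-T)


def _linear_cftree(a=0.3, b=150.0, xs=(0.002, 0.005, 0.008, 0.012, 0.02),
                   tips=(0.004, 0.01, 0.015, 0.006, 0.009, 0.011)):
    """Caterpillar tree whose internal branches satisfy T = a + b x exactly."""
    labels = [f"t{i}" for i in range(len(tips))]
    nwk = f"({labels[0]}:{tips[0]},{labels[1]}:{tips[1]})"
    for i, x in enumerate(xs):
        cf = _cf(a + b * x)
        nxt = labels[i + 2] if i + 2 < len(labels) else None
        if nxt is not None:
            nwk = f"({nwk}{cf:.15f}:{x},{nxt}:{tips[i + 2]})"
        else:
            nwk = f"({nwk}{cf:.15f}:{x},extra:{0.01})"
    return CFTree.from_newick(nwk + ";")


class TestCFInversion:
    def test_round_trip_exact(self):
        # complement form stays exact out to long branches; the plain CF
        # form is limited by the precision of 1 - cf near 1
        for T in np.linspace(0.0, 20.0, 101):
            comp = coalescent_length_to_cf(T, as_complement=True)
            assert cf_to_coalescent_length(complement=comp) == \
                pytest.approx(T, abs=1e-12)
        for T in np.linspace(0.0, 8.0, 81):
            assert cf_to_coalescent_length(coalescent_length_to_cf(T)) == \
                pytest.approx(T, abs=1e-12)

    def test_known_points(self):
        assert cf_to_coalescent_length(1 / 3) == pytest.approx(0.0, abs=1e-12)
        assert cf_to_coalescent_length(1 - 2 / (3 * np.e)) == pytest.approx(1.0)
        assert cf_to_coalescent_length(0.90) == pytest.approx(-np.log(0.15))

    def test_cf_at_or_above_one_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            val = cf_to_coalescent_length(1.0)
        assert np.isfinite(val)

    def test_percent_labels_normalized(self):
        tree = CFTree.from_newick(
            "(((a:0.01,b:0.01)75.5:0.02,c:0.03)80:0.01,d:0.05);")
        with pytest.warns(UserWarning, match="percentage"):
            xs, ys = tree.internal_points()
        assert len(xs) == 2


class TestRegression:
    def test_exact_linear_fixture_recovered_to_machine_precision(self):
        tree = _linear_cftree(a=0.3038, b=157.03)
        fit = fit_conversion(tree)
        assert fit.slope == pytest.approx(157.03, rel=1e-9)
        assert fit.intercept == pytest.approx(0.3038, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.n_points == 5

    def test_too_few_points_rejected(self):
        tree = CFTree.from_newick(
            f"(((a:0.01,b:0.01){_cf(1.0):.12f}:0.02,c:0.03):0.01,d:0.05);")
        with pytest.raises(ConversionError):
            fit_conversion(tree)

    def test_star_like_cf_excluded_with_warning(self):
        nwk = (f"((((a:0.01,b:0.01)0.30:0.02,c:0.02){_cf(0.5):.12f}:0.01,"
               f"d:0.03){_cf(1.2):.12f}:0.02,(e:0.01,f:0.02){_cf(2.0):.12f}:0.015);")
        tree = CFTree.from_newick(nwk)
        with pytest.warns(UserWarning, match="excluded"):
            xs, _ = tree.internal_points()
        assert len(xs) == 3

    def test_tip_prediction_and_extrapolation_warning(self):
        tree = _linear_cftree(a=0.1, b=100.0,
                              tips=(0.004, 0.01, 0.015, 0.006, 0.009, 0.05))
        fit = fit_conversion(tree)
        with pytest.warns(UserWarning, match="extrapolation"):
            tips = predict_tips(tree, fit)
        assert tips["t5"] == pytest.approx(0.1 + 100.0 * 0.05, rel=1e-6)

    def test_prediction_interval_covers_new_observations(self):
        # fixture regenerated from a known line with noise: the 95%
        # prediction interval should cover a fresh draw ~95% of the time
        rng = np.random.default_rng(2020)
        a, b, sigma = 0.3, 150.0, 0.15
        xs = np.linspace(0.002, 0.02, 8)
        xstar = 0.011
        cover = 0
        n_rep = 400
        import statsmodels.api as sm
        for _ in range(n_rep):
            y = a + b * xs + rng.normal(0, sigma, xs.size)
            res = sm.OLS(y, sm.add_constant(xs)).fit()
            fr = res.get_prediction(
                sm.add_constant(np.array([xstar]), has_constant="add")
            ).summary_frame(alpha=0.05)
            ynew = a + b * xstar + rng.normal(0, sigma)
            cover += int(fr["obs_ci_lower"][0] <= ynew <= fr["obs_ci_upper"][0])
        assert cover / n_rep >= 0.92

    def test_bounds_order(self):
        tree = _linear_cftree()
        fit = fit_conversion(tree)
        lo = predict_tips(tree, fit, bound="lower95")
        mid = predict_tips(tree, fit, bound="point")
        hi = predict_tips(tree, fit, bound="upper95")
        for k in mid:
            assert lo[k] <= mid[k] <= hi[k]


def _tip_depths(tree):
    d = _depths(tree)
    return {lf.taxon.label: d[lf] for lf in tree.leaf_node_iter()}


class TestSmoothing:
    def test_already_ultrametric_tree_unchanged(self):
        nwk = "((a:1,b:1):1,(c:1.5,d:1.5):0.5);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        for method in ("extend", "redistribute"):
            out = smooth(tree, method)
            depths = _tip_depths(out)
            assert set(np.round(list(depths.values()), 9)) == {2.0}
            if method == "extend":
                lengths = {lf.taxon.label: lf.edge.length
                           for lf in out.leaf_node_iter()}
                assert lengths["a"] == pytest.approx(1.0)

    def test_extend_arithmetic_on_three_taxon_example(self):
        tree = dendropy.Tree.get(data="((A:1,B:2):1,C:4);", schema="newick")
        out = smooth(tree, "extend")
        lengths = {lf.taxon.label: lf.edge.length for lf in out.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(3.0)
        assert lengths["B"] == pytest.approx(3.0)
        assert lengths["C"] == pytest.approx(4.0)
        internal = [nd.edge.length for nd in out.preorder_internal_node_iter()
                    if nd.parent_node is not None]
        assert internal == pytest.approx([1.0])

    @pytest.mark.parametrize("method", ["extend", "redistribute"])
    def test_random_trees_become_ultrametric(self, method, rng):
        for _ in range(20):
            n = rng.integers(4, 10)
            taxa = [f"s{i}" for i in range(n)]
            import random as pyrandom
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=int(n),
                rng=pyrandom.Random(int(rng.integers(1 << 30))))
            for t, lf in zip(taxa, tree.leaf_node_iter()):
                lf.edge.length = float(rng.uniform(0.1, 2.0))
            out = smooth(tree, method)
            depths = list(_tip_depths(out).values())
            assert max(depths) - min(depths) < 1e-9

    def test_extend_preserves_internal_branches_exactly(self, rng):
        import random as pyrandom
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=8,
            rng=pyrandom.Random(17))
        before = [nd.edge.length for nd in tree.preorder_internal_node_iter()
                  if nd.parent_node is not None]
        out = smooth(tree, "extend")
        after = [nd.edge.length for nd in out.preorder_internal_node_iter()
                 if nd.parent_node is not None]
        assert after == pytest.approx(before, abs=0.0)


class TestEndToEnd:
    def test_subs2coal_produces_ultrametric_coalescent_tree(self):
        tree = _linear_cftree(a=0.2, b=120.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, fit = subs2coal(tree, smoothing="extend")
        depths = list(_tip_depths(out).values())
        assert max(depths) - min(depths) < 1e-9
        assert fit.n_points == 5

    def test_outgroup_excluded_and_regrafted(self):
        tree = _linear_cftree(a=0.2, b=120.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, fit = subs2coal(tree, smoothing="extend",
                                 exclude_outgroup="extra")
        labs = {lf.taxon.label for lf in out.leaf_node_iter()}
        assert "extra" in labs
        depths = _tip_depths(out)
        assert max(depths.values()) - min(depths.values()) < 1e-9

    def test_estimated_tree_arm_is_conservative_for_hemiplasy(self):
        # emulation of the estimation pipeline: regenerate a CF tree from
        # the known 8-taxon fixture (with estimation noise inflating short
        # branches, the documented direction of error), convert back, and
        # compare conditional hemiplasy probabilities
        from hemicoal import SpeciesNetwork, TraitPattern, run
        from hemicoal.fixtures import eight_taxon_test_tree
        net, pattern = eight_taxon_test_tree()
        rate, n_trees = 0.05, 150_000
        true_summary, _ = run(net, pattern, rate, n_trees, seed=404)

        # build the synthetic "estimated" substitutions/site tree
        scale = 0.01  # subs per site per coalescent unit
        rng = np.random.default_rng(11)
        src = dendropy.Tree.get(data=net.to_newick(), schema="newick")
        for nd in src.preorder_node_iter():
            if nd.parent_node is None:
                continue
            T = nd.edge.length
            if not nd.is_leaf():
                # estimation error inflates short internal branches
                T_obs = T + float(rng.uniform(0.0, 0.15))
                nd.label = f"{_cf(T_obs):.12f}"
            nd.edge.length = T * scale * float(rng.uniform(1.0, 1.2))
        cftree = CFTree(src)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coal_tree, _ = subs2coal(cftree, smoothing="extend")
        est_net = SpeciesNetwork.from_newick(
            coal_tree.as_string(schema="newick", suppress_rooting=True))
        est_summary, _ = run(est_net, TraitPattern(pattern.derived_taxa,
                                                   est_net.taxa),
                             rate, n_trees, seed=405)
        assert est_summary.hemiplasy_only_fraction <= \
            true_summary.hemiplasy_only_fraction + 0.02
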