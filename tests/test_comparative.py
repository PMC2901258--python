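"""Independent contrasts and the regression battery.

Oracles: direct evaluation of the contrast formula, an independently
coded generalized-least-squares fit under the Brownian covariance of
the same tree, and hand-evaluated closed forms for the through-origin
regression.
"""

import numpy as np
import pandas as pd
import pytest

from divclock import (
    BackboneTree,
    DatedTree,
    pic_contrasts,
    regress_ols,
    regress_through_origin,
    run_regression_battery,
    simulate_bd_tree,
)
from divclock.comparative import DegeneratePredictorError
from divclock.simulate import brownian_trait
from divclock.trees import TreeValidationError


def backbone_from(newick: str, mode: str = "gradual") -> BackboneTree:
    return BackboneTree(DatedTree.from_string(newick).tree, mode=mode)


def gls_slope(backbone: BackboneTree, x: dict, y: dict, mode: str) -> float:
    """GLS slope of y on x under the Brownian covariance of the tree.

    Independent construction: C[i, j] is the shared root-to-MRCA path
    length of tips i and j (all-ones branch lengths in punctuational
    mode); beta = (X' C^-1 X)^-1 X' C^-1 y with an intercept column.
    """
    labels = backbone.tip_labels
    tree = backbone.tree
    pdm = {}
    # shared path length = depth of the MRCA under the working lengths
    lengths = backbone.working_branch_lengths()
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[node] = depth[node.parent_node] + lengths[node]
    leaf = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    import dendropy

    for i, a in enumerate(labels):
        for b in labels[i:]:
            mrca = dendropy.Tree.mrca(tree, taxa=[leaf[a].taxon, leaf[b].taxon])
            pdm[(a, b)] = pdm[(b, a)] = depth[mrca] if a != b else depth[leaf[a]]
    C = np.array([[pdm[(a, b)] for b in labels] for a in labels])
    Ci = np.linalg.inv(C)
    X = np.column_stack([np.ones(len(labels)), [x[a] for a in labels]])
    yv = np.array([y[a] for a in labels])
    beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ yv)
    return float(beta[1])


class TestContrasts:
    def test_two_tip_direct_formula(self):
        bb = backbone_from("(A:1,B:1);")
        cs = pic_contrasts(bb, {"A": 3.0, "B": 1.0})
        assert len(cs) == 1
        assert abs(cs.contrasts[0]) == pytest.approx(2 / np.sqrt(2))

    def test_constant_trait_all_zero(self):
        bb = backbone_from("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        cs = pic_contrasts(bb, {t: 4.2 for t in "ABCD"})
        assert np.all(cs.contrasts == 0.0)

    def test_k_minus_one_contrasts(self):
        bb = backbone_from("(((A:1,B:1):1,C:2):1,(D:2,E:2):1);")
        cs = pic_contrasts(bb, dict(zip("ABCDE", [1.0, 2.0, 0.5, 3.0, 1.5])))
        assert len(cs) == bb.n_tips - 1

    @pytest.mark.parametrize("mode", ["gradual", "punctuational"])
    def test_three_tip_slope_matches_gls(self, mode):
        # two contrasts only, so compare the through-origin slope formula
        # directly against the GLS construction
        bb = backbone_from("((A:1,B:1):1.5,C:2.5);", mode=mode)
        x = {"A": 0.2, "B": 1.1, "C": 0.7}
        y = {"A": 2.0, "B": 0.4, "C": 1.3}
        cx = pic_contrasts(bb, x, mode=mode).contrasts
        cy = pic_contrasts(bb, y, mode=mode).contrasts
        slope = np.sum(cx * cy) / np.sum(cx * cx)
        assert slope == pytest.approx(gls_slope(bb, x, y, mode), abs=1e-8)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("mode", ["gradual", "punctuational"])
    def test_random_backbones_slope_matches_gls(self, seed, mode):
        rng = np.random.default_rng(seed)
        tree = simulate_bd_tree(lam=0.3, mu=0.05, n_tips=9, seed=rng)
        bb = BackboneTree(tree.tree, mode=mode)
        x = brownian_trait(bb, sigma2=1.0, seed=rng)
        y = brownian_trait(bb, sigma2=1.0, seed=rng)
        cx = pic_contrasts(bb, x, mode=mode)
        cy = pic_contrasts(bb, y, mode=mode)
        res = regress_through_origin(cx, cy)
        assert res.slope == pytest.approx(gls_slope(bb, x, y, mode), abs=1e-8)

    def test_missing_trait_raises(self):
        bb = backbone_from("(A:1,B:1);")
        with pytest.raises(KeyError):
            pic_contrasts(bb, {"A": 1.0})

    def test_polytomy_strict_vs_zero_length(self):
        bb = backbone_from("(A:2,B:2,C:2);")
        trait = {"A": 1.0, "B": 2.0, "C": 4.0}
        with pytest.raises(TreeValidationError, match="polytomy"):
            pic_contrasts(bb, trait, polytomy_policy="strict")
        cs = pic_contrasts(bb, trait, polytomy_policy="zero_length")
        assert len(cs) == 2


class TestThroughOrigin:
    def test_exact_linearity(self):
        bb = backbone_from("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        x = {"A": 0.0, "B": 2.0, "C": 1.0, "D": 3.0}
        y = {k: 2 * v for k, v in x.items()}
        res = regress_through_origin(pic_contrasts(bb, x), pic_contrasts(bb, y))
        assert res.slope == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_hand_evaluated_closed_forms(self):
        # cx = (1, 2, 3), cy = (1, 1, 2):
        # slope = (1 + 2 + 6) / (1 + 4 + 9) = 9/14
        # r2 = 81 / (14 * 6) = 27/28; F = r2/(1-r2) * 2 = 54
        from divclock.comparative import ContrastSet

        cx = ContrastSet(np.array([1.0, 2.0, 3.0]), ["n1", "n2", "n3"], "gradual")
        cy = ContrastSet(np.array([1.0, 1.0, 2.0]), ["n1", "n2", "n3"], "gradual")
        res = regress_through_origin(cx, cy)
        assert res.slope == pytest.approx(9 / 14)
        assert res.r2 == pytest.approx(27 / 28)
        assert res.F == pytest.approx(54.0)
        assert res.df == (1, 2)
        assert res.intercept is None

    def test_positivization_preserves_everything(self):
        from divclock.comparative import ContrastSet, positivize

        rng = np.random.default_rng(3)
        raw_x, raw_y = rng.normal(size=10), rng.normal(size=10)
        ids = [f"n{i}" for i in range(10)]
        cx = ContrastSet(raw_x, ids, "gradual")
        cy = ContrastSet(raw_y, ids, "gradual")
        px, py = positivize(cx, cy)
        assert np.all(px >= 0)
        np.testing.assert_allclose(np.abs(px), np.abs(raw_x))
        res = regress_through_origin(cx, cy)
        # sums of products are flip-invariant, so the statistics match
        # the unflipped closed forms exactly
        assert res.slope == pytest.approx(np.sum(raw_x * raw_y) / np.sum(raw_x**2))
        assert res.r2 == pytest.approx(
            np.sum(raw_x * raw_y) ** 2 / (np.sum(raw_x**2) * np.sum(raw_y**2))
        )

    def test_f_r2_identity(self):
        from divclock.comparative import ContrastSet

        rng = np.random.default_rng(8)
        ids = [f"n{i}" for i in range(12)]
        cx = ContrastSet(rng.normal(size=12), ids, "gradual")
        cy = ContrastSet(rng.normal(size=12), ids, "gradual")
        res = regress_through_origin(cx, cy)
        assert res.F == pytest.approx(
            res.r2 / (1 - res.r2) * res.df[1], abs=1e-10
        )

    def test_degenerate_predictor(self):
        from divclock.comparative import ContrastSet

        cx = ContrastSet(np.zeros(5), list("abcde"), "gradual")
        cy = ContrastSet(np.ones(5), list("abcde"), "gradual")
        with pytest.raises(DegeneratePredictorError):
            regress_through_origin(cx, cy)


class TestOLS:
    def test_f_r2_identity_and_df(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=13)
        y = 2 * x + rng.normal(size=13)
        res = regress_ols(x, y)
        assert res.df == (1, 11)
        assert res.F == pytest.approx(res.r2 / (1 - res.r2) * 11, abs=1e-10)

    def test_collinear_data(self):
        x = np.arange(1.0, 11.0)
        res = regress_ols(x, 3 * x + 1)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)
        assert res.p_value < 1e-12

    def test_zero_variance_predictor(self):
        with pytest.raises(DegeneratePredictorError):
            regress_ols(np.ones(5), np.arange(5.0))


class TestBattery:
    @staticmethod
    def _table(n=6, constant_rate=False, rng=None):
        rng = rng or np.random.default_rng(11)
        lam = rng.uniform(0.1, 1.5, size=n)
        eps = rng.uniform(0, 0.9, size=n)
        return pd.DataFrame(
            {
                "clade_id": [f"clade_{i:02d}" for i in range(1, n + 1)],
                "lam": lam,
                "mu": eps * lam,
                "epsilon": eps,
                "mean_rate": (
                    np.full(n, 4e-3) if constant_rate
                    else rng.uniform(1e-3, 8e-3, size=n)
                ),
                "rate_cv": rng.uniform(0.4, 1.1, size=n),
                "n_tips": rng.integers(40, 300, size=n),
                "crown_age": rng.uniform(5, 50, size=n),
                "node_density": rng.uniform(0.5, 10, size=n),
            }
        )

    def test_full_battery_shape_and_df(self):
        table = self._table()
        tree = simulate_bd_tree(lam=0.3, mu=0.0, n_tips=6, seed=13)
        for i, leaf in enumerate(tree.tree.leaf_node_iter(), start=1):
            leaf.taxon.label = f"clade_{i:02d}"
        bb = BackboneTree(tree.tree)
        battery = run_regression_battery(table, backbone=bb)
        main = battery[battery.analysis != "artifact_check"]
        # 2 responses x 2 predictors x {non-PIC, PIC-gradual, PIC-punct}
        assert len(main) == 12
        non_pic = main[main.analysis == "non_pic"]
        assert set(non_pic.df2) == {len(table) - 2}
        pic = main[main.analysis.str.startswith("pic")]
        assert set(pic.df2) == {len(table) - 2}  # k-1 contrasts -> k-2
        checks = battery[battery.analysis == "artifact_check"]
        assert set(checks.predictor) == {"node_density", "n_tips", "crown_age"}

    def test_constant_mean_rate_flagged_degenerate(self):
        battery = run_regression_battery(self._table(constant_rate=True))
        degenerate = battery[battery.note == "degenerate predictor"]
        assert set(degenerate.predictor) == {"mean_rate"}
        assert np.isnan(degenerate.slope).all()

    def test_backbone_table_mismatch(self):
        table = self._table()
        tree = simulate_bd_tree(lam=0.3, mu=0.0, n_tips=6, seed=13)
        bb = BackboneTree(tree.tree)  # tips still t1..t6
        with pytest.raises(ValueError, match="backbone tips"):
            run_regression_battery(table, backbone=bb)
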