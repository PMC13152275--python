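"""PGLS, phylogenetic ANOVA, variance tests, model selection, and ICC."""

import numpy as np
import pandas as pd
import pytest

from ovoflux.comparative import (
    glm_model_selection,
    group_variance_test,
    pgls,
    phylo_anova,
    repeatability_icc,
)
from ovoflux.phylo import PhyloCovariance, parse_newick, vcv_matrix
from ovoflux.synthetic import simulate_tree


@pytest.fixture(scope="module")
def hand_dataset():
    """5 species on a hand-built tree with fixed trait values."""
    t = parse_newick("(((A:1,B:1):1,(C:0.5,D:0.5):1.5):1,E:3);")
    y = {"A": 1.2, "B": 0.8, "C": -0.3, "D": 0.1, "E": 2.5}
    x = {"A": 0.5, "B": 0.4, "C": -0.2, "D": 0.0, "E": 1.1}
    return t, y, x


class TestPGLS:
    def test_identity_covariance_equals_ols(self):
        rng = np.random.default_rng(0)
        labels = [f"s{i}" for i in range(12)]
        y = dict(zip(labels, rng.standard_normal(12)))
        X = pd.DataFrame({"x": rng.standard_normal(12)}, index=labels)
        C = PhyloCovariance(np.eye(12), labels)
        fit = pgls(y, X, C)
        yv = np.array([y[lab] for lab in labels])
        Xm = np.column_stack([np.ones(12), X.loc[labels, "x"]])
        beta = np.linalg.lstsq(Xm, yv, rcond=None)[0]
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_exact_linear_relation(self):
        labels = ["a", "b", "c", "d"]
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = dict(zip(labels, 2.0 * x + 1.0))
        X = pd.DataFrame({"x": x}, index=labels)
        fit = pgls(y, X, PhyloCovariance(np.eye(4), labels))
        assert fit.r_squared == pytest.approx(1.0)
        assert np.allclose(fit.residuals.to_numpy(), 0.0, atol=1e-10)

    def test_matches_dense_gls_oracle(self, hand_dataset):
        t, y, x = hand_dataset
        C = vcv_matrix(t)
        X = pd.DataFrame({"x": [x[lab] for lab in C.labels]}, index=C.labels)
        fit = pgls(y, X, C)
        # independent dense matrix-algebra oracle
        V = C.matrix
        Vi = np.linalg.inv(V)
        yv = np.array([y[lab] for lab in C.labels])
        Xm = np.column_stack([np.ones(C.n), X["x"].to_numpy()])
        beta = np.linalg.solve(Xm.T @ Vi @ Xm, Xm.T @ Vi @ yv)
        e = yv - Xm @ beta
        s2 = e @ Vi @ e / (C.n - 2)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(Xm.T @ Vi @ Xm)))
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)
        assert np.allclose(fit.bse.to_numpy(), se, atol=1e-8)
        # GLS orthogonality of residuals to design columns
        assert np.allclose(Xm.T @ Vi @ fit.residuals.to_numpy(), 0.0, atol=1e-8)

    def test_invariant_to_row_order(self, hand_dataset):
        t, y, x = hand_dataset
        C = vcv_matrix(t)
        X = pd.DataFrame({"x": [x[lab] for lab in C.labels]}, index=C.labels)
        f1 = pgls(y, X, C)
        perm = list(reversed(C.labels))
        C2 = C.reorder(perm)
        X2 = X.loc[perm]
        f2 = pgls(y, X2, C2)
        assert np.allclose(f1.params.to_numpy(), f2.params.to_numpy(), atol=1e-10)
        assert f1.r_squared == pytest.approx(f2.r_squared, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        labels = ["a", "b", "c", "d"]
        x = np.arange(4.0)
        X = pd.DataFrame({"x1": x, "x2": 2 * x}, index=labels)
        with pytest.raises(ValueError, match="collinear"):
            pgls(dict(zip(labels, x)), X, PhyloCovariance(np.eye(4), labels))


class TestPhyloAnova:
    def test_extreme_separation_minimal_p(self, tree20):
        rng = np.random.default_rng(1)
        labels = tree20.tip_labels
        groups = {lab: ("hi" if i < 10 else "lo") for i, lab in enumerate(labels)}
        x = {lab: (10.0 if groups[lab] == "hi" else 0.0) + 0.01 * rng.standard_normal()
             for lab in labels}
        res = phylo_anova(tree20, x, groups, nsim=199, seed=2)
        assert res.p_simulation == pytest.approx(1.0 / 200.0)

    def test_zero_within_group_variance_degenerate(self, tree20):
        labels = tree20.tip_labels
        groups = {lab: ("a" if i < 10 else "b") for i, lab in enumerate(labels)}
        x = {lab: (1.0 if groups[lab] == "a" else 2.0) for lab in labels}
        with pytest.warns(UserWarning, match="degenerate"):
            res = phylo_anova(tree20, x, groups, nsim=99, seed=3)
        assert res.degenerate
        assert res.p_simulation == pytest.approx(1.0 / 100.0)

    def test_small_group_rejected(self, tree20):
        labels = tree20.tip_labels
        groups = {lab: "a" for lab in labels}
        groups[labels[0]] = "b"
        with pytest.raises(ValueError):
            phylo_anova(tree20, {lab: 0.0 for lab in labels}, groups, nsim=9, seed=0)

    def test_star_tree_simulation_p_matches_parametric(self):
        """On a star tree with normal data the Brownian null is iid, so
        the simulation p should track the parametric F p-value."""
        star = parse_newick("(" + ",".join(f"t{i}:1" for i in range(30)) + ");")
        rng = np.random.default_rng(4)
        labels = star.tip_labels
        x = dict(zip(labels, rng.standard_normal(30)))
        groups = {lab: ["a", "b", "c"][i % 3] for i, lab in enumerate(labels)}
        res = phylo_anova(star, x, groups, nsim=5000, seed=5)
        mc_sd = np.sqrt(res.p_parametric * (1 - res.p_parametric) / 5000)
        assert abs(res.p_simulation - res.p_parametric) < 4 * mc_sd + 1e-3


class TestGroupVarianceTest:
    def test_identical_groups_give_zero_f(self, tree20):
        labels = tree20.tip_labels
        vals = np.tile([0.0, 1.0, 2.0, 3.0, 4.0], 4)
        x = dict(zip(labels, vals))
        groups = {lab: ("a" if i < 10 else "b") for i, lab in enumerate(labels)}
        # same five deviations in both groups -> Levene F exactly 0
        res = group_variance_test(x, groups, tree20, nsim=99, seed=1)
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_detects_scaled_spread(self, tree100):
        rng = np.random.default_rng(6)
        labels = tree100.tip_labels
        groups = {lab: ("wide" if i < 50 else "narrow") for i, lab in enumerate(labels)}
        hits = 0
        for rep in range(20):
            x = {lab: (10.0 if groups[lab] == "wide" else 1.0) * rng.standard_normal()
                 for lab in labels}
            res = group_variance_test(x, groups, tree100, nsim=499, seed=rep)
            hits += res.p_simulation <= 0.01
        assert hits >= 19


class TestGlmSelection:
    def test_single_candidate_full_weight(self):
        tab = pd.DataFrame({"y": [1.0, 2.0, 1.5, 2.5, 3.0, 2.0]})
        ms = glm_model_selection(tab, "y", [[]])
        assert ms.table["weight"].iloc[0] == pytest.approx(1.0)
        assert ms.table["dAICc"].iloc[0] == 0.0

    def test_nested_deviance_monotone(self):
        rng = np.random.default_rng(7)
        tab = pd.DataFrame({
            "y": rng.standard_normal(40),
            "a": rng.standard_normal(40),
            "b": rng.standard_normal(40),
        })
        ms = glm_model_selection(tab, "y", [[], ["a"], ["a", "b"]])
        ll = ms.table.set_index("predictors")["loglik"]
        assert ll["a"] >= ll["1"] - 1e-10
        assert ll["a+b"] >= ll["a"] - 1e-10

    def test_selects_true_predictors(self):
        """Response built from mass + station offsets: that set should
        win AICc in most replicates."""
        rng = np.random.default_rng(8)
        wins = 0
        nrep = 40
        for _ in range(nrep):
            n = 60
            mass = rng.uniform(5, 15, n)
            station = rng.choice(["low", "mid", "high"], n)
            offs = {"low": 0.0, "mid": -1.0, "high": -2.0}
            y = 0.5 * mass + np.array([offs[s] for s in station]) + rng.normal(0, 0.5, n)
            tab = pd.DataFrame({"y": y, "mass": mass, "station": station,
                                "noise": rng.standard_normal(n)})
            ms = glm_model_selection(
                tab, "y", [[], ["mass"], ["station"], ["mass", "station"],
                           ["mass", "station", "noise"]])
            wins += ms.table["predictors"].iloc[0] == "mass+station"
        assert wins >= 0.8 * nrep

    def test_missing_predictor_raises(self):
        tab = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(KeyError):
            glm_model_selection(tab, "y", [["nope"]])


class TestRepeatability:
    def test_perfect_repeatability(self):
        vals = pd.DataFrame({"group": np.repeat(["a", "b", "c"], 3),
                             "value": np.repeat([1.0, 5.0, 9.0], 3)})
        res = repeatability_icc(vals, nboot=50, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_recovers_known_icc(self):
        """Between-variance 9, within 1 -> true ICC 0.9."""
        rng = np.random.default_rng(9)
        g = 200
        means = rng.normal(0, 3.0, g)
        vals = pd.DataFrame({
            "group": np.repeat(np.arange(g), 3),
            "value": np.repeat(means, 3) + rng.normal(0, 1.0, g * 3),
        })
        res = repeatability_icc(vals, nboot=200, seed=1)
        assert abs(res.R - 0.9) < 0.05
        assert res.ci_lower <= res.R <= res.ci_upper
        assert res.lrt_p < 1e-10

    def test_pure_noise_low_r(self):
        rng = np.random.default_rng(10)
        rs = []
        for rep in range(60):
            vals = pd.DataFrame({"group": np.repeat(np.arange(100), 3),
                                 "value": rng.standard_normal(300)})
            rs.append(repeatability_icc(vals, nboot=0, seed=rep).R)
        assert np.mean(rs) <= 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(11)
        vals = pd.DataFrame({"group": np.repeat(np.arange(20), 3),
                             "value": rng.standard_normal(60)})
        shifted = vals.assign(value=5.0 - 3.2 * vals["value"])
        r1 = repeatability_icc(vals, nboot=0, seed=0).R
        r2 = repeatability_icc(shifted, nboot=0, seed=0).R
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_all_singletons_rejected(self):
        vals = pd.DataFrame({"group": ["a", "b", "c"], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            repeatability_icc(vals)
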