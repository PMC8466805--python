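"""Honest causal forest: local estimator, trees, weights, CATE, screening."""

import numpy as np
import pandas as pd
import pytest

from childhte import (
    EffectSpec,
    SimConfig,
    cite_distribution_summary,
    fit_causal_forest,
    forest_design,
    forest_weights,
    generate_dataset,
    local_tau,
    median_split_profile,
    orthogonalize,
    predict_cate,
    select_covariates,
    subgroup_effect,
    two_stage_fit,
    variable_importance,
)
from childhte.forest import (
    CausalForest,
    CausalTree,
    ForestParams,
    NuisanceEstimates,
    _Leaf,
    _Node,
    fit_regression_forest,
    grow_causal_tree,
    predict_cate_from_weights,
    split_gain,
)


def _hand_forest(X, y_res, w_res, trees):
    """Assemble a CausalForest around hand-built trees and residuals."""
    n = len(y_res)
    nus = NuisanceEstimates(
        m_hat=np.zeros(n), p_hat=np.full(n, 0.5),
        y_res=np.asarray(y_res, float), w_res=np.asarray(w_res, float),
    )
    return CausalForest(
        trees=trees, feature_names=[f"x{j}" for j in range(X.shape[1])],
        params=ForestParams(n_trees=len(trees)), seed=0, n=n,
        X=np.asarray(X, float), W=(np.asarray(w_res) > 0).astype(int), nuisance=nus,
    )


def _leaf_node(est_idx, y_res, w_res, leaves):
    e = np.asarray(est_idx, int)
    cross = w_res[e] * y_res[e]
    den = w_res[e] ** 2
    leaves.append(_Leaf(est_idx=e, tau=cross.sum() / den.sum(),
                        mean_cross=cross.mean(), mean_den=den.mean()))
    return _Node(leaf_id=len(leaves) - 1)


# ---------------------------------------------------------------------------
# nuisance and residual layer


def test_regression_forest_constant_target():
    X = np.random.default_rng(1).normal(size=(60, 2))
    with pytest.warns(UserWarning, match="constant"):
        pred = fit_regression_forest(X, np.full(60, 3.0), n_trees=10, seed=1)
    assert np.all(pred == 3.0)


def test_regression_forest_null_and_recoverable_signal():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(1500, 3))
    noise = rng.normal(size=1500)
    oob = fit_regression_forest(X, noise, n_trees=100, seed=3)
    r2 = 1 - np.mean((noise - oob) ** 2) / noise.var()
    assert abs(r2) < 0.05 or r2 < 0  # no spurious out-of-bag skill

    step = np.where(X[:, 0] > 0, 2.0, -2.0) + 0.1 * rng.normal(size=1500)
    oob2 = fit_regression_forest(X, step, n_trees=100, seed=4)
    rmse = np.sqrt(np.mean((step - oob2) ** 2))
    assert rmse < 0.2 * step.std()


def test_regression_forest_clips_binary_targets():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(300, 2))
    w = (rng.random(300) < 0.95).astype(float)
    p = fit_regression_forest(X, w, n_trees=50, seed=6)
    assert p.min() >= 0.01 and p.max() <= 0.99


def test_orthogonalize_trivial_and_errors():
    Y = np.array([1.0, 2.0, 3.0])
    W = np.array([1, 0, 1])
    y_res, w_res = orthogonalize(Y, W, (Y, np.full(3, 0.5)))
    assert np.all(y_res == 0)
    assert set(w_res) == {0.5, -0.5}
    with pytest.raises(ValueError, match="length"):
        orthogonalize(Y, W, (Y[:2], np.full(3, 0.5)))


def test_rlearner_recovers_constant_effect_under_randomization():
    # oracle: 1-D least squares of outcome residual on treatment residual
    rng = np.random.default_rng(7)
    n = 4000
    x = rng.normal(size=n)
    W = rng.integers(0, 2, n)
    tau0 = 0.7
    Y = 0.5 * x + tau0 * W + rng.normal(size=n)
    y_res, w_res = orthogonalize(Y, W, (0.5 * x + 0.5 * tau0, np.full(n, 0.5)))
    slope = float(np.sum(w_res * y_res) / np.sum(w_res**2))
    assert slope == pytest.approx(tau0, abs=0.1)


# ---------------------------------------------------------------------------
# local tau and split gain


def test_local_tau_single_and_symmetric_pairs():
    pairs = (np.array([1.0]), np.array([0.5]))
    assert local_tau(pairs, [0]) == pytest.approx(2.0, abs=1e-15)
    pairs2 = (np.array([1.0, -1.0]), np.array([0.5, -0.5]))
    assert local_tau(pairs2, [0, 1]) == pytest.approx(2.0, abs=1e-15)


def test_local_tau_matches_bruteforce_on_seven_pairs():
    rng = np.random.default_rng(8)
    y_res = rng.normal(size=7)
    w_res = rng.normal(size=7)
    idx = [0, 2, 3, 5, 6]
    num = sum(w_res[i] * y_res[i] for i in idx)
    den = sum(w_res[i] ** 2 for i in idx)
    assert local_tau((y_res, w_res), idx) == pytest.approx(num / den, abs=1e-12)


def test_local_tau_degenerate_inputs():
    with pytest.raises(ValueError, match="empty"):
        local_tau((np.array([1.0]), np.array([1.0])), [])
    with pytest.raises(ValueError, match="undefined"):
        local_tau((np.array([1.0, 2.0]), np.zeros(2)), [0, 1])


def test_split_gain_equal_children_equals_parent_scale():
    w_res = np.array([0.5, -0.5, 0.5, -0.5])
    y_res = w_res * 2.0  # tau = 2 everywhere, noiseless
    gain = split_gain((y_res, w_res), [0, 1], [2, 3])
    assert gain == pytest.approx(4 * 2.0**2, abs=1e-12)


def test_split_gain_maximized_at_true_boundary():
    # noiseless opposite effects; exhaustive scan over candidate boundaries
    x = np.linspace(0, 1, 20)
    w_res = np.tile([0.5, -0.5], 10)
    tau = np.where(x < 0.5, 1.0, -1.0)
    y_res = w_res * tau
    pairs = (y_res, w_res)
    cuts = list(range(2, 18, 2))  # keep both arms in each child
    gains = [split_gain(pairs, np.arange(c), np.arange(c, 20)) for c in cuts]
    assert cuts[int(np.argmax(gains))] == 10  # the true effect boundary


# ---------------------------------------------------------------------------
# honest trees


def _make_residual_problem(n, seed, tau_fn, noise=0.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    W = rng.integers(0, 2, n)
    w_res = W - 0.5
    y_res = w_res * tau_fn(x) + noise * rng.normal(size=n)
    return x[:, None], (y_res, w_res), W


def test_noiseless_constant_effect_grows_no_splits():
    X, pairs, W = _make_residual_problem(200, 9, lambda x: 0.5 * np.ones_like(x))
    tree = grow_causal_tree(X, pairs, W, np.arange(200), ForestParams(), seed=1)
    assert tree.root.is_leaf
    assert tree.leaves[0].tau == pytest.approx(0.5, abs=1e-12)


def test_step_effect_threshold_recovery():
    X, pairs, W = _make_residual_problem(
        2000, 10, lambda x: np.where(x < 0.4, 1.0, -1.0), noise=0.3
    )
    tree = grow_causal_tree(X, pairs, W, np.arange(2000), ForestParams(), seed=2)
    assert not tree.root.is_leaf
    assert tree.root.feature == 0
    assert abs(tree.root.threshold - 0.4) < 0.1


def _tree_shape(node):
    if node.is_leaf:
        return "L"
    return f"({node.feature}:{node.threshold:.12g}{_tree_shape(node.left)}{_tree_shape(node.right)})"


def test_honesty_estimation_half_outcomes_cannot_move_splits():
    X, (y_res, w_res), W = _make_residual_problem(
        600, 12, lambda x: np.where(x < 0.5, 1.0, -1.0), noise=0.2
    )
    params = ForestParams()
    tree = grow_causal_tree(X, (y_res, w_res), W, np.arange(600), params, seed=3)
    perturbed = y_res.copy()
    perturbed[tree.est_idx] += np.random.default_rng(13).normal(0, 5, len(tree.est_idx))
    tree2 = grow_causal_tree(X, (perturbed, w_res), W, np.arange(600), params, seed=3)
    assert _tree_shape(tree.root) == _tree_shape(tree2.root)
    # and leaf effects come from the estimation half only
    perturbed_split = y_res.copy()
    perturbed_split[tree.split_idx] += 99.0
    tree3 = grow_causal_tree(X, (perturbed_split, w_res), W, np.arange(600), params, seed=3)
    same_structure = _tree_shape(tree.root) == _tree_shape(tree3.root)
    if same_structure:
        assert [lf.tau for lf in tree3.leaves] == pytest.approx(
            [lf.tau for lf in tree.leaves], abs=1e-12
        )


def test_tree_halves_are_disjoint_and_leaf_arms_respect_min_leaf():
    cfg = SimConfig(n_total=600, seed=14, effect_spec=EffectSpec(tau0=0.3))
    ds, _ = generate_dataset(cfg)
    f = fit_causal_forest(
        forest_design(ds), ds["outcome"], ds["treatment"],
        ForestParams(n_trees=5, nuisance_trees=30), seed=4,
    )
    W = ds["treatment"].to_numpy()
    for tree in f.trees:
        assert not set(tree.split_idx) & set(tree.est_idx)
        for lf in tree.leaves:
            assert (W[lf.est_idx] == 1).sum() >= f.params.min_leaf
            assert (W[lf.est_idx] == 0).sum() >= f.params.min_leaf


def test_forest_determinism():
    cfg = SimConfig(n_total=400, seed=15, effect_spec=EffectSpec(tau0=0.3))
    ds, _ = generate_dataset(cfg)
    Xd = forest_design(ds)
    a = fit_causal_forest(Xd, ds["outcome"], ds["treatment"], ForestParams(n_trees=8, nuisance_trees=30), seed=5)
    b = fit_causal_forest(Xd, ds["outcome"], ds["treatment"], ForestParams(n_trees=8, nuisance_trees=30), seed=5)
    assert np.array_equal(predict_cate(a), predict_cate(b))
    assert [_tree_shape(t.root) for t in a.trees] == [_tree_shape(t.root) for t in b.trees]


def test_forest_parameter_validation():
    cfg = SimConfig(n_total=100, seed=16)
    ds, _ = generate_dataset(cfg)
    with pytest.raises(ValueError, match="min_leaf"):
        fit_causal_forest(
            forest_design(ds), ds["outcome"], ds["treatment"],
            ForestParams(n_trees=2, min_leaf=20, nuisance_trees=10), seed=6,
        )


# ---------------------------------------------------------------------------
# weights and CATE


def test_forest_weights_single_tree_hand_case():
    y_res = np.array([1.0, 2.0, 0.5, 1.5, 1.0, 2.5])
    w_res = np.array([0.5, -0.5, 0.5, -0.5, 0.5, -0.5])
    X = np.zeros((6, 1))
    leaves: list = []
    root = _leaf_node([2, 5], y_res, w_res, leaves)
    tree = CausalTree(root=root, split_idx=np.array([0, 1]), est_idx=np.array([2, 5]), leaves=leaves)
    f = _hand_forest(X, y_res, w_res, [tree])
    alpha = forest_weights(f, [0.0]).alpha
    expected = np.zeros(6)
    expected[[2, 5]] = 0.5
    assert np.allclose(alpha, expected)


def test_forest_weights_two_tree_overlap():
    y_res = np.arange(4, dtype=float)
    w_res = np.array([0.5, -0.5, 0.5, -0.5])
    X = np.zeros((4, 1))
    leaves1: list = []
    t1 = CausalTree(root=_leaf_node([1, 2], y_res, w_res, leaves1),
                    split_idx=np.array([0]), est_idx=np.array([1, 2]), leaves=leaves1)
    leaves2: list = []
    t2 = CausalTree(root=_leaf_node([2, 3], y_res, w_res, leaves2),
                    split_idx=np.array([0]), est_idx=np.array([2, 3]), leaves=leaves2)
    f = _hand_forest(X, y_res, w_res, [t1, t2])
    alpha = forest_weights(f, [0.0]).alpha
    assert alpha[2] == pytest.approx(0.5)
    assert alpha[1] == pytest.approx(0.25)
    assert alpha[3] == pytest.approx(0.25)
    assert alpha.sum() == pytest.approx(1.0)


def test_predict_cate_uniform_weights_reduce_to_local_tau():
    rng = np.random.default_rng(17)
    y_res = rng.normal(size=8)
    w_res = np.where(rng.random(8) < 0.5, 0.5, -0.5)
    X = np.zeros((8, 1))
    leaves: list = []
    tree = CausalTree(root=_leaf_node(list(range(8)), y_res, w_res, leaves),
                      split_idx=np.array([], dtype=int), est_idx=np.arange(8), leaves=leaves)
    f = _hand_forest(X, y_res, w_res, [tree])
    tau_forest = predict_cate(f, np.zeros((1, 1)))[0]
    assert tau_forest == pytest.approx(local_tau((y_res, w_res), range(8)), abs=1e-12)
    assert predict_cate_from_weights(f, [0.0]) == pytest.approx(tau_forest, abs=1e-12)


def test_hand_computed_weighted_cate_on_ten_records():
    # fully hand-computed weighted estimator on a 10-record, 2-leaf tree
    y_res = np.array([0.4, -0.2, 0.6, -0.1, 0.3, 0.9, -0.6, 0.2, -0.4, 0.5])
    w_res = np.array([0.5, -0.5, 0.5, -0.5, 0.5, 0.5, -0.5, 0.5, -0.5, 0.5])
    x = np.array([0.1, 0.2, 0.3, 0.4, 0.45, 0.6, 0.7, 0.8, 0.9, 0.95])[:, None]
    leaves: list = []
    left = _leaf_node([0, 1, 3], y_res, w_res, leaves)
    right = _leaf_node([6, 8, 9], y_res, w_res, leaves)
    root = _Node(feature=0, threshold=0.5, left=left, right=right)
    tree = CausalTree(root=root, split_idx=np.array([2, 4, 5, 7]),
                      est_idx=np.array([0, 1, 3, 6, 8, 9]), leaves=leaves)
    f = _hand_forest(x, y_res, w_res, [tree])
    for q, est in ((0.2, [0, 1, 3]), (0.8, [6, 8, 9])):
        alpha = np.zeros(10)
        alpha[est] = 1 / 3
        expected = np.sum(alpha * w_res * y_res) / np.sum(alpha * w_res**2)
        assert predict_cate(f, np.array([[q]]))[0] == pytest.approx(expected, abs=1e-12)
        assert predict_cate_from_weights(f, [q]) == pytest.approx(expected, abs=1e-12)


def test_fast_path_matches_explicit_weights_on_fitted_forest():
    cfg = SimConfig(n_total=300, seed=18, effect_spec=EffectSpec(tau0=0.4))
    ds, _ = generate_dataset(cfg)
    Xd = forest_design(ds)
    f = fit_causal_forest(Xd, ds["outcome"], ds["treatment"], ForestParams(n_trees=10, nuisance_trees=30), seed=7)
    cite = predict_cate(f)
    for i in (0, 57, 123, 299):
        assert cite[i] == pytest.approx(predict_cate_from_weights(f, Xd.iloc[i]), abs=1e-10)
        assert forest_weights(f, Xd.iloc[i]).alpha.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# importance, screening, summaries


def test_variable_importance_single_feature_forest():
    X, pairs, W = _make_residual_problem(
        1000, 19, lambda x: np.where(x < 0.5, 1.0, -1.0), noise=0.2
    )
    nus = NuisanceEstimates(m_hat=np.zeros(1000), p_hat=np.full(1000, 0.5),
                            y_res=pairs[0], w_res=pairs[1])
    f = fit_causal_forest(X, pairs[0], W, ForestParams(n_trees=20, nuisance_trees=10), seed=8, nuisance=nus)
    imp = variable_importance(f)
    assert imp.loc[0, "importance"] == pytest.approx(1.0)
    assert sorted(imp["rank"]) == list(range(1, len(imp) + 1))


def test_select_covariates_rules():
    table = pd.DataFrame({
        "covariate": [f"v{i}" for i in range(10)],
        "importance": [0.368, 0.158, 0.155, 0.06, 0.06, 0.05, 0.05, 0.04, 0.03, 0.029],
    })
    sel = select_covariates(table)
    assert sel == ["v0", "v1", "v2"]

    equal = pd.DataFrame({"covariate": ["a", "b"], "importance": [0.5, 0.5]})
    assert select_covariates(equal) == ["a", "b"]

    single = pd.DataFrame({"covariate": ["a", "b"], "importance": [1.0, 0.0]})
    assert select_covariates(single) == ["a"]


def test_two_stage_smoke_and_determinism():
    cfg = SimConfig(n_total=400, seed=20, effect_spec=EffectSpec(tau0=0.3))
    ds, _ = generate_dataset(cfg)
    res = two_stage_fit(ds, stage1_trees=10, stage2_trees=20,
                        params=ForestParams(nuisance_trees=20), seed=9)
    assert res.selected
    assert len(res.cite) == 400
    assert set(res.stage2.feature_names) == set(res.selected)
    res2 = two_stage_fit(ds, stage1_trees=10, stage2_trees=20,
                         params=ForestParams(nuisance_trees=20), seed=9)
    assert res2.selected == res.selected
    assert np.array_equal(res2.cite, res.cite)


def test_cite_summary_rules():
    s = cite_distribution_summary(np.full(10, 0.7))
    assert s.interval == (0.7, 0.7)
    assert s.verdict == "homogeneous-sign"

    rng = np.random.default_rng(22)
    z = rng.normal(size=10000)
    s2 = cite_distribution_summary(z)
    assert s2.interval[0] == pytest.approx(-1.96, abs=0.08)
    assert s2.interval[1] == pytest.approx(1.96, abs=0.08)
    assert s2.verdict == "heterogeneous (sign-varying)"
    s3 = cite_distribution_summary(z, rule="conventional")
    assert "zero" in s3.verdict

    with pytest.raises(ValueError):
        cite_distribution_summary([0.1])


def test_subgroup_effect_rules():
    cite = np.array([0.2, 0.2, 0.2, 0.2])
    W = np.array([1, 0, 1, 0])
    eff = subgroup_effect(cite, W, np.array([True, True, False, False]))
    assert eff.estimate == pytest.approx(0.2)
    assert eff.estimand == "CATC"

    full = subgroup_effect(np.array([0.1, 0.3, 0.5, 0.7]), W, np.ones(4, bool), estimand="CATE")
    assert full.estimate == pytest.approx(0.4)

    with pytest.raises(ValueError, match="control"):
        subgroup_effect(cite, np.array([1, 1, 1, 1]), np.ones(4, bool))
    with pytest.raises(ValueError, match="empty"):
        subgroup_effect(cite, W, np.zeros(4, bool))


def test_median_split_profile_rules():
    rng = np.random.default_rng(23)
    n = 10000
    cov = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    cite = rng.normal(size=n)  # independent of covariates
    prof = median_split_profile(cite, cov).set_index("covariate")
    assert abs(prof.loc["a", "gap"]) < 0.06
    assert abs(prof.loc["b", "gap"]) < 0.06

    # CITE equal to a covariate: that covariate separates sharply
    prof2 = median_split_profile(cov["a"].to_numpy(), cov).set_index("covariate")
    assert prof2.loc["a", "gap"] > 1.0
    assert prof2.loc["a", "p"] < 1e-10

    # odd n: median goes to the lower half
    cite_odd = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    cov_odd = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
    prof3 = median_split_profile(cite_odd, cov_odd)
    assert prof3.loc[0, "mean_below_median"] == pytest.approx(2.0)  # {1,2,3}

    with pytest.raises(ValueError, match="constant"):
        median_split_profile(np.ones(10), cov.head(10))
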