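"""Honest causal forest for conditional treatment-effect estimation.

The estimator follows the orthogonalized (R-learner) construction.  With
nuisance functions m(x) = E[Y|X=x] and p(x) = E[W|X=x] estimated by
out-of-bag random-forest predictions, the partially linear model

    Y - m(X) = (W - p(X)) tau(X) + eps

identifies tau locally: over a neighborhood N(x),

    tau_hat = sum_{i in N(x)} (W_i - p_i)(Y_i - m_i) / sum_{i in N(x)} (W_i - p_i)^2

The forest's adaptive neighborhood is realized by honest trees: each tree
is grown on half of its subsample (the split half) by greedily maximizing
the heterogeneity criterion n_L tau_L^2 + n_R tau_R^2, while leaf effects
are computed only from the disjoint estimation half, so no outcome is used
both to place a split and to estimate the effect behind it.  Averaging
leaf co-membership across trees gives nonnegative weights alpha_i(x)
summing to one, and the forest CATE is the alpha-weighted version of the
local ratio above.

A two-stage procedure mirrors the field's screening practice: grow a first
forest on all covariates, rank them by (depth-discounted) split frequency,
keep those above the mean importance, and regrow the forest on the
selected covariates for the final per-unit effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .descriptives import welch_t_test

# ---------------------------------------------------------------------------
# nuisance estimation


@dataclass
class NuisanceEstimates:
    """Out-of-bag m(x), p(x) and the residual pairs they induce."""

    m_hat: np.ndarray
    p_hat: np.ndarray
    y_res: np.ndarray
    w_res: np.ndarray


def fit_regression_forest(
    X,
    target,
    n_trees: int = 200,
    min_leaf: int = 5,
    seed: int = 0,
    binary: bool | None = None,
) -> np.ndarray:
    """Random-forest regression returning out-of-bag predictions per record.

    Out-of-bag predictions act as cross-fitting: no record's own outcome
    enters its prediction.  Records that happen to be in-bag for every tree
    fall back to the in-sample forest prediction.  Binary targets (e.g. the
    treatment indicator) have predictions clipped to [0.01, 0.99] so the
    induced treatment residuals cannot vanish.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(target, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 records for nuisance estimation")
    if np.ptp(t) == 0:
        warnings.warn("constant target: returning constant predictions")
        return np.full(len(t), t[0])
    if binary is None:
        binary = set(np.unique(t)).issubset({0.0, 1.0})
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        min_samples_leaf=min_leaf,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed % (2**31),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse-OOB warning handled below
        rf.fit(X, t)
        oob = np.array(rf.oob_prediction_, dtype=float)
    missing = ~np.isfinite(oob)
    if missing.any():
        oob[missing] = rf.predict(X[missing])
    if binary:
        oob = np.clip(oob, 0.01, 0.99)
    return oob


def estimate_nuisance(
    X, Y, W, n_trees: int = 200, min_leaf: int = 5, seed: int = 0
) -> NuisanceEstimates:
    """Fit the outcome and propensity nuisance forests and residualize."""
    rng = np.random.default_rng(seed)
    m_hat = fit_regression_forest(
        X, Y, n_trees=n_trees, min_leaf=min_leaf, seed=int(rng.integers(2**31)), binary=False
    )
    p_hat = fit_regression_forest(
        X, W, n_trees=n_trees, min_leaf=min_leaf, seed=int(rng.integers(2**31)), binary=True
    )
    y_res, w_res = orthogonalize(Y, W, (m_hat, p_hat))
    return NuisanceEstimates(m_hat=m_hat, p_hat=p_hat, y_res=y_res, w_res=w_res)


def orthogonalize(Y, W, nuisance) -> tuple[np.ndarray, np.ndarray]:
    """Residual pairs (Y - m_hat, W - p_hat)."""
    if isinstance(nuisance, NuisanceEstimates):
        m_hat, p_hat = nuisance.m_hat, nuisance.p_hat
    else:
        m_hat, p_hat = nuisance
    y = np.asarray(Y, float)
    w = np.asarray(W, float)
    m_hat = np.asarray(m_hat, float)
    p_hat = np.asarray(p_hat, float)
    if not (len(y) == len(w) == len(m_hat) == len(p_hat)):
        raise ValueError("length mismatch between outcomes, treatment and nuisances")
    return y - m_hat, w - p_hat


# ---------------------------------------------------------------------------
# local effect and split criterion


def local_tau(residual_pairs, index_set) -> float:
    """Residual-on-residual effect over an index set.

    tau_hat = sum (w_res * y_res) / sum (w_res^2) over the set.
    """
    y_res, w_res = residual_pairs
    idx = np.asarray(index_set, dtype=int)
    if idx.size == 0:
        raise ValueError("index set is empty")
    den = float(np.sum(np.asarray(w_res)[idx] ** 2))
    if den <= 0:
        raise ValueError("all treatment residuals zero: effect undefined on this set")
    num = float(np.sum(np.asarray(w_res)[idx] * np.asarray(y_res)[idx]))
    return num / den


def split_gain(residual_pairs, left_set, right_set) -> float:
    """Heterogeneity criterion n_L tau_L^2 + n_R tau_R^2 (larger is better)."""
    left = np.asarray(left_set, dtype=int)
    right = np.asarray(right_set, dtype=int)
    return len(left) * local_tau(residual_pairs, left) ** 2 + len(right) * local_tau(
        residual_pairs, right
    ) ** 2


# ---------------------------------------------------------------------------
# honest trees


@dataclass
class _Leaf:
    est_idx: np.ndarray  # global indices of the estimation-half records here
    tau: float
    mean_cross: float  # mean over est_idx of w_res*y_res
    mean_den: float  # mean over est_idx of w_res^2


@dataclass
class _Node:
    feature: int = -1
    threshold: float = float("nan")
    left: "_Node | None" = None
    right: "_Node | None" = None
    leaf_id: int = -1  # >= 0 marks a leaf

    @property
    def is_leaf(self) -> bool:
        return self.leaf_id >= 0


@dataclass
class CausalTree:
    root: _Node
    split_idx: np.ndarray  # global indices of the split (structure) half
    est_idx: np.ndarray  # global indices of the estimation half
    leaves: list[_Leaf]

    def assign_leaves(self, X: np.ndarray) -> np.ndarray:
        """Leaf id for each row of X (vectorized routing)."""
        out = np.empty(len(X), dtype=int)
        stack = [(self.root, np.arange(len(X)))]
        while stack:
            node, idx = stack.pop()
            if node.is_leaf:
                out[idx] = node.leaf_id
                continue
            go_left = X[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[go_left]))
            stack.append((node.right, idx[~go_left]))
        return out

    def split_features(self) -> list[tuple[int, int]]:
        """(feature, depth) of every internal node; root has depth 1."""
        out: list[tuple[int, int]] = []
        stack = [(self.root, 1)]
        while stack:
            node, depth = stack.pop()
            if node.is_leaf:
                continue
            out.append((node.feature, depth))
            stack.append((node.left, depth + 1))
            stack.append((node.right, depth + 1))
        return out


@dataclass
class ForestParams:
    """Tuning knobs of the causal forest.

    min_leaf applies per treatment arm within BOTH honest halves of every
    leaf, which guarantees each leaf builds its own counterfactual.
    """

    n_trees: int = 200
    min_leaf: int = 5
    mtry: int | None = None  # default ceil(sqrt(p))
    max_depth: int | None = None
    subsample_fraction: float = 0.5
    honest_fraction: float = 0.5
    with_replacement: bool = False
    nuisance_trees: int = 200
    split_penalty: float = 1.0
    gain_rel_tol: float = 1e-10


def _best_split_for_feature(
    vals_s: np.ndarray,
    cross_s: np.ndarray,
    den_s: np.ndarray,
    treat_s: np.ndarray,
    vals_e_treat: np.ndarray,
    vals_e_ctrl: np.ndarray,
    min_leaf: int,
    split_penalty: float = 1.0,
) -> tuple[float, float] | None:
    """Best admissible (gain, threshold) along one feature, or None.

    Candidate thresholds are midpoints between consecutive distinct
    split-half values; a candidate is admissible when both children keep at
    least ``min_leaf`` treated and control units in the split half AND in
    the estimation half.

    The gain is n_L tau_L^2 + n_R tau_R^2 minus, per child,
    ``split_penalty`` times n_child Var_hat(tau_child): without the
    correction E[n tau_hat^2] exceeds n tau^2 by exactly n Var(tau_hat),
    so pure-noise splits would otherwise carry a systematically positive
    gain and greedy search would favor covariates with many candidate
    thresholds.
    """
    ns = len(vals_s)
    order = np.argsort(vals_s, kind="mergesort")
    sv = vals_s[order]
    boundary = np.nonzero(sv[:-1] < sv[1:])[0]  # left child = positions <= b
    if boundary.size == 0:
        return None
    thr = 0.5 * (sv[boundary] + sv[boundary + 1])

    c = cross_s[order]
    d = den_s[order]
    c_cross = np.cumsum(c)
    c_den = np.cumsum(d)
    c_treat = np.cumsum(treat_s[order])
    c_c2 = np.cumsum(c * c)
    c_d2 = np.cumsum(d * d)
    c_cd = np.cumsum(c * d)
    nL = boundary + 1
    crossL, denL, treatL = c_cross[boundary], c_den[boundary], c_treat[boundary]
    c2L, d2L, cdL = c_c2[boundary], c_d2[boundary], c_cd[boundary]
    crossR = c_cross[-1] - crossL
    denR = c_den[-1] - denL
    treatR = c_treat[-1] - treatL
    c2R, d2R, cdR = c_c2[-1] - c2L, c_d2[-1] - d2L, c_cd[-1] - cdL
    nR = ns - nL
    ctrlL = nL - treatL
    ctrlR = nR - treatR

    etL = np.searchsorted(vals_e_treat, thr, side="right")
    ecL = np.searchsorted(vals_e_ctrl, thr, side="right")
    etR = len(vals_e_treat) - etL
    ecR = len(vals_e_ctrl) - ecL

    ok = (
        (treatL >= min_leaf)
        & (ctrlL >= min_leaf)
        & (treatR >= min_leaf)
        & (ctrlR >= min_leaf)
        & (etL >= min_leaf)
        & (ecL >= min_leaf)
        & (etR >= min_leaf)
        & (ecR >= min_leaf)
        & (denL > 0)
        & (denR > 0)
    )
    if not ok.any():
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        tauL = np.where(denL > 0, crossL / np.where(denL > 0, denL, 1.0), 0.0)
        tauR = np.where(denR > 0, crossR / np.where(denR > 0, denR, 1.0), 0.0)
        # Var_hat(tau) = sum (c_i - tau d_i)^2 / (sum d_i)^2, via cumulants
        sseL = np.maximum(c2L - 2 * tauL * cdL + tauL**2 * d2L, 0.0)
        sseR = np.maximum(c2R - 2 * tauR * cdR + tauR**2 * d2R, 0.0)
        varL = np.where(denL > 0, sseL / np.where(denL > 0, denL, 1.0) ** 2, 0.0)
        varR = np.where(denR > 0, sseR / np.where(denR > 0, denR, 1.0) ** 2, 0.0)
    gain = nL * (tauL**2 - split_penalty * varL) + nR * (tauR**2 - split_penalty * varR)
    gain[~ok] = -np.inf
    best = int(np.argmax(gain))
    return float(gain[best]), float(thr[best])


def grow_causal_tree(
    X: np.ndarray,
    residual_pairs,
    W,
    subsample_indices,
    params: ForestParams,
    seed: int,
) -> CausalTree:
    """Grow one honest tree on a subsample.

    The subsample is split (stratified by arm) into a split half that
    chooses the structure and an estimation half that supplies every leaf's
    effect; recursion stops when no admissible split improves the
    heterogeneity gain beyond a relative tolerance or the depth limit is
    reached.
    """
    y_res, w_res = (np.asarray(a, float) for a in residual_pairs)
    w = np.asarray(W, dtype=int)
    sub = np.asarray(subsample_indices, dtype=int)
    if len(np.unique(w[sub])) < 2:
        raise ValueError("subsample lacks one treatment arm")
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    mtry = params.mtry if params.mtry is not None else int(np.ceil(np.sqrt(p)))
    mtry = min(mtry, p)

    # stratified honest halves: split treated and controls separately
    treated = sub[w[sub] == 1]
    controls = sub[w[sub] == 0]
    rng.shuffle(treated)
    rng.shuffle(controls)
    ht = int(round(params.honest_fraction * len(treated)))
    hc = int(round(params.honest_fraction * len(controls)))
    split_idx = np.concatenate([treated[:ht], controls[:hc]])
    est_idx = np.concatenate([treated[ht:], controls[hc:]])

    cross = w_res * y_res
    den = w_res**2
    leaves: list[_Leaf] = []

    def make_leaf(e_idx: np.ndarray) -> _Node:
        d = float(np.sum(den[e_idx]))
        c = float(np.sum(cross[e_idx]))
        tau = c / d if d > 0 else 0.0
        leaves.append(
            _Leaf(
                est_idx=e_idx,
                tau=tau,
                mean_cross=c / len(e_idx),
                mean_den=d / len(e_idx),
            )
        )
        node = _Node(leaf_id=len(leaves) - 1)
        return node

    def build(s_idx: np.ndarray, e_idx: np.ndarray, depth: int) -> _Node:
        if params.max_depth is not None and depth > params.max_depth:
            return make_leaf(e_idx)
        ds = float(np.sum(den[s_idx]))
        tau_parent = float(np.sum(cross[s_idx])) / ds if ds > 0 else 0.0
        # parent baseline scored with the same variance correction as children
        sse_p = float(np.sum((cross[s_idx] - tau_parent * den[s_idx]) ** 2))
        var_p = sse_p / ds**2 if ds > 0 else 0.0
        base = len(s_idx) * (tau_parent**2 - params.split_penalty * var_p)

        feats = rng.choice(p, size=mtry, replace=False)
        best: tuple[float, int, float] | None = None  # (gain, feature, thr)
        for f in feats:
            ve = X[e_idx, f]
            we = w[e_idx]
            res = _best_split_for_feature(
                X[s_idx, f],
                cross[s_idx],
                den[s_idx],
                (w[s_idx] == 1).astype(float),
                np.sort(ve[we == 1]),
                np.sort(ve[we == 0]),
                params.min_leaf,
                params.split_penalty,
            )
            if res is None:
                continue
            gain, thr = res
            if best is None or gain > best[0]:
                best = (gain, int(f), thr)
        if best is None:
            return make_leaf(e_idx)
        gain, f, thr = best
        improved = gain - base > params.gain_rel_tol * max(base, 1e-12)
        if not improved:
            return make_leaf(e_idx)
        node = _Node(feature=f, threshold=thr)
        sL = s_idx[X[s_idx, f] <= thr]
        sR = s_idx[X[s_idx, f] > thr]
        eL = e_idx[X[e_idx, f] <= thr]
        eR = e_idx[X[e_idx, f] > thr]
        node.left = build(sL, eL, depth + 1)
        node.right = build(sR, eR, depth + 1)
        return node

    root = build(split_idx, est_idx, 1)
    return CausalTree(root=root, split_idx=split_idx, est_idx=est_idx, leaves=leaves)


# ---------------------------------------------------------------------------
# forest


@dataclass
class CausalForest:
    trees: list[CausalTree]
    feature_names: list[str]
    params: ForestParams
    seed: int
    n: int
    X: np.ndarray
    W: np.ndarray
    nuisance: NuisanceEstimates
    y_res: np.ndarray = field(init=False)
    w_res: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.y_res = self.nuisance.y_res
        self.w_res = self.nuisance.w_res

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _as_matrix(X, feature_names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def fit_causal_forest(
    X,
    Y,
    W,
    params: ForestParams | None = None,
    seed: int = 0,
    nuisance: NuisanceEstimates | None = None,
) -> CausalForest:
    """Fit an honest causal forest.

    Nuisances are fitted once (out-of-bag) before any tree is grown; each
    tree then gets an independent half-subsample drawn without replacement
    (with-replacement bootstrap available via params).
    """
    params = params or ForestParams()
    Xm, names = _as_matrix(X)
    y = np.asarray(Y, float)
    w = np.asarray(W, int)
    n = len(y)
    if n < 50:
        raise ValueError("need at least 50 records to fit a causal forest")
    if (w == 1).sum() < params.min_leaf * 4 or (w == 0).sum() < params.min_leaf * 4:
        raise ValueError("each arm must have at least 4*min_leaf records")
    sub_n = int(round(params.subsample_fraction * n))
    if sub_n < 4 * params.min_leaf:
        raise ValueError("min_leaf too large for the subsample size")

    rng = np.random.default_rng(seed)
    if nuisance is None:
        nuisance = estimate_nuisance(
            Xm, y, w, n_trees=params.nuisance_trees, min_leaf=params.min_leaf,
            seed=int(rng.integers(2**31)),
        )
    pairs = (nuisance.y_res, nuisance.w_res)

    trees: list[CausalTree] = []
    for _ in range(params.n_trees):
        for _attempt in range(20):
            sub = rng.choice(n, size=sub_n, replace=params.with_replacement)
            if len(np.unique(w[sub])) == 2:
                break
        else:
            raise RuntimeError("could not draw a subsample containing both arms")
        tree_seed = int(rng.integers(2**31))
        trees.append(grow_causal_tree(Xm, pairs, w, sub, params, tree_seed))
    return CausalForest(
        trees=trees, feature_names=names, params=params, seed=seed, n=n,
        X=Xm, W=w, nuisance=nuisance,
    )


@dataclass
class ForestWeights:
    alpha: np.ndarray  # length n_train, nonnegative, sums to 1


def forest_weights(forest: CausalForest, x) -> ForestWeights:
    """Adaptive-neighborhood weights alpha_i(x) for one query point.

    alpha_i(x) averages, over trees, the indicator that record i shares
    x's leaf estimation set, normalized by that set's size; trees whose
    leaf at x has an empty estimation set are skipped.
    """
    xq = np.asarray(x, dtype=float).reshape(1, -1)
    if xq.shape[1] != forest.X.shape[1]:
        raise ValueError("query point has wrong number of covariates")
    raw = np.zeros(forest.n)
    used = 0
    for tree in forest.trees:
        leaf = tree.leaves[tree.assign_leaves(xq)[0]]
        if len(leaf.est_idx) == 0:
            continue
        raw[leaf.est_idx] += 1.0 / len(leaf.est_idx)
        used += 1
    if used == 0:
        raise ValueError("no tree produced a nonempty estimation leaf for this point")
    alpha = raw / raw.sum()
    return ForestWeights(alpha=alpha)


def predict_cate(
    forest: CausalForest,
    X=None,
    nuisance: NuisanceEstimates | None = None,
    den_tol: float = 1e-12,
) -> np.ndarray:
    """Forest CATE tau_hat(x): the alpha-weighted residual-on-residual ratio.

    Equivalent to evaluating the weighted estimator with
    :func:`forest_weights`, but computed from per-leaf sufficient
    statistics so the full training sample can be scored quickly.
    ``X=None`` scores the training records themselves (the per-unit CITEs).
    """
    nus = nuisance or forest.nuisance
    cross = nus.w_res * nus.y_res
    den = nus.w_res**2
    if X is None:
        Xq = forest.X
    else:
        Xq, _ = _as_matrix(X)
    num_acc = np.zeros(len(Xq))
    den_acc = np.zeros(len(Xq))
    for tree in forest.trees:
        leaf_ids = tree.assign_leaves(Xq)
        mc = np.array([lf.mean_cross for lf in tree.leaves])
        md = np.array([lf.mean_den for lf in tree.leaves])
        num_acc += mc[leaf_ids]
        den_acc += md[leaf_ids]
    if np.any(den_acc <= den_tol):
        raise ValueError("weighted treatment-residual mass vanishes at some query point")
    return num_acc / den_acc


def predict_cate_from_weights(forest: CausalForest, x) -> float:
    """Explicit-weights evaluation of the forest CATE (slow reference path)."""
    alpha = forest_weights(forest, x).alpha
    num = float(np.sum(alpha * forest.w_res * forest.y_res))
    den = float(np.sum(alpha * forest.w_res**2))
    if den <= 1e-12:
        raise ValueError("weighted treatment-residual mass vanishes at this point")
    return num / den


# ---------------------------------------------------------------------------
# importance, screening, two-stage fit


def variable_importance(forest: CausalForest, max_depth: int = 4, decay: float = 2.0) -> pd.DataFrame:
    """Split-frequency importance, discounted by depth.

    Each internal node at depth d (root = 1, counted up to ``max_depth``)
    contributes decay^(-d) to its split variable; scores are normalized to
    sum to one and ranked.
    """
    scores = np.zeros(len(forest.feature_names))
    for tree in forest.trees:
        for feat, depth in tree.split_features():
            if depth <= max_depth:
                scores[feat] += decay ** (-depth)
    total = scores.sum()
    if total == 0:
        warnings.warn("forest has no splits: importance is all zero")
    else:
        scores = scores / total
    out = pd.DataFrame({"covariate": forest.feature_names, "importance": scores})
    out["rank"] = out["importance"].rank(ascending=False, method="first").astype(int)
    return out.sort_values("rank").reset_index(drop=True)


def select_covariates(importance_table: pd.DataFrame) -> list[str]:
    """Covariates whose importance strictly exceeds the mean (1/p); if the
    scores are all equal, keep everything."""
    if len(importance_table) == 0:
        raise ValueError("importance table is empty")
    imp = importance_table["importance"]
    mean = imp.mean()
    selected = importance_table.loc[imp > mean, "covariate"].tolist()
    if not selected:
        return importance_table["covariate"].tolist()
    return selected


EDUCATION_LABELS = {
    1: "no_formal_education",
    2: "primary_school",
    3: "junior_high_school",
    4: "high_school",
    5: "junior_college",
    6: "bachelor_degree",
    7: "master",
}
REGION_LABELS = {1: "eastern", 2: "central", 3: "western"}


def forest_design(dataset: pd.DataFrame) -> pd.DataFrame:
    """One-hot design matrix for the forest.

    Categorical covariates (mother's education, region, wealth quintile)
    enter as level dummies; ages and log income stay numeric; residence is
    encoded as a rural dummy.
    """
    d = {}
    d["child_gender_male"] = dataset["child_gender"].astype(float)
    d["child_age"] = dataset["child_age"].astype(float)
    d["mother_age"] = dataset["mother_age"].astype(float)
    for lvl, lab in EDUCATION_LABELS.items():
        d[f"mother_edu_{lab}"] = (dataset["mother_education"] == lvl).astype(float)
    d["log_income_pc"] = dataset["log_income_pc"].astype(float)
    d["living_area_rural"] = (dataset["living_area"] == 0).astype(float)
    for lvl, lab in REGION_LABELS.items():
        d[f"region_{lab}"] = (dataset["region"] == lvl).astype(float)
    for q in range(1, 6):
        d[f"wealth_q{q}"] = (dataset["wealth_quintile"] == q).astype(float)
    return pd.DataFrame(d, index=dataset.index)


def tune_forest_params(
    X, Y, W,
    min_leaf_grid=(5, 10),
    mtry_grid=(None,),
    n_trees_tune: int = 50,
    seed: int = 0,
    nuisance: NuisanceEstimates | None = None,
) -> ForestParams:
    """Small grid search over (min_leaf, mtry) scored by the R-learner loss
    mean((y_res - tau_hat(x) w_res)^2) on out-of-bag-style CITEs."""
    best_loss, best = np.inf, None
    rng = np.random.default_rng(seed)
    base_seed = int(rng.integers(2**31))
    for ml in min_leaf_grid:
        for mt in mtry_grid:
            params = ForestParams(n_trees=n_trees_tune, min_leaf=ml, mtry=mt)
            try:
                f = fit_causal_forest(X, Y, W, params, seed=base_seed, nuisance=nuisance)
            except ValueError:
                continue
            nuisance = f.nuisance
            tau = predict_cate(f)
            loss = float(np.mean((f.y_res - tau * f.w_res) ** 2))
            if loss < best_loss:
                best_loss, best = loss, params
    if best is None:
        raise ValueError("no admissible parameter combination in the grid")
    return best


@dataclass
class TwoStageResult:
    stage1: CausalForest
    importance: pd.DataFrame
    selected: list[str]
    stage2: CausalForest
    cite: np.ndarray  # per-record CITE from the stage-2 forest


def two_stage_fit(
    dataset: pd.DataFrame,
    outcome: str = "outcome",
    stage1_trees: int = 200,
    stage2_trees: int = 500,
    params: ForestParams | None = None,
    seed: int = 0,
    tune: bool = False,
    design: pd.DataFrame | None = None,
) -> TwoStageResult:
    """Screen-and-refit: stage-1 forest on all covariates, keep the
    above-mean-importance covariates, regrow the forest on them."""
    Xd = design if design is not None else forest_design(dataset)
    Y = dataset[outcome].to_numpy(float)
    W = dataset["treatment"].to_numpy(int)
    rng = np.random.default_rng(seed)
    base = params or ForestParams()

    p1 = ForestParams(**{**base.__dict__, "n_trees": stage1_trees})
    stage1 = fit_causal_forest(Xd, Y, W, p1, seed=int(rng.integers(2**31)))
    imp = variable_importance(stage1)
    selected = select_covariates(imp)

    # stage 2 restricts only the trees to the screened covariates; the
    # nuisances keep the full covariate set (they adjust for confounding,
    # which screening must not undo)
    X2 = Xd[selected]
    nuisance = stage1.nuisance
    if tune:
        tuned = tune_forest_params(
            X2, Y, W, seed=int(rng.integers(2**31)), nuisance=nuisance
        )
        p2 = ForestParams(**{**tuned.__dict__, "n_trees": stage2_trees})
    else:
        p2 = ForestParams(**{**base.__dict__, "n_trees": stage2_trees})
    stage2 = fit_causal_forest(X2, Y, W, p2, seed=int(rng.integers(2**31)), nuisance=nuisance)
    cite = predict_cate(stage2)
    return TwoStageResult(stage1=stage1, importance=imp, selected=selected, stage2=stage2, cite=cite)


# ---------------------------------------------------------------------------
# CITE distribution, subgroups, profiling


@dataclass
class CiteSummary:
    interval: tuple[float, float]  # 2.5th-97.5th percentile, 3 decimals
    verdict: str
    histogram: pd.DataFrame
    mean: float
    sd: float


def cite_distribution_summary(
    cite_values, bins: int = 20, rule: str = "sign-varying"
) -> CiteSummary:
    """Empirical 95% interval of the CITE distribution plus a verdict.

    ``rule='sign-varying'`` (default) declares heterogeneity when the
    interval straddles zero, reading the interval as evidence that the
    per-unit effects change sign.  ``rule='conventional'`` inverts the
    call: an interval excluding zero is read as a uniformly signed,
    hence detectably nonzero, effect.
    """
    cite = np.asarray(cite_values, float)
    if len(cite) < 2:
        raise ValueError("need at least 2 CITE values")
    lo, hi = np.quantile(cite, [0.025, 0.975])
    counts, edges = np.histogram(cite, bins=bins)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    straddles = lo < 0 < hi
    if rule == "sign-varying":
        verdict = "heterogeneous (sign-varying)" if straddles else "homogeneous-sign"
    elif rule == "conventional":
        verdict = "effect indistinguishable from zero" if straddles else "uniformly signed effect"
    else:
        raise ValueError(f"unknown verdict rule {rule!r}")
    return CiteSummary(
        interval=(round(float(lo), 3), round(float(hi), 3)),
        verdict=verdict,
        histogram=hist,
        mean=float(cite.mean()),
        sd=float(cite.std(ddof=1)) if len(cite) > 1 else 0.0,
    )


@dataclass
class SubgroupEffect:
    subgroup: str
    estimand: str  # CATC | CATE
    estimate: float
    se: float
    n: int


def subgroup_effect(
    cite_values, W, subgroup_mask, estimand: str = "CATC", label: str = ""
) -> SubgroupEffect:
    """Average CITE within a subgroup.

    CATC (default) averages over the subgroup's control units, matching
    the convention of reporting effects for the uninsured; CATE averages
    over all subgroup members.  SE is the naive sd/sqrt(n) of the averaged
    CITEs — not a calibrated forest variance.
    """
    cite = np.asarray(cite_values, float)
    w = np.asarray(W)
    mask = np.asarray(subgroup_mask, bool)
    if not mask.any():
        raise ValueError("subgroup is empty")
    if estimand == "CATC":
        sel = mask & (w == 0)
        if not sel.any():
            raise ValueError("no control units in subgroup: CATC undefined")
    elif estimand == "CATE":
        sel = mask
    else:
        raise ValueError(f"unknown estimand {estimand!r}")
    vals = cite[sel]
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return SubgroupEffect(
        subgroup=label, estimand=estimand, estimate=float(vals.mean()), se=se, n=int(len(vals))
    )


def median_split_profile(cite_values, covariates: pd.DataFrame) -> pd.DataFrame:
    """Covariate means for above- vs below-median CITE halves.

    Records at the median go to the lower half; each covariate row carries
    a Welch t-test of the between-half gap.
    """
    cite = np.asarray(cite_values, float)
    if len(cite) < 4:
        raise ValueError("need at least 4 records")
    med = np.median(cite)
    lower = cite <= med
    if lower.all() or not lower.any():
        raise ValueError("CITE values are constant: no median split possible")
    rows = []
    for c in covariates.columns:
        x = covariates[c].to_numpy(float)
        res = welch_t_test(x[~lower], x[lower])
        rows.append(
            {
                "covariate": c,
                "mean_above_median": x[~lower].mean(),
                "mean_below_median": x[lower].mean(),
                "gap": x[~lower].mean() - x[lower].mean(),
                "t": res.t,
                "p": res.p,
                "stars": res.stars,
            }
        )
    return pd.DataFrame(rows)
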