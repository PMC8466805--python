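"""Propensity-score matching: logit propensity, common support, matching, ATT.

The enrollment propensity P(W=1|x) is estimated by a maximum-likelihood
logit fitted with iteratively reweighted least squares.  Treated units are
matched to controls on the one-dimensional propensity score (nearest
neighbor with k=1 or k=4, or Epanechnikov kernel weighting with bandwidth
0.06 by default), inside the common-support interval, and the average
treatment effect on the treated is

    ATT = mean over treated of ( Y_i - sum_j w_ij Y_j )

with nonparametric-bootstrap standard errors (full re-estimation inside
each resample).  Matching is with replacement by default: controls are a
small minority (~14%) of the cohort, so sampling without replacement would
exhaust the pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .descriptives import stars_from_p
from scipy import stats


class SeparationError(RuntimeError):
    """Raised when the logit MLE diverges (perfectly separated arms)."""


# ---------------------------------------------------------------------------
# propensity model


@dataclass
class PropensityModel:
    coefficients: pd.Series  # index: "intercept" + covariate names
    converged: bool
    n_iter: int
    log_likelihood: float
    columns: list[str]

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        X = _design(covariates, self.columns)
        return X @ self.coefficients.to_numpy()


@dataclass
class PropensityScores:
    score: np.ndarray
    in_support: np.ndarray | None = None  # set by common_support

    def __len__(self) -> int:
        return len(self.score)


def _design(covariates: pd.DataFrame, columns: list[str]) -> np.ndarray:
    missing = [c for c in columns if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate columns missing: {missing}")
    return np.column_stack(
        [np.ones(len(covariates))] + [covariates[c].to_numpy(float) for c in columns]
    )


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the dependent columns via incremental rank of column prefixes
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j - 1])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_propensity_logit(
    covariates: pd.DataFrame,
    W,
    columns: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PropensityModel:
    """Maximum-likelihood logit of enrollment on covariates via IRLS.

    Converges when the largest coefficient change drops below ``tol``.
    Raises :class:`SeparationError` on diverging coefficients (perfect
    separation) and ``ValueError`` on a rank-deficient design, naming the
    collinear columns.
    """
    w = np.asarray(W, dtype=float)
    if set(np.unique(w)) - {0.0, 1.0}:
        raise ValueError("W must be binary 0/1")
    if w.min() == w.max():
        raise ValueError("W has no variation: cannot fit a propensity model")
    if columns is None:
        columns = [c for c in covariates.columns if c not in ("cohort", "treatment", "outcome")]
    X = _design(covariates, columns)
    _check_full_rank(X, columns)

    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        v = np.clip(p * (1.0 - p), 1e-10, None)
        z = eta + (w - p) / v
        XtW = X.T * v
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"IRLS normal equations singular at iter {it}") from exc
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.max(np.abs(beta)) > 1e2:
            raise SeparationError("coefficients diverging: data likely perfectly separated")
        if delta < tol:
            converged = True
            break
    if not converged and np.all(np.abs(w - expit(X @ beta)) < 1e-3):
        # likelihood keeps improving toward a perfect classifier: no MLE exists
        raise SeparationError("coefficients diverging: data likely perfectly separated")
    eta = X @ beta
    ll = float(np.sum(w * eta - np.log1p(np.exp(np.clip(eta, None, 700)))))
    return PropensityModel(
        coefficients=pd.Series(beta, index=["intercept"] + list(columns)),
        converged=converged,
        n_iter=it,
        log_likelihood=ll,
        columns=list(columns),
    )


def predict_propensity(model: PropensityModel, covariates: pd.DataFrame) -> PropensityScores:
    """Fitted enrollment probabilities inv-logit(x'beta)."""
    if not model.converged:
        raise ValueError("propensity model did not converge")
    return PropensityScores(score=expit(model.linear_predictor(covariates)))


# ---------------------------------------------------------------------------
# support and matching


def common_support(scores: PropensityScores | np.ndarray, W) -> tuple[tuple[float, float], np.ndarray]:
    """Overlap interval of the two arms' score ranges, plus per-record flags.

    interval = [max(min treated, min control), min(max treated, max control)];
    records outside are flagged False and excluded from matching.
    """
    s = scores.score if isinstance(scores, PropensityScores) else np.asarray(scores, float)
    w = np.asarray(W)
    if (w == 1).sum() == 0 or (w == 0).sum() == 0:
        raise ValueError("both arms must be nonempty")
    lo = max(s[w == 1].min(), s[w == 0].min())
    hi = min(s[w == 1].max(), s[w == 0].max())
    if lo > hi:
        raise ValueError("empty common-support interval")
    flags = (s >= lo) & (s <= hi)
    if isinstance(scores, PropensityScores):
        scores.in_support = flags
    return (float(lo), float(hi)), flags


@dataclass
class MatchResult:
    method: str  # nn_1 | nn_k | kernel
    matches: dict[int, list[tuple[int, float]]]  # treated idx -> [(control idx, weight)]
    k: int | None = None
    bandwidth: float | None = None
    n_dropped: int = 0
    support: tuple[float, float] | None = None

    @property
    def treated_indices(self) -> list[int]:
        return list(self.matches)

    def control_weight_totals(self, n: int) -> np.ndarray:
        """Total matching weight each of the n records receives as a control."""
        w = np.zeros(n)
        for pairs in self.matches.values():
            for j, wt in pairs:
                w[j] += wt
        return w


def nn_match(
    scores: PropensityScores | np.ndarray,
    W,
    k: int = 1,
    with_replacement: bool = True,
    support_flags: np.ndarray | None = None,
) -> MatchResult:
    """k-nearest-neighbor matching on |p_t - p_c| with weights 1/k.

    Ties are broken toward the lowest record index.  Matching is with
    replacement by default; without replacement controls are consumed
    greedily in treated-index order.
    """
    s = scores.score if isinstance(scores, PropensityScores) else np.asarray(scores, float)
    w = np.asarray(W)
    flags = support_flags
    if flags is None and isinstance(scores, PropensityScores) and scores.in_support is not None:
        flags = scores.in_support
    if flags is None:
        flags = np.ones(len(s), dtype=bool)
    treated = np.where((w == 1) & flags)[0]
    controls = np.where((w == 0) & flags)[0]
    if len(controls) < k:
        raise ValueError(f"k={k} exceeds the in-support control pool ({len(controls)})")
    matches: dict[int, list[tuple[int, float]]] = {}
    available = set(controls.tolist())
    for i in treated:
        pool = controls if with_replacement else np.array(sorted(available), dtype=int)
        if len(pool) < k:
            break
        d = np.abs(s[pool] - s[i])
        # stable sort on (distance, index): lowest index wins exact ties
        order = np.lexsort((pool, d))
        chosen = pool[order[:k]]
        matches[int(i)] = [(int(j), 1.0 / k) for j in chosen]
        if not with_replacement:
            available -= set(chosen.tolist())
    return MatchResult(method="nn_1" if k == 1 else "nn_k", matches=matches, k=k)


def epanechnikov(u: np.ndarray) -> np.ndarray:
    """K(u) = 0.75 (1 - u^2) on |u| < 1, else 0."""
    u = np.asarray(u, dtype=float)
    return np.where(np.abs(u) < 1.0, 0.75 * (1.0 - u**2), 0.0)


def gaussian_kernel(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * np.asarray(u, float) ** 2) / np.sqrt(2 * np.pi)


_KERNELS = {"epanechnikov": epanechnikov, "gaussian": gaussian_kernel}


def kernel_match_weights(
    scores: PropensityScores | np.ndarray,
    W,
    bandwidth: float = 0.06,
    kernel: str = "epanechnikov",
    support_flags: np.ndarray | None = None,
) -> MatchResult:
    """Kernel matching: control j gets weight K((p_i - p_j)/h), normalized.

    Treated units with zero total kernel mass (no control within the
    kernel's reach) are dropped with a warning; the drop count is recorded.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    K = _KERNELS[kernel]
    s = scores.score if isinstance(scores, PropensityScores) else np.asarray(scores, float)
    w = np.asarray(W)
    flags = support_flags
    if flags is None and isinstance(scores, PropensityScores) and scores.in_support is not None:
        flags = scores.in_support
    if flags is None:
        flags = np.ones(len(s), dtype=bool)
    treated = np.where((w == 1) & flags)[0]
    controls = np.where((w == 0) & flags)[0]
    if len(controls) == 0:
        raise ValueError("no in-support controls")
    matches: dict[int, list[tuple[int, float]]] = {}
    n_dropped = 0
    kw = K((s[treated][:, None] - s[controls][None, :]) / bandwidth)
    for row, i in enumerate(treated):
        mass = kw[row].sum()
        if mass <= 0:
            n_dropped += 1
            continue
        wts = kw[row] / mass
        nz = np.nonzero(wts)[0]
        matches[int(i)] = [(int(controls[j]), float(wts[j])) for j in nz]
    if n_dropped:
        warnings.warn(f"kernel matching dropped {n_dropped} treated unit(s) with zero kernel mass")
    return MatchResult(method="kernel", matches=matches, bandwidth=bandwidth, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# effects


@dataclass
class EffectEstimate:
    estimand: str  # ATE | ATT | ATC
    value: float
    se: float | None = None
    stars: str = ""
    n_treated: int = 0
    n_control_used: int = 0

    def with_se(self, se: float, star_thresholds=(0.01, 0.05, 0.05)) -> "EffectEstimate":
        """Attach a standard error and normal-approximation stars (** 5%, *** 1%)."""
        if se < 0:
            raise ValueError("SE must be >= 0")
        p = 2 * (1 - stats.norm.cdf(abs(self.value) / se)) if se > 0 else 0.0
        return EffectEstimate(
            estimand=self.estimand,
            value=self.value,
            se=se,
            stars=stars_from_p(p, star_thresholds),
            n_treated=self.n_treated,
            n_control_used=self.n_control_used,
        )


def estimate_att(match_result: MatchResult, Y, W) -> EffectEstimate:
    """ATT from matched sets: mean over treated of Y_i minus its weighted controls."""
    y = np.asarray(Y, dtype=float)
    if not match_result.matches:
        raise ValueError("no treated units matched")
    diffs = []
    controls_used: set[int] = set()
    for i, pairs in match_result.matches.items():
        wt = np.array([p[1] for p in pairs])
        cj = np.array([p[0] for p in pairs], dtype=int)
        diffs.append(y[i] - float(wt @ y[cj]))
        controls_used.update(cj.tolist())
    return EffectEstimate(
        estimand="ATT",
        value=float(np.mean(diffs)),
        n_treated=len(diffs),
        n_control_used=len(controls_used),
    )


def naive_difference(Y, W) -> float:
    """Unadjusted treated-minus-control mean difference (biased under confounding)."""
    y = np.asarray(Y, float)
    w = np.asarray(W)
    return float(y[w == 1].mean() - y[w == 0].mean())


def matched_att(
    dataset: pd.DataFrame,
    outcome: str = "outcome",
    method: str = "kernel",
    k: int = 1,
    bandwidth: float = 0.06,
    kernel: str = "epanechnikov",
    columns: list[str] | None = None,
) -> EffectEstimate:
    """Full PSM pipeline on one dataset: logit -> support -> match -> ATT."""
    W = dataset["treatment"].to_numpy()
    model = fit_propensity_logit(dataset, W, columns=columns)
    scores = predict_propensity(model, dataset)
    _, flags = common_support(scores, W)
    if method == "kernel":
        mr = kernel_match_weights(scores, W, bandwidth=bandwidth, kernel=kernel, support_flags=flags)
    else:
        mr = nn_match(scores, W, k=k, support_flags=flags)
    return estimate_att(mr, dataset[outcome].to_numpy(), W)


def bootstrap_se(
    dataset: pd.DataFrame,
    estimator,
    B: int = 200,
    seed: int = 0,
    max_failure_rate: float = 0.10,
) -> float:
    """Nonparametric bootstrap SE of ``estimator(resampled dataset) -> float``.

    Each resample redraws records with replacement and re-runs the full
    estimator (propensity refit, re-matching).  Raises if more than
    ``max_failure_rate`` of resamples fail.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    values, failures = [], []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = dataset.iloc[idx].reset_index(drop=True)
        try:
            values.append(float(estimator(boot)))
        except Exception as exc:  # noqa: BLE001 - diagnostics collected below
            failures.append(repr(exc))
    if len(failures) > max_failure_rate * B:
        raise RuntimeError(
            f"estimator failed on {len(failures)}/{B} resamples; first: {failures[0]}"
        )
    return float(np.std(values, ddof=1))


# ---------------------------------------------------------------------------
# diagnostics


def balance_check(
    covariates: pd.DataFrame,
    W,
    match_result: MatchResult,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Standardized mean differences before and after matching.

    std diff = (mean_T - mean_C) / sqrt((var_T + var_C)/2), with the
    pre-matching pooled SD used as the scale for both rows so the before
    and after columns are comparable.  Post-matching uses matched treated
    units and weight-aggregated controls.
    """
    w = np.asarray(W)
    if columns is None:
        columns = [c for c in covariates.columns if c not in ("cohort", "treatment", "outcome")]
    treated_matched = np.array(match_result.treated_indices, dtype=int)
    cw = match_result.control_weight_totals(len(covariates))
    rows = []
    for c in columns:
        x = covariates[c].to_numpy(float)
        vt, vc = x[w == 1].var(ddof=1), x[w == 0].var(ddof=1)
        pooled = np.sqrt((vt + vc) / 2.0)
        if pooled == 0:
            warnings.warn(f"covariate {c!r} has zero pooled variance; skipped")
            continue
        pre = (x[w == 1].mean() - x[w == 0].mean()) / pooled
        post_t = x[treated_matched].mean()
        post_c = float(np.average(x, weights=cw)) if cw.sum() > 0 else np.nan
        post = (post_t - post_c) / pooled
        rows.append({"covariate": c, "std_diff_pre": pre, "std_diff_post": post})
    return pd.DataFrame(rows)


def propensity_histogram(
    scores: PropensityScores | np.ndarray, W, bins: int = 20
) -> pd.DataFrame:
    """Binned score counts per arm — the overlap figure's plot data."""
    s = scores.score if isinstance(scores, PropensityScores) else np.asarray(scores, float)
    w = np.asarray(W)
    edges = np.linspace(0.0, 1.0, bins + 1)
    t_counts, _ = np.histogram(s[w == 1], bins=edges)
    c_counts, _ = np.histogram(s[w == 0], bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "treated_count": t_counts,
            "control_count": c_counts,
        }
    )
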