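"""Synthetic confounded child-cohort generator with known ground truth.

Every record carries both potential outcomes, so downstream estimators
(matching ATT, causal-forest CATE) can be validated against the truth:

    y0 = f(x) + eps,   y1 = y0 + tau(x),   Y = W*y1 + (1-W)*y0   (exactly)

Enrollment W is a Bernoulli draw from a logit in the covariates, which makes
the naive treated-minus-control mean difference biased while matching and
orthogonalized forests remain consistent.

Each stage (covariates, treatment, outcomes) runs on its own RNG stream
derived from the master seed by fixed sub-seeding, so stages are
independently reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import COVARIATES, MODIFIERS, SLOPE_CENTERS, EffectSpec, SimConfig

# fixed sub-seed offsets for per-stage RNG streams
_STAGE_OFFSET = {"covariates": 1, "treatment": 2, "outcomes": 3}

TRUTH_COLUMNS = ["y0", "y1", "tau_true", "p_select"]


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STAGE_OFFSET[stage])))


def generate_covariates(config: SimConfig) -> pd.DataFrame:
    """Draw the covariate table (no treatment, no outcome).

    Preschool records (ages 0-5) come first, then school-age (6-16); a
    ``cohort`` tag column records the split.  Deterministic given
    ``config.seed``.
    """
    rng = _stage_rng(config.seed, "covariates")
    p = config.covariate_params
    n = config.n_total
    n_pre = int(round(config.cohort_split * n))

    child_age = np.concatenate(
        [rng.integers(0, 6, size=n_pre), rng.integers(6, 17, size=n - n_pre)]
    ).astype(float)
    cohort = np.array(["preschool"] * n_pre + ["school_age"] * (n - n_pre))

    child_gender = (rng.random(n) < p["male_share"]).astype(int)
    birth_age = rng.normal(p["mother_birth_age_mean"], p["mother_birth_age_sd"], n)
    lo, hi = p["mother_age_range"]
    mother_age = np.clip(child_age + birth_age, lo, hi)
    edu_probs = np.asarray(p["education_probs"], dtype=float)
    edu_probs = edu_probs / edu_probs.sum()
    mother_education = rng.choice(np.arange(1, 8), size=n, p=edu_probs)
    log_income = rng.normal(p["log_income_mean"], p["log_income_sd"], n)
    living_area = (rng.random(n) < p["urban_share"]).astype(int)
    reg_probs = np.asarray(p["region_probs"], dtype=float)
    reg_probs = reg_probs / reg_probs.sum()
    region = rng.choice(np.arange(1, 4), size=n, p=reg_probs)

    # wealth quintile: within-sample quintile rank of income plus jitter,
    # a documented stand-in for an unobserved wealth index
    score = log_income + rng.normal(0.0, p["wealth_jitter_sd"], n)
    wealth_quintile = (
        pd.qcut(pd.Series(score).rank(method="first"), 5, labels=False).to_numpy() + 1
    )

    df = pd.DataFrame(
        {
            "child_gender": child_gender,
            "child_age": child_age,
            "mother_age": mother_age,
            "mother_education": mother_education,
            "log_income_pc": log_income,
            "living_area": living_area,
            "region": region,
            "wealth_quintile": wealth_quintile,
            "cohort": cohort,
        }
    )
    return df


def assign_treatment(
    covariates: pd.DataFrame,
    selection_coefs: np.ndarray | list[float],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw enrollment W_i ~ Bernoulli(inv-logit(beta . [1, x_i])).

    Returns ``(W, p_select)``.  ``selection_coefs`` is intercept-first,
    followed by the covariates in :data:`childhte.config.COVARIATES` order.
    """
    beta = np.asarray(selection_coefs, dtype=float)
    X = np.column_stack(
        [np.ones(len(covariates))] + [covariates[c].to_numpy(float) for c in COVARIATES]
    )
    if X.shape[1] != beta.shape[0]:
        raise ValueError(
            f"selection_coefs has length {beta.shape[0]}, expected {X.shape[1]} "
            "(intercept + covariates)"
        )
    p_select = expit(X @ beta)
    rng = _stage_rng(seed, "treatment")
    W = (rng.random(len(covariates)) < p_select).astype(int)
    return W, p_select


def true_cate(covariates: pd.DataFrame, effect_spec: EffectSpec) -> np.ndarray:
    """Evaluate the ground-truth tau(x) on each record."""
    tau = np.full(len(covariates), effect_spec.tau0, dtype=float)
    for name, inc in effect_spec.increments.items():
        mask = covariates.eval(MODIFIERS[name]).to_numpy()
        tau = tau + inc * mask
    for cov, slope in effect_spec.slopes.items():
        tau = tau + slope * (covariates[cov].to_numpy(float) - SLOPE_CENTERS[cov])
    return tau


def _baseline_f(covariates: pd.DataFrame, f_coefs: dict[str, float]) -> np.ndarray:
    age = covariates["child_age"].to_numpy(float)
    return (
        f_coefs.get("intercept", 0.0)
        + f_coefs.get("mother_education", 0.0)
        * (covariates["mother_education"].to_numpy(float) - 3.0)
        + f_coefs.get("log_income_pc", 0.0)
        * (covariates["log_income_pc"].to_numpy(float) - 9.0)
        + f_coefs.get("child_age", 0.0) * age
        + f_coefs.get("child_age_sq", 0.0) * age**2
    )


def simulate_outcomes(
    covariates: pd.DataFrame,
    treatment: np.ndarray,
    effect_spec: EffectSpec,
    noise_sd: float,
    seed: int,
    f_coefs: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Realize outcomes under a partially linear model Y = f(x) + W tau(x) + eps.

    Returns ``(dataset, truth)`` where ``dataset`` is the covariate table with
    ``treatment`` and ``outcome`` columns appended and ``truth`` holds the
    per-record potential outcomes ``y0``/``y1``, ``tau_true`` and (if present
    on input) the selection probability.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    f_coefs = f_coefs if f_coefs is not None else {"mother_education": 0.25, "log_income_pc": 0.35, "child_age": -0.02}
    W = np.asarray(treatment, dtype=int)
    rng = _stage_rng(seed, "outcomes")
    eps = rng.normal(0.0, noise_sd, len(covariates)) if noise_sd > 0 else np.zeros(len(covariates))
    tau = true_cate(covariates, effect_spec)
    y0 = _baseline_f(covariates, f_coefs) + eps
    y1 = y0 + tau
    Y = np.where(W == 1, y1, y0)

    dataset = covariates.copy()
    dataset["treatment"] = W
    dataset["outcome"] = Y
    truth = pd.DataFrame({"y0": y0, "y1": y1, "tau_true": tau}, index=covariates.index)
    return dataset, truth


def generate_dataset(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full draw: covariates -> confounded enrollment -> outcomes.

    Returns ``(dataset, truth)``; ``truth`` includes ``p_select``.
    """
    cov = generate_covariates(config)
    W, p_select = assign_treatment(cov, config.selection_coefs, config.seed)
    dataset, truth = simulate_outcomes(
        cov, W, config.effect_spec, config.noise_sd, config.seed, config.f_coefs
    )
    truth["p_select"] = p_select
    return dataset, truth


def write_dataset(
    dataset: pd.DataFrame,
    path: str | Path,
    truth: pd.DataFrame | None = None,
    seed: int | None = None,
) -> None:
    """Write the cohort (and optional truth table) as CSV, recording the seed."""
    path = Path(path)
    dataset.to_csv(path, index=False)
    if truth is not None:
        truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    meta = {"seed": seed, "n": int(len(dataset)), "columns": list(dataset.columns)}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_dataset(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
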