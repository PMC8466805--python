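"""Configuration objects for the synthetic cohort generator and the pipeline.

The generator emulates a rural-child insurance cohort: ~5552 children, ~86%
enrolled in resident basic medical insurance, enrollment confounded with
mother's age/education, household income, region and urban residence, and
anthropometric outcomes (WHZ/WAZ/HAZ z-scores for ages 0-5, BMI for 6-16)
carrying a configurable heterogeneous treatment effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

#: covariate column order used everywhere (design matrices, selection logit)
COVARIATES = [
    "child_gender",
    "child_age",
    "mother_age",
    "mother_education",
    "log_income_pc",
    "living_area",
    "region",
    "wealth_quintile",
]

#: binary effect modifiers the generator understands (name -> predicate description)
MODIFIERS = {
    "rural": "living_area == 0",
    "urban": "living_area == 1",
    "male": "child_gender == 1",
    "female": "child_gender == 0",
    "low_mother_education": "mother_education <= 2",
    "high_mother_education": "mother_education >= 5",
    "older_mother": "mother_age >= 35",
    "low_income": "log_income_pc < 9.0",
    "poorest_wealth": "wealth_quintile == 1",
    "western": "region == 3",
}

#: centering constants for continuous effect slopes (roughly cohort means)
SLOPE_CENTERS = {
    "child_age": 8.0,
    "mother_age": 34.0,
    "mother_education": 3.0,
    "log_income_pc": 9.0,
    "wealth_quintile": 3.0,
}


@dataclass
class EffectSpec:
    """Heterogeneous treatment-effect specification tau(x).

    tau(x) = tau0 + sum of increments over the binary modifiers that hold
    at x + sum of slope * (covariate - center) terms.

    ``increments`` keys may be written either as the modifier name ("rural")
    or with an "_increment" suffix ("rural_increment").
    """

    tau0: float = 0.15
    increments: dict[str, float] = field(default_factory=dict)
    slopes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for key, val in self.increments.items():
            name = key.removesuffix("_increment")
            if name not in MODIFIERS:
                raise ValueError(
                    f"unknown effect modifier {key!r}; known: {sorted(MODIFIERS)}"
                )
            norm[name] = float(val)
        self.increments = norm
        for key in self.slopes:
            if key not in SLOPE_CENTERS:
                raise ValueError(
                    f"unknown slope covariate {key!r}; known: {sorted(SLOPE_CENTERS)}"
                )


# Selection-logit coefficients: intercept followed by COVARIATES order.
# Negative loadings on income and urban residence, positive on mother's age
# and child's age: enrolled children are older, poorer, with older and less
# educated mothers.  The intercept is calibrated so the default covariate
# mix yields an enrollment share of ~0.857 (4760 of 5552).
DEFAULT_SELECTION_COEFS = [
    4.240,   # intercept (calibrated)
    0.0,     # child_gender
    0.05,    # child_age
    0.03,    # mother_age
    -0.15,   # mother_education
    -0.35,   # log_income_pc
    -0.50,   # living_area (urban)
    0.0,     # region
    0.0,     # wealth_quintile
]

#: baseline outcome surface f(x), linear with documented coefficients
DEFAULT_F_COEFS = {
    "intercept": 0.0,
    "mother_education": 0.25,
    "log_income_pc": 0.35,
    "child_age": -0.02,
    "child_age_sq": 0.0,  # optional curvature
}

DEFAULT_COVARIATE_PARAMS: dict[str, Any] = {
    "male_share": 0.53,
    "mother_birth_age_mean": 27.0,
    "mother_birth_age_sd": 5.0,
    "mother_age_range": (16.0, 55.0),
    "education_probs": (0.12, 0.30, 0.33, 0.13, 0.06, 0.05, 0.01),
    "log_income_mean": 9.0,
    "log_income_sd": 0.95,
    "urban_share": 0.35,
    "region_probs": (0.30, 0.35, 0.35),
    "wealth_jitter_sd": 0.30,
}


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort draw."""

    n_total: int = 5552
    cohort_split: float = 0.363  # preschool (ages 0-5) fraction; rest school-age 6-16
    covariate_params: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    selection_coefs: list[float] = field(default_factory=lambda: list(DEFAULT_SELECTION_COEFS))
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    f_coefs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_F_COEFS))
    noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if not 0.0 <= self.cohort_split <= 1.0:
            raise ValueError("cohort_split must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        params = dict(DEFAULT_COVARIATE_PARAMS)
        params.update(self.covariate_params)
        self.covariate_params = params
        if params["mother_birth_age_sd"] < 0:
            raise ValueError("mother_birth_age_sd must be >= 0")
        if params["log_income_sd"] < 0:
            raise ValueError("log_income_sd must be >= 0")
        if isinstance(self.effect_spec, dict):
            self.effect_spec = EffectSpec(**self.effect_spec)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
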