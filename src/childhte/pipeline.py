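"""End-to-end study replica and parameter-recovery experiment.

``run_full_analysis`` drives one synthetic (or CSV) cohort through the full
chain — descriptives, propensity-score matching for every cohort-appropriate
outcome, and the two-stage honest causal forest per cohort — writing the
tabular artifacts and a JSON manifest.  Preschool (ages 0-5, outcomes
WHZ/WAZ/HAZ) and school-age (6-16, outcome BMI) cohorts are analyzed as
independent runs, never pooled.

``parameter_recovery_experiment`` replays the generator with fresh seeds and
scores every estimator against the known ground truth (bias/RMSE of the ATT
estimators, CITE-level RMSE, subgroup-contrast recovery).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import COVARIATES, MODIFIERS, EffectSpec, SimConfig
from . import descriptives, matching, forest as cf
from .synthetic import (
    assign_treatment,
    generate_covariates,
    simulate_outcomes,
    true_cate,
)

PRESCHOOL_OUTCOMES = ["whz", "waz", "haz"]
SCHOOL_OUTCOMES = ["bmi"]

#: BMI baseline surface for the school-age cohort: mean near 18.3, rising
#: with age, mildly with income/education; noise sd near the published 5.2
DEFAULT_BMI_F_COEFS = {
    "intercept": 17.0,
    "mother_education": 0.25,
    "log_income_pc": 0.35,
    "child_age": 0.12,
    "child_age_sq": 0.0,
}


@dataclass
class RunConfig:
    """One full-analysis run: exactly one input source (synthetic or CSV)."""

    sim: SimConfig = field(default_factory=SimConfig)
    input_csv: str | None = None
    school_effect: EffectSpec = field(default_factory=lambda: EffectSpec(tau0=-0.5))
    bmi_noise_sd: float = 3.0
    bandwidth: float = 0.06
    bootstrap_B: int = 50
    stage1_trees: int = 100
    stage2_trees: int = 200
    nuisance_trees: int = 100
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if isinstance(self.school_effect, dict):
            self.school_effect = EffectSpec(**self.school_effect)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sub_seed(master: int, tag: str) -> int:
    """Stable per-stage sub-seed below 2**31 (crc32 keeps it process-independent)."""
    h = np.random.SeedSequence([int(master), zlib.crc32(tag.encode())])
    return int(h.generate_state(1)[0] % (2**31))


def simulate_study(config: RunConfig) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Draw the study cohort as a wide table.

    Columns: covariates + cohort + treatment + whz/waz/haz (NaN for
    school-age rows) + bmi (NaN for preschool rows).  Returns the wide
    table and per-outcome ground-truth tables (indexed like the subset
    rows they describe).
    """
    sim = config.sim
    cov = generate_covariates(sim)
    W, p_select = assign_treatment(cov, sim.selection_coefs, sim.seed)
    wide = cov.copy()
    wide["treatment"] = W
    truths: dict[str, pd.DataFrame] = {}

    pre = cov["cohort"] == "preschool"
    sch = ~pre
    for name in PRESCHOOL_OUTCOMES:
        sub = cov[pre]
        ds, truth = simulate_outcomes(
            sub, W[pre.to_numpy()], sim.effect_spec, sim.noise_sd,
            seed=_sub_seed(sim.seed, name), f_coefs=sim.f_coefs,
        )
        wide.loc[pre, name] = ds["outcome"].to_numpy()
        truth["p_select"] = p_select[pre.to_numpy()]
        truths[name] = truth
    if sch.any():
        sub = cov[sch]
        ds, truth = simulate_outcomes(
            sub, W[sch.to_numpy()], config.school_effect, config.bmi_noise_sd,
            seed=_sub_seed(sim.seed, "bmi"), f_coefs=DEFAULT_BMI_F_COEFS,
        )
        wide.loc[sch, "bmi"] = ds["outcome"].to_numpy()
        truth["p_select"] = p_select[sch.to_numpy()]
        truths["bmi"] = truth
    return wide, truths


def _outcome_cohort(outcome: str) -> str:
    if outcome in PRESCHOOL_OUTCOMES:
        return "preschool"
    if outcome in SCHOOL_OUTCOMES:
        return "school_age"
    raise ValueError(f"unknown outcome {outcome!r}")


def psm_table(
    wide: pd.DataFrame,
    outcomes: list[str],
    bandwidth: float = 0.06,
    bootstrap_B: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Matching estimates for each outcome: NN-1, NN-4 and kernel ATT with
    bootstrap SEs (full re-estimation inside each resample)."""
    rows = []
    methods = [("nn_1", dict(method="nn", k=1)), ("nn_4", dict(method="nn", k=4)),
               ("kernel", dict(method="kernel", bandwidth=bandwidth))]
    for outcome in outcomes:
        sub = wide.loc[wide[outcome].notna(), COVARIATES + ["treatment", outcome]].reset_index(drop=True)
        for tag, kw in methods:
            est = matching.matched_att(sub, outcome=outcome, columns=COVARIATES, **kw)
            if bootstrap_B >= 2:
                se = matching.bootstrap_se(
                    sub,
                    lambda d, _kw=kw, _o=outcome: matching.matched_att(
                        d, outcome=_o, columns=COVARIATES, **_kw
                    ).value,
                    B=bootstrap_B,
                    seed=_sub_seed(seed, f"boot-{outcome}-{tag}"),
                )
                est = est.with_se(se)
            rows.append(
                {
                    "outcome": outcome,
                    "n": int(len(sub)),
                    "method": tag,
                    "att": est.value,
                    "se": est.se,
                    "stars": est.stars,
                    "n_treated": est.n_treated,
                    "n_control_used": est.n_control_used,
                }
            )
    return pd.DataFrame(rows)


def _forest_subgroups(
    cite: np.ndarray, W: np.ndarray, design: pd.DataFrame, selected: list[str]
) -> pd.DataFrame:
    """CATC for every level of the selected covariates (dummy columns give
    their two levels; continuous columns split at the median)."""
    rows = []
    for covname in selected:
        col = design[covname].to_numpy(float)
        if set(np.unique(col)).issubset({0.0, 1.0}):
            level_masks = [(f"{covname}=1", col == 1), (f"{covname}=0", col == 0)]
        else:
            med = np.median(col)
            level_masks = [(f"{covname}>median", col > med), (f"{covname}<=median", col <= med)]
        for label, mask in level_masks:
            if not (mask & (W == 0)).any():
                continue
            eff = cf.subgroup_effect(cite, W, mask, estimand="CATC", label=label)
            rows.append(
                {"subgroup": eff.subgroup, "estimand": eff.estimand,
                 "catc": eff.estimate, "se": eff.se, "n_controls": eff.n}
            )
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig, outdir: str | Path) -> dict:
    """Run simulate -> describe -> match -> forest and write the bundle.

    Artifacts written to ``outdir``: descriptives.csv, psm_estimates.csv,
    propensity_histogram.csv, importance.csv, subgroups.csv,
    cite_histogram.csv, median_split_profile.csv, manifest.json.
    Deterministic given the master seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.input_csv is not None:
        wide = pd.read_csv(config.input_csv)
    else:
        wide, _ = simulate_study(config)
    outcomes = [o for o in PRESCHOOL_OUTCOMES + SCHOOL_OUTCOMES if o in wide.columns]
    for o in outcomes:
        if (_outcome_cohort(o) == "preschool") != (
            wide.loc[wide[o].notna(), "cohort"].eq("preschool").all()
        ):
            raise ValueError(f"outcome {o!r} present outside its cohort")

    desc = descriptives.summarize_by_group(wide)
    desc.to_csv(outdir / "descriptives.csv", index=False)

    psm = psm_table(wide, outcomes, bandwidth=config.bandwidth,
                    bootstrap_B=config.bootstrap_B, seed=config.seed)
    psm.to_csv(outdir / "psm_estimates.csv", index=False)

    # overlap figure data from the pooled propensity fit
    model = matching.fit_propensity_logit(wide, wide["treatment"].to_numpy(), columns=COVARIATES)
    scores = matching.predict_propensity(model, wide)
    matching.propensity_histogram(scores, wide["treatment"].to_numpy()).to_csv(
        outdir / "propensity_histogram.csv", index=False
    )

    params = cf.ForestParams(min_leaf=config.min_leaf, nuisance_trees=config.nuisance_trees)
    imp_rows, sub_rows, hist_rows, profile_rows = [], [], [], []
    manifest: dict = {
        "seed": config.seed,
        "config": {
            "bandwidth": config.bandwidth,
            "bootstrap_B": config.bootstrap_B,
            "stage1_trees": config.stage1_trees,
            "stage2_trees": config.stage2_trees,
            "min_leaf": config.min_leaf,
            "n_total": int(len(wide)),
        },
        "cohorts": {},
    }
    for cohort, outcome in (("preschool", "whz"), ("school_age", "bmi")):
        if outcome not in wide.columns:
            continue
        sub = wide.loc[wide[outcome].notna()].reset_index(drop=True)
        if len(sub) < 50:
            continue
        res = cf.two_stage_fit(
            sub, outcome=outcome,
            stage1_trees=config.stage1_trees, stage2_trees=config.stage2_trees,
            params=params, seed=_sub_seed(config.seed, f"forest-{cohort}"),
        )
        W = sub["treatment"].to_numpy(int)
        summary = cf.cite_distribution_summary(res.cite)
        imp = res.importance.copy()
        imp.insert(0, "cohort", cohort)
        imp_rows.append(imp)
        sg = _forest_subgroups(res.cite, W, cf.forest_design(sub), res.selected)
        sg.insert(0, "cohort", cohort)
        sub_rows.append(sg)
        hist = summary.histogram.copy()
        hist.insert(0, "cohort", cohort)
        hist_rows.append(hist)
        if np.ptp(res.cite) > 0:  # a split-less forest has no profile to report
            prof = cf.median_split_profile(res.cite, sub[COVARIATES])
            prof.insert(0, "cohort", cohort)
            profile_rows.append(prof)
        manifest["cohorts"][cohort] = {
            "outcome": outcome,
            "n": int(len(sub)),
            "cite_interval_95": list(summary.interval),
            "verdict": summary.verdict,
            "mean_cite": summary.mean,
            "selected_covariates": res.selected,
        }

    def _write(rows, name, columns):
        frame = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(columns=columns)
        )
        frame.to_csv(outdir / name, index=False)

    _write(imp_rows, "importance.csv", ["cohort", "covariate", "importance", "rank"])
    _write(sub_rows, "subgroups.csv", ["cohort", "subgroup", "estimand", "catc", "se", "n_controls"])
    _write(hist_rows, "cite_histogram.csv", ["cohort", "bin_left", "bin_right", "count"])
    _write(profile_rows, "median_split_profile.csv",
           ["cohort", "covariate", "mean_above_median", "mean_below_median", "gap", "t", "p", "stars"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


ARTIFACT_FILES = [
    "descriptives.csv",
    "psm_estimates.csv",
    "propensity_histogram.csv",
    "importance.csv",
    "subgroups.csv",
    "cite_histogram.csv",
    "median_split_profile.csv",
    "manifest.json",
]


# ---------------------------------------------------------------------------
# parameter recovery


@dataclass
class RecoveryConfig:
    """Conditions of the recovery experiment (one single-outcome cohort)."""

    n: int = 2000
    effect_spec: EffectSpec = field(default_factory=lambda: EffectSpec(tau0=0.5))
    noise_sd: float = 0.8
    n_trees: int = 100
    nuisance_trees: int = 100
    min_leaf: int = 5
    bandwidth: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.effect_spec, dict):
            self.effect_spec = EffectSpec(**self.effect_spec)


@dataclass
class RecoveryReport:
    estimators: pd.DataFrame  # per-estimator bias and RMSE
    cite_rmse: float
    tau_sd: float
    subgroup_contrast_error: float | None
    n_replicates: int
    n_failures: int
    seeds: list[int]


def _one_recovery_replicate(config: RecoveryConfig, seed: int) -> dict:
    sim = SimConfig(
        n_total=config.n, effect_spec=config.effect_spec,
        noise_sd=config.noise_sd, seed=seed,
    )
    from .synthetic import generate_dataset

    ds, truth = generate_dataset(sim)
    W = ds["treatment"].to_numpy(int)
    Y = ds["outcome"].to_numpy(float)
    tau = truth["tau_true"].to_numpy()
    true_att = float(tau[W == 1].mean())
    true_ate = float(tau.mean())

    out = {
        "naive": (matching.naive_difference(Y, W), true_att),
        "nn_1": (matching.matched_att(ds, columns=COVARIATES, method="nn", k=1).value, true_att),
        "nn_4": (matching.matched_att(ds, columns=COVARIATES, method="nn", k=4).value, true_att),
        "kernel": (
            matching.matched_att(
                ds, columns=COVARIATES, method="kernel", bandwidth=config.bandwidth
            ).value,
            true_att,
        ),
    }
    params = cf.ForestParams(
        n_trees=config.n_trees, min_leaf=config.min_leaf, nuisance_trees=config.nuisance_trees
    )
    f = cf.fit_causal_forest(
        cf.forest_design(ds), Y, W, params, seed=_sub_seed(seed, "forest")
    )
    cite = cf.predict_cate(f)
    out["forest_ate"] = (float(cite.mean()), true_ate)
    result = {"estimates": out, "cite_rmse": float(np.sqrt(np.mean((cite - tau) ** 2))),
              "tau_sd": float(tau.std())}

    if config.effect_spec.increments:
        name, inc = next(iter(config.effect_spec.increments.items()))
        mask = ds.eval(MODIFIERS[name]).to_numpy()
        contrast = float(cite[mask].mean() - cite[~mask].mean())
        result["subgroup_contrast_error"] = abs(contrast - inc)
    return result


def parameter_recovery_experiment(
    config: RecoveryConfig, n_replicates: int = 5
) -> RecoveryReport:
    """Bias/RMSE of every estimator against the generator's ground truth."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(config.seed)
    seeds = [int(rng.integers(2**31)) for _ in range(n_replicates)]
    reps, failures = [], 0
    for s in seeds:
        try:
            reps.append(_one_recovery_replicate(config, s))
        except Exception:  # noqa: BLE001 - failed replicates are counted, not fatal
            failures += 1
    if not reps:
        raise RuntimeError("all recovery replicates failed")
    names = list(reps[0]["estimates"])
    rows = []
    for name in names:
        errs = np.array([r["estimates"][name][0] - r["estimates"][name][1] for r in reps])
        rows.append({"estimator": name, "bias": float(errs.mean()),
                     "rmse": float(np.sqrt(np.mean(errs**2)))})
    sub_errs = [r["subgroup_contrast_error"] for r in reps if "subgroup_contrast_error" in r]
    return RecoveryReport(
        estimators=pd.DataFrame(rows),
        cite_rmse=float(np.mean([r["cite_rmse"] for r in reps])),
        tau_sd=float(np.mean([r["tau_sd"] for r in reps])),
        subgroup_contrast_error=float(np.mean(sub_errs)) if sub_errs else None,
        n_replicates=len(reps),
        n_failures=failures,
        seeds=seeds,
    )


def write_recovery_report(report: RecoveryReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.estimators.to_csv(outdir / "recovery_estimators.csv", index=False)
    meta = {
        "cite_rmse": report.cite_rmse,
        "tau_sd": report.tau_sd,
        "subgroup_contrast_error": report.subgroup_contrast_error,
        "n_replicates": report.n_replicates,
        "n_failures": report.n_failures,
        "seeds": report.seeds,
    }
    (outdir / "recovery_report.json").write_text(json.dumps(meta, indent=2))
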