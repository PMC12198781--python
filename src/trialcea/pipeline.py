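"""End-to-end scenario driver: filter -> effects -> costing -> imputation -> CEA.

One :class:`ScenarioConfig` fixes the analysis perspective (societal or
healthcare), the analysed population (modified intention-to-treat, which only
drops early deaths, or per-protocol, which additionally drops non-adherent
intervention participants), whether home-care costs are excluded, the effect
outcome (QALY from EQ-5D-5L or WALY from ICECAP-A), discounting, imputation
and bootstrap settings, and the master seed. The four published sensitivity
scenarios and both outcomes run from one config matrix without code changes.

The per-protocol analysis re-runs imputation on the filtered population (the
filter is applied before the imputation stage), which respects the
split-by-arm imputation principle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cea import DEFAULT_WTP_GRID, IncrementalCostEffectiveness, IncrementalResult
from .costing import (
    FOLLOWUP_MONTHS,
    RESOURCE_MONTHS,
    FrictionPolicy,
    UnitPriceTable,
    period_components,
)
from .effects import (
    UTILITY_MONTHS,
    DiscountPolicy,
    TariffTable,
    UtilityAccrual,
    toy_tariff,
    utilities_from_table,
)
from .exceptions import ConfigurationError, ValidationError
from .imputation import (
    ChainedEquationsImputer,
    ImputationConfig,
    home_care_impute,
    item_level_fill,
)
from .synthetic import SyntheticTrial

_UTIL_PREFIX = {"EQ5D5L": "eq5d", "ICECAPA": "icecap"}
_COMP_PREFIX = {"healthcare": "hc", "home_care": "hm", "patient_family": "pf", "productivity": "pr"}
_COVARIATE_COLS = ("age", "sex_male", "copd", "asthma", "t2dm", "chf")
_CONDITION_COLS = ("copd", "asthma", "t2dm", "chf")

PERSPECTIVES = ("societal", "healthcare")
POPULATIONS = ("mitt", "per_protocol")
OUTCOMES = ("qaly", "waly")


@dataclass(frozen=True)
class ScenarioConfig:
    """Settings for one cost-effectiveness scenario run."""

    name: str = "base_case"
    perspective: str = "societal"
    population: str = "mitt"
    exclude_home_care: bool = False
    effect_outcome: str = "qaly"
    wtp: float = 20_000.0
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID
    discount: DiscountPolicy = field(default_factory=DiscountPolicy)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    bootstrap_replications: int = 5000
    intervention_fee: float = 27.0
    prorate_fee: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perspective not in PERSPECTIVES:
            raise ConfigurationError(f"perspective must be one of {PERSPECTIVES}")
        if self.population not in POPULATIONS:
            raise ConfigurationError(f"population must be one of {POPULATIONS}")
        if self.effect_outcome not in OUTCOMES:
            raise ConfigurationError(f"effect_outcome must be one of {OUTCOMES}")
        if self.wtp < 0:
            raise ConfigurationError("willingness-to-pay must be non-negative")


@dataclass
class RunReport:
    """Scenario result: incremental estimates plus per-arm descriptives."""

    scenario: dict
    n_by_arm: dict[str, int]
    result: IncrementalResult
    arm_means: dict
    provenance: dict
    bootstrap_pairs: np.ndarray | None = None  # (B, 2) of (dC*, dE*); not serialised

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "n_by_arm": self.n_by_arm,
            "result": self.result.to_dict(),
            "arm_means": self.arm_means,
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _derived_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([int(seed), stream]).generate_state(1)[0] % (2**31))


def apply_population_filter(participants: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """mITT drops early deaths; per-protocol additionally drops non-adherent
    intervention participants. The control arm is never filtered by adherence."""
    for colname in ("adherent", "died"):
        if colname not in participants.columns:
            raise ValidationError(f"participants table lacks the {colname!r} flag")
    kept = participants[participants["died"].astype(bool) == False]  # noqa: E712
    if config.population == "per_protocol":
        drop = (kept["arm"] == "intervention") & (~kept["adherent"].astype(bool))
        kept = kept[~drop]
    return kept.reset_index(drop=True)


def apply_perspective(
    components: Mapping[str, float],
    perspective: str,
    exclude_home_care: bool = False,
) -> float:
    """Total cost under a perspective, from a component breakdown.

    ``components`` may carry home care either inside ``healthcare`` or split
    out under ``home_care``. The healthcare perspective keeps healthcare
    (incl. home care) and intervention components only; the societal
    perspective adds patient/family and productivity costs.
    """
    if perspective not in PERSPECTIVES:
        raise ConfigurationError(f"perspective must be one of {PERSPECTIVES}")
    home = 0.0 if exclude_home_care else float(components.get("home_care", 0.0))
    total = float(components.get("healthcare", 0.0)) + home + float(components.get("intervention", 0.0))
    if perspective == "societal":
        total += float(components.get("patient_family", 0.0)) + float(components.get("productivity", 0.0))
    return total


def _trial_tables(trial) -> dict[str, pd.DataFrame]:
    if isinstance(trial, SyntheticTrial):
        return {
            "participants": trial.participants,
            "utilities": trial.utilities,
            "resources": trial.resources,
        }
    return dict(trial)


def build_analysis_frame(
    participants: pd.DataFrame,
    utilities: pd.DataFrame,
    resources: pd.DataFrame,
    prices: UnitPriceTable | None = None,
    friction: FrictionPolicy | None = None,
    tariffs: Mapping[str, TariffTable] | None = None,
) -> tuple[pd.DataFrame, list[str], list[str], dict]:
    """Assemble the wide per-participant analysis dataset.

    Applies the deterministic imputation tiers (item-level fill, home-care
    modal completion), values resource volumes into per-period euro
    components, and pivots everything to one row per participant: covariates,
    utilities per instrument and month, and cost components per period.
    Returns ``(frame, imputable_columns, predictor_columns, provenance)``.
    """
    tariffs = tariffs or {"EQ5D5L": toy_tariff("EQ5D5L"), "ICECAPA": toy_tariff("ICECAPA")}
    ids = participants["participant_id"]
    utilities = utilities[utilities["participant_id"].isin(ids)]
    resources = resources[resources["participant_id"].isin(ids)].reset_index(drop=True)

    utilities = utilities_from_table(utilities, tariffs)
    resources, item_prov = item_level_fill(resources, participants)
    resources, home_prov = home_care_impute(resources, participants)
    comps = period_components(resources, participants, prices, friction)

    frame = participants.set_index("participant_id").copy()
    frame["arm_indicator"] = (frame["arm"] == "intervention").astype(float)
    frame["sex_male"] = (frame["sex"] == "male").astype(float)

    util_wide = utilities.pivot_table(
        index="participant_id", columns=["instrument", "month"], values="utility",
        aggfunc="first", dropna=False,
    )
    for (inst, month), series in util_wide.items():
        frame[f"{_UTIL_PREFIX[inst]}_m{int(month)}"] = series

    comp_wide = comps.set_index(["participant_id", "month"])
    for comp, prefix in _COMP_PREFIX.items():
        wide = comp_wide[comp].unstack("month")
        for month in wide.columns:
            frame[f"{prefix}_m{int(month)}"] = wide[month]

    util_cols = [
        f"{p}_m{m}" for p in _UTIL_PREFIX.values() for m in UTILITY_MONTHS
    ]
    cost_cols = [
        f"{p}_m{m}" for c, p in _COMP_PREFIX.items() if c != "home_care"
        for m in RESOURCE_MONTHS
    ]
    impute_cols = [c for c in util_cols + cost_cols if c in frame.columns]
    predictors = ["age", "sex_male", "education", *_CONDITION_COLS]
    provenance = {
        "item_level_fills": item_prov,
        "home_care_fills": home_prov,
    }
    return frame.reset_index(), impute_cols, predictors, provenance


def outcome_frame(completed: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Per-participant outcomes for one completed dataset under a scenario.

    Effects: discounted accrual of the chosen instrument's utilities.
    Costs: follow-up period components summed with year-two discounting, the
    scenario perspective applied, the intervention fee added to the
    intervention arm, and the baseline (pre-trial recall) period kept as the
    baseline-cost covariate.
    """
    prefix = "eq5d" if config.effect_outcome == "qaly" else "icecap"
    instrument = "EQ5D5L" if config.effect_outcome == "qaly" else "ICECAPA"
    accrual = UtilityAccrual(
        rate_effects=config.discount.rate_effects,
        cutover_month=config.discount.cutover_month,
        instrument=instrument,
    ).fit()
    U = completed[[f"{prefix}_m{m}" for m in UTILITY_MONTHS]].to_numpy(float)
    effect = accrual.transform(U)

    def total_for(months: Sequence[int]) -> np.ndarray:
        total = np.zeros(len(completed))
        for month in months:
            factor = (
                config.discount.cost_factor
                if month > config.discount.cutover_month
                else 1.0
            )
            comp = completed[f"hc_m{month}"].to_numpy(float).copy()
            if not config.exclude_home_care:
                comp = comp + completed[f"hm_m{month}"].to_numpy(float)
            if config.perspective == "societal":
                comp = comp + completed[f"pf_m{month}"].to_numpy(float)
                comp = comp + completed[f"pr_m{month}"].to_numpy(float)
            total += factor * comp
        return total

    fee = config.intervention_fee * (1.5 if config.prorate_fee else 1.0)
    total_cost = total_for(FOLLOWUP_MONTHS) + fee * completed["arm_indicator"].to_numpy(float)
    baseline_cost = total_for([0])

    out = completed[
        ["participant_id", "arm", "arm_indicator", *_COVARIATE_COLS]
    ].copy()
    out["effect"] = effect
    out["total_cost"] = total_cost
    out["baseline_utility"] = completed[f"{prefix}_m0"].to_numpy(float)
    out["baseline_cost"] = baseline_cost
    return out


_ADJUST_COVARIATES = ("baseline_utility", "baseline_cost", *_COVARIATE_COLS)


def run_scenario(
    trial,
    config: ScenarioConfig | None = None,
    prices: UnitPriceTable | None = None,
    friction: FrictionPolicy | None = None,
    tariffs: Mapping[str, TariffTable] | None = None,
) -> RunReport:
    """Run the full pipeline for one scenario; deterministic given the seed."""
    config = config or ScenarioConfig()
    tables = _trial_tables(trial)
    participants = apply_population_filter(tables["participants"], config)
    n_by_arm = participants["arm"].value_counts().to_dict()

    frame, impute_cols, predictors, provenance = build_analysis_frame(
        participants, tables["utilities"], tables["resources"], prices, friction, tariffs
    )

    any_missing = frame[impute_cols].isna().any().any()
    if any_missing:
        imputer = ChainedEquationsImputer(
            m=config.imputation.m,
            pmm_donors=config.imputation.pmm_donors,
            max_iterations=config.imputation.max_iterations,
            split_by_arm=config.imputation.split_by_arm,
            group_col="arm",
            columns=tuple(impute_cols),
            predictors=tuple(predictors),
            random_state=(
                config.imputation.seed
                if config.imputation.seed is not None
                else _derived_seed(config.seed, 1)
            ),
        )
        completed = imputer.fit_transform(frame)
    else:
        completed = [frame]

    outcome_frames = [outcome_frame(c, config) for c in completed]
    df_complete = len(frame) - (2 + len(_ADJUST_COVARIATES))
    cea = IncrementalCostEffectiveness(
        cost_col="total_cost",
        effect_col="effect",
        covariates=_ADJUST_COVARIATES,
        B=config.bootstrap_replications,
        wtp_grid=config.wtp_grid,
        wtp_reference=config.wtp,
        random_state=_derived_seed(config.seed, 2),
        df_complete=df_complete,
    ).fit(outcome_frames)

    arm_means = _arm_means(outcome_frames, completed, config)
    report = RunReport(
        scenario=_config_dict(config),
        n_by_arm={str(k): int(v) for k, v in n_by_arm.items()},
        result=cea.result_,
        arm_means=arm_means,
        provenance={
            "package_version": __version__,
            "seed": config.seed,
            "n_analysed": int(len(participants)),
            "n_imputations": len(completed),
            "n_item_level_fills": len(provenance["item_level_fills"]),
            "n_home_care_fills": len(provenance["home_care_fills"]),
            "bootstrap_redraws": cea.bootstrap_.n_redrawn,
        },
        bootstrap_pairs=cea.bootstrap_.pairs,
    )
    return report


def _arm_means(outcome_frames, completed_frames, config: ScenarioConfig) -> dict:
    """Per-arm mean effects and component costs, pooled over imputations."""
    eff = pd.concat(outcome_frames)
    means: dict[str, dict[str, float]] = {}
    means["effect"] = eff.groupby("arm")["effect"].mean().to_dict()
    means["total_cost"] = eff.groupby("arm")["total_cost"].mean().to_dict()
    pooled = pd.concat(completed_frames)
    for comp, prefix in _COMP_PREFIX.items():
        cols = [f"{prefix}_m{m}" for m in FOLLOWUP_MONTHS]
        discounted = np.zeros(len(pooled))
        for month, col in zip(FOLLOWUP_MONTHS, cols):
            factor = (
                config.discount.cost_factor
                if month > config.discount.cutover_month
                else 1.0
            )
            discounted += factor * pooled[col].to_numpy(float)
        means[comp] = (
            pd.Series(discounted, index=pooled.index)
            .groupby(pooled["arm"])
            .mean()
            .to_dict()
        )
    fee = config.intervention_fee * (1.5 if config.prorate_fee else 1.0)
    means["intervention"] = {"control": 0.0, "intervention": fee}
    return means


def _config_dict(config: ScenarioConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["wtp_grid"] = [float(raw["wtp_grid"][0]), float(raw["wtp_grid"][-1]), len(raw["wtp_grid"])]
    return raw


def scenario_matrix(
    base: ScenarioConfig | None = None, outcomes: Sequence[str] = ("qaly",)
) -> list[ScenarioConfig]:
    """The published scenario set: societal base case, healthcare perspective,
    per-protocol, and home-care exclusion — per requested effect outcome."""
    base = base or ScenarioConfig()
    variants = [
        ("societal", dict(perspective="societal")),
        ("healthcare", dict(perspective="healthcare")),
        ("per_protocol", dict(population="per_protocol")),
        ("excl_home_care", dict(exclude_home_care=True)),
    ]
    configs = []
    for outcome in outcomes:
        for name, kwargs in variants:
            label = f"{name}_{outcome}"
            configs.append(
                dataclasses.replace(base, name=label, effect_outcome=outcome, **kwargs)
            )
    return configs


def run_scenarios(
    trial,
    base: ScenarioConfig | None = None,
    outcomes: Sequence[str] = ("qaly",),
    **kwargs,
) -> dict[str, RunReport]:
    """Run the whole scenario matrix; one report per scenario."""
    return {
        cfg.name: run_scenario(trial, cfg, **kwargs)
        for cfg in scenario_matrix(base, outcomes)
    }
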