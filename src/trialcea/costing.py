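"""Valuation of resource-use volumes into euro costs.

Resource use is recorded every three months (months 0, 3, ..., 18) as
volumes per category: primary-care contacts, out-of-hours care, paramedical
and mental healthcare, hospital care, home care, informal care, out-of-pocket
prevention spending, and productivity losses. Volumes are valued with Dutch
standard unit prices expressed in 2024 euros; older prices are indexed with
consumer-price-index factors.

Productivity losses from paid work are valued with the friction cost method:
a sick worker's lost days are valued at the sex-specific hourly wage only up
to the friction period (143 working days, the time needed to replace them).
Unpaid work and informal care use the replacement cost method (the market
price of hiring a substitute, EUR 19/hour). Productivity questions have a
4-week recall on a 3-month schedule, so each observation is extrapolated to
its full period (x3) before valuation.

Costs in the second follow-up year (the T15 and T18 periods) are discounted
at 4% annually. The intervention arm additionally carries a fixed digital-
platform subscription fee (EUR 27/year; optionally prorated to 1.5x for the
18-month horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from .effects import DiscountPolicy
from .exceptions import (
    ConfigurationError,
    IndexationError,
    PreconditionError,
    PricingError,
    ValidationError,
)

#: Months at which the resource-use questionnaires are administered.
RESOURCE_MONTHS: tuple[int, ...] = (0, 3, 6, 9, 12, 15, 18)

#: Follow-up periods contributing to the 18-month cost horizon. The baseline
#: questionnaire recalls the pre-trial period and enters the analysis as the
#: baseline-cost covariate instead.
FOLLOWUP_MONTHS: tuple[int, ...] = (3, 6, 9, 12, 15, 18)

#: Unit prices in 2024 euros. Prevention spending is recorded directly in
#: euros (pass-through price of 1); paid absence is valued through the
#: friction policy's sex-specific wages, not this table.
UNIT_PRICES_2024: dict[str, float] = {
    "gp_consult_physical": 44.0,
    "gp_consult_phone": 22.0,
    "gp_visitation": 66.0,
    "ooh_physical": 120.0,
    "ooh_phone": 35.0,
    "ooh_visitation": 180.0,
    "paramedical": 44.0,
    "mental_hcp": 84.0,
    "outpatient": 119.0,
    "emergency": 340.0,
    "hospitalisation_day": 624.0,
    "ambulance": 674.0,
    "home_domestic": 31.0,
    "home_personal": 66.0,
    "home_nursing": 95.0,
    "informal_care_hour": 19.0,
    "prevention_euro": 1.0,
    "unpaid_loss_hour": 19.0,
}

CATEGORIES: tuple[str, ...] = tuple(UNIT_PRICES_2024) + ("paid_absence_day",)

HOME_CARE_CATEGORIES: tuple[str, ...] = ("home_domestic", "home_personal", "home_nursing")

#: Cost component of each category. Home care is split out so perspectives and
#: the exclude-home-care scenario can treat it separately; for reporting it is
#: part of healthcare costs.
COMPONENT_OF: dict[str, str] = {
    **{c: "healthcare" for c in (
        "gp_consult_physical", "gp_consult_phone", "gp_visitation",
        "ooh_physical", "ooh_phone", "ooh_visitation",
        "paramedical", "mental_hcp",
        "outpatient", "emergency", "hospitalisation_day", "ambulance",
    )},
    **{c: "home_care" for c in HOME_CARE_CATEGORIES},
    "informal_care_hour": "patient_family",
    "prevention_euro": "patient_family",
    "paid_absence_day": "productivity",
    "unpaid_loss_hour": "productivity",
}

COMPONENTS: tuple[str, ...] = ("healthcare", "home_care", "patient_family", "productivity")

#: Reporting groups mirroring the cost rows of a trial results table.
GROUP_OF: dict[str, str] = {
    "gp_consult_physical": "gp", "gp_consult_phone": "gp", "gp_visitation": "gp",
    "ooh_physical": "gp", "ooh_phone": "gp", "ooh_visitation": "gp",
    "outpatient": "hospital", "hospitalisation_day": "hospital",
    "emergency": "acute", "ambulance": "acute",
    "paramedical": "allied_health", "mental_hcp": "allied_health",
    "home_domestic": "home_care", "home_personal": "home_care", "home_nursing": "home_care",
    "informal_care_hour": "informal_care",
    "prevention_euro": "out_of_pocket",
    "paid_absence_day": "productivity", "unpaid_loss_hour": "productivity",
}


@dataclass(frozen=True)
class FrictionPolicy:
    """Friction-cost parameters for productivity valuation.

    ``friction_days`` caps the valued length of one sick-leave spell (Dutch
    convention: 143 working days = 20 weeks). Wages are hourly, applied for
    ``hours_per_day`` hours per lost working day; unpaid work and informal
    care are valued at ``replacement_rate`` per hour.
    """

    friction_days: float = 143.0
    hours_per_day: float = 8.0
    wage_male: float = 50.0
    wage_female: float = 41.0
    replacement_rate: float = 19.0

    def __post_init__(self) -> None:
        for name in ("friction_days", "hours_per_day", "wage_male", "wage_female", "replacement_rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    def wage(self, sex: str) -> float:
        if sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {sex!r}")
        return self.wage_male if sex == "male" else self.wage_female


@dataclass(frozen=True)
class AbsenceSpell:
    """One sick-leave spell: start month, working days lost, sex, hours/day."""

    start_month: float
    working_days: float
    sex: str
    hours_per_day: float | None = None


@dataclass
class CostBreakdown:
    """Per-participant cost components in euros; total is their exact sum."""

    participant_id: object
    healthcare: float = 0.0
    home_care: float = 0.0
    patient_family: float = 0.0
    productivity: float = 0.0
    intervention: float = 0.0
    detail: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return (
            self.healthcare + self.home_care + self.patient_family
            + self.productivity + self.intervention
        )


class UnitPriceTable:
    """Category -> unit price in 2024 euros, with price-index factors.

    ``index_factors`` maps a source year to the multiplier that converts that
    year's euros to 2024 euros (factor for 2024 is 1).
    """

    def __init__(
        self,
        prices: Mapping[str, float] | pd.DataFrame | None = None,
        index_factors: Mapping[int, float] | None = None,
    ):
        if prices is None:
            prices = UNIT_PRICES_2024
        if isinstance(prices, pd.DataFrame):
            prices = dict(zip(prices["category"], prices["unit_price_2024"].astype(float)))
        self._prices = {str(k): float(v) for k, v in prices.items()}
        for cat, price in self._prices.items():
            if price <= 0:
                raise ConfigurationError(f"unit price for {cat!r} must be positive")
        self.index_factors = {2024: 1.0, **(dict(index_factors) if index_factors else {})}

    def price(self, category: str) -> float:
        try:
            return self._prices[category]
        except KeyError:
            raise PricingError(f"no unit price for category {category!r}") from None

    def __contains__(self, category: str) -> bool:
        return category in self._prices

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": list(self._prices), "unit_price_2024": list(self._prices.values())}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, index_factors=None) -> "UnitPriceTable":
        return cls(pd.read_csv(path), index_factors)


def default_unit_prices() -> UnitPriceTable:
    """The bundled 2024 Dutch unit-price table."""
    return UnitPriceTable()


def index_price(price: float, source_year: int, table: UnitPriceTable) -> float:
    """Convert a price from its source year to 2024 euros via index factors."""
    try:
        factor = table.index_factors[int(source_year)]
    except KeyError:
        raise IndexationError(f"no price-index factor for year {source_year}") from None
    return float(price) * float(factor)


def value_period(
    volumes: Mapping[str, float],
    prices: UnitPriceTable,
    sex: str | None = None,
    friction: FrictionPolicy | None = None,
) -> dict[str, float]:
    """Value one period's volumes into euros per category.

    ``euros = volume x unit price``; prevention volumes pass through as euros.
    Paid absence days need ``sex`` (and a friction policy for the wage and
    hours per day); the friction *cap* is applied at spell level elsewhere.
    """
    out: dict[str, float] = {}
    for category, volume in volumes.items():
        volume = float(volume)
        if volume < 0:
            raise ValidationError(f"negative volume for {category!r}")
        if category == "paid_absence_day":
            if sex is None:
                raise ValidationError("paid_absence_day valuation requires sex")
            policy = friction or FrictionPolicy()
            out[category] = volume * policy.hours_per_day * policy.wage(sex)
        else:
            out[category] = volume * prices.price(category)
    return out


def productivity_cost(
    spells: Iterable[AbsenceSpell],
    unpaid_hours: float = 0.0,
    policy: FrictionPolicy | None = None,
) -> float:
    """Friction-cost valuation of sick-leave spells plus replacement-cost
    valuation of unpaid-work hours.

    Each spell is valued for at most ``policy.friction_days`` working days.
    """
    policy = policy or FrictionPolicy()
    if unpaid_hours < 0:
        raise ValidationError("unpaid_hours must be non-negative")
    total = float(unpaid_hours) * policy.replacement_rate
    for spell in spells:
        if spell.working_days < 0:
            raise ValidationError("spell durations must be non-negative")
        hours = spell.hours_per_day if spell.hours_per_day is not None else policy.hours_per_day
        days = min(spell.working_days, policy.friction_days)
        total += days * hours * policy.wage(spell.sex)
    return total


def extrapolate_pcq(monthly_observation: float) -> float:
    """Extrapolate a 4-week productivity observation to its 3-month period.

    The observation at month t stands in for the two unobserved months of the
    period (t-3, t], so the period loss is three times the monthly loss. Works
    on volumes (absence days, unpaid hours) before valuation or on valued
    euros, both being linear.
    """
    return 3.0 * float(monthly_observation)


def discount_and_aggregate(
    period_breakdowns: pd.DataFrame,
    policy: DiscountPolicy | None = None,
    arm: str = "control",
    intervention_fee: float = 27.0,
    prorate_fee: bool = False,
    months: Sequence[int] | None = None,
) -> CostBreakdown:
    """Aggregate one participant's per-period component costs with discounting.

    ``period_breakdowns`` has one row per period with columns ``month`` and the
    four components. Periods after the discount cutover (T15, T18) are
    multiplied by ``1/(1 + rate_costs)``. Intervention-arm participants receive
    the fixed subscription fee once (flat EUR 27 by default, or prorated 1.5x
    for the 18-month horizon when ``prorate_fee``); the control arm never does.
    """
    policy = policy or DiscountPolicy()
    if months is None:
        months = RESOURCE_MONTHS
    present = set(int(m) for m in period_breakdowns["month"])
    missing = sorted(set(months) - present)
    if missing:
        raise PreconditionError(f"missing cost period(s) at month(s) {missing}")
    rows = period_breakdowns.set_index("month")
    out = CostBreakdown(participant_id=period_breakdowns.get("participant_id", pd.Series([None])).iloc[0])
    for month in months:
        factor = policy.cost_factor if month > policy.cutover_month else 1.0
        for comp in COMPONENTS:
            value = float(rows.loc[month, comp]) * factor
            setattr(out, comp, getattr(out, comp) + value)
            out.detail[(month, comp)] = value
    if arm == "intervention":
        out.intervention = intervention_fee * (1.5 if prorate_fee else 1.0)
    return out


def _chained_friction_days(days_by_period: np.ndarray, cap: float) -> np.ndarray:
    """Valued days per period under a friction cap carried across consecutive
    positive periods. NaN (missing questionnaire) breaks the chain and stays NaN.
    """
    n, k = days_by_period.shape
    valued = np.full_like(days_by_period, np.nan)
    cum = np.zeros(n)
    for j in range(k):
        col = days_by_period[:, j]
        obs = np.isfinite(col)
        cum[~obs] = 0.0  # chain broken by a missing period
        new_cum = np.where(obs, cum + np.nan_to_num(col), cum)
        valued[obs, j] = np.minimum(new_cum[obs], cap) - np.minimum(cum[obs], cap)
        cum = np.where(obs & (np.nan_to_num(col) > 0), new_cum, 0.0)
    return valued


def period_components(
    resources: pd.DataFrame,
    participants: pd.DataFrame,
    prices: UnitPriceTable | None = None,
    friction: FrictionPolicy | None = None,
) -> pd.DataFrame:
    """Value a long resource panel into per-participant, per-period components.

    Returns one row per (participant_id, month) with euro columns
    ``healthcare``, ``home_care``, ``patient_family`` and ``productivity``.
    A questionnaire-missing volume (NaN) makes its component NaN for that
    period. Productivity observations are PCQ-extrapolated (x3) and paid
    absence is friction-capped with spells chained across consecutive
    positive periods.
    """
    prices = prices or default_unit_prices()
    friction = friction or FrictionPolicy()

    unknown = set(resources["category"].unique()) - set(CATEGORIES)
    if unknown:
        raise PricingError(f"unpriced categories: {sorted(unknown)}")
    if (resources["volume"].dropna() < 0).any():
        raise ValidationError("volumes must be non-negative")

    # A recorded row with NaN volume means "missing"; an absent row means zero
    # use. Pivot volumes and row presence separately to keep the distinction.
    months = sorted(int(m) for m in resources["month"].unique())
    ids = participants["participant_id"].tolist()
    grid = pd.MultiIndex.from_product([ids, months], names=["participant_id", "month"])
    wide = resources.pivot(
        index=["participant_id", "month"], columns="category", values="volume"
    ).reindex(grid)
    present = resources.assign(_one=1.0).pivot(
        index=["participant_id", "month"], columns="category", values="_one"
    ).reindex(grid)
    for cat in CATEGORIES:
        if cat not in wide.columns:
            wide[cat] = np.nan
            present[cat] = np.nan
    wide = wide.where(present.notna(), 0.0).sort_index()

    sex = participants.set_index("participant_id")["sex"].reindex(
        wide.index.get_level_values(0)
    ).to_numpy()
    day_value = np.where(
        sex == "male",
        friction.hours_per_day * friction.wage_male,
        friction.hours_per_day * friction.wage_female,
    )

    out = pd.DataFrame(index=wide.index)
    euro = {
        cat: wide[cat].to_numpy(float) * prices.price(cat)
        for cat in UNIT_PRICES_2024
    }
    out["healthcare"] = sum(euro[c] for c, comp in COMPONENT_OF.items() if comp == "healthcare")
    out["home_care"] = sum(euro[c] for c in HOME_CARE_CATEGORIES)
    out["patient_family"] = euro["informal_care_hour"] + euro["prevention_euro"]

    # productivity: extrapolate, chain paid absence through the friction cap
    paid = wide["paid_absence_day"].unstack("month").reindex(columns=months)
    paid_days = extrapolate_pcq(1.0) * paid.to_numpy(float)
    valued_days = _chained_friction_days(paid_days, friction.friction_days)
    paid_valued = pd.DataFrame(valued_days, index=paid.index, columns=paid.columns).stack(
        future_stack=True
    ).reindex(wide.index)
    day_rate = pd.Series(day_value, index=wide.index)
    unpaid = 3.0 * wide["unpaid_loss_hour"] * friction.replacement_rate
    out["productivity"] = paid_valued * day_rate + unpaid

    return out.reset_index()
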