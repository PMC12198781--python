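"""Utility valuation and discounted QALY/WALY accrual.

A participant answers a preference-based instrument (EQ-5D-5L for
health-related quality of life, ICECAP-A for capability well-being) at months
0, 6, 12 and 18. A tariff maps each level profile to a single utility index
(EQ-5D-5L on [-0.446, 1], ICECAP-A on [0, 1]). Quality- and well-being-
adjusted life years are the area under the utility curve over the 18-month
horizon, computed by the trapezoid rule in year units, with accrual in the
second year discounted at an annual rate.

The tariffs bundled here are *synthetic toy tariffs* built from additive
per-dimension decrements, anchored at 1.0 for the best profile. They exist so
the pipeline and its tests run without licensed national value sets; real
analyses must supply a national tariff table via :meth:`TariffTable.from_csv`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    ConfigurationError,
    PreconditionError,
    TariffCoverageError,
    ValidationError,
)

#: Months at which the utility instruments are administered.
UTILITY_MONTHS: tuple[int, ...] = (0, 6, 12, 18)

#: Utility range per instrument (worst imaginable state, best state).
INSTRUMENT_RANGES: dict[str, tuple[float, float]] = {
    "EQ5D5L": (-0.446, 1.0),
    "ICECAPA": (0.0, 1.0),
}

#: Number of response levels per dimension (all instruments have 5 dimensions).
INSTRUMENT_LEVELS: dict[str, int] = {"EQ5D5L": 5, "ICECAPA": 4}

N_DIMENSIONS = 5
_RANGE_TOL = 1e-9

_DIM_COLS = [f"dim{i}" for i in range(1, N_DIMENSIONS + 1)]

# Toy additive decrements: fraction of the dimension's maximum decrement lost
# at each level, and the per-dimension maxima. EQ-5D-5L maxima sum to 1.446 so
# the worst profile (5,5,5,5,5) scores exactly -0.446; ICECAP-A maxima sum to
# 1.0 so the no-capability profile (1,1,1,1,1) scores 0.
_EQ5D_MAX_DECREMENT = (0.270, 0.250, 0.250, 0.366, 0.310)
_EQ5D_LEVEL_FRACTION = (0.0, 0.15, 0.35, 0.65, 1.0)
_ICECAP_MAX_DECREMENT = (0.20, 0.20, 0.20, 0.20, 0.20)


@dataclass(frozen=True)
class DiscountPolicy:
    """Annual discounting applied to accrual after ``cutover_month``.

    Parameters
    ----------
    rate_effects : float
        Annual discount rate for effects (default 1.5%).
    rate_costs : float
        Annual discount rate for costs (default 4%). Used by the costing
        module; kept here so one policy object travels through the pipeline.
    cutover_month : int
        Accrual in months strictly after this point is discounted by one
        annual factor. With the default of 12, year-two accrual (the T15 and
        T18 periods) is multiplied by 1/(1+rate).
    """

    rate_effects: float = 0.015
    rate_costs: float = 0.04
    cutover_month: int = 12

    def __post_init__(self) -> None:
        if self.rate_effects < 0 or self.rate_costs < 0:
            raise ConfigurationError("discount rates must be non-negative")
        if not 0 <= self.cutover_month <= 18:
            raise ConfigurationError("cutover_month must lie within the 18-month horizon")

    @property
    def effect_factor(self) -> float:
        return 1.0 / (1.0 + self.rate_effects)

    @property
    def cost_factor(self) -> float:
        return 1.0 / (1.0 + self.rate_costs)


class TariffTable:
    """Societal valuation of instrument level profiles.

    Wraps a DataFrame with columns ``dim1..dim5`` and ``utility`` and provides
    validated O(1) profile lookup.
    """

    def __init__(self, instrument: str, table: pd.DataFrame):
        if instrument not in INSTRUMENT_RANGES:
            raise ValidationError(f"unknown instrument {instrument!r}")
        missing = [c for c in _DIM_COLS + ["utility"] if c not in table.columns]
        if missing:
            raise ValidationError(f"tariff table missing columns {missing}")
        self.instrument = instrument
        self.table = table.reset_index(drop=True)
        lo, hi = INSTRUMENT_RANGES[instrument]
        utils = table["utility"].to_numpy(float)
        if (utils < lo - _RANGE_TOL).any() or (utils > hi + _RANGE_TOL).any():
            raise ValidationError(
                f"tariff utilities outside the {instrument} range [{lo}, {hi}]"
            )
        keys = map(tuple, table[_DIM_COLS].astype(int).to_numpy())
        self._lookup = dict(zip(keys, utils))

    def utility(self, profile: Sequence[int]) -> float:
        """Tariff value of one level profile (validates dimension and levels)."""
        profile = tuple(int(level) for level in profile)
        if len(profile) != N_DIMENSIONS:
            raise ValidationError(
                f"{self.instrument} profiles have {N_DIMENSIONS} dimensions, got {len(profile)}"
            )
        n_levels = INSTRUMENT_LEVELS[self.instrument]
        for i, level in enumerate(profile, start=1):
            if not 1 <= level <= n_levels:
                raise ValidationError(
                    f"level {level} out of range 1..{n_levels} in dimension {i}"
                )
        try:
            return float(self._lookup[profile])
        except KeyError:
            raise TariffCoverageError(
                f"profile {profile} absent from the {self.instrument} tariff"
            ) from None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, instrument: str, path) -> "TariffTable":
        return cls(instrument, pd.read_csv(path))


def toy_tariff(instrument: str) -> TariffTable:
    """Build the bundled synthetic toy tariff for ``instrument``.

    Additive decrements per dimension; the best profile scores exactly 1.0 and
    the worst scores the instrument's lower bound (-0.446 or 0.0).
    """
    n_levels = INSTRUMENT_LEVELS[instrument]
    if instrument == "EQ5D5L":
        # level 1 = no problems; decrement grows with the level
        dec = np.array(
            [[frac * mx for frac in _EQ5D_LEVEL_FRACTION] for mx in _EQ5D_MAX_DECREMENT]
        )
    elif instrument == "ICECAPA":
        # level 4 = full capability; decrement grows as the level falls
        dec = np.array(
            [[(n_levels - lvl) / (n_levels - 1) * mx for lvl in range(1, n_levels + 1)]
             for mx in _ICECAP_MAX_DECREMENT]
        )
    else:
        raise ValidationError(f"unknown instrument {instrument!r}")
    profiles = np.array(list(itertools.product(range(1, n_levels + 1), repeat=N_DIMENSIONS)))
    utilities = 1.0 - dec[np.arange(N_DIMENSIONS), profiles - 1].sum(axis=1)
    lo, _ = INSTRUMENT_RANGES[instrument]
    utilities = np.clip(utilities, lo, 1.0)  # guard float dust at the anchor
    frame = pd.DataFrame(profiles, columns=_DIM_COLS)
    frame["utility"] = utilities
    return TariffTable(instrument, frame)


def utility_from_profile(profile: Sequence[int], tariff: TariffTable) -> float:
    """Look up the utility of one level profile in a tariff table."""
    return tariff.utility(profile)


def _as_month_map(
    utilities: Mapping[int, float] | Sequence[float],
    months: Sequence[int],
) -> dict[int, float]:
    if isinstance(utilities, Mapping):
        return {int(k): float(v) for k, v in utilities.items()}
    vals = list(utilities)
    if len(vals) != len(months):
        raise ValidationError(
            f"expected {len(months)} utilities for months {tuple(months)}, got {len(vals)}"
        )
    return {m: float(v) for m, v in zip(months, vals)}


def accrue(
    utilities: Mapping[int, float] | Sequence[float],
    policy: DiscountPolicy | None = None,
    instrument: str = "EQ5D5L",
    months: Sequence[int] = UTILITY_MONTHS,
) -> float:
    """Discounted trapezoid accrual of utilities into QALYs or WALYs.

    ``utilities`` is either a mapping month -> utility or a sequence aligned
    with ``months``. Each interval contributes its trapezoid area in year
    units; intervals starting at or after ``policy.cutover_month`` are
    multiplied by ``1/(1 + rate_effects)``.

    Raises
    ------
    PreconditionError
        If any scheduled observation is missing or non-finite (imputation is
        an upstream responsibility), naming the offending month.
    ValidationError
        If a utility lies outside the instrument's range.
    """
    if policy is None:
        policy = DiscountPolicy()
    by_month = _as_month_map(utilities, months)
    lo, hi = INSTRUMENT_RANGES[instrument]
    for m in months:
        if m not in by_month or not np.isfinite(by_month[m]):
            raise PreconditionError(f"utility at month {m} is missing")
        if not lo - _RANGE_TOL <= by_month[m] <= hi + _RANGE_TOL:
            raise ValidationError(
                f"utility {by_month[m]} at month {m} outside {instrument} range [{lo}, {hi}]"
            )
    total = 0.0
    ordered = sorted(months)
    for t0, t1 in zip(ordered[:-1], ordered[1:]):
        segment = 0.5 * (by_month[t0] + by_month[t1]) * (t1 - t0) / 12.0
        if t0 >= policy.cutover_month:
            segment *= policy.effect_factor
        total += segment
    return total


class UtilityAccrual(TransformerMixin, BaseEstimator):
    """Vectorised QALY/WALY accrual as a scikit-learn transformer.

    ``transform`` maps an ``(n, 4)`` array of utilities at months 0/6/12/18 to
    an ``(n,)`` array of discounted life-year-adjusted values. Stateless;
    ``fit`` only validates parameters.
    """

    def __init__(
        self,
        rate_effects: float = 0.015,
        cutover_month: int = 12,
        instrument: str = "EQ5D5L",
    ):
        self.rate_effects = rate_effects
        self.cutover_month = cutover_month
        self.instrument = instrument

    def _policy(self) -> DiscountPolicy:
        return DiscountPolicy(
            rate_effects=self.rate_effects, cutover_month=self.cutover_month
        )

    def _weights(self) -> np.ndarray:
        policy = self._policy()
        months = np.asarray(UTILITY_MONTHS, dtype=float)
        w = np.zeros(len(months))
        for i in range(len(months) - 1):
            width = (months[i + 1] - months[i]) / 12.0
            factor = policy.effect_factor if months[i] >= policy.cutover_month else 1.0
            w[i] += 0.5 * width * factor
            w[i + 1] += 0.5 * width * factor
        return w

    def fit(self, X=None, y=None) -> "UtilityAccrual":
        self._policy()
        self.weights_ = self._weights()
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(UTILITY_MONTHS):
            raise ValidationError(
                f"expected an (n, {len(UTILITY_MONTHS)}) utility matrix, got shape {X.shape}"
            )
        if not np.isfinite(X).all():
            bad = np.argwhere(~np.isfinite(X))[0]
            raise PreconditionError(
                f"utility at month {UTILITY_MONTHS[bad[1]]} is missing (row {bad[0]})"
            )
        return X @ self._weights()


def utilities_from_table(
    table: pd.DataFrame, tariffs: Mapping[str, TariffTable]
) -> pd.DataFrame:
    """Normalise a long utilities table to (participant_id, instrument, month, utility).

    Accepts either a ``utility`` column or level-profile columns ``dim1..dim5``
    (converted through the supplied tariffs).
    """
    table = table.copy()
    if "utility" in table.columns:
        return table[["participant_id", "instrument", "month", "utility"]]
    if not all(c in table.columns for c in _DIM_COLS):
        raise ValidationError("utilities table needs a 'utility' column or dim1..dim5 levels")

    def _value(row) -> float:
        levels = row[_DIM_COLS]
        if levels.isna().any():
            return np.nan
        return tariffs[row["instrument"]].utility(levels.astype(int))

    table["utility"] = table.apply(_value, axis=1)
    return table[["participant_id", "instrument", "month", "utility"]]
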