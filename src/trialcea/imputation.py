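"""Three-tier missing-data handling and Rubin's-rules pooling.

Missingness in trial questionnaires arises at three levels and each gets its
own remedy, applied in order:

1. *Item level* — a contact was reported but its volume was not
   (``item_missing`` flag): filled deterministically with the arm x timepoint
   mean of observed volumes, falling back to the participant's own mean over
   other timepoints, and escalating to questionnaire-level missingness when no
   donor information exists anywhere.
2. *Home care* — extremely zero-inflated (about 95-99% of participants report
   none), so chained-equation imputation is not viable; each participant's
   missing entries are set to the mode of their own observed series (smallest
   value on ties), falling back to the arm-level mode.
3. *Questionnaire level* — utilities and period cost totals are imputed with
   multiple imputation by chained equations using predictive mean matching
   (MICE-PMM), split by treatment arm, producing ``m`` completed datasets.

Estimates from the m completed datasets are pooled with Rubin's rules:
pooled estimate = mean, total variance ``T = W + (1 + 1/m) B`` with ``W`` the
mean within-imputation variance and ``B`` the between-imputation variance,
and confidence intervals from a t distribution with (Barnard-)Rubin degrees
of freedom.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .costing import HOME_CARE_CATEGORIES
from .exceptions import ConfigurationError, ImputationError, ValidationError

_MODE_NONE = object()


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for the chained-equations stage.

    ``m`` completed datasets (default 15, matching an expected ~15% of missing
    outcome data), ``pmm_donors`` nearest predicted-mean neighbours per draw,
    ``max_iterations`` chained cycles, and arm-wise splitting on by default.
    """

    m: int = 15
    pmm_donors: int = 5
    split_by_arm: bool = True
    max_iterations: int = 20
    seed: int | None = None
    predictors: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ConfigurationError("m must be at least 2")
        if self.pmm_donors < 1:
            raise ConfigurationError("pmm_donors must be at least 1")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be at least 1")


@dataclass
class PooledEstimate:
    """Rubin's-rules pooled estimate over m imputed datasets."""

    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    ci_low: float
    ci_high: float
    m: int
    df: float

    @property
    def se(self) -> float:
        return math.sqrt(self.total_variance)


def item_level_fill(
    resources: pd.DataFrame,
    participants: pd.DataFrame,
    skip_categories: Sequence[str] = HOME_CARE_CATEGORIES,
) -> tuple[pd.DataFrame, list[dict]]:
    """Resolve item-level gaps (contact reported, volume missing).

    Fills each flagged missing volume with the mean of observed positive
    volumes in the same arm x timepoint x category cell; if the cell has no
    donors, with the participant's own mean over other timepoints; otherwise
    the gap is left NaN with its flag cleared, escalating it to
    questionnaire-level missingness. Home-care categories are skipped (they
    have their own tier). Returns the completed panel and a provenance list.
    """
    resources = resources.copy()
    if "item_missing" not in resources.columns:
        resources["item_missing"] = 0
    arm_of = participants.set_index("participant_id")["arm"]
    resources["_arm"] = resources["participant_id"].map(arm_of)

    flagged = resources["item_missing"].astype(bool) & resources["volume"].isna()
    flagged &= ~resources["category"].isin(list(skip_categories))
    observed = resources["volume"].notna()

    donors = resources[observed & (resources["volume"] > 0)]
    cell_means = donors.groupby(["_arm", "month", "category"], observed=True)["volume"].mean()
    own = resources[observed]
    own_means = own.groupby(["participant_id", "category"], observed=True)["volume"].mean()

    provenance: list[dict] = []
    fill = pd.Series(np.nan, index=resources.index[flagged])
    for idx in resources.index[flagged]:
        row = resources.loc[idx]
        key = (row["_arm"], row["month"], row["category"])
        if key in cell_means.index:
            value, tier = cell_means.loc[key], "arm_timepoint_mean"
        elif (row["participant_id"], row["category"]) in own_means.index:
            value, tier = own_means.loc[(row["participant_id"], row["category"])], "participant_mean"
        else:
            value, tier = np.nan, "escalated_to_questionnaire"
        fill.loc[idx] = value
        provenance.append(
            {
                "participant_id": row["participant_id"],
                "month": int(row["month"]),
                "category": str(row["category"]),
                "tier": tier,
                "value": None if np.isnan(value) else float(value),
            }
        )
    resources.loc[fill.index, "volume"] = fill
    resources.loc[flagged, "item_missing"] = 0
    return resources.drop(columns="_arm"), provenance


def _smallest_mode(values: np.ndarray):
    """Most frequent value; smallest on ties. None for empty input."""
    if len(values) == 0:
        return _MODE_NONE
    uniq, counts = np.unique(values, return_counts=True)
    return uniq[counts == counts.max()].min()


def home_care_impute(
    resources: pd.DataFrame,
    participants: pd.DataFrame,
    categories: Sequence[str] = HOME_CARE_CATEGORIES,
) -> tuple[pd.DataFrame, list[dict]]:
    """Complete home-care series with each participant's modal value.

    Deterministic: every missing home-care entry becomes the mode of that
    participant's observed values for the category (smallest modal value on
    ties); a fully missing series falls back to the arm-level mode, recorded
    in provenance.
    """
    resources = resources.copy()
    arm_of = participants.set_index("participant_id")["arm"]
    provenance: list[dict] = []
    mask_cat = resources["category"].isin(list(categories))
    sub = resources[mask_cat]
    arm_modes = {
        (arm, cat): _smallest_mode(grp["volume"].dropna().to_numpy())
        for (arm, cat), grp in sub.assign(_arm=sub["participant_id"].map(arm_of)).groupby(
            ["_arm", "category"], observed=True
        )
    }
    for (pid, cat), grp in sub.groupby(["participant_id", "category"], observed=True):
        missing_idx = grp.index[grp["volume"].isna()]
        if len(missing_idx) == 0:
            continue
        mode = _smallest_mode(grp["volume"].dropna().to_numpy())
        tier = "participant_mode"
        if mode is _MODE_NONE:
            mode = arm_modes.get((arm_of.loc[pid], cat), _MODE_NONE)
            tier = "arm_mode"
        if mode is _MODE_NONE:
            mode = 0.0  # no home care observed anywhere in the arm
            tier = "arm_mode_empty_zero"
        resources.loc[missing_idx, "volume"] = float(mode)
        for idx in missing_idx:
            provenance.append(
                {
                    "participant_id": pid,
                    "month": int(resources.loc[idx, "month"]),
                    "category": cat,
                    "tier": tier,
                    "value": float(mode),
                }
            )
    if "item_missing" in resources.columns:
        resources.loc[mask_cat, "item_missing"] = 0
    return resources, provenance


class ChainedEquationsImputer(BaseEstimator):
    """Multiple imputation by chained equations with predictive mean matching.

    For each incomplete variable (visited in order of ascending missingness) a
    linear regression on the variable's predictor set is fit to the observed
    rows; regression coefficients are perturbed with a draw from their
    sampling distribution, and each missing entry receives the *observed*
    value of one of the ``pmm_donors`` rows whose predicted mean is nearest to
    the missing row's prediction. Arms are imputed independently when
    ``split_by_arm`` (the recommended practice for trial data). Deterministic
    given ``random_state``; every imputed value lies within the observed
    support of its variable (the PMM property).

    Parameters mirror :class:`ImputationConfig`; ``columns`` is the set of
    imputable outcome columns and ``predictors`` the always-complete covariate
    columns. The per-variable regression uses the covariates plus the same
    variable family (identical column prefix up to ``_m``) at other
    timepoints.
    """

    def __init__(
        self,
        m: int = 15,
        pmm_donors: int = 5,
        max_iterations: int = 20,
        split_by_arm: bool = True,
        group_col: str = "arm",
        columns: tuple[str, ...] | None = None,
        predictors: tuple[str, ...] | None = None,
        family_predictors: bool = True,
        random_state: int | None = None,
        ridge: float = 1e-6,
    ):
        self.m = m
        self.pmm_donors = pmm_donors
        self.max_iterations = max_iterations
        self.split_by_arm = split_by_arm
        self.group_col = group_col
        self.columns = columns
        self.predictors = predictors
        self.family_predictors = family_predictors
        self.random_state = random_state
        self.ridge = ridge

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _family(col: str) -> str:
        return col.rsplit("_m", 1)[0] if "_m" in col else col

    def _model_columns(self, target: str, impute_cols: list[str], predictors: list[str]) -> list[str]:
        cols = list(predictors)
        if self.family_predictors:
            cols += [c for c in impute_cols if c != target and self._family(c) == self._family(target)]
        else:
            cols += [c for c in impute_cols if c != target]
        return cols

    def _impute_group(
        self,
        frame: pd.DataFrame,
        impute_cols: list[str],
        predictors: list[str],
        rng: np.random.Generator,
    ) -> pd.DataFrame:
        out = frame.copy()
        masks = {c: frame[c].isna().to_numpy() for c in impute_cols}
        incomplete = [c for c in impute_cols if masks[c].any()]
        for c in incomplete:
            if masks[c].all():
                raise ImputationError(f"variable {c!r} has no observed values in its group")
        incomplete.sort(key=lambda c: (masks[c].mean(), c))

        # initialise gaps with random draws from the observed marginal
        for c in incomplete:
            observed = frame.loc[~masks[c], c].to_numpy(float)
            out.loc[masks[c], c] = rng.choice(observed, size=int(masks[c].sum()), replace=True)

        k = self.pmm_donors
        for _ in range(self.max_iterations):
            for c in incomplete:
                miss = masks[c]
                model_cols = self._model_columns(c, impute_cols, predictors)
                X = np.column_stack(
                    [np.ones(len(out))] + [out[mc].to_numpy(float) for mc in model_cols]
                )
                y = out[c].to_numpy(float)
                Xo, yo = X[~miss], y[~miss]
                XtX = Xo.T @ Xo
                lam = self.ridge * max(np.trace(XtX) / XtX.shape[0], 1.0)
                A = XtX + lam * np.eye(XtX.shape[0])
                beta = np.linalg.solve(A, Xo.T @ yo)
                resid = yo - Xo @ beta
                dof = max(len(yo) - X.shape[1], 1)
                sigma2 = float(resid @ resid) / dof
                # Bayesian-flavoured parameter draw (type-1 PMM)
                cov = sigma2 * np.linalg.inv(A)
                beta_star = rng.multivariate_normal(beta, cov)
                yhat_obs = Xo @ beta
                yhat_mis = X[miss] @ beta_star
                order = np.argsort(np.abs(yhat_obs[None, :] - yhat_mis[:, None]), axis=1, kind="stable")
                donor_pool = order[:, : min(k, len(yo))]
                choice = rng.integers(0, donor_pool.shape[1], size=donor_pool.shape[0])
                donors = donor_pool[np.arange(len(choice)), choice]
                vals = y.copy()
                vals[miss] = yo[donors]
                out[c] = vals
        return out

    # -- API ---------------------------------------------------------------

    def fit_transform(self, frame: pd.DataFrame, y=None) -> list[pd.DataFrame]:
        """Return ``m`` completed copies of ``frame`` (deterministic given seed)."""
        if self.m < 2:
            raise ConfigurationError("m must be at least 2")
        if self.pmm_donors < 1:
            raise ConfigurationError("pmm_donors must be at least 1")
        impute_cols = list(self.columns) if self.columns is not None else [
            c for c in frame.columns if frame[c].dtype.kind in "fi" and frame[c].isna().any()
        ]
        predictors = list(self.predictors or [])
        for c in impute_cols + predictors:
            if c not in frame.columns:
                raise ValidationError(f"column {c!r} not in frame")
        for c in impute_cols:
            if frame[c].notna().sum() == 0:
                raise ImputationError(f"variable {c!r} has no observed values")

        if self.split_by_arm:
            if self.group_col not in frame.columns:
                raise ValidationError(f"group column {self.group_col!r} not in frame")
            groups = [(key, g) for key, g in frame.groupby(self.group_col, sort=True, observed=True)]
        else:
            groups = [("__all__", frame)]

        # One independent stream per (imputation, group key), keyed by a stable
        # digest of the group label so each arm's chain never consumes entropy
        # from the other arm's data.
        base = 0 if self.random_state is None else int(self.random_state)
        completed: list[pd.DataFrame] = []
        for imp_idx in range(self.m):
            parts = []
            for key, g in groups:
                digest = zlib.crc32(str(key).encode("utf8"))
                rng = np.random.default_rng(np.random.SeedSequence([base, imp_idx, digest]))
                parts.append(self._impute_group(g, impute_cols, predictors, rng))
            completed.append(pd.concat(parts).loc[frame.index])
        self.n_imputations_ = self.m
        self.imputed_columns_ = impute_cols
        return completed

    def fit(self, frame: pd.DataFrame, y=None) -> "ChainedEquationsImputer":
        self.completed_ = self.fit_transform(frame)
        return self


def mice_pmm(
    frame: pd.DataFrame,
    config: ImputationConfig | None = None,
    columns: Sequence[str] | None = None,
    predictors: Sequence[str] | None = None,
    group_col: str = "arm",
) -> list[pd.DataFrame]:
    """Functional wrapper over :class:`ChainedEquationsImputer`."""
    config = config or ImputationConfig()
    imputer = ChainedEquationsImputer(
        m=config.m,
        pmm_donors=config.pmm_donors,
        max_iterations=config.max_iterations,
        split_by_arm=config.split_by_arm,
        group_col=group_col,
        columns=tuple(columns) if columns is not None else None,
        predictors=tuple(predictors) if predictors is not None else (config.predictors or None),
        random_state=config.seed,
    )
    return imputer.fit_transform(frame)


def rubin_pool(
    estimates: Sequence[float],
    variances: Sequence[float],
    df_complete: float | None = None,
    alpha: float = 0.05,
) -> PooledEstimate:
    """Pool m estimates and their variances with Rubin's rules.

    ``T = W + (1 + 1/m) B``; the confidence interval uses a t distribution
    with Rubin's large-sample degrees of freedom, replaced by the
    Barnard-Rubin small-sample adjustment when ``df_complete`` is given. With
    ``B = 0`` (identical imputations) the interval is normal-theory.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape or est.ndim != 1:
        raise ValidationError("estimates and variances must be 1-d and the same length")
    m = len(est)
    if m < 2:
        raise ValidationError("Rubin pooling requires at least 2 imputations")
    if (var < 0).any():
        raise ValidationError("variances must be non-negative")

    pooled = float(est.mean())
    W = float(var.mean())
    # identical estimates have exactly zero between-imputation variance
    # (guard float dust from the mean subtraction)
    B = 0.0 if np.ptp(est) == 0.0 else float(est.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B

    if B == 0.0 or T == 0.0:
        df = math.inf
    else:
        lam = (1.0 + 1.0 / m) * B / T
        df = (m - 1) / lam**2
        if df_complete is not None:
            df_obs = (df_complete + 1.0) / (df_complete + 3.0) * df_complete * (1.0 - lam)
            df = 1.0 / (1.0 / df + 1.0 / df_obs)
    crit = stats.norm.ppf(1 - alpha / 2) if math.isinf(df) else stats.t.ppf(1 - alpha / 2, df)
    half = crit * math.sqrt(T)
    return PooledEstimate(
        estimate=pooled,
        within_variance=W,
        between_variance=B,
        total_variance=T,
        ci_low=pooled - half,
        ci_high=pooled + half,
        m=m,
        df=df,
    )
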