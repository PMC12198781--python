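"""Incremental cost-effectiveness estimation with bootstrap uncertainty.

Adjusted mean differences in costs (dC) and effects (dE) between arms come
from ordinary least squares with the arm indicator and baseline covariates
(baseline cost and utility, age, sex, condition flags). The incremental
cost-effectiveness ratio is ICER = dC / dE from the *unrounded* pooled
estimates. Sampling uncertainty is characterised by non-parametric
bootstrapping: participants are resampled with replacement, stratified by
arm, within each imputed dataset (ceil(B/m) replicates per dataset,
concatenated and truncated to B pairs), and the (dC*, dE*) cloud is
summarised as cost-effectiveness-plane quadrant proportions and a
cost-effectiveness acceptability curve CEAC(lambda) = P(lambda dE - dC > 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import PreconditionError, SingularityError, ValidationError
from .imputation import PooledEstimate, rubin_pool

#: Ceiling ratios (euros per unit effect) for the acceptability curve.
DEFAULT_WTP_GRID: tuple[float, ...] = tuple(float(x) for x in range(0, 100_001, 500))

DEFAULT_WTP_REFERENCE = 20_000.0

#: |dE| below this is treated as zero when forming an ICER.
ICER_TOLERANCE = 1e-9


@dataclass(frozen=True)
class AdjustmentSpec:
    """One adjusted-regression contrast: outcome ~ arm + covariates."""

    outcome: str
    covariates: tuple[str, ...]
    arm_col: str = "arm_indicator"


@dataclass
class BootstrapResult:
    """Bootstrap (dC*, dE*) pairs; ``pairs`` has shape (B, 2)."""

    pairs: np.ndarray
    B: int
    seed: int | None
    n_redrawn: int = 0

    @property
    def delta_cost(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def delta_effect(self) -> np.ndarray:
        return self.pairs[:, 1]


@dataclass
class IncrementalResult:
    """Pooled incremental result for one scenario."""

    delta_cost: float
    delta_cost_ci: tuple[float, float]
    delta_effect: float
    delta_effect_ci: tuple[float, float]
    icer: float | None
    quadrants: dict[str, float]
    ceac: dict[float, float]
    wtp_reference: float = DEFAULT_WTP_REFERENCE
    prob_cost_effective: float = math.nan
    pooled_cost: PooledEstimate | None = None
    pooled_effect: PooledEstimate | None = None

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_cost_ci": list(self.delta_cost_ci),
            "delta_effect": self.delta_effect,
            "delta_effect_ci": list(self.delta_effect_ci),
            "icer": self.icer,
            "quadrants": self.quadrants,
            "wtp_reference": self.wtp_reference,
            "prob_cost_effective": self.prob_cost_effective,
            "ceac": {str(k): v for k, v in self.ceac.items()},
        }


def _design(frame: pd.DataFrame, spec: AdjustmentSpec) -> tuple[np.ndarray, np.ndarray]:
    cols = [spec.arm_col, *spec.covariates]
    missing = [c for c in cols + [spec.outcome] if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing columns {missing}")
    X = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy(float) for c in cols])
    y = frame[spec.outcome].to_numpy(float)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise PreconditionError("outcome and covariates must be complete (impute first)")
    return X, y


def _arm_effect(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS arm coefficient (column 1) and its squared standard error."""
    n, p = X.shape
    XtX = X.T @ X
    try:
        beta = np.linalg.solve(XtX, X.T @ y)
        inv_col = np.linalg.solve(XtX, np.eye(p)[:, 1])
    except np.linalg.LinAlgError:
        raise SingularityError("design matrix is singular") from None
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / max(n - p, 1)
    return float(beta[1]), sigma2 * float(inv_col[1])


def adjusted_difference(
    frame: pd.DataFrame, spec: AdjustmentSpec
) -> tuple[float, float]:
    """Adjusted between-arm mean difference on one completed dataset.

    Fits ``outcome ~ intercept + arm + covariates`` by OLS and returns the arm
    coefficient and its squared standard error. Collinear covariates raise
    :class:`SingularityError` naming the offending columns.
    """
    X, y = _design(frame, spec)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = ["intercept", spec.arm_col, *spec.covariates]
        offenders = _collinear_columns(X, names)
        raise SingularityError(f"collinear design columns: {offenders}")
    return _arm_effect(X, y)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    offenders = []
    for j in range(1, X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
            offenders.append(names[j])
    return offenders or names[1:]


def icer(delta_cost: float, delta_effect: float, tolerance: float = ICER_TOLERANCE) -> float:
    """dC / dE; NaN (the undefined flag) when |dE| is below tolerance.

    Sign interpretation is deferred to the CE-plane quadrants: a negative
    ICER is ambiguous between dominance and being dominated.
    """
    if abs(delta_effect) < tolerance:
        return math.nan
    return float(delta_cost) / float(delta_effect)


def bootstrap_pairs(
    frames: Sequence[pd.DataFrame],
    cost_spec: AdjustmentSpec,
    effect_spec: AdjustmentSpec,
    B: int = 5000,
    seed: int | None = None,
    arm_col: str = "arm_indicator",
    max_redraws: int = 100,
) -> BootstrapResult:
    """Arm-stratified non-parametric bootstrap of (dC*, dE*) pairs.

    Within each of the m imputed datasets, participants are resampled with
    replacement separately per arm (preserving arm sizes) and both adjusted
    regressions are refit; ceil(B/m) replicates per dataset are concatenated
    and truncated to B. A replicate whose resampled design is singular (e.g. a
    covariate constant in the resample) is redrawn and counted, never
    silently dropped.
    """
    if B < 1:
        raise ValidationError("B must be positive")
    m = len(frames)
    per_frame = math.ceil(B / m)
    rng = np.random.default_rng(seed)
    pairs = np.empty((per_frame * m, 2))
    n_redrawn = 0
    row = 0
    for frame in frames:
        Xc, yc = _design(frame, cost_spec)
        Xe, ye = _design(frame, effect_spec)
        arm = frame[arm_col].to_numpy(float)
        idx_by_arm = [np.flatnonzero(arm == v) for v in (0.0, 1.0)]
        if any(len(ix) == 0 for ix in idx_by_arm):
            raise ValidationError("both arms must be present in every dataset")
        for _ in range(per_frame):
            for attempt in range(max_redraws + 1):
                take = np.concatenate(
                    [rng.choice(ix, size=len(ix), replace=True) for ix in idx_by_arm]
                )
                try:
                    dc, _ = _arm_effect(Xc[take], yc[take])
                    de, _ = _arm_effect(Xe[take], ye[take])
                except SingularityError:
                    n_redrawn += 1
                    continue
                if np.isfinite(dc) and np.isfinite(de):
                    break
                n_redrawn += 1
            else:
                raise ValidationError("bootstrap replicate could not be drawn")
            pairs[row] = (dc, de)
            row += 1
    return BootstrapResult(pairs=pairs[:B], B=B, seed=seed, n_redrawn=n_redrawn)


def quadrant_proportions(pairs: np.ndarray) -> dict[str, float]:
    """CE-plane quadrant shares of (dC, dE) pairs; sums to exactly 1.

    NE: dE>0, dC>0 (more effective, more costly); SE: dE>0, dC<=0 (dominant);
    SW: dE<=0, dC<=0; NW: dE<=0, dC>0 (dominated).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        raise ValidationError("empty pair set")
    dc, de = pairs[:, 0], pairs[:, 1]
    ne = float(np.mean((de > 0) & (dc > 0)))
    se = float(np.mean((de > 0) & (dc <= 0)))
    sw = float(np.mean((de <= 0) & (dc <= 0)))
    # complement against the accumulated partial sum so the four proportions
    # add to exactly 1.0 in floating point
    partial = ne + se + sw
    nw = max(0.0, 1.0 - partial)
    return {"NE": ne, "SE": se, "SW": sw, "NW": nw}


def ceac(pairs: np.ndarray, wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> dict[float, float]:
    """Acceptability curve: CEAC(lambda) = share of pairs with lambda*dE - dC > 0.

    CEAC(0) is the probability of cost saving; the large-lambda limit is the
    probability of a positive effect.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        raise ValidationError("empty pair set")
    grid = np.asarray(list(wtp_grid), dtype=float)
    if (grid < 0).any():
        raise ValidationError("willingness-to-pay values must be non-negative")
    dc, de = pairs[:, 0], pairs[:, 1]
    nb = grid[:, None] * de[None, :] - dc[None, :]
    probs = (nb > 0).mean(axis=1)
    return {float(l): float(p) for l, p in zip(grid, probs)}


class IncrementalCostEffectiveness(BaseEstimator):
    """Pooled incremental cost-effectiveness analysis over imputed datasets.

    ``fit`` takes the list of m completed analysis datasets (each with the
    outcome columns, arm indicator and covariates), Rubin-pools the adjusted
    dC and dE, bootstraps the joint uncertainty and derives the ICER,
    CE-plane quadrants and the CEAC.

    Fitted attributes: ``delta_cost_``, ``delta_effect_`` (with ``*_ci_``),
    ``icer_``, ``quadrants_``, ``ceac_``, ``prob_cost_effective_``,
    ``bootstrap_`` and ``result_``.
    """

    def __init__(
        self,
        cost_col: str = "total_cost",
        effect_col: str = "qaly",
        covariates: tuple[str, ...] = (),
        arm_col: str = "arm_indicator",
        B: int = 5000,
        wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
        wtp_reference: float = DEFAULT_WTP_REFERENCE,
        random_state: int | None = None,
        df_complete: float | None = None,
    ):
        self.cost_col = cost_col
        self.effect_col = effect_col
        self.covariates = covariates
        self.arm_col = arm_col
        self.B = B
        self.wtp_grid = wtp_grid
        self.wtp_reference = wtp_reference
        self.random_state = random_state
        self.df_complete = df_complete

    def fit(self, frames: Sequence[pd.DataFrame], y=None) -> "IncrementalCostEffectiveness":
        if len(frames) == 0:
            raise ValidationError("need at least one completed dataset")
        cost_spec = AdjustmentSpec(self.cost_col, tuple(self.covariates), self.arm_col)
        effect_spec = AdjustmentSpec(self.effect_col, tuple(self.covariates), self.arm_col)

        cost_fits = [adjusted_difference(f, cost_spec) for f in frames]
        effect_fits = [adjusted_difference(f, effect_spec) for f in frames]
        if len(frames) >= 2:
            pooled_c = rubin_pool(*zip(*cost_fits), df_complete=self.df_complete)
            pooled_e = rubin_pool(*zip(*effect_fits), df_complete=self.df_complete)
        else:
            pooled_c = _single_fit_estimate(*cost_fits[0], self.df_complete)
            pooled_e = _single_fit_estimate(*effect_fits[0], self.df_complete)

        boot = bootstrap_pairs(
            list(frames), cost_spec, effect_spec, B=self.B,
            seed=self.random_state, arm_col=self.arm_col,
        )
        quads = quadrant_proportions(boot.pairs)
        curve = ceac(boot.pairs, self.wtp_grid)
        icer_value = icer(pooled_c.estimate, pooled_e.estimate)
        ref_pairs = boot.pairs
        prob_ref = float(
            np.mean(self.wtp_reference * ref_pairs[:, 1] - ref_pairs[:, 0] > 0)
        )

        self.pooled_cost_ = pooled_c
        self.pooled_effect_ = pooled_e
        self.delta_cost_ = pooled_c.estimate
        self.delta_cost_ci_ = (pooled_c.ci_low, pooled_c.ci_high)
        self.delta_effect_ = pooled_e.estimate
        self.delta_effect_ci_ = (pooled_e.ci_low, pooled_e.ci_high)
        self.icer_ = None if math.isnan(icer_value) else icer_value
        self.quadrants_ = quads
        self.ceac_ = curve
        self.prob_cost_effective_ = prob_ref
        self.bootstrap_ = boot
        self.result_ = IncrementalResult(
            delta_cost=self.delta_cost_,
            delta_cost_ci=self.delta_cost_ci_,
            delta_effect=self.delta_effect_,
            delta_effect_ci=self.delta_effect_ci_,
            icer=self.icer_,
            quadrants=quads,
            ceac=curve,
            wtp_reference=self.wtp_reference,
            prob_cost_effective=prob_ref,
            pooled_cost=pooled_c,
            pooled_effect=pooled_e,
        )
        return self


def _single_fit_estimate(estimate: float, variance: float, df_complete: float | None) -> PooledEstimate:
    """Complete-data analogue of a pooled estimate (no imputation spread)."""
    from scipy import stats

    df = df_complete if df_complete is not None else math.inf
    crit = stats.norm.ppf(0.975) if math.isinf(df) else stats.t.ppf(0.975, df)
    half = crit * math.sqrt(variance)
    return PooledEstimate(
        estimate=float(estimate),
        within_variance=float(variance),
        between_variance=0.0,
        total_variance=float(variance),
        ci_low=float(estimate) - half,
        ci_high=float(estimate) + half,
        m=1,
        df=df,
    )
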