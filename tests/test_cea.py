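"""Adjusted contrasts, ICER arithmetic, bootstrap, quadrants and CEACs."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import trialcea as t
from trialcea.cea import AdjustmentSpec, bootstrap_pairs, ceac, quadrant_proportions


def _random_frame(seed, n=80, effect=0.5):
    rng = np.random.default_rng(seed)
    arm = np.repeat([0.0, 1.0], n // 2)
    age = rng.normal(60, 8, n)
    base = rng.normal(10, 2, n)
    y = 5 + 0.3 * age + 0.5 * base + effect * arm + rng.normal(0, 1, n)
    cost = 100 + 2 * age + 30 * arm + rng.normal(0, 20, n)
    return pd.DataFrame(
        {
            "arm_indicator": arm,
            "age": age,
            "baseline": base,
            "effect_outcome": y,
            "total_cost": cost,
        }
    )


class TestAdjustedDifference:
    def test_null_contrast_on_mirrored_arms(self):
        frame = pd.DataFrame(
            {
                "arm_indicator": [0.0, 0.0, 1.0, 1.0],
                "age": [50.0, 60.0, 50.0, 60.0],
                "y": [1.0, 2.0, 1.0, 2.0],
            }
        )
        est, var = t.adjusted_difference(frame, AdjustmentSpec("y", ("age",)))
        assert est == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_ols(self):
        frame = _random_frame(1)
        spec = AdjustmentSpec("effect_outcome", ("age", "baseline"))
        est, var = t.adjusted_difference(frame, spec)
        X = sm.add_constant(frame[["arm_indicator", "age", "baseline"]])
        fit = sm.OLS(frame["effect_outcome"], X).fit()
        assert est == pytest.approx(fit.params["arm_indicator"], rel=1e-10)
        assert var == pytest.approx(fit.bse["arm_indicator"] ** 2, rel=1e-10)

    def test_recovers_simulated_effect(self):
        ests = [
            t.adjusted_difference(
                _random_frame(seed, n=2000), AdjustmentSpec("effect_outcome", ("age", "baseline"))
            )[0]
            for seed in range(8)
        ]
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.5) < 4 * max(se, 1e-3)

    def test_collinear_covariates_named(self):
        frame = _random_frame(2)
        frame["age_copy"] = frame["age"]
        with pytest.raises(t.SingularityError, match="age"):
            t.adjusted_difference(frame, AdjustmentSpec("effect_outcome", ("age", "age_copy")))

    def test_incomplete_data_rejected(self):
        frame = _random_frame(3)
        frame.loc[0, "effect_outcome"] = np.nan
        with pytest.raises(t.PreconditionError):
            t.adjusted_difference(frame, AdjustmentSpec("effect_outcome", ("age",)))


class TestICER:
    def test_printed_rounded_inputs(self):
        assert t.icer(1213, 0.019) == pytest.approx(63842.105, abs=0.01)

    def test_zero_cost_difference(self):
        assert t.icer(0.0, 0.05) == 0.0

    def test_zero_effect_is_flagged_undefined(self):
        assert math.isnan(t.icer(500.0, 0.0))
        assert math.isnan(t.icer(500.0, 1e-12))


class TestBootstrap:
    def _degenerate_frame(self):
        # every participant identical within arm -> zero resampling variance
        rows = []
        for arm, y, cost in ((0.0, 1.0, 100.0), (1.0, 1.4, 180.0)):
            for _ in range(10):
                rows.append({"arm_indicator": arm, "age": 60.0, "y": y, "cost": cost})
        return pd.DataFrame(rows)

    def test_degenerate_data_gives_constant_pairs(self):
        frame = self._degenerate_frame()
        cost_spec = AdjustmentSpec("cost", ())
        effect_spec = AdjustmentSpec("y", ())
        boot = bootstrap_pairs([frame], cost_spec, effect_spec, B=50, seed=0)
        np.testing.assert_allclose(boot.pairs[:, 0], 80.0, atol=1e-9)
        np.testing.assert_allclose(boot.pairs[:, 1], 0.4, atol=1e-9)

    def test_same_seed_reproduces_pairs(self):
        frame = _random_frame(4)
        specs = (
            AdjustmentSpec("total_cost", ("age", "baseline")),
            AdjustmentSpec("effect_outcome", ("age", "baseline")),
        )
        a = bootstrap_pairs([frame], *specs, B=100, seed=42)
        b = bootstrap_pairs([frame], *specs, B=100, seed=42)
        np.testing.assert_array_equal(a.pairs, b.pairs)

    def test_requested_number_of_pairs(self):
        frames = [_random_frame(s) for s in range(3)]
        specs = (
            AdjustmentSpec("total_cost", ("age",)),
            AdjustmentSpec("effect_outcome", ("age",)),
        )
        boot = bootstrap_pairs(frames, *specs, B=100, seed=1)
        assert boot.pairs.shape == (100, 2)
        assert np.isfinite(boot.pairs).all()

    def test_sampling_covariance_tracks_known_truth(self):
        # with iid bivariate-normal outcomes and no covariates, the bootstrap
        # pair cloud estimates the sampling covariance of the two arm-mean
        # differences: Sigma * (1/n0 + 1/n1)
        rng = np.random.default_rng(7)
        n = 400
        cov = np.array([[400.0, 1.5], [1.5, 0.01]])
        draws = rng.multivariate_normal([0, 0], cov, size=2 * n)
        frame = pd.DataFrame(
            {
                "arm_indicator": np.repeat([0.0, 1.0], n),
                "cost": draws[:, 0],
                "eff": draws[:, 1],
            }
        )
        boot = bootstrap_pairs(
            [frame], AdjustmentSpec("cost", ()), AdjustmentSpec("eff", ()), B=5000, seed=8
        )
        expected = cov * (2.0 / n)
        got = np.cov(boot.pairs.T)
        assert got[0, 0] == pytest.approx(expected[0, 0], rel=0.10)
        assert got[1, 1] == pytest.approx(expected[1, 1], rel=0.10)


class TestQuadrants:
    def test_symmetric_four_points(self):
        pairs = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], dtype=float)
        quads = quadrant_proportions(pairs)
        assert quads == {"NE": 0.25, "SE": 0.25, "SW": 0.25, "NW": 0.25}

    def test_all_north_east(self):
        pairs = np.ones((10, 2))
        assert quadrant_proportions(pairs)["NE"] == 1.0

    def test_origin_centred_normal_splits_evenly(self):
        rng = np.random.default_rng(9)
        quads = quadrant_proportions(rng.standard_normal((5000, 2)))
        for q in quads.values():
            assert q == pytest.approx(0.25, abs=0.02)

    def test_boundary_ties_are_deterministic(self):
        pairs = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        quads = quadrant_proportions(pairs)
        # dC=0 counts as "not more costly"; dE=0 as "not more effective"
        assert quads["NE"] == 0.0
        for q in ("SE", "SW", "NW"):
            assert quads[q] == pytest.approx(1 / 3)

    def test_empty_input_rejected(self):
        with pytest.raises(t.ValidationError):
            quadrant_proportions(np.empty((0, 2)))


class TestCEAC:
    def test_dominant_intervention(self):
        pairs = np.tile([-10.0, 0.1], (20, 1))
        curve = ceac(pairs, [0, 1000, 50000])
        assert all(v == 1.0 for v in curve.values())

    def test_step_at_icer(self):
        pairs = np.tile([10.0, 0.001], (20, 1))
        curve = ceac(pairs, [0, 5000, 9999, 10001, 20000])
        assert curve[0.0] == 0.0
        assert curve[9999.0] == 0.0
        assert curve[10001.0] == 1.0

    def test_endpoint_identities(self):
        rng = np.random.default_rng(10)
        pairs = rng.standard_normal((1000, 2))
        curve = ceac(pairs, [0.0, 1e12])
        assert curve[0.0] == np.mean(pairs[:, 0] < 0)
        assert curve[1e12] == np.mean(pairs[:, 1] > 0)

    def test_negative_wtp_rejected(self):
        with pytest.raises(t.ValidationError):
            ceac(np.ones((5, 2)), [-1.0])


class TestIncrementalCostEffectiveness:
    def test_fit_pools_and_matches_bootstrap_means(self):
        frames = [_random_frame(s, n=200) for s in (20, 21)]
        est = t.IncrementalCostEffectiveness(
            cost_col="total_cost",
            effect_col="effect_outcome",
            covariates=("age", "baseline"),
            B=2000,
            random_state=0,
        ).fit(frames)
        assert est.quadrants_["NE"] + est.quadrants_["SE"] + est.quadrants_["SW"] + est.quadrants_["NW"] == 1.0
        assert 0.0 <= est.prob_cost_effective_ <= 1.0
        # Rubin point estimates agree with the bootstrap pair means (MC error)
        boot_dc = est.bootstrap_.pairs[:, 0].mean()
        boot_de = est.bootstrap_.pairs[:, 1].mean()
        assert boot_dc == pytest.approx(est.delta_cost_, abs=3 * est.pooled_cost_.se / np.sqrt(10))
        assert boot_de == pytest.approx(est.delta_effect_, abs=3 * est.pooled_effect_.se / np.sqrt(10))
        assert est.icer_ == pytest.approx(est.delta_cost_ / est.delta_effect_)
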