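"""Item-level fills, home-care modal completion, MICE-PMM and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest

import trialcea as t
from trialcea.costing import RESOURCE_MONTHS


def _panel(rows):
    return pd.DataFrame(rows, columns=["participant_id", "month", "category", "volume", "item_missing"])


def _participants(ids_arms):
    return pd.DataFrame(
        {"participant_id": [i for i, _ in ids_arms], "arm": [a for _, a in ids_arms]}
    )


class TestItemLevelFill:
    def test_arm_timepoint_mean_donor(self):
        parts = _participants([(1, "intervention"), (2, "intervention"), (3, "intervention")])
        panel = _panel(
            [
                (1, 3, "paramedical", np.nan, 1),
                (2, 3, "paramedical", 2.0, 0),
                (3, 3, "paramedical", 3.0, 0),
            ]
        )
        filled, prov = t.item_level_fill(panel, parts)
        assert filled["volume"].iloc[0] == pytest.approx(2.5)
        assert filled["item_missing"].iloc[0] == 0
        assert prov[0]["tier"] == "arm_timepoint_mean"

    def test_no_flags_is_identity(self):
        parts = _participants([(1, "control")])
        panel = _panel([(1, 3, "paramedical", 2.0, 0), (1, 6, "paramedical", np.nan, 0)])
        filled, prov = t.item_level_fill(panel, parts)
        pd.testing.assert_frame_equal(filled, panel)
        assert prov == []

    def test_falls_back_to_participants_own_mean(self):
        parts = _participants([(1, "control")])
        panel = _panel(
            [
                (1, 3, "paramedical", np.nan, 1),
                (1, 6, "paramedical", 1.0, 0),
                (1, 9, "paramedical", 1.0, 0),
            ]
        )
        filled, prov = t.item_level_fill(panel, parts)
        assert filled["volume"].iloc[0] == pytest.approx(1.0)
        assert prov[0]["tier"] == "participant_mean"

    def test_escalates_when_no_donor_anywhere(self):
        parts = _participants([(1, "control")])
        panel = _panel([(1, 3, "paramedical", np.nan, 1)])
        filled, prov = t.item_level_fill(panel, parts)
        assert np.isnan(filled["volume"].iloc[0])
        assert filled["item_missing"].iloc[0] == 0  # now questionnaire-level
        assert prov[0]["tier"] == "escalated_to_questionnaire"


class TestHomeCareImpute:
    def _series(self, values, pid=1, cat="home_nursing"):
        return _panel(
            [(pid, m, cat, v, 0) for m, v in zip(RESOURCE_MONTHS, values)]
        )

    def test_mode_of_observed_values(self):
        parts = _participants([(1, "intervention")])
        panel = self._series([0, 0, 0, 50, np.nan, 0, 0])
        filled, _ = t.home_care_impute(panel, parts)
        assert filled.loc[filled["month"] == 12, "volume"].iloc[0] == 0.0

    def test_constant_series(self):
        parts = _participants([(1, "control")])
        panel = self._series([0, 0, np.nan, 0, 0, np.nan, 0])
        filled, _ = t.home_care_impute(panel, parts)
        assert (filled["volume"] == 0).all()

    def test_bimodal_tie_breaks_to_smallest(self):
        parts = _participants([(1, "intervention")])
        panel = self._series([50, 50, 95, 95, np.nan, np.nan, np.nan])
        filled, _ = t.home_care_impute(panel, parts)
        assert (filled.loc[filled["volume"].index[4:], "volume"] == 50).all()

    def test_fully_missing_series_uses_arm_mode(self):
        parts = _participants([(1, "intervention"), (2, "intervention")])
        panel = pd.concat(
            [
                self._series([np.nan] * 7, pid=1),
                self._series([7, 7, 7, 7, 7, 7, 7], pid=2),
            ],
            ignore_index=True,
        )
        filled, prov = t.home_care_impute(panel, parts)
        assert (filled.loc[filled["participant_id"] == 1, "volume"] == 7).all()
        assert prov[0]["tier"] == "arm_mode"


def _mcar_frame(seed, n=60, missing=0.2):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "arm": np.repeat(["control", "intervention"], n // 2),
            "age": rng.normal(60, 8, n).round(1),
            "y_m0": rng.normal(10, 2, n),
            "y_m6": rng.normal(11, 2, n),
        }
    )
    frame["y_m6"] += 0.8 * (frame["y_m0"] - 10)
    mask = rng.random(n) < missing
    frame.loc[mask, "y_m6"] = np.nan
    return frame


class TestMicePMM:
    def test_complete_data_yields_identical_copies(self):
        frame = _mcar_frame(0, missing=0.0)
        out = t.mice_pmm(frame, t.ImputationConfig(m=3, seed=1), columns=["y_m0", "y_m6"], predictors=["age"])
        assert len(out) == 3
        for c in out:
            pd.testing.assert_frame_equal(c, frame)

    def test_single_donor_takes_nearest_predicted_neighbour(self):
        # y is a noise-free increasing function of x, so for any positive
        # slope draw the nearest-prediction donor of the largest-x missing row
        # is the largest observed x; enumeration is the oracle.
        frame = pd.DataFrame(
            {
                "arm": ["a"] * 10,
                "x": np.arange(10.0),
                "y": 10.0 * np.arange(10.0),
            }
        )
        frame.loc[9, "y"] = np.nan
        cfg = t.ImputationConfig(m=2, pmm_donors=1, seed=3)
        out = t.mice_pmm(frame, cfg, columns=["y"], predictors=["x"])
        for c in out:
            assert c.loc[9, "y"] == 80.0

    def test_imputed_values_lie_in_observed_support(self):
        frame = _mcar_frame(4)
        observed = set(frame["y_m6"].dropna())
        out = t.mice_pmm(frame, t.ImputationConfig(m=4, seed=5), columns=["y_m0", "y_m6"], predictors=["age"])
        for c in out:
            assert set(c["y_m6"]) <= observed | set(frame["y_m6"].dropna())
            assert not c["y_m6"].isna().any()

    def test_seeded_determinism(self):
        frame = _mcar_frame(6)
        a = t.mice_pmm(frame, t.ImputationConfig(m=3, seed=9), columns=["y_m6"], predictors=["age", "y_m0"])
        b = t.mice_pmm(frame, t.ImputationConfig(m=3, seed=9), columns=["y_m6"], predictors=["age", "y_m0"])
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_control_permutation_never_touches_intervention(self):
        frame = _mcar_frame(7)
        out1 = t.mice_pmm(frame, t.ImputationConfig(m=2, seed=11), columns=["y_m6"], predictors=["age", "y_m0"])
        ctrl = frame[frame["arm"] == "control"].sample(frac=1.0, random_state=1)
        permuted = pd.concat([ctrl, frame[frame["arm"] == "intervention"]])
        out2 = t.mice_pmm(permuted, t.ImputationConfig(m=2, seed=11), columns=["y_m6"], predictors=["age", "y_m0"])
        for a, b in zip(out1, out2):
            ia = a[a["arm"] == "intervention"]["y_m6"]
            ib = b[b["arm"] == "intervention"]["y_m6"].reindex(ia.index)
            pd.testing.assert_series_equal(ia, ib)

    def test_variable_with_no_observed_values_is_an_error(self):
        frame = _mcar_frame(8)
        frame["y_m6"] = np.nan
        with pytest.raises(t.ImputationError, match="y_m6"):
            t.mice_pmm(frame, t.ImputationConfig(m=2, seed=1), columns=["y_m6"], predictors=["age"])

    def test_mcar_pooled_estimate_tracks_complete_data(self):
        # pooled mean of the imputed variable should track the complete-data
        # mean well within sampling noise
        gaps = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            frame = _mcar_frame(200 + seed, n=120, missing=0.25)
            complete_mean = np.nan
            truth = _mcar_frame(200 + seed, n=120, missing=0.0)["y_m6"].mean()
            out = t.mice_pmm(
                frame, t.ImputationConfig(m=5, seed=seed), columns=["y_m6"], predictors=["age", "y_m0"]
            )
            pooled = np.mean([c["y_m6"].mean() for c in out])
            gaps.append(pooled - truth)
        assert abs(np.mean(gaps)) < 0.35  # ~3 SEs of the Monte-Carlo mean gap


class TestRubinPool:
    def test_hand_computed_pooling(self):
        pooled = t.rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert pooled.estimate == pytest.approx(2.0)
        assert pooled.within_variance == pytest.approx(1.0)
        assert pooled.between_variance == pytest.approx(1.0)
        assert pooled.total_variance == pytest.approx(1.0 + (4.0 / 3.0))

    def test_identical_imputations_have_no_between_variance(self):
        pooled = t.rubin_pool([5.0] * 15, [1.0] * 15)
        assert pooled.estimate == 5.0
        assert pooled.between_variance == 0.0
        assert pooled.total_variance == 1.0
        assert pooled.ci_low == pytest.approx(5.0 - 1.959964, abs=1e-4)

    def test_single_imputation_rejected(self):
        with pytest.raises(t.ValidationError):
            t.rubin_pool([1.0], [1.0])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(t.ValidationError):
            t.rubin_pool([1.0, 2.0], [1.0])

    def test_order_invariance(self):
        a = t.rubin_pool([1.0, 5.0, 2.0], [0.5, 0.2, 0.9])
        b = t.rubin_pool([5.0, 2.0, 1.0], [0.2, 0.9, 0.5])
        assert a.estimate == pytest.approx(b.estimate)
        assert a.total_variance == pytest.approx(b.total_variance)
        assert a.ci_low == pytest.approx(b.ci_low)

    def test_variance_identity_on_random_inputs(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            m = int(rng.integers(2, 20))
            est = rng.normal(size=m)
            var = rng.uniform(0.1, 2.0, size=m)
            pooled = t.rubin_pool(est, var)
            B = est.var(ddof=1)
            assert pooled.total_variance == pytest.approx(
                pooled.within_variance + (1 + 1 / m) * B
            )

    def test_barnard_rubin_df_smaller_than_classic(self):
        classic = t.rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        small = t.rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0], df_complete=20)
        assert small.df < classic.df
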