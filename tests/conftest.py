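import numpy as np
import pandas as pd
import pytest

import trialcea as t


@pytest.fixture(scope="session")
def study_trial():
    """One default-calibration synthetic trial, shared across tests."""
    return t.generate_trial(t.default_study_config(seed=7))


@pytest.fixture(scope="session")
def complete_trial():
    """A small trial with no missingness and no deaths (rectangular panel)."""
    cfg = t.GeneratorConfig(
        n_intervention=120,
        n_control=60,
        missing_prob_questionnaire=0.0,
        missing_prob_item=0.0,
        death_prob=0.0,
        seed=11,
    )
    return t.generate_trial(cfg)


def balanced_recovery_config(seed, n=400, delta_effect=0.02, delta_cost=1200.0):
    """Arm-exchangeable baseline distributions so the adjusted estimand equals
    the configured truth exactly (see the generator's calibration notes)."""
    return t.GeneratorConfig(
        n_intervention=n,
        n_control=n,
        true_delta_effect=delta_effect,
        true_delta_cost=delta_cost,
        missing_prob_questionnaire=0.0,
        missing_prob_item=0.0,
        death_prob=0.0,
        baseline_utility_mean_by_arm={"EQ5D5L": (0.86, 0.86), "ICECAPA": (0.87, 0.87)},
        baseline_utility_sd_by_arm={"EQ5D5L": (0.15, 0.15), "ICECAPA": (0.1, 0.1)},
        seed=seed,
    )


def adjusted_contrasts(trial, scenario=None):
    """Adjusted (dE, se_E, dC, se_C) for one trial under one scenario."""
    from trialcea.cea import AdjustmentSpec, adjusted_difference
    from trialcea.pipeline import (
        _ADJUST_COVARIATES,
        ScenarioConfig,
        apply_population_filter,
        build_analysis_frame,
        outcome_frame,
    )

    scenario = scenario or ScenarioConfig()
    parts = apply_population_filter(trial.participants, scenario)
    frame, _, _, _ = build_analysis_frame(parts, trial.utilities, trial.resources)
    of = outcome_frame(frame, scenario)
    de, ve = adjusted_difference(of, AdjustmentSpec("effect", _ADJUST_COVARIATES))
    dc, vc = adjusted_difference(of, AdjustmentSpec("total_cost", _ADJUST_COVARIATES))
    return de, ve**0.5, dc, vc**0.5
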