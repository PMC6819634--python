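"""Multinomial regression: closed-form oracles, coverage, invariants."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ipvconsist.regression import (
    Covariate,
    ModelSpec,
    OUTCOME_ORDER,
    draw_outcomes,
    fit_multinomial,
    sensitivity_complete_responders,
)
from ipvconsist.recovery import recovery_experiment, true_beta

BIN_SPEC = ModelSpec(covariates=(Covariate("exposed", (False, True), False),))


def _profiles_from_counts(a, b, c, d):
    """2x2 layout: rows exposed/unexposed, cols reference/other class."""
    rows = (
        [{"consistency_class": "consistent_ipv", "exposed": True}] * a
        + [{"consistency_class": "consistent_never_ipv", "exposed": True}] * b
        + [{"consistency_class": "consistent_ipv", "exposed": False}] * c
        + [{"consistency_class": "consistent_never_ipv", "exposed": False}] * d
    )
    df = pd.DataFrame(rows)
    df["complete"] = True
    return df


def test_saturated_two_class_fit_equals_cross_product_ratio():
    a, b, c, d = 200, 310, 150, 340
    fit = fit_multinomial(_profiles_from_counts(a, b, c, d), BIN_SPEC)
    expected = (b * c) / (a * d)  # odds of never-class for exposed vs unexposed
    got = fit.table.loc[fit.table["level"] == "True", "odds_ratio"].item()
    assert got == pytest.approx(expected, abs=1e-4)
    assert fit.table["ci_low"].item() <= got <= fit.table["ci_high"].item()


def test_two_class_fit_matches_binary_logit():
    """Collapsing the outcome to two classes reproduces binary logistic results."""
    df = _profiles_from_counts(180, 300, 170, 320)
    fit = fit_multinomial(df, BIN_SPEC)
    y = (df["consistency_class"] == "consistent_never_ipv").astype(float)
    X = sm.add_constant(df["exposed"].astype(float))
    ref = sm.Logit(y, X).fit(disp=False)
    np.testing.assert_allclose(
        fit.coefs["consistent_never_ipv"].to_numpy(), ref.params.to_numpy(), atol=1e-6
    )


def test_weighted_fit_at_unit_weights_matches_statsmodels():
    rng = np.random.default_rng(11)
    n = 2000
    x = (rng.random(n) < 0.3).astype(float)
    beta = true_beta()
    y = draw_outcomes(np.column_stack([np.ones(n), x]), beta, rng)
    df = pd.DataFrame(
        {
            "consistency_class": [OUTCOME_ORDER[j] for j in y],
            "income_stress_half": x.astype(bool),
            "complete": True,
        }
    )
    spec = ModelSpec(covariates=(Covariate("income_stress_half", (False, True), False),))
    unweighted = fit_multinomial(df, spec)
    weighted = fit_multinomial(df, spec, weights=np.ones(n))
    np.testing.assert_allclose(weighted.coefs.to_numpy(), unweighted.coefs.to_numpy(), atol=1e-6)
    np.testing.assert_allclose(weighted.ses.to_numpy(), unweighted.ses.to_numpy(), atol=1e-5)


def test_null_covariate_cis_mostly_cover_one():
    """Independence by construction: pooled CI coverage of OR = 1 near 95%.

    Within one dataset the five contrasts share the reference-class count,
    so their ORs move together; coverage is therefore pooled over
    replicates rather than judged on a single fit.
    """
    rng = np.random.default_rng(5)
    n = 5000
    probs = np.array([0.075, 0.032, 0.769, 0.024, 0.054, 0.047])
    covered = total = 0
    for _ in range(20):
        x = rng.random(n) < 0.4  # independent of outcome by construction
        y = rng.choice(6, size=n, p=probs / probs.sum())
        df = pd.DataFrame(
            {
                "consistency_class": [OUTCOME_ORDER[j] for j in y],
                "exposed": x,
                "complete": True,
            }
        )
        fit = fit_multinomial(df, BIN_SPEC)
        covers = (fit.table["ci_low"] <= 1.0) & (1.0 <= fit.table["ci_high"])
        covered += int(covers.sum())
        total += len(covers)
    assert covered / total >= 0.9


def test_probabilities_sum_to_one_and_likelihood_improves():
    fit = fit_multinomial(_profiles_from_counts(120, 250, 110, 260), BIN_SPEC)
    np.testing.assert_allclose(fit.fitted_probs.sum(axis=1), 1.0, atol=1e-10)
    assert fit.loglik >= fit.loglik_null - 1e-9


def test_coverage_of_injected_coefficients():
    res = recovery_experiment(n=4000, n_reps=30, seed=2)
    assert res["coverage_never_pct"] >= 90.0
    assert abs(res["mean_or_never"] - res["true_or_never"]) < 0.1


def test_incomplete_records_dropped_and_reported():
    df = _profiles_from_counts(100, 200, 100, 200)
    df.loc[df.index[:25], "complete"] = False
    fit = fit_multinomial(df, BIN_SPEC)
    assert fit.n_dropped == 25
    assert fit.n_used == len(df) - 25


def test_zero_cell_levels_reported_not_silently_dropped():
    df = _profiles_from_counts(100, 200, 100, 200)
    spec = ModelSpec(covariates=(Covariate("exposed", (False, True, "never_seen"), False),))
    fit = fit_multinomial(df, spec)
    flagged = {(z["covariate"], z["level"]) for z in fit.zero_cells}
    assert ("exposed", "never_seen") in flagged
    assert "exposed=never_seen" in fit.coefs.index


def test_sensitivity_requires_six_wave_responders():
    df = _profiles_from_counts(50, 100, 50, 100)
    df["answered_count"] = 5
    with pytest.raises(ValueError, match="six"):
        sensitivity_complete_responders(df)


def test_sensitivity_equals_full_fit_without_missingness():
    df = _profiles_from_counts(150, 260, 140, 270)
    df["answered_count"] = 6
    full = fit_multinomial(df, BIN_SPEC)
    sens = sensitivity_complete_responders(df, BIN_SPEC)
    np.testing.assert_allclose(sens.coefs.to_numpy(), full.coefs.to_numpy(), atol=1e-8)


def test_reference_outcome_must_be_present():
    df = _profiles_from_counts(0, 200, 0, 200)
    df = df[df["consistency_class"] != "consistent_ipv"]
    with pytest.raises(ValueError):
        fit_multinomial(df, BIN_SPEC)
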