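"""Generator vs enumeration oracle, null behaviour, calibration self-consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ipvconsist.calibrate import calibrate_error_rates, onset_distribution
from ipvconsist.classify import ELIGIBLE_CLASSES, ConsistencyClass, classify_cohort
from ipvconsist.cohort import filter_eligible, pattern_string
from ipvconsist.presets import available_presets, load_preset
from ipvconsist.simulate import (
    EffectParams,
    SimParams,
    cross_sectional_bias,
    exact_class_distribution,
    simulate_cohort,
)

C = ConsistencyClass
INCONSISTENT = {C.MAINLY_IPV, C.MAINLY_NO_IPV, C.MIXED_IPV}


def test_same_seed_is_bit_identical():
    p = SimParams(n=500, seed=42)
    a = simulate_cohort(p)
    b = simulate_cohort(p)
    assert a.to_frame().equals(b.to_frame())
    c = simulate_cohort(p, seed=43)
    assert not c.to_frame().equals(a.to_frame())


def test_error_free_reporting_never_inconsistent():
    p = SimParams(n=4000, fp=0.0, fn=0.0, seed=1)
    eligible, _ = filter_eligible(simulate_cohort(p))
    assert not INCONSISTENT & set(classify_cohort(eligible))


def test_no_prevalence_no_fp_gives_all_never():
    p = SimParams(n=2000, prev_ever=0.0, fp=0.0, seed=2)
    eligible, _ = filter_eligible(simulate_cohort(p))
    assert set(classify_cohort(eligible)) == {C.CONSISTENT_NEVER_IPV}


def test_exact_distribution_sums_to_one():
    dist = exact_class_distribution(SimParams())
    assert abs(sum(dist.probabilities.values()) - 1.0) < 1e-12


def test_exact_null_puts_zero_mass_on_inconsistent_classes():
    dist = exact_class_distribution(SimParams(fp=0.0, fn=0.0))
    for c in INCONSISTENT:
        assert dist.probabilities[c.value] == 0.0


def test_false_positives_alone_can_mimic_later_onset():
    p = SimParams(prev_ever=0.0, fp=0.03, fn=0.0)
    dist = exact_class_distribution(p)
    assert dist.probabilities["consistent_later_ipv"] > 0.0


def test_simulated_frequencies_match_oracle_within_3se():
    p = load_preset("paper_like", n=30000, seed=9)
    exact = exact_class_distribution(p)
    eligible, _ = filter_eligible(simulate_cohort(p))
    classes = classify_cohort(eligible)
    n = len(classes)
    for c in ELIGIBLE_CLASSES:
        emp = sum(1 for x in classes if x is c) / n
        ex = exact.probabilities[c.value]
        se = max(np.sqrt(ex * (1 - ex) / n), 1e-9)
        assert abs(emp - ex) <= 3 * se, c


@settings(max_examples=6, derandomize=True, deadline=None)
@given(
    fp=st.floats(0.0, 0.05),
    fn=st.floats(0.0, 0.4),
    prev=st.floats(0.05, 0.5),
    beta=st.floats(0.0, 1.5),
)
def test_oracle_agreement_across_random_parameters(fp, fn, prev, beta):
    p = SimParams(
        n=12000, fp=fp, fn=fn, prev_ever=prev, seed=17,
        effects=EffectParams(beta_fn=beta, beta_fp=beta / 2, beta_dropout=beta / 4),
    )
    exact = exact_class_distribution(p)
    eligible, _ = filter_eligible(simulate_cohort(p))
    classes = classify_cohort(eligible)
    n = len(classes)
    for c in ELIGIBLE_CLASSES:
        emp = sum(1 for x in classes if x is c) / n
        ex = exact.probabilities[c.value]
        se = max(np.sqrt(ex * (1 - ex) / n), 1e-9)
        assert abs(emp - ex) <= 4 * se


def test_more_false_negatives_raise_inconsistency_among_ever():
    """P(mainly-IPV or mixed) is nondecreasing in fn on a small grid."""
    base = SimParams(prev_ever=0.3, fp=0.005)
    last = -1.0
    for fn in (0.0, 0.05, 0.1, 0.2, 0.3):
        dist = exact_class_distribution(base.replace(fn=fn))
        mass = dist.probabilities["mainly_ipv"] + dist.probabilities["mixed_ipv"]
        assert mass >= last - 1e-12
        last = mass


def test_cross_sectional_bias_signs():
    p = SimParams()
    assert all(cross_sectional_bias(p.replace(fp=0.0, fn=0.0), w) == 0.0 for w in range(1, 7))
    for w in range(1, 7):
        assert cross_sectional_bias(p.replace(fp=0.0, fn=0.15), w) < 0.0
        assert cross_sectional_bias(p.replace(fp=0.05, fn=0.0), w) > 0.0


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        SimParams(fp=1.2).validate()
    with pytest.raises(ValueError):
        SimParams(onset_probs=(1.0,) * 7).validate()
    with pytest.raises(ValueError):
        simulate_cohort(SimParams(n=0))


def test_calibration_recovers_known_parameters():
    truth = SimParams(fp=0.01, fn=0.15, prev_ever=0.25,
                      onset_probs=onset_distribution(0.6))
    target = {k: 100 * v for k, v in exact_class_distribution(truth).probabilities.items()}
    res = calibrate_error_rates(
        target,
        fixed=truth,
        fp_grid=np.array([0.0, 0.01, 0.02]),
        fn_grid=np.array([0.05, 0.15, 0.25]),
        prev_grid=np.array([0.15, 0.25, 0.35]),
        pi0_grid=np.array([0.4, 0.6, 0.8]),
        refine=False,
    )
    assert res.distance < 1e-10
    assert res.params.fn == pytest.approx(0.15)
    assert res.params.prev_ever == pytest.approx(0.25)


def test_infeasible_target_reports_large_distance_without_error():
    target = {"consistent_ipv": 10.0, "consistent_later_ipv": 10.0,
              "consistent_never_ipv": 20.0, "mainly_ipv": 5.0,
              "mainly_no_ipv": 5.0, "mixed_ipv": 50.0}
    res = calibrate_error_rates(
        target, fixed=SimParams(fp=0.0, fn=0.0),
        fp_grid=np.array([0.0]), fn_grid=np.array([0.0]),
        prev_grid=np.array([0.2]), pi0_grid=np.array([0.6]), refine=False,
    )
    assert res.distance > 1000.0


def test_empty_grid_rejected():
    with pytest.raises(ValueError, match="grid"):
        calibrate_error_rates(
            {c.value: 10.0 for c in ELIGIBLE_CLASSES},
            fp_grid=np.array([]), refine=False,
        )


def test_presets_ship_and_load():
    names = available_presets()
    assert {"paper_like", "null_model"} <= set(names)
    p = load_preset("paper_like", n=100, seed=3)
    assert p.n == 100 and p.seed == 3
    p.validate()
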