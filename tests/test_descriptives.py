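"""Descriptive tables: class summary arithmetic and column percentages."""

import numpy as np
import pytest

from conftest import CLASS_PATTERNS, cohort_from_patterns

from ipvconsist._util import round_half_up
from ipvconsist.classify import ConsistencyClass, classify_cohort
from ipvconsist.covariates import build_profiles
from ipvconsist.descriptives import (
    characteristics_table,
    summarize_classes,
    tabulate_by_nsurveys,
)

C = ConsistencyClass


def test_round_half_up_matches_table_convention():
    assert round_half_up(100 * 587 / 10966, 1) == 5.4
    assert round_half_up(0.05, 1) == 0.1
    assert round_half_up(2.25, 1) == 2.3


def test_summary_reproduces_printed_percentages(paper_counts_classes):
    s = summarize_classes(paper_counts_classes)
    assert s.total == 10966
    assert s.percents == {
        "consistent_ipv": 7.5,
        "consistent_later_ipv": 3.2,
        "consistent_never_ipv": 76.9,
        "mainly_ipv": 2.4,
        "mainly_no_ipv": 5.4,
        "mixed_ipv": 4.7,
    }
    assert s.pct_consistent == 87.6
    assert s.pct_inconsistent == 12.4
    assert s.pct_ever_reported == 23.1
    assert s.pct_consistent_ever_ipv == 10.7
    assert s.within_inconsistent_pct == {
        "mainly_ipv": 19,
        "mainly_no_ipv": 43,
        "mixed_ipv": 38,
    }


def test_summary_percents_sum_to_100(paper_counts_classes):
    s = summarize_classes(paper_counts_classes)
    # the printed six-class row itself sums to 100.1; boundary inclusive
    assert abs(sum(s.percents.values()) - 100.0) <= 0.1 + 1e-9


def test_single_class_cohort():
    s = summarize_classes([C.CONSISTENT_NEVER_IPV] * 10)
    assert s.percents["consistent_never_ipv"] == 100.0
    assert sum(v for k, v in s.percents.items() if k != "consistent_never_ipv") == 0.0


def test_summary_rejects_empty_and_ineligible():
    with pytest.raises(ValueError):
        summarize_classes([])
    with pytest.raises(ValueError):
        summarize_classes([C.INELIGIBLE])


def test_nsurveys_margins_match_printed_row(paper_margins_cohort):
    profiles = build_profiles(paper_margins_cohort)
    tab = tabulate_by_nsurveys(profiles)
    assert tab.loc[6, "all_women"] == 65.1
    assert tab.loc[3, "all_women"] == 8.5
    assert tab.loc[4, "all_women"] == 10.7
    assert tab.loc[5, "all_women"] == 15.7


def test_mixed_cell_zero_for_three_answers():
    # 3-answer records of every achievable class plus longer mixed records
    cohort = cohort_from_patterns(
        [("YYY...", 5), ("YNN...", 5), ("NNN...", 5), ("YNYN..", 5), ("YYNNYY", 5)]
    )
    tab = tabulate_by_nsurveys(build_profiles(cohort))
    assert tab.loc[3, "mixed_ipv"] == 0.0
    col_sums = tab.dropna(axis=1, how="all").sum(axis=0)
    assert np.allclose(col_sums, 100.0, atol=0.2)


def _two_record_profiles():
    from ipvconsist.cohort import Cohort, WomanRecord, parse_pattern

    a = WomanRecord(id="a", ipv=parse_pattern("YYY..."), area="major_city")
    b = WomanRecord(id="b", ipv=parse_pattern("YYY..."), area="remote_very_remote")
    return build_profiles(Cohort([a, b]))


def test_weighted_area_percentages_two_record_toy():
    ch = characteristics_table(_two_record_profiles(), weighted=True)
    area = ch[(ch.variable == "area") & (ch.consistency_class == "consistent_ipv")]
    vals = dict(zip(area.level, area.percent))
    assert vals["major_city"] == 66.7  # weight 1 of total 1.5
    assert vals["remote_very_remote"] == 33.3


def test_weighting_invariant_to_global_rescale():
    profiles = _two_record_profiles()
    scaled = profiles.assign(weight=profiles["weight"] * 7.3)
    a = characteristics_table(profiles, weighted=True)
    b = characteristics_table(scaled, weighted=True)
    assert a.equals(b)


def test_equal_weights_match_unweighted():
    profiles = _two_record_profiles().assign(weight=1.0)
    a = characteristics_table(profiles, weighted=True)
    b = characteristics_table(profiles, weighted=False)
    assert a.equals(b)
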