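from pathlib import Path

import pytest

from ipvconsist.classify import ConsistencyClass
from ipvconsist.cohort import Cohort, WomanRecord, parse_pattern

FIXTURES = Path(__file__).parent / "fixtures"

#: one six-wave pattern per class (pattern, class) used to rebuild cohorts
#: with prescribed class counts
CLASS_PATTERNS = {
    ConsistencyClass.CONSISTENT_IPV: "YYYYYY",
    ConsistencyClass.CONSISTENT_LATER_IPV: "NNNYYY",
    ConsistencyClass.CONSISTENT_NEVER_IPV: "NNNNNN",
    ConsistencyClass.MAINLY_IPV: "YYYNYY",
    ConsistencyClass.MAINLY_NO_IPV: "YNNNNN",
    ConsistencyClass.MIXED_IPV: "YYNNYY",
}

#: published class counts (total 10,966)
PAPER_COUNTS = {
    ConsistencyClass.CONSISTENT_IPV: 827,
    ConsistencyClass.CONSISTENT_LATER_IPV: 347,
    ConsistencyClass.CONSISTENT_NEVER_IPV: 8436,
    ConsistencyClass.MAINLY_IPV: 258,
    ConsistencyClass.MAINLY_NO_IPV: 587,
    ConsistencyClass.MIXED_IPV: 511,
}

#: published answered-count margins: 936/1173/1722/7135 women answered 3/4/5/6
PAPER_MARGINS = {3: 936, 4: 1173, 5: 1722, 6: 7135}


def cohort_from_patterns(pattern_counts, prefix="r") -> Cohort:
    """Cohort with the given multiset of IPV patterns (covariates empty)."""
    records = []
    i = 0
    for pattern, count in pattern_counts:
        for _ in range(count):
            i += 1
            records.append(WomanRecord(id=f"{prefix}{i:06d}", ipv=parse_pattern(pattern)))
    return Cohort(records, provenance="constructed")


@pytest.fixture(scope="session")
def toy_patterns_path() -> Path:
    return FIXTURES / "toy_patterns.csv"


@pytest.fixture(scope="session")
def paper_counts_classes() -> list:
    out = []
    for cls, count in PAPER_COUNTS.items():
        out.extend([cls] * count)
    return out


@pytest.fixture(scope="session")
def paper_counts_cohort() -> Cohort:
    return cohort_from_patterns([(CLASS_PATTERNS[c], n) for c, n in PAPER_COUNTS.items()])


@pytest.fixture(scope="session")
def paper_margins_cohort() -> Cohort:
    """Cohort whose answered-count margins equal the published row totals."""
    return cohort_from_patterns(
        [("YYY...", 936), ("YYYY..", 1173), ("YYYYY.", 1722), ("YYYYYY", 7135)]
    )
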