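"""Consistency classification of six-wave yes/no response sequences.

A woman's answered responses (in wave order, skipping missing waves) are
classified into six consistency classes.  Writing ``r`` for the answered
subsequence, ``n = |r|`` and ``y`` for its number of YES answers, and
calling a YES that is followed by a later NO a *drop*:

* no drop, ``y == n``  -> CONSISTENT_IPV (always reported IPV)
* no drop, ``y == 0``  -> CONSISTENT_NEVER_IPV
* no drop, otherwise   -> CONSISTENT_LATER_IPV (a block of NOs then YESes)
* drop, ``y == n - 1`` -> MAINLY_IPV (a single NO among YESes)
* drop, ``y == 1``     -> MAINLY_NO_IPV (a single YES, later contradicted)
* drop, otherwise      -> MIXED_IPV

Because the item asks about *lifetime* experience, any drop contradicts an
earlier answer; the three drop classes are the "inconsistent" ones.
Sequences with a missing wave-1 answer or fewer than three answers overall
are INELIGIBLE.

Monotone sequences are always consistent: NYY is CONSISTENT_LATER_IPV even
though it has exactly one NO, and a sequence such as YYNN, with two YESes
and two NOs all in one direction, still falls to MIXED_IPV because the
named single-discrepancy classes require exactly one minority answer.
"""

from __future__ import annotations

from enum import Enum
from typing import Mapping, Sequence

from .cohort import Cohort, Response, parse_pattern

__all__ = [
    "ConsistencyClass",
    "ELIGIBLE_CLASSES",
    "CONSISTENT_CLASSES",
    "INCONSISTENT_CLASSES",
    "classify",
    "classify_pattern",
    "classify_cohort",
    "enumerate_class_counts",
]


class ConsistencyClass(Enum):
    CONSISTENT_IPV = "consistent_ipv"
    CONSISTENT_LATER_IPV = "consistent_later_ipv"
    CONSISTENT_NEVER_IPV = "consistent_never_ipv"
    MAINLY_IPV = "mainly_ipv"
    MAINLY_NO_IPV = "mainly_no_ipv"
    MIXED_IPV = "mixed_ipv"
    INELIGIBLE = "ineligible"


#: the six analysis classes, in the source tables' column order
ELIGIBLE_CLASSES = (
    ConsistencyClass.CONSISTENT_IPV,
    ConsistencyClass.CONSISTENT_LATER_IPV,
    ConsistencyClass.CONSISTENT_NEVER_IPV,
    ConsistencyClass.MAINLY_IPV,
    ConsistencyClass.MAINLY_NO_IPV,
    ConsistencyClass.MIXED_IPV,
)
CONSISTENT_CLASSES = ELIGIBLE_CLASSES[:3]
INCONSISTENT_CLASSES = ELIGIBLE_CLASSES[3:]


def classify(seq: Sequence[Response]) -> ConsistencyClass:
    """Classify one six-wave response sequence (total function, never raises)."""
    if seq[0] is Response.MISSING:
        return ConsistencyClass.INELIGIBLE
    answered = [r for r in seq if r is not Response.MISSING]
    n = len(answered)
    if n < 3:
        return ConsistencyClass.INELIGIBLE
    y = sum(1 for r in answered if r is Response.YES)
    # a drop = some YES occurring before a later NO
    seen_yes = False
    drop = False
    for r in answered:
        if r is Response.YES:
            seen_yes = True
        elif seen_yes:  # NO after a YES
            drop = True
            break
    if not drop:
        if y == n:
            return ConsistencyClass.CONSISTENT_IPV
        if y == 0:
            return ConsistencyClass.CONSISTENT_NEVER_IPV
        return ConsistencyClass.CONSISTENT_LATER_IPV
    if y == n - 1:
        return ConsistencyClass.MAINLY_IPV
    if y == 1:
        return ConsistencyClass.MAINLY_NO_IPV
    return ConsistencyClass.MIXED_IPV


def classify_pattern(pattern: str) -> ConsistencyClass:
    """Classify a compact pattern string such as ``'YNY'`` or ``'Y.N..Y'``."""
    return classify(parse_pattern(pattern))


def classify_cohort(cohort: Cohort) -> list[ConsistencyClass]:
    """Classes for every record, in cohort order."""
    return [classify(r.ipv) for r in cohort]


def enumerate_class_counts(n_answered: int) -> Mapping[ConsistencyClass, int]:
    """Brute-force classification of all ``2**n`` fully-answered YES/NO strings.

    Serves as an exhaustiveness oracle: the six classes partition the strings,
    so the counts always sum to ``2**n_answered``.
    """
    if not 3 <= n_answered <= 6:
        raise ValueError(f"n_answered must be in 3..6, got {n_answered}")
    counts = {c: 0 for c in ELIGIBLE_CLASSES}
    for bits in range(2 ** n_answered):
        seq = tuple(
            Response.YES if (bits >> i) & 1 else Response.NO for i in range(n_answered)
        ) + (Response.MISSING,) * (6 - n_answered)
        counts[classify(seq)] += 1
    return counts
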