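#!/usr/bin/env python
"""Classify the eligible cohort into the six consistency classes.

Annotates the eligible cohort CSV with a consistency_class column and
writes the class summary (counts, percentages, consistent/inconsistent
aggregates, within-inconsistent shares).
"""

from pathlib import Path

from ipvconsist.classify import classify_cohort
from ipvconsist.cohort import read_cohort
from ipvconsist.descriptives import summarize_classes

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(OUT / "cohort_eligible.csv")
    classes = classify_cohort(cohort)
    frame = cohort.to_frame()
    frame["consistency_class"] = [c.value for c in classes]
    frame.to_csv(OUT / "classified.csv", index=False)
    summary = summarize_classes(classes)
    summary.to_json(OUT / "class_summary.json")
    print(f"classified {summary.total} eligible women")
    for name, pct in summary.percents.items():
        print(f"  {name:22s} {summary.counts[name]:6d}  {pct:5.1f}%")
    print(f"consistent overall: {summary.pct_consistent}%  "
          f"inconsistent: {summary.pct_inconsistent}%  "
          f"ever reported IPV: {summary.pct_ever_reported}%")
    print(f"within the inconsistent: {summary.within_inconsistent_pct}")


if __name__ == "__main__":
    main()
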