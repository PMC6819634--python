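#!/usr/bin/env python
"""Simulate the paper-like six-wave cohort and apply the eligibility filter.

Writes the raw cohort, the eligible subset, and the exclusion summary
(including the wave-1 IPV prevalence contrast between excluded and
included women) under results/.
"""

from pathlib import Path

from ipvconsist.cohort import filter_eligible, write_cohort
from ipvconsist.presets import load_preset
from ipvconsist.simulate import simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
N = 20_000
SEED = 20191029


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = load_preset("paper_like", n=N, seed=SEED)
    cohort = simulate_cohort(params)
    eligible, exclusions = filter_eligible(cohort)
    write_cohort(cohort, OUT / "cohort.csv")
    write_cohort(eligible, OUT / "cohort_eligible.csv")
    exclusions.to_json(OUT / "exclusions.json")
    print(f"simulated {len(cohort)} women (paper_like preset, seed {SEED})")
    print(f"eligible: {exclusions.n_eligible}  excluded: {exclusions.n_excluded} "
          f"({100 * exclusions.n_excluded / exclusions.n_input:.1f}%)")
    print("wave-1 IPV prevalence  included: "
          f"{exclusions.wave1_prevalence_included:.1f}%  "
          f"excluded: {exclusions.wave1_prevalence_excluded:.1f}%")
    print("(excluded women report more IPV at wave 1, as in the real cohort)")


if __name__ == "__main__":
    main()
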