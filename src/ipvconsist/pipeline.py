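"""End-to-end orchestration: simulate/read -> filter -> classify -> tables -> fit.

Every stage writes plain CSV/JSON so each step is independently checkable;
a run manifest (config, seed, package versions) suffices to reproduce any
output exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .classify import classify_cohort
from .cohort import Cohort, filter_eligible, read_cohort, write_cohort
from .covariates import build_profiles
from .descriptives import characteristics_table, summarize_classes, tabulate_by_nsurveys
from .presets import load_preset
from .regression import fit_multinomial, sensitivity_complete_responders
from .simulate import simulate_cohort

__all__ = ["RunConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("ipvconsist")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    input_path: Optional[str] = None
    preset: Optional[str] = None
    n: Optional[int] = None
    seed: Optional[int] = None
    weighting: bool = True
    model: str = "both"  # full | sensitivity | both | none
    out_dir: str = "results/run"

    def validate(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("exactly one of input_path or preset must be given")
        if self.model not in ("full", "sensitivity", "both", "none"):
            raise ValueError(f"unknown model variant {self.model!r}")


@dataclass
class ReportBundle:
    """Paths of everything a run wrote."""

    out_dir: Path
    files: dict[str, Path]
    summary: dict


def _stage(name: str, n_in: int, n_out: int) -> None:
    log.info("%s: %d records in, %d out", name, n_in, n_out)


def run_pipeline(config: RunConfig) -> ReportBundle:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    # --- acquire cohort
    if config.input_path is not None:
        cohort = read_cohort(config.input_path)
        params_note = {"input": str(config.input_path)}
    else:
        overrides = {}
        if config.n is not None:
            overrides["n"] = config.n
        if config.seed is not None:
            overrides["seed"] = config.seed
        params = load_preset(config.preset, **overrides)
        cohort = simulate_cohort(params)
        files["cohort"] = out / "cohort.csv"
        write_cohort(cohort, files["cohort"])
        params_note = {"preset": config.preset, "params": dataclasses.asdict(params)}
    _stage("input", len(cohort), len(cohort))

    # --- eligibility
    eligible, exclusions = filter_eligible(cohort)
    _stage("filter_eligible", len(cohort), len(eligible))
    assert len(eligible) + exclusions.n_excluded == len(cohort)
    files["exclusions"] = out / "exclusions.json"
    exclusions.to_json(files["exclusions"])

    # --- classify + profiles
    classes = classify_cohort(eligible)
    profiles = build_profiles(eligible)
    classified = eligible.to_frame()
    classified["consistency_class"] = [c.value for c in classes]
    files["classified"] = out / "classified.csv"
    classified.to_csv(files["classified"], index=False)
    _stage("classify", len(eligible), len(profiles))

    # --- descriptives
    summary = summarize_classes(classes)
    files["class_summary"] = out / "class_summary.json"
    summary.to_json(files["class_summary"])
    nsurv = tabulate_by_nsurveys(profiles)
    files["nsurveys_table"] = out / "nsurveys_table.csv"
    nsurv.rename_axis("answered_count").to_csv(files["nsurveys_table"])
    chars = characteristics_table(profiles, weighted=config.weighting)
    files["characteristics"] = out / "characteristics.csv"
    chars.to_csv(files["characteristics"], index=False)

    # --- regression
    if config.model in ("full", "both"):
        fit = fit_multinomial(profiles)
        files["or_table_full"] = out / "or_table_full.csv"
        fit.to_csv(files["or_table_full"])
        _stage("fit_full", fit.n_used + fit.n_dropped, fit.n_used)
    if config.model in ("sensitivity", "both"):
        sens = sensitivity_complete_responders(profiles)
        files["or_table_sensitivity"] = out / "or_table_sensitivity.csv"
        sens.to_csv(files["or_table_sensitivity"])
        _stage("fit_sensitivity", len(profiles), sens.n_used)

    manifest = {
        "config": dataclasses.asdict(config),
        "source": params_note,
        "versions": _versions(),
        "n_input": len(cohort),
        "n_eligible": len(eligible),
        "n_excluded": exclusions.n_excluded,
    }
    files["manifest"] = out / "manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return ReportBundle(out_dir=out, files=files, summary=dataclasses.asdict(summary))


def _versions() -> dict[str, str]:
    import numpy, pandas, scipy, statsmodels

    return {
        "ipvconsist": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
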