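"""Descriptive summaries: class counts/percentages and column-percentage tables.

Percentages follow the printed-table convention: one decimal, rounded half
up (587/10,966 -> 5.4).  Within-inconsistent shares are printed as whole
percentages.  The characteristics table weights percentages by the design
weight correcting intentional oversampling of rural/remote strata; weighted
column percentages are invariant to a global rescaling of the weights.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._util import round_half_up
from .classify import (
    CONSISTENT_CLASSES,
    ELIGIBLE_CLASSES,
    INCONSISTENT_CLASSES,
    ConsistencyClass,
)

__all__ = ["ClassSummary", "summarize_classes", "tabulate_by_nsurveys", "characteristics_table"]


@dataclass
class ClassSummary:
    """Counts and one-decimal percentages for the six consistency classes,
    plus the derived aggregates quoted alongside them: the consistent and
    inconsistent totals, the ever-reported share (everyone but consistent
    never), the share consistently reporting IPV (consistent + consistent
    later), and integer within-inconsistent shares."""

    counts: dict[str, int]
    total: int
    percents: dict[str, float]
    n_consistent: int
    pct_consistent: float
    n_inconsistent: int
    pct_inconsistent: float
    n_ever_reported: int
    pct_ever_reported: float
    pct_consistent_ever_ipv: float
    within_inconsistent_pct: dict[str, int]

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s


def summarize_classes(classes: Sequence[ConsistencyClass]) -> ClassSummary:
    """Summarise a classified cohort (no INELIGIBLE entries allowed)."""
    if len(classes) == 0:
        raise ValueError("cannot summarise an empty cohort")
    if any(c is ConsistencyClass.INELIGIBLE for c in classes):
        raise ValueError("cohort contains ineligible records; filter first")
    total = len(classes)
    counts = {c.value: 0 for c in ELIGIBLE_CLASSES}
    for c in classes:
        counts[c.value] += 1
    percents = {k: round_half_up(100.0 * v / total, 1) for k, v in counts.items()}
    n_cons = sum(counts[c.value] for c in CONSISTENT_CLASSES)
    n_incons = sum(counts[c.value] for c in INCONSISTENT_CLASSES)
    n_ever = total - counts[ConsistencyClass.CONSISTENT_NEVER_IPV.value]
    within = {
        c.value: (
            int(round_half_up(100.0 * counts[c.value] / n_incons, 0)) if n_incons else 0
        )
        for c in INCONSISTENT_CLASSES
    }
    n_cons_ipv = (
        counts[ConsistencyClass.CONSISTENT_IPV.value]
        + counts[ConsistencyClass.CONSISTENT_LATER_IPV.value]
    )
    return ClassSummary(
        counts=counts,
        total=total,
        percents=percents,
        n_consistent=n_cons,
        pct_consistent=round_half_up(100.0 * n_cons / total, 1),
        n_inconsistent=n_incons,
        pct_inconsistent=round_half_up(100.0 * n_incons / total, 1),
        n_ever_reported=n_ever,
        pct_ever_reported=round_half_up(100.0 * n_ever / total, 1),
        pct_consistent_ever_ipv=round_half_up(100.0 * n_cons_ipv / total, 1),
        within_inconsistent_pct=within,
    )


_ALL = "all_women"


def tabulate_by_nsurveys(profiles: pd.DataFrame) -> pd.DataFrame:
    """Unweighted column percentages of answered-count (3,4,5,6) by class.

    ``profiles`` is the output of :func:`~ipvconsist.covariates.build_profiles`
    restricted to an eligible cohort.  Columns are the six classes plus an
    all-women margin; the column base sizes are stored in ``.attrs['n']``.
    """
    cols = [c.value for c in ELIGIBLE_CLASSES] + [_ALL]
    out = pd.DataFrame(index=[3, 4, 5, 6], columns=cols, dtype=float)
    bases: dict[str, int] = {}
    for col in cols:
        sub = profiles if col == _ALL else profiles[profiles["consistency_class"] == col]
        bases[col] = len(sub)
        for k in out.index:
            n_k = int((sub["answered_count"] == k).sum())
            out.loc[k, col] = round_half_up(100.0 * n_k / len(sub), 1) if len(sub) else float("nan")
    out.attrs["n"] = bases
    return out


#: variable -> ordered levels, for the characteristics table
_CHARACTERISTIC_VARS: dict[str, Optional[list]] = {
    "area": ["major_city", "inner_regional", "outer_regional", "remote_very_remote"],
    "qualification": ["lt_year12", "year12", "trade_cert_diploma", "university"],
    "baseline_rel": ["married_defacto", "divorced_separated", "widowed_single"],
    "trajectory": ["never_sep_div", "remained_sep_div", "became_partnered", "became_sep_div"],
    "partner_stress_w1": [True],
    "partner_stress_half": [True],
    "income_stress_w1": [True],
    "income_stress_half": [True],
}


def characteristics_table(profiles: pd.DataFrame, weighted: bool = True) -> pd.DataFrame:
    """Tidy weighted column-percentage table of covariates by class.

    One row per (variable, level, class); percentages are within-class,
    among records with the variable observed.  Boolean variables report the
    TRUE share only, mirroring the printed "stressed (%)" rows.  A class
    with zero total weight yields an empty column and a warning.
    """
    rows = []
    for cls in ELIGIBLE_CLASSES:
        sub = profiles[profiles["consistency_class"] == cls.value]
        w = sub["weight"] if weighted else pd.Series(1.0, index=sub.index)
        if len(sub) == 0:
            continue
        if float(w.sum()) <= 0:
            warnings.warn(f"zero total weight in class column {cls.value}; column left empty")
            continue
        for var, levels in _CHARACTERISTIC_VARS.items():
            obs = sub[var].notna()
            denom = float(w[obs].sum())
            if denom <= 0:
                continue
            for level in levels:
                num = float(w[obs & (sub[var] == level)].sum())
                rows.append(
                    {
                        "variable": var,
                        "level": str(level),
                        "consistency_class": cls.value,
                        "percent": round_half_up(100.0 * num / denom, 1),
                    }
                )
    return pd.DataFrame(rows, columns=["variable", "level", "consistency_class", "percent"])
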