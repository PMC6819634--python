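"""Calibrate misreporting parameters against a target class distribution.

Grid search plus Nelder–Mead refinement over (false-positive rate,
false-negative rate, lifetime prevalence, pre-study onset share),
minimising the squared distance between the exact enumerated class
distribution and target class percentages.  Attrition and covariate
parameters stay fixed at the supplied values.

The calibrated rates are illustrative — they make the synthetic cohort's
class table look like the published one; they are not estimates of the real
cohort's error rates, which the source data cannot identify.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import minimize

from .classify import ELIGIBLE_CLASSES
from .simulate import SimParams, exact_class_distribution

__all__ = ["CalibrationResult", "calibrate_error_rates", "onset_distribution"]


def onset_distribution(pi0: float, decay: float = 0.75) -> tuple[float, ...]:
    """Onset-wave distribution: mass ``pi0`` before wave 1, geometric decay
    (rate ``decay``) over onsets at waves 2..6, nothing at wave 1 (an onset
    at wave 1 is observationally identical to onset 0)."""
    tail = np.array([decay ** i for i in range(5)])
    tail = (1.0 - pi0) * tail / tail.sum()
    return (float(pi0), 0.0, *(float(t) for t in tail))


@dataclass
class CalibrationResult:
    params: SimParams
    distance: float  # sum of squared percentage-point errors
    target: dict[str, float]

    @property
    def achieved(self) -> dict[str, float]:
        dist = exact_class_distribution(self.params)
        return {k: 100.0 * v for k, v in dist.probabilities.items()}


def _distance(params: SimParams, target_pct: np.ndarray) -> float:
    got = exact_class_distribution(params).as_array() * 100.0
    return float(np.sum((got - target_pct) ** 2))


def calibrate_error_rates(
    target: Mapping[str, float],
    fixed: Optional[SimParams] = None,
    fp_grid: np.ndarray = np.linspace(0.0, 0.04, 5),
    fn_grid: np.ndarray = np.linspace(0.05, 0.45, 9),
    prev_grid: np.ndarray = np.linspace(0.10, 0.40, 7),
    pi0_grid: np.ndarray = np.linspace(0.3, 0.9, 5),
    refine: bool = True,
) -> CalibrationResult:
    """Find (fp, fn, prev_ever, onset spread) best matching target percentages.

    ``target`` maps the six class names to percentages.  Infeasible targets
    do not raise: the best achievable point and its (large) distance are
    returned.
    """
    base = fixed if fixed is not None else SimParams()
    target_pct = np.array([float(target[c.value]) for c in ELIGIBLE_CLASSES])
    if min(len(fp_grid), len(fn_grid), len(prev_grid), len(pi0_grid)) == 0:
        raise ValueError("empty calibration grid")

    best = None
    for fp in fp_grid:
        for fn in fn_grid:
            for prev in prev_grid:
                for pi0 in pi0_grid:
                    p = base.replace(
                        fp=float(fp), fn=float(fn), prev_ever=float(prev),
                        onset_probs=onset_distribution(pi0),
                    )
                    d = _distance(p, target_pct)
                    if best is None or d < best[0]:
                        best = (d, float(fp), float(fn), float(prev), float(pi0))
    d0, fp0, fn0, prev0, pi00 = best

    if refine:
        def _unpack(x):
            fp, fn, prev, pi0 = 1.0 / (1.0 + np.exp(-x))
            return base.replace(
                fp=float(fp), fn=float(fn), prev_ever=float(prev),
                onset_probs=onset_distribution(float(pi0)),
            )

        def objective(x):
            return _distance(_unpack(x), target_pct)

        x0 = np.array([_logit(v) for v in (fp0, fn0, prev0, pi00)])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400})
        if res.fun < d0:
            p_best = _unpack(res.x)
            return CalibrationResult(p_best, float(res.fun), dict(target))
    p_best = base.replace(
        fp=fp0, fn=fn0, prev_ever=prev0, onset_probs=onset_distribution(pi00)
    )
    return CalibrationResult(p_best, d0, dict(target))


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))
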