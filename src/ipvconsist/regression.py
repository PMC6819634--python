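"""Baseline-category multinomial logistic regression of consistency class.

The outcome is the six-level consistency class with CONSISTENT_IPV as the
reference category; covariates are the derived longitudinal variables with
the reference levels of the published model (major city, less than year 12,
never separated/divorced, not stressed, six surveys).  Results are odds
ratios with Wald 95% confidence intervals computed on the log-odds scale
(z = 1.959964).

The unweighted fit (the default, matching the published analysis) is
delegated to ``statsmodels.discrete.MNLogit``.  An optional per-record
weight vector switches to an in-package Newton–Raphson fit of the weighted
likelihood; at unit weights the two routes agree to numerical precision.

Complete-case handling: records flagged incomplete upstream are dropped and
the drop is reported, never silent.  Covariate levels with zero cells
against any outcome class are reported on the result rather than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _st

from .classify import ELIGIBLE_CLASSES, ConsistencyClass

__all__ = [
    "Z_95",
    "ModelSpec",
    "DEFAULT_SPEC",
    "SENSITIVITY_SPEC",
    "ORTable",
    "FitFailure",
    "build_design",
    "fit_multinomial",
    "sensitivity_complete_responders",
    "draw_outcomes",
]

Z_95 = 1.959964

#: outcome categories with the reference class first
OUTCOME_ORDER = [
    ConsistencyClass.CONSISTENT_IPV.value,
    ConsistencyClass.CONSISTENT_LATER_IPV.value,
    ConsistencyClass.CONSISTENT_NEVER_IPV.value,
    ConsistencyClass.MAINLY_IPV.value,
    ConsistencyClass.MAINLY_NO_IPV.value,
    ConsistencyClass.MIXED_IPV.value,
]


@dataclass(frozen=True)
class Covariate:
    name: str
    levels: tuple
    reference: object


@dataclass(frozen=True)
class ModelSpec:
    """Ordered categorical covariates with declared reference levels."""

    covariates: tuple[Covariate, ...]
    reference_outcome: str = ConsistencyClass.CONSISTENT_IPV.value

    def drop(self, name: str) -> "ModelSpec":
        return ModelSpec(
            covariates=tuple(c for c in self.covariates if c.name != name),
            reference_outcome=self.reference_outcome,
        )


DEFAULT_SPEC = ModelSpec(
    covariates=(
        Covariate("area", ("major_city", "inner_regional", "outer_regional", "remote_very_remote"), "major_city"),
        Covariate("qualification", ("lt_year12", "year12", "trade_cert_diploma", "university"), "lt_year12"),
        Covariate(
            "trajectory",
            ("never_sep_div", "remained_sep_div", "became_partnered", "became_sep_div"),
            "never_sep_div",
        ),
        Covariate("partner_stress_half", (False, True), False),
        Covariate("income_stress_half", (False, True), False),
        Covariate("n_surveys_cat", ("six", "five", "three_four"), "six"),
    )
)

#: complete-responder model: everyone answered six surveys, so the
#: survey-count covariate is removed
SENSITIVITY_SPEC = DEFAULT_SPEC.drop("n_surveys_cat")


class FitFailure(RuntimeError):
    """Raised when the maximum-likelihood fit does not converge."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None) -> None:
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class ORTable:
    """Fitted odds ratios with 95% CIs, plus the underlying coefficients.

    ``table`` has one row per (outcome class != reference, covariate level
    != reference) with columns outcome_class, covariate, level, odds_ratio,
    ci_low, ci_high, p_value and a significance marker at the 0.05 level
    (annotation only; no selection is done on it).
    """

    table: pd.DataFrame
    coefs: pd.DataFrame  # design columns x non-reference outcome classes
    ses: pd.DataFrame
    loglik: float
    loglik_null: float
    n_used: int
    n_dropped: int
    n_reference_group: int
    converged: bool
    zero_cells: list = field(default_factory=list)
    fitted_probs: Optional[np.ndarray] = None  # rows sum to 1 over outcome classes

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_design(profiles: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, list[tuple[str, object]]]:
    """Dummy-coded design matrix with intercept; returns (X, column meta).

    Column meta pairs each non-intercept column with its (covariate, level).
    Unknown levels in the data raise; declared levels absent from the data
    produce an all-zero column, which is left in place and will surface as a
    zero-cell report (never silently dropped).
    """
    n = len(profiles)
    X = pd.DataFrame({"const": np.ones(n)}, index=profiles.index)
    meta: list[tuple[str, object]] = []
    for cov in spec.covariates:
        col = profiles[cov.name]
        unknown = set(col.dropna().unique()) - set(cov.levels)
        if unknown:
            raise ValueError(f"unknown levels {sorted(map(str, unknown))} for covariate {cov.name}")
        for level in cov.levels:
            if level == cov.reference:
                continue
            X[f"{cov.name}={level}"] = (col == level).astype(float)
            meta.append((cov.name, level))
    return X, meta


def _zero_cell_report(profiles: pd.DataFrame, spec: ModelSpec, outcome: pd.Series) -> list:
    report = []
    for cov in spec.covariates:
        ct = pd.crosstab(profiles[cov.name], outcome)
        for level in cov.levels:
            if level not in ct.index or (ct.loc[level] == 0).any() or ct.columns.size < len(OUTCOME_ORDER):
                present = ct.loc[level] if level in ct.index else None
                zero_classes = (
                    [c for c in OUTCOME_ORDER if c not in ct.columns or (level in ct.index and ct.loc[level].get(c, 0) == 0)]
                    if present is not None
                    else list(OUTCOME_ORDER)
                )
                if zero_classes:
                    report.append({"covariate": cov.name, "level": level, "empty_against": zero_classes})
    return report


def fit_multinomial(
    profiles: pd.DataFrame,
    spec: ModelSpec = DEFAULT_SPEC,
    weights: Optional[Sequence[float]] = None,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> ORTable:
    """Maximum-likelihood baseline-category logit on complete-case records."""
    if "complete" in profiles.columns:
        used = profiles[profiles["complete"]].copy()
    else:
        used = profiles.copy()
    n_dropped = len(profiles) - len(used)
    if used.empty:
        raise ValueError("no complete-case records to fit")

    outcome = used["consistency_class"]
    present = [c for c in OUTCOME_ORDER if (outcome == c).any()]
    if len(present) < 2:
        raise ValueError("need at least two outcome classes present")
    if spec.reference_outcome not in present:
        raise ValueError(f"reference outcome {spec.reference_outcome!r} absent from data")
    classes = [spec.reference_outcome] + [c for c in present if c != spec.reference_outcome]
    y = outcome.map({c: i for i, c in enumerate(classes)}).to_numpy()

    X, meta = build_design(used, spec)
    zero_cells = _zero_cell_report(used, spec, outcome)
    # a level absent from the data gives an all-zero column: report it and
    # exclude it from the numerical fit (its coefficients come back as NaN)
    all_cols = list(X.columns)
    degenerate = [c for c in all_cols[1:] if X[c].nunique() == 1]
    X = X.drop(columns=degenerate)

    if weights is None:
        beta, se, llf, llnull, probs, converged, diag = _fit_statsmodels(X.to_numpy(), y, len(classes), tol, maxiter)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] == len(profiles) and "complete" in profiles.columns:
            w = w[profiles["complete"].to_numpy()]
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        beta, se, llf, llnull, probs, converged, diag = _fit_newton(X.to_numpy(), y, len(classes), w, tol, maxiter)
    if not converged:
        raise FitFailure("multinomial fit did not converge", diagnostics=diag)

    coefs = pd.DataFrame(beta, index=list(X.columns), columns=classes[1:]).reindex(all_cols)
    ses = pd.DataFrame(se, index=list(X.columns), columns=classes[1:]).reindex(all_cols)

    rows = []
    for j, cls in enumerate(classes[1:]):
        for (cov_name, level), col in zip(meta, all_cols[1:]):
            b = coefs.loc[col, cls]
            s = ses.loc[col, cls]
            z = b / s if s > 0 else np.nan
            p = 2 * _st.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append(
                {
                    "outcome_class": cls,
                    "covariate": cov_name,
                    "level": str(level),
                    "odds_ratio": float(np.exp(b)),
                    "ci_low": float(np.exp(b - Z_95 * s)),
                    "ci_high": float(np.exp(b + Z_95 * s)),
                    "p_value": float(p),
                    "significant_0.05": bool(p < 0.05) if np.isfinite(p) else False,
                }
            )
    table = pd.DataFrame(rows)
    return ORTable(
        table=table,
        coefs=coefs,
        ses=ses,
        loglik=llf,
        loglik_null=llnull,
        n_used=len(used),
        n_dropped=n_dropped,
        n_reference_group=int((outcome == spec.reference_outcome).sum()),
        converged=converged,
        zero_cells=zero_cells,
        fitted_probs=probs,
    )


def _fit_statsmodels(X: np.ndarray, y: np.ndarray, n_classes: int, tol: float, maxiter: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(y, X)
        res = model.fit(method="newton", maxiter=maxiter, gtol=tol, disp=False)
    converged = bool(res.mle_retvals.get("converged", False))
    probs = res.predict(X)
    diag = {"iterations": res.mle_retvals.get("iterations"), "loglik": float(res.llf)}
    return (
        np.asarray(res.params),
        np.asarray(res.bse),
        float(res.llf),
        float(res.llnull),
        np.asarray(probs),
        converged,
        diag,
    )


def _mnlogit_probs(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Class probabilities with the reference class in column 0."""
    eta = X @ beta  # (n, J-1)
    eta = np.column_stack([np.zeros(len(X)), eta])
    eta -= eta.max(axis=1, keepdims=True)
    ex = np.exp(eta)
    return ex / ex.sum(axis=1, keepdims=True)


def _fit_newton(X: np.ndarray, y: np.ndarray, n_classes: int, w: np.ndarray, tol: float, maxiter: int):
    """Weighted Newton–Raphson for the baseline-category logit.

    Analytic gradient and observed information; step-halving keeps the
    weighted log-likelihood monotone.  Standard errors come from the
    inverse information at the optimum.
    """
    n, p = X.shape
    J = n_classes
    Y = np.zeros((n, J))
    Y[np.arange(n), y] = 1.0
    beta = np.zeros((p, J - 1))

    def loglik(b):
        pr = _mnlogit_probs(X, b)
        return float(np.sum(w * np.log(np.clip(pr[np.arange(n), y], 1e-300, None))))

    ll = loglik(beta)
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        pr = _mnlogit_probs(X, beta)
        resid = Y[:, 1:] - pr[:, 1:]  # (n, J-1)
        grad = (X * w[:, None]).T @ resid  # (p, J-1)
        g = grad.reshape(-1, order="F")
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        # observed information: blocks H[j,k] = X' diag(w p_j (d_jk - p_k)) X
        H = np.zeros((p * (J - 1), p * (J - 1)))
        for j in range(1, J):
            for k in range(1, J):
                d = w * pr[:, j] * ((1.0 if j == k else 0.0) - pr[:, k])
                H[(j - 1) * p : j * p, (k - 1) * p : k * p] = (X * d[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as e:
            raise FitFailure(f"singular information matrix: {e}", {"iteration": it, "loglik": ll})
        new = beta + step.reshape((p, J - 1), order="F")
        ll_new = loglik(new)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new = beta + step.reshape((p, J - 1), order="F")
            ll_new = loglik(new)
            halvings += 1
        beta, ll = new, ll_new
    pr = _mnlogit_probs(X, beta)
    H = np.zeros((p * (J - 1), p * (J - 1)))
    for j in range(1, J):
        for k in range(1, J):
            d = w * pr[:, j] * ((1.0 if j == k else 0.0) - pr[:, k])
            H[(j - 1) * p : j * p, (k - 1) * p : k * p] = (X * d[:, None]).T @ X
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov)).reshape((p, J - 1), order="F")
    # weighted null log-likelihood (intercept-only model = weighted class shares)
    shares = np.array([np.sum(w[y == j]) for j in range(J)]) / np.sum(w)
    llnull = float(np.sum(w * np.log(np.clip(shares[y], 1e-300, None))))
    return beta, se, ll, llnull, pr, converged, {"iterations": it, "loglik": ll}


def sensitivity_complete_responders(
    profiles: pd.DataFrame,
    spec: ModelSpec = DEFAULT_SPEC,
    weights: Optional[Sequence[float]] = None,
) -> ORTable:
    """Refit restricted to women who answered the IPV item at all six waves."""
    six = profiles[profiles["answered_count"] == 6]
    if six.empty:
        raise ValueError("no records answered all six surveys; sensitivity subset is empty")
    sub_spec = spec.drop("n_surveys_cat")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[(profiles["answered_count"] == 6).to_numpy()]
    return fit_multinomial(six, sub_spec, weights=weights)


def draw_outcomes(X: np.ndarray, beta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample outcome codes (0 = reference) from a baseline-category logit.

    Used by the parameter-recovery harness: simulate outcomes with known
    coefficients, refit, and check CI coverage.
    """
    probs = _mnlogit_probs(np.asarray(X, dtype=float), beta)
    u = rng.random(len(probs))
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
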