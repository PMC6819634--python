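"""Synthetic six-wave cohort generator with an exact enumeration oracle.

Generative model
----------------
Each woman has a latent *lifetime* IPV state: with probability
``prev_ever`` she ever experiences IPV by the final wave, with an onset
wave drawn from ``onset_probs`` (onset 0 = before wave 1).  The truth is
absorbing — once experienced, "ever in a violent relationship" stays true —
so every observed inconsistency is reporting error by construction:

* false negative: answers NO at a wave despite IPV history up to that wave
  (per-wave probability ``fn``);
* false positive: answers YES with no history (per-wave probability ``fp``).

Missingness mixes monotone dropout (answering waves 1..k only) with
intermittent skipping (wave 1 plus a random subset of later waves), with
mixture weight ``monotone_weight``; ``answer_margins`` gives the
proportions answering exactly 3/4/5/6 waves and the remaining mass becomes
ineligible patterns (wave-1 only, wave-1 plus one later wave, or wave 1
missing).  Ineligibility odds may be tilted for ever-IPV women
(``ineligible_or``), reproducing the higher wave-1 prevalence observed
among excluded women.

A binary latent stress propensity ``S`` (more common among ever-IPV women)
drives the per-wave partner-stress items and shifts the error and dropout
rates on the logit scale — the minimal mechanism producing realistic
covariate/class associations.  ``exact_class_distribution`` marginalises
the whole model by enumeration (states x answered-wave patterns x response
strings), so simulated class frequencies can be checked against exact
probabilities to Monte-Carlo error.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .classify import ELIGIBLE_CLASSES, ConsistencyClass, classify
from .cohort import AREA_LEVELS, QUAL_LEVELS, Cohort, Response, WomanRecord

__all__ = [
    "CovariateParams",
    "EffectParams",
    "SimParams",
    "ClassDistribution",
    "simulate_cohort",
    "exact_class_distribution",
    "cross_sectional_bias",
]

_WAVES = np.arange(1, 7)


@dataclass(frozen=True)
class CovariateParams:
    """Covariate layer: category probabilities and emission rates.

    ``stress_latent`` is P(S=1 | never-IPV, ever-IPV); ``pstress_emit`` is
    the per-wave probability of reporting high partner stress given S;
    ``istress_probs`` the per-wave high income-stress probability by
    never/ever IPV; trajectory-type probabilities are (never sep/div,
    remained, became partnered, became sep/div).
    """

    area_probs: tuple[float, ...] = (0.506, 0.310, 0.153, 0.031)
    qual_probs: tuple[float, ...] = (0.44, 0.17, 0.21, 0.18)
    stress_latent: tuple[float, float] = (0.05, 0.25)
    pstress_emit: tuple[float, float] = (0.03, 0.55)
    istress_probs: tuple[float, float] = (0.08, 0.25)
    traj_probs_never: tuple[float, ...] = (0.837, 0.051, 0.030, 0.082)
    traj_probs_ever: tuple[float, ...] = (0.45, 0.20, 0.15, 0.20)
    baseline_item_missing: float = 0.01
    stress_item_missing: float = 0.02


@dataclass(frozen=True)
class EffectParams:
    """Logit-scale shifts applied when the stress latent S = 1."""

    beta_fn: float = 0.0
    beta_fp: float = 0.0
    beta_dropout: float = 0.0


@dataclass(frozen=True)
class SimParams:
    """Full generative parameter set (defaults: calibrated paper-like preset)."""

    n: int = 10966
    prev_ever: float = 0.1898571
    onset_probs: tuple[float, ...] = (
        0.8964400, 0.0, 0.0339450, 0.0254588, 0.0190941, 0.0143206, 0.0107415,
    )
    fp: float = 0.0123259
    fn: float = 0.0848335
    #: unconditional proportions answering exactly 3, 4, 5, 6 waves;
    #: the remainder (~0.199) becomes ineligible answer patterns
    answer_margins: tuple[float, ...] = (0.0681, 0.0857, 0.1258, 0.5214)
    ineligible_or: float = 1.6
    monotone_weight: float = 0.55
    #: ineligible mass split: wave-1 only / wave-1 + one later / wave-1 missing
    ineligible_split: tuple[float, ...] = (0.69, 0.16, 0.15)
    covariates: CovariateParams = field(default_factory=CovariateParams)
    effects: EffectParams = field(
        default_factory=lambda: EffectParams(beta_fn=2.5, beta_fp=1.5, beta_dropout=0.1)
    )
    seed: int = 20191029

    def validate(self) -> None:
        def _chk01(name, *vals):
            for v in vals:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} must be in [0, 1], got {v}")

        if self.n <= 0:
            raise ValueError("n must be positive")
        _chk01("prev_ever", self.prev_ever)
        _chk01("fp/fn", self.fp, self.fn)
        _chk01("onset_probs", *self.onset_probs)
        if len(self.onset_probs) != 7 or abs(sum(self.onset_probs) - 1.0) > 1e-6:
            raise ValueError("onset_probs must have 7 entries (onset 0..6) summing to 1")
        _chk01("answer_margins", *self.answer_margins)
        if len(self.answer_margins) != 4 or sum(self.answer_margins) > 1.0 + 1e-9:
            raise ValueError("answer_margins must give P(answer 3,4,5,6 waves) with sum <= 1")
        if sum(self.answer_margins) <= 0:
            raise ValueError("answer_margins must have positive mass")
        _chk01("monotone_weight", self.monotone_weight)
        _chk01("ineligible_split", *self.ineligible_split)
        if abs(sum(self.ineligible_split) - 1.0) > 1e-9:
            raise ValueError("ineligible_split must sum to 1")
        if self.ineligible_or <= 0:
            raise ValueError("ineligible_or must be positive")

    @property
    def ineligible_frac(self) -> float:
        return 1.0 - float(sum(self.answer_margins))

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


@dataclass
class ClassDistribution:
    """Exact probabilities of the six classes, conditional on eligibility."""

    probabilities: dict[str, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.probabilities[c.value] for c in ELIGIBLE_CLASSES])


def _shifted(p: float, beta: float) -> float:
    """Logit-shift a probability; degenerate 0/1 stay put (no error mass)."""
    if p <= 0.0 or p >= 1.0 or beta == 0.0:
        return p
    return 1.0 / (1.0 + math.exp(-(math.log(p / (1 - p)) + beta)))


def _ineligible_probs(params: SimParams) -> tuple[float, float]:
    """(q_never, q_ever): per-group ineligibility probabilities.

    The odds tilt ``ineligible_or`` is applied to ever-IPV women while the
    marginal ineligible fraction is held at ``1 - sum(answer_margins)``.
    """
    F = params.ineligible_frac
    rho, prev = params.ineligible_or, params.prev_ever
    if F <= 0:
        return 0.0, 0.0
    if rho == 1.0 or prev in (0.0, 1.0):
        return F, F

    def marginal(q_n: float) -> float:
        odds = rho * q_n / (1 - q_n)
        q_e = odds / (1 + odds)
        return prev * q_e + (1 - prev) * q_n - F

    q_n = brentq(marginal, 1e-12, 1 - 1e-12)
    odds = rho * q_n / (1 - q_n)
    return q_n, odds / (1 + odds)


def _k_probs_given_s(params: SimParams, s: int) -> np.ndarray:
    """P(answered count = 3..6 | eligible, S=s), with the dropout tilt."""
    m = np.asarray(params.answer_margins, dtype=float)
    k = np.array([3, 4, 5, 6], dtype=float)
    tilt = np.exp(params.effects.beta_dropout * s * (6.0 - k))
    p = m * tilt
    return p / p.sum()


def _eligible_patterns() -> dict[int, list[tuple[int, ...]]]:
    """Answered-wave patterns containing wave 1, keyed by answered count."""
    out: dict[int, list[tuple[int, ...]]] = {}
    for k in (3, 4, 5, 6):
        out[k] = [(1,) + rest for rest in combinations(range(2, 7), k - 1)]
    return out


_PATTERNS = _eligible_patterns()


def _string_classes(k: int) -> np.ndarray:
    """Class index (into ELIGIBLE_CLASSES) of each of the 2**k answered strings."""
    idx = {c: i for i, c in enumerate(ELIGIBLE_CLASSES)}
    out = np.empty(2 ** k, dtype=np.int64)
    for bits in range(2 ** k):
        seq = tuple(
            Response.YES if (bits >> i) & 1 else Response.NO for i in range(k)
        ) + (Response.MISSING,) * (6 - k)
        out[bits] = idx[classify(seq)]
    return out


_STRING_CLASSES = {k: _string_classes(k) for k in (3, 4, 5, 6)}
_BITS = {k: (np.arange(2 ** k)[:, None] >> np.arange(k)[None, :]) & 1 for k in (3, 4, 5, 6)}


def _pattern_prob(params: SimParams, k: int, pattern: tuple[int, ...]) -> float:
    mono = pattern == tuple(range(1, k + 1))
    p = (1.0 - params.monotone_weight) / math.comb(5, k - 1)
    if mono:
        p += params.monotone_weight
    return p


def exact_class_distribution(params: SimParams) -> ClassDistribution:
    """Exact class probabilities by full enumeration, given eligibility.

    Sums over latent state (ever x onset x stress latent), answered-wave
    pattern and response string; runs in well under a second.
    """
    params.validate()
    q_n, q_e = _ineligible_probs(params)
    s_never, s_ever = params.covariates.stress_latent
    acc = np.zeros(len(ELIGIBLE_CLASSES))
    total = 0.0
    for ever in (0, 1):
        p_ever = params.prev_ever if ever else 1.0 - params.prev_ever
        if p_ever == 0.0:
            continue
        p_elig = 1.0 - (q_e if ever else q_n)
        onset_states = (
            [(o, params.onset_probs[o]) for o in range(7) if params.onset_probs[o] > 0]
            if ever
            else [(99, 1.0)]
        )
        p_s1 = s_ever if ever else s_never
        for s, p_s in ((0, 1.0 - p_s1), (1, p_s1)):
            if p_s == 0.0:
                continue
            fn_s = _shifted(params.fn, s * params.effects.beta_fn)
            fp_s = _shifted(params.fp, s * params.effects.beta_fp)
            k_probs = _k_probs_given_s(params, s)
            for ki, k in enumerate((3, 4, 5, 6)):
                base = p_ever * p_s * p_elig * k_probs[ki]
                if base == 0.0:
                    continue
                bits = _BITS[k]
                cls = _STRING_CLASSES[k]
                for pattern in _PATTERNS[k]:
                    p_pat = _pattern_prob(params, k, pattern)
                    waves = np.asarray(pattern)
                    for o, p_o in onset_states:
                        hist = (ever == 1) & (waves >= o)
                        q = np.where(hist, 1.0 - fn_s, fp_s)
                        string_p = np.prod(np.where(bits == 1, q, 1.0 - q), axis=1)
                        w = base * p_pat * p_o
                        np.add.at(acc, cls, w * string_p)
                        total += w
    if total <= 0:
        raise ValueError("no eligible probability mass under these parameters")
    acc /= total
    return ClassDistribution({c.value: float(p) for c, p in zip(ELIGIBLE_CLASSES, acc)})


def cross_sectional_bias(params: SimParams, wave: int) -> float:
    """Apparent minus true lifetime prevalence at one wave, exactly.

    Apparent: P(YES | answered wave w).  True: P(IPV history up to wave w |
    answered wave w).  Conditioning both on answering the wave isolates
    measurement error from attrition-driven selection, so fp = fn = 0 gives
    exactly zero bias at every wave.
    """
    params.validate()
    if not 1 <= wave <= 6:
        raise ValueError("wave must be in 1..6")
    q_n, q_e = _ineligible_probs(params)
    s_never, s_ever = params.covariates.stress_latent
    split = params.ineligible_split

    # P(answer wave | ineligible pattern branch)
    if wave == 1:
        a_inel = split[0] + split[1]
    else:
        a_inel = split[1] * (1.0 / 5.0) + split[2] * (16.0 / 31.0)

    p_answer = 0.0
    p_yes = 0.0
    p_true = 0.0
    for ever in (0, 1):
        p_ever = params.prev_ever if ever else 1.0 - params.prev_ever
        if p_ever == 0.0:
            continue
        q = q_e if ever else q_n
        p_hist = (
            sum(p for o, p in enumerate(params.onset_probs) if o <= wave) if ever else 0.0
        )
        p_s1 = s_ever if ever else s_never
        for s, p_s in ((0, 1.0 - p_s1), (1, p_s1)):
            if p_s == 0.0:
                continue
            fn_s = _shifted(params.fn, s * params.effects.beta_fn)
            fp_s = _shifted(params.fp, s * params.effects.beta_fp)
            k_probs = _k_probs_given_s(params, s)
            if wave == 1:
                a_elig = 1.0
            else:
                # monotone: wave answered iff wave <= k; intermittent: (k-1)/5
                a_elig = sum(
                    kp
                    * (
                        params.monotone_weight * (1.0 if wave <= k else 0.0)
                        + (1.0 - params.monotone_weight) * (k - 1) / 5.0
                    )
                    for kp, k in zip(k_probs, (3, 4, 5, 6))
                )
            a = p_ever * p_s * ((1.0 - q) * a_elig + q * a_inel)
            yes_given_state = p_hist * (1.0 - fn_s) + (1.0 - p_hist) * fp_s
            p_answer += a
            p_yes += a * yes_given_state
            p_true += a * p_hist
    if p_answer <= 0:
        raise ValueError("no probability of answering this wave")
    return p_yes / p_answer - p_true / p_answer


def _choice_codes(rng: np.random.Generator, probs, size: int) -> np.ndarray:
    cum = np.cumsum(np.asarray(probs, dtype=float))
    cum /= cum[-1]
    return np.searchsorted(cum, rng.random(size), side="right")


def simulate_cohort(params: SimParams, seed: Optional[int] = None) -> Cohort:
    """Draw a reproducible cohort from the generative model.

    ``seed`` overrides ``params.seed``; the same (params, seed) pair yields a
    bit-identical cohort.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n
    cov = params.covariates
    eff = params.effects

    ever = rng.random(n) < params.prev_ever
    s_lat = rng.random(n) < np.where(ever, cov.stress_latent[1], cov.stress_latent[0])
    onset = _choice_codes(rng, params.onset_probs, n)
    onset = np.where(ever, onset, 99)

    q_never, q_ever = _ineligible_probs(params)
    inelig = rng.random(n) < np.where(ever, q_ever, q_never)

    # answered-wave pattern
    answered = np.zeros((n, 6), dtype=bool)
    k_probs = np.vstack([_k_probs_given_s(params, 0), _k_probs_given_s(params, 1)])
    k = 3 + _choice_codes_rows(rng, k_probs[s_lat.astype(int)], n)
    mono = rng.random(n) < params.monotone_weight
    later_rank = np.argsort(rng.random((n, 5)), axis=1)  # ranks of waves 2..6
    for i in range(n):
        if inelig[i]:
            continue
        answered[i, 0] = True
        if mono[i]:
            answered[i, 1 : k[i]] = True
        else:
            answered[i, 1 + later_rank[i, : k[i] - 1]] = True
    # ineligible patterns
    ine_idx = np.flatnonzero(inelig)
    if ine_idx.size:
        t = _choice_codes(rng, params.ineligible_split, ine_idx.size)
        one_later = rng.integers(1, 6, size=ine_idx.size)
        subset = rng.integers(1, 32, size=ine_idx.size)  # nonempty subset of waves 2..6
        for j, i in enumerate(ine_idx):
            if t[j] == 0:
                answered[i, 0] = True
            elif t[j] == 1:
                answered[i, 0] = True
                answered[i, one_later[j]] = True
            else:
                for b in range(5):
                    answered[i, 1 + b] = bool((subset[j] >> b) & 1)

    # responses
    fn_row = np.array([params.fn, _shifted(params.fn, eff.beta_fn)])[s_lat.astype(int)]
    fp_row = np.array([params.fp, _shifted(params.fp, eff.beta_fp)])[s_lat.astype(int)]
    hist = ever[:, None] & (onset[:, None] <= _WAVES[None, :])
    p_yes = np.where(hist, 1.0 - fn_row[:, None], fp_row[:, None])
    yes = rng.random((n, 6)) < p_yes

    # covariates
    area_code = _choice_codes(rng, cov.area_probs, n)
    qual_code = _choice_codes(rng, cov.qual_probs, n)
    area_miss = rng.random(n) < cov.baseline_item_missing
    qual_miss = rng.random(n) < cov.baseline_item_missing
    traj_p = np.vstack([cov.traj_probs_never, cov.traj_probs_ever])
    traj_type = _choice_codes_rows(rng, traj_p[ever.astype(int)], n)
    change_wave = rng.integers(2, 7, size=n)
    stable_status = _choice_codes(rng, (0.80, 0.08, 0.06, 0.06), n)  # married/defacto/widowed/single
    pstress = rng.random((n, 6)) < np.array(cov.pstress_emit)[s_lat.astype(int)][:, None]
    istress = rng.random((n, 6)) < np.array(cov.istress_probs)[ever.astype(int)][:, None]
    item_miss = rng.random((n, 6, 2)) < cov.stress_item_missing

    stable_names = ("married", "defacto", "widowed", "single")
    records = []
    for i in range(n):
        ipv = tuple(
            (Response.YES if yes[i, w] else Response.NO) if answered[i, w] else Response.MISSING
            for w in range(6)
        )
        rel = []
        for w in range(6):
            if not answered[i, w]:
                rel.append(None)
                continue
            tt = traj_type[i]
            if tt == 0:
                rel.append(stable_names[stable_status[i]])
            elif tt == 1:
                rel.append("divorced")
            elif tt == 2:
                rel.append("divorced" if (w + 1) < change_wave[i] else "married")
            else:
                rel.append("married" if (w + 1) < change_wave[i] else "divorced")
        ps = tuple(
            bool(pstress[i, w]) if answered[i, w] and not item_miss[i, w, 0] else None
            for w in range(6)
        )
        ins = tuple(
            bool(istress[i, w]) if answered[i, w] and not item_miss[i, w, 1] else None
            for w in range(6)
        )
        records.append(
            WomanRecord(
                id=f"w{i + 1:06d}",
                ipv=ipv,
                area=None if area_miss[i] else AREA_LEVELS[area_code[i]],
                qualification=None if qual_miss[i] else QUAL_LEVELS[qual_code[i]],
                relationship_status=tuple(rel),
                partner_stress_high=ps,
                income_stress_high=ins,
            )
        )
    seed_used = params.seed if seed is None else seed
    return Cohort(records, provenance=f"simulated(seed={seed_used}, n={n})")


def _choice_codes_rows(rng: np.random.Generator, probs: np.ndarray, size: int) -> np.ndarray:
    """Row-wise categorical draw: probs is (size, n_categories)."""
    cum = np.cumsum(probs, axis=1)
    cum /= cum[:, -1:]
    return (cum < rng.random(size)[:, None]).sum(axis=1)
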