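# ipvconsist

Longitudinal consistency analysis of lifetime yes/no survey items, built
around the intimate-partner-violence (IPV) question asked of a six-wave
women's cohort (1996–2016): *"Have you ever been in a violent relationship
with a partner/spouse?"* A lifetime item can legitimately move NO → YES as
life happens, but never YES → NO — so repeated administrations expose
reporting error that a single cross-sectional survey cannot.

The package is for survey methodologists and epidemiologists who want to

* classify six-wave response sequences into the six consistency classes —
  Consistent IPV (YES at every answered wave), Consistent later IPV (a
  block of NOs then YESes), Consistent never IPV, and the inconsistent
  classes Mainly IPV (one contradicted NO), Mainly no IPV (one later-denied
  YES) and Mixed IPV (everything else);
* derive the longitudinal covariates (separation/divorce trajectory,
  partner- and income-stress over time, answered-count category, design
  weights for two-fold rural oversampling) and produce the descriptive
  column-percentage tables;
* fit the baseline-category multinomial logistic regression of class on
  covariates (Consistent IPV as reference; odds ratios with Wald 95% CIs),
  plus the six-survey complete-responder sensitivity model;
* stress-test all of it against a synthetic cohort generator whose
  misreporting mechanism (per-wave false-negative/false-positive rates on
  an absorbing lifetime truth, mixed monotone/intermittent attrition) is
  marginalised *exactly* by an enumeration oracle.

The model at the core: with answered subsequence r (n answers, y YESes), a
sequence is inconsistent iff some YES precedes a later NO; consistent
sequences split by y = n / 0 < y < n / y = 0, inconsistent ones by
y = n − 1 / y = 1 / otherwise. In the generator, a woman with IPV history
up to wave w answers YES with probability 1 − fn and otherwise with
probability fp, so the class probabilities are an explicit function of
(prevalence, onset distribution, fp, fn, attrition) — computable in closed
form by summing over at most 2⁶ answer patterns × 8 latent states × 2⁶
response strings.

## Worked example

```sh
ipvconsist classify --pattern YNY
# mainly_ipv
python analysis/01_simulate_cohort.py
python analysis/02_classify_consistency.py
```

which prints (seed 20191029, n = 20,000, `paper_like` preset):

```
simulated 20000 women (paper_like preset, seed 20191029)
eligible: 16062  excluded: 3938 (19.7%)
wave-1 IPV prevalence  included: 13.8%  excluded: 19.0%
classified 16062 eligible women
  consistent_ipv           1179    7.3%
  consistent_later_ipv      551    3.4%
  consistent_never_ipv    12359   76.9%
  mainly_ipv                529    3.3%
  mainly_no_ipv             894    5.6%
  mixed_ipv                 550    3.4%
consistent overall: 87.7%  inconsistent: 12.3%  ever reported IPV: 23.1%
```

About 88% of simulated women answer consistently and 23% ever report IPV —
the structure the calibrated error rates (fp ≈ 1.2%, fn ≈ 8.5% base, higher
in a small high-stress subgroup) were chosen to produce. The remaining
drivers (`analysis/03…05`) build the descriptive tables, fit the
regressions (the full and six-survey-responder models agree in direction
for every strong effect), and quantify the cross-sectional consequence of
misreporting: a single-wave survey under-estimates true lifetime-to-date
prevalence by about 2 percentage points at every wave under the calibrated
rates, and by exactly zero under the error-free `null_model` preset.

The same steps are available as subcommands
(`ipvconsist simulate|classify|summarize|fit|run`); `ipvconsist run
--preset paper_like --n 20000 --seed 7 --out results/run` writes the whole
report bundle with a reproducibility manifest.

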