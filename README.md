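# airhappy

Bayesian multilevel ordinal modelling of self-rated happiness, with
model-based valuation of air-quality improvement.

## The problem

How much is a day of clean air worth to an urban resident? The
life-satisfaction approach answers this without market transactions: regress
self-rated happiness on both income and air pollution, then read off the
marginal rate of substitution between the two. This package implements that
analysis for a two-level survey design — respondents nested in cities, a
5-point ordinal happiness response, individual socio-demographics (income in
bands, education, marriage, housing, self-rated health, *hukou* registration)
and city-level exposures (annual polluted days, climate, per-capita GDP,
industry share) — together with a calibrated synthetic-survey generator so
that every stage is testable end to end without any restricted survey data.

## The model

For respondent *i* in city *k* with happiness score *y* ∈ {1, …, J}:

```
logit P(y_ik ≤ j) = α_j − x'_ik β − z'_k γ − u_k ,   u_k ~ N(0, σ_u²)
```

a proportional-odds cumulative logit with strictly increasing thresholds α_j
and a city random intercept u_k. Equivalently, a latent happiness variable
h\* = x'β + z'γ + u_k + ε with standard-logistic ε falls between thresholds.
Income enters as its natural log. Estimation is by adaptive
Metropolis-within-Gibbs MCMC (single-site random-walk updates for thresholds
and coefficients, a vectorised block update for the u_k, conjugate
inverse-gamma Gibbs for σ_u²) with Normal(0, 10⁶) priors on location
parameters and Inverse-Gamma(0.001, 0.001) on σ_u²; the full protocol is 3
chains × 50,000 iterations, 30,000 burn-in, thinning 10. Convergence is
monitored with split-R̂, model comparison uses DIC, and the between-city share
of latent variance is the variance partitioning coefficient
σ_u²/(σ_u² + π²/3).

With the fitted coefficients, valuation follows from the latent-variable
formulation (β_poll the pollution coefficient, γ_inc the log-income
coefficient, m monthly income):

* marginal willingness to pay: `WTP = (−β_poll / γ_inc) · m` RMB per
  one-polluted-day reduction (also computed per city from citywide mean
  incomes);
* compensating surplus of a discrete abatement Δ:
  `CS = m · (1 − exp((β_poll/γ_inc) · Δ))`.

## Worked example

```python
import airhappy as ah
from airhappy.inference import HierarchicalOrdinalRegression

individuals, cities = ah.simulate_survey(ah.default_scenario())  # 43 cities
est = HierarchicalOrdinalRegression(
    individual_predictors=("income_rmb",),
    city_predictors=("polluted_days",),
    transforms={"income_rmb": "log"},
    n_chains=2, n_iterations=5000, burn_in=2000, thin=5, random_state=1,
).fit(individuals, cities=cities)
print(est.summary_.loc[["b_income_rmb", "g_polluted_days", "sigma_u2"]])
```

prints (generating truths: income 0.28, pollution −0.003, σ_u² 0.1):

```
                   median    ci_2.5   ci_97.5  sig
parameter
b_income_rmb     0.314140  0.246971  0.383493  ***
g_polluted_days -0.004665 -0.006510 -0.002876  ***
sigma_u2         0.094765  0.056626  0.170272  ***
```

Both credible intervals cover their truths and the city-level variance is
recovered. Valuation from a fitted model:

```python
from airhappy.valuation import odds_effect, valuation_report
odds_effect(-0.002, 69)            # -> 14.80: a 69-day reduction raises the
                                   #    odds of higher happiness by ~15%
res = ah.valuation_report(est.draws_, individuals, delta_days=69)
res.wtp_rmb, res.wtp_pct, res.cs_rmb
```

The same machinery is exposed on the command line (`airhappy simulate`,
`airhappy fit`, `airhappy valuate`, `airhappy robustness`,
`airhappy reproduce-worked-examples`), and `ah.run_analysis(AnalysisConfig(...))`
drives the full nested model ladder (income+pollution → +covariates →
+health dummies) plus both robustness checks (local-*hukou* subset; 5→3
category collapse).

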