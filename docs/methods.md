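# Methods

## Model

Self-rated happiness `y ∈ {1..J}` (J = 5 by default) for respondent *i* in
city *k* follows a multilevel cumulative-logit (proportional-odds) model

    logit P(y_ik ≤ j) = α_j − x'_ik β − z'_k γ − u_k,   j = 1..J−1,

with strictly increasing thresholds α, individual covariates x, city
covariates z and a city random intercept u_k ~ N(0, σ_u²). The equivalent
latent-variable reading — h\* = x'β + z'γ + u_k + ε with standard-logistic ε,
and y the interval of h\* between thresholds — is what licenses the economic
valuation: coefficients are marginal effects on a common latent happiness
scale, so their ratios are marginal rates of substitution.

Key conventions:

* **Sign.** A positive coefficient raises the odds of a *higher* category.
* **No intercept.** The J−1 thresholds absorb it; u has prior mean zero.
* **Income is logged.** The WTP formula `(−β_poll/γ_inc)·income` is the
  marginal rate of substitution only when income enters in logs; a linear
  income specification would make the `×income` factor wrong. All other
  predictors enter in natural units, except per-capita GDP, rescaled to
  10,000-RMB units (`gdp_pc_10k`) to keep its coefficient at a numerically
  sane magnitude.
* **Categorical encodings.** Binary covariates are 0/1 against the natural
  reference (female, non-owner, non-commodity housing, unmarried, no
  degree); self-rated health enters as four dummies against the lowest
  category; the five-level age band enters as its index treated as
  continuous — the simplest encoding consistent with reporting a single age
  coefficient.

## Priors and MCMC

Thresholds and regression coefficients receive independent Normal(0, 10⁶)
priors; σ_u² receives Inverse-Gamma(0.001, 0.001). Both are configurable
(`PriorSpec`), and sensitivity runs amount to refitting with a different
`PriorSpec`.

The sampler is single-site adaptive random-walk Metropolis within Gibbs,
the scheme classic multilevel MCMC software uses for this model family:

1. each threshold in turn (proposals breaking the ordering are rejected;
   only the two bracketing response categories enter the ratio);
2. each β/γ coefficient in turn, with the linear predictor updated
   incrementally (dummy columns touch only their non-zero rows);
3. all u_k in one vectorised pass — their full conditionals are independent
   across cities;
4. a conjugate inverse-gamma Gibbs draw for σ_u² given u:
   IG(a + K/2, b + Σu²/2).

Proposal scales adapt in batches of `adapt_interval` (default 50) iterations
toward a target acceptance of 0.44 during burn-in only and are frozen
afterwards, so the retained draws come from a fixed transition kernel.
Initialisation: thresholds at the empirical cumulative logits of the
response (clipped away from 0/1, nudged into strict order when categories
are empty, which also raises a weak-identification warning), coefficients
and u at zero, σ_u² at 0.1. Non-finite initial likelihoods trigger a small
jittered re-initialisation loop before erroring.

Two purely numerical choices: (i) design columns are mean-centred inside the
sampler and thresholds shifted back per retained draw
(α = α_centred + μ'c), which removes the strong threshold–coefficient
random-walk correlation at short chain lengths without changing the model;
(ii) the incremental linear-predictor state is refreshed from scratch every
500 iterations to cap floating-point drift.

Defaults reproduce the full protocol — 3 chains × 50,000 iterations, 30,000
burn-in, thinning 10 — but every experiment in the test suite runs the
scaled-down protocol (2 chains × 5,000 iterations, 2,000 burn-in, thin 5, or
smaller), which the recovery experiments show is sufficient for these data
sizes.

## Summaries and diagnostics

Posterior tables report the median and equal-tailed 95% interval per
parameter, pooled across chains, using the linear-interpolation (type-7)
quantile convention; significance markers \*, \*\*, \*\*\* flag a 90/95/99%
interval excluding zero. Convergence uses classic split-R̂ (each chain
halved; between/within variance ratio), with a pipeline warning above 1.05.
DIC uses the Spiegelhalter plug-in form: pD = D̄ − D(θ̄) at the posterior
mean with the likelihood conditional on the city intercepts (variants of DIC
differ; this one is documented so comparisons stay internally consistent).
The variance partitioning coefficient is σ_u²/(σ_u² + π²/3), the city-level
share of latent variance given the fixed logistic residual variance π²/3.

## Valuation

From a fitted model with pollution coefficient β_poll (latent units per
polluted day) and log-income coefficient γ_inc:

* odds effect of a Δ-day reduction: 100·(exp(−β_poll·Δ) − 1) percent;
* marginal WTP: (−β_poll/γ_inc)·income, RMB per polluted-day reduction;
* per-city WTP applies the same formula to each city's mean income (computed
  from the individual table), so WTP in RMB is proportional to income while
  WTP as a percentage of income is constant across cities;
* compensating surplus of a discrete abatement Δ:
  income·(1 − exp((β_poll/γ_inc)·Δ)), which is ≤ WTP·Δ (concavity), ≤ income,
  and → WTP·Δ as Δ → 0.

Point estimates plug in posterior medians; a 95% uncertainty interval for
WTP comes from applying the formula draw by draw (draws with a non-positive
income coefficient are excluded with a warning). A positive pollution
coefficient yields negative WTP and a warning — never a silent clip.
Valuation requires γ_inc > 0; it errors otherwise. The default discrete
abatement is Δ = 69 days, one between-city standard deviation of annual
polluted days. CS as a share of annual income uses 12× the mean monthly
income.

Income recorded only in bands is converted to a continuous RMB/month figure
by band midpoints, with the open-ended top band set to 1.5× its lower bound —
a simple, documented extrapolation rule.

## Synthetic-data generator

`ScenarioConfig` defaults emulate the survey region's published descriptive
statistics: 43 cities with uniform 82–208 respondents each (≈ 6,200 total);
polluted days N(153, 69²) rounded and clipped to [0, 365]; wind N(2.40,
0.27²), temperature N(12, 2.28²), precipitation N(594, 115.13²); per-capita
GDP and industry share bivariate normal with means (60,217 RMB, 46.69%) and
correlation 0.5 — the one city-level correlation that is documented; income
log-normal with mean 6,868 and SD 5,311 RMB/month, binned into seven bands
(<2,000 … ≥20,000); binary covariate proportions (male 53.43%, college
62.04%, owner 63.71%, commodity housing 43.04%) and five-level age and
health distributions matching the published shares. Quantities the source
material does not pin down are configurable defaults chosen once: the
married share (0.70), the local-*hukou* share (0.70), the industry-share SD
(8 percentage points), and the income-band cut points.

The response is drawn from the latent model itself, so the generator and the
likelihood are exactly consistent. The generating coefficients in
`TrueParameters` are synthetic truths of plausible sign and magnitude
(income 0.28 per log-RMB, pollution −0.003 per day, σ_u² = 0.1, health
dummies increasing from 0.5 to 2.5, etc.), with thresholds (1.1, 2.5, 4.8,
7.1) chosen so the marginal response distribution lands near the published
one (~69% in the top two categories, ~4–5% in the bottom two). They are
documented testbed values, not empirical claims.

Domain bounds are enforced by clipping rather than truncated-normal
resampling; at the calibrated parameters the clipped mass is negligible and
the simplicity keeps the generator transparent. City and individual draws
use separate child streams of the scenario seed, so `generate_cities` and
`generate_individuals` are independently reproducible.

What the generator does *not* emulate: spatial structure (no coordinates,
no spatially correlated exposures), daily PM2.5 series (polluted days are
drawn directly), measurement error in self-reports, item non-response
patterns, and any dependence between individual covariates beyond city
membership (covariates are mutually independent given the city). Passing
tests therefore demonstrate correctness of the machinery under the assumed
model, not robustness to real-data violations of it.

## Simulation experiments and their scales

The test suite runs, among others:

* a parameter-recovery study — 20 replicates of the full-size scenario
  (43 × 82–208) at the scaled-down chain protocol, checking 95% interval
  coverage of the pollution and income coefficients and plug-in WTP
  accuracy;
* a DIC-ordering study — 20 replicates at 20 cities × 60–100 respondents,
  checking that a model containing the truly predictive covariates beats
  its lean nested rival;
* an MLE cross-check — with no simulated between-city heterogeneity, the
  posterior medians agree with an independent ordinal-regression maximum
  likelihood fit (statsmodels) within two posterior SDs;
* oracle equivalences — the vectorised likelihood and DIC against
  brute-force enumeration, category probabilities against direct logistic
  CDF differences at 1e-12.

The reduced problem sizes are the package's own choice of experiment scale;
they are large enough that the checks above are sharp.

## Known limitations

* A city-level coefficient estimated from K = 43 cities has an irreducible
  sampling floor: its standard error is approximately
  √((σ_u² + π²/3n̄) / (K·Var(z))) regardless of the thousands of
  respondents, about 0.0008 latent units/day at the calibrated scenario —
  a ~26% relative error on a true −0.003. Ratios of coefficients (WTP)
  inherit this noise, so point WTP from any single survey of this design
  carries substantial uncertainty; the draw-wise WTP interval reports it
  honestly.
* Strictly proportional odds: no category-specific or partial-proportional
  slopes.
* Cross-sectional associations only; nothing here identifies causal effects
  of pollution on happiness.
* No Hamiltonian/NUTS sampler and no WAIC/LOO; the single-site scheme is
  faithful to the classic protocol but mixes more slowly than gradient-based
  samplers on strongly correlated posteriors.
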