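# Methods

This note records the models behind `uhcmon`, the defaults that matter,
and what the synthetic data do and do not establish about behaviour on
real surveys.

## The estimation problem

UHC monitoring asks two questions of a country's household surveys:
what fraction of the population receives each essential health service,
and what fraction is financially harmed by paying for care. Both are
population proportions that must be estimated under a complex sampling
design, compared across socioeconomic groups, and extrapolated forward
to a target date (2030) with honest uncertainty. `uhcmon` implements
that chain: design-based estimation → composite indices → inequality
indices → Bayesian trend projection.

## Synthetic surveys

Real DHS/GLSS microdata are access-restricted, so the package generates
its own with known parameters.

**Coverage survey.** Per survey year, `n_clusters` clusters of
`households_per_cluster` households. Latent wealth is a cluster random
effect plus household noise, standard normal marginally with
intra-cluster correlation 0.3 — enough correlation that design-based
variance estimation is genuinely exercised (cluster effects inflate
variance roughly 1.5–2× over simple random sampling at these sizes).
Binary assets are Bernoulli with probabilities monotone in wealth,
their cut points spread over ±1.2 so asset prevalences span roughly
25–75%. Outcome *k* is Bernoulli of
`inv_logit(a0 + b·(year − year0) + g·wealth + region offset)`.
Sampling weights are log-normal with coefficient of variation 0.25
(mild, inverse-inclusion-probability-like variation without
extreme-weight pathologies), normalised to sum to the per-year sample
size. Optional outcome missingness (default 0) lets the pipeline's
missing-data paths be tested.

The 17 default indicators and their intercepts/slopes are anchored to
published national coverage levels for Ghana around 1995 and 2015
(logit-interpolated), so the default scenario reproduces the familiar
qualitative picture: immunisations near target, family planning and
care-seeking for pneumonia lagging, steep wealth gradients for
institutional delivery and sanitation. Wealth gradients `g` are graded
accordingly (≈0.2 for immunisations up to 1.8 for delivery care and
sanitation, in logit units per SD of latent wealth).

**Expenditure survey.** Per wave: household size 1 + Poisson(3);
per-capita total consumption log-normal; food share Beta with
wave-specific mean (0.55 falling to 0.47 across waves) and
concentration 18; OOP health spending zero-inflated (P(any) = 0.7)
log-normal, capped at non-food spending so the accounting identity
`food + non-food = total ≥ OOP + food` holds row by row. Log-OOP has
elasticity 0.7 with respect to log-consumption: less than unity, so the
OOP *share* of non-food spending falls with wealth and catastrophic
spending concentrates mildly among the poor (quintile-1 incidence
roughly twice quintile-5 in the first wave), rather than the extreme
gradient full independence would produce. Wave parameters keep the OOP
level roughly flat while nominal consumption grows, so CHE incidence
declines from ≈13% to ≈2% across the four default waves — the
historical pattern the package is meant to exercise.

What the generator does **not** emulate: survey nonresponse,
questionnaire-specific eligibility windows (e.g. antenatal-care timing,
vaccination card versus recall), item nonresponse in assets, price
deflation across waves, or household rosters. Passing tests therefore
demonstrate correctness of the estimators and samplers under a clean
two-stage design, not robustness to those real-data complications.

## Wealth index and quintiles

Assets are standardized to weighted mean 0 / variance 1; the score is
the projection onto the leading eigenvector of the (unweighted)
correlation matrix of standardized assets. Standardizing with weights
keeps the score's weighted mean at zero while leaving the principal
axis itself unweighted — a pragmatic resolution of the fact that
survey-weighted PCA is rarely used in practice. The sign is fixed
against the raw asset count. The index is computed per survey year:
each survey carries its own index, so scores are not comparable across
years (only ranks are used downstream).

Quintile assignment uses each household's midpoint rank in the
cumulative weight distribution (ties kept in input order for
reproducibility); a household falls in the fifth of [0,1) containing
its midpoint. This is equivalent to weighted 20/40/60/80-percentile cut
points with a deterministic rule for households that straddle a cut,
and it makes assignment invariant to any strictly increasing transform
of the score. Fewer than five distinct scores is treated as an error
rather than silently collapsing quintiles.

## Coverage estimation

Hajek ratio estimator with Taylor linearisation, clusters as PSUs
within year. The confidence interval is Wald on the logit scale —
chosen because every downstream step works with logits, and because it
respects [0,1]. Proportions of exactly 0 or 1 keep their point value
but get a half-success continuity adjustment before the logit, keeping
intervals and downstream transforms finite. An empty denominator yields
a flagged missing estimate, never a silent zero.

## Composite indices

DerSimonian–Laird random-effects pooling on the percent scale of the
point estimates: `w_i = 1/SE_i²`, `Q = Σ w_i (y_i − ȳ_w)²`,
`τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`, with pooled mean and SE
from weights `1/(SE_i² + τ²)`. Percent-scale pooling keeps the
"mean value of the indicators" interpretation exact under equal SEs; a
logit-scale variant is available behind the `scale` flag for
sensitivity analysis near the boundary. The composite coverage index
weights its four specialties equally, with DPT3 double-weighted within
immunisation — monotone in every argument and bounded in [0,100].

## Financial hardship

All comparisons are per-capita (household totals divided by household
size); an adult-equivalence exponent was deliberately not introduced,
keeping the accounting transparent. The CHE threshold is strict
(`share > 0.25`). The poverty line uses the lower-inclusive weighted
quantile (smallest value whose cumulative weight fraction reaches the
target) for both band edges; an empty band widens symmetrically by one
percentile at a time, logged. Poverty lines are per wave in nominal
terms — no CPI deflation — so lines are not comparable across waves,
only incidences are. Impoverishment follows the guideline reading that
a household already below the line before paying cannot be *newly*
impoverished; the hardship flag is the logical union, which gives the
bounds `max(CHE, IMP) ≤ hardship ≤ CHE + IMP` checked in the tests.

## Trend model

Observed proportions p_it are logit-transformed and modelled as

    y_it = α + β (t − t0) + ε,   ε ~ N(0, σ²),   p(α, β, σ²) ∝ 1/σ²

with year centred at the first survey (numerical conditioning only;
results invariant). The likelihood is unweighted across survey years:
per-survey sampling variances are not propagated into the trend fit,
which matches regressing published point estimates; the spread of
logit-scale residuals absorbs both sampling and structural error. This
is the main simplification of the trend module and the reason its
credible intervals should be read as trend uncertainty, not full design
uncertainty.

Two samplers target the identical posterior. The conjugate sampler
draws σ² from its scaled inverse-χ² marginal (n−k degrees of freedom)
and the coefficients from their conditional normal — exact, used as the
oracle. The MCMC sampler is a two-block Gibbs chain alternating
β | σ² ~ N(β̂, σ²(X'X)⁻¹) and σ² | β ~ InvGamma(n/2, RSS(β)/2), run as
two chains with overdispersed initial variances (×0.1 and ×10), 5000
burn-in iterations each and 1000 retained draws by default. Convergence
is declared when every parameter's PSRF ≤ 1.02; otherwise the burn-in
doubles up to a 200,000-iteration cap and a nonconvergent fit is
returned flagged, never silently. Because both conditionals are exact,
the chain mixes in practice within a handful of iterations; the
machinery (PSRF, burn-in doubling, the cap) exists to keep the fitting
contract honest rather than to rescue a sticky sampler.

Degenerate inputs: exact-line data have their residual variance floored
at 1e-8 on the logit scale (logged) so the posterior stays proper;
grouped fits reject groups with fewer than two observations by name.

**Grouped model.** Group intercept offsets relative to the
alphabetically first label, plus group-specific slopes when
`interaction=True`. DIC — `Dbar + pD` with `pD = Dbar − D(posterior
mean)` — selects between the two. The `pD ≈ number of parameters`
identity and the model-recovery property are asymptotic: at five waves
per group the plug-in deviance is inflated enough relative to the
χ²-type penalty that the interaction model is over-selected (≈77%
recovery in internal simulations), so the recovery simulation is run at
eight waves per five groups, where the asymptotic regime applies and
recovery is ≈85%. With real five-wave data, DIC selection should be
read as a mild preference, not a sharp test.

**Derived quantities.** Projections push draws of the *mean trend*
through the inverse logit (no new-observation noise — the target is the
systematic trajectory); a posterior-predictive variant would add
N(0, σ²) draws on the logit scale first. Credible intervals therefore
widen monotonically with extrapolation distance on the logit scale;
on the percent scale the inverse logit compresses them again as
coverage saturates near 0% or 100%. The annual rate of change is the
endpoint geometric rate `100·[(c_end/c_start)^(1/Δt) − 1]` computed per
draw. The coverage-target probability is the fraction of draws at or
above 80% in 2030. Full financial-risk protection (0% hardship
incidence) has probability zero under any continuous posterior, so it
is operationalised as incidence below ε = 1 percentage point by
default; ε is a reporting convention, exposed as `frp_epsilon`, and
results should always be quoted together with it.

## Inequality

SII/RII are computed on quintile-level aggregates (five values, five
rank midpoints, share weights) rather than household-level regression:
this matches how results are reported, makes the closed form exact, and
lets posterior draws of the five quintile trajectories propagate into
SII/RII credible intervals by direct evaluation per joint draw. The
regression is linear on the percent scale (identity link), so SII reads
directly in percentage points. The known cost: with steep gradients the
fitted value at a rank extreme can leave [0,100], in which case RII is
undefined (flagged, `None`) or unstable; SII remains well-defined.
Draws must be jointly indexed across quintiles — permuting draws within
one quintile destroys the posterior dependence and is checked in the
tests as a contract.

## Sizes and runtime

The default synthetic scenario uses 100 clusters × 25 households × 5
survey years (12,500 coverage records) and 3,000 households × 4
expenditure waves; the demo scenario scales down to 40 × 15 and 1,200
households, which keeps a full pipeline run (17 indicators, quintile
and region models, DIC selection everywhere) to a few minutes at most
on one CPU. The acceptance script's simulation studies use 200
replicates for slope calibration and 100 for DIC recovery — enough for
binomial standard errors of 1.5 and 4 points respectively.

## Known limitations

- Trend fits ignore per-survey sampling variances (see above); a
  variance-weighted likelihood is the natural extension.
- Identity-link SII/RII can produce out-of-range fitted extremes for
  steep gradients; a logit-link variant would bound them at the cost of
  the percentage-point reading.
- The annual-rate definition (endpoint geometric) is one of several in
  use; rates computed from series that start near zero coverage are
  dominated by the early exponential phase and can look dramatic.
- Wealth quintiles in the expenditure pipeline come from per-capita
  consumption rather than an asset index, as expenditure surveys carry
  no asset module here; the two rankings agree only approximately in
  real data.
- No nonresponse adjustment, poststratification, or calibration
  weighting; weights are taken as given.
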