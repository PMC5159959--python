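# Methods

## Scope and model

`dietcra` implements a desk-scale comparative risk assessment of dietary
risks for NCD burden.  The quantity at its core is the population
attributable fraction for a continuous exposure,

    PAF_ast = ( ∫_l^u RR_as(x) P_ast(x) dx − RR_as(TMREL) )
              / ∫_l^u RR_as(x) P_ast(x) dx ,

applied per risk-outcome-stratum and then rolled into attributable
counts, rates and shares via cause-specific burden envelopes.  The PAF
expression only equals the conventional attributable fraction when the
relative-risk curve is normalised at the counterfactual exposure; all
curves here satisfy RR(TMREL) = 1 by construction, so the fraction
reduces to `1 − 1/E[RR]` and, for capped curves, lies in [0, 1).

### Exposure distributions

Intakes are right-skewed, so the default family is lognormal,
moment-matched to the stratum mean and sd; gamma and truncated normal
are selectable per risk in config.  The integration support [l, u]
defaults to the 0.001 and 0.999 quantiles of the fitted distribution
(config-overridable); the density is renormalised over the support.  A
zero sd marks an explicit point mass (the degenerate everyone-at-x
population), for which E[RR] = RR(mean).

### Relative-risk curves

Log-linear in exposure: `RR(x) = exp(β · excess(x))` where the excess is
the signed distance from the TMREL toward the harmful side — above it
for harmful-high risks (sodium, red meat), below it for harmful-low
risks (fruits, fibre) — and is clamped at zero on the no-risk side when
the curve is capped (the default), producing the monotone plateau at
RR = 1.  Mediated risks compose two stages: a linear mediator shift per
exposure unit (mmHg systolic blood pressure per g/day sodium; BMI units
per serving of sugar-sweetened beverages) and a log-linear curve on the
mediator scale.  The composition is again log-linear in exposure with
slope `slope × β_mediator`, equals 1 at the TMREL, and is identically 1
when the mediator slope is zero.

### TMRELs

Each risk carries a single optimal intake; its uncertainty is uniform on
[0.8·m, 1.2·m] (±20%), sampled once per Monte Carlo draw and shared
across outcomes, strata and periods.  The band half-width is a config
value (`tmrel_uncertainty`, default 0.2) so the zero-uncertainty limit
of the whole pipeline is reachable in tests.

### Numerical integration

E[RR] is computed by Gauss–Legendre quadrature.  A capped curve has a
derivative discontinuity at the TMREL, which destroys the spectral
convergence of a single panel, so the integral is split at the (clipped)
TMREL and each smooth piece integrated separately; 64 nodes per piece
then agree with node-doubled references to ~4e-16 over the default
parameter ranges.  The scalar entry point (`compute_paf`) additionally
doubles nodes until successive estimates agree to 1e-8 (default start
256, ceiling 4096) and raises if they do not; quadrature weights are
self-normalised by the density's own quadrature mass so truncation-mass
error cancels.  The vectorised draw-level path evaluates the same
piecewise rule over broadcast parameter arrays in bounded-memory chunks.

## Exposure estimation

The estimator replaces a full Bayesian hierarchical meta-regression
engine with two transparent components that preserve its borrow-strength
semantics at desk scale:

1. **Pooled regression** (`fit_global`): inverse-variance weighted WLS of
   reported stratum means on sex, age-group midpoint, year and named
   covariates (statsmodels backend).  Columns without variation are
   dropped rather than fit as degenerate; genuinely collinear columns
   are named in the error.
2. **Cascade** (`cascade_fit`): at each level the parent estimate enters
   as a Gaussian prior with variance `parent_sd² / prior_strength`
   (default prior_strength 1.0, config-overridable) and is combined by
   precision weighting with the inverse-variance weighted mean of the
   data local to the node's subtree.  With no local data the child
   inherits the parent estimate unchanged, and `source_level` records
   the level the estimate was actually informed from.

One refinement matters: before each cascade step the parent sd is
inflated by a method-of-moments between-children heterogeneity term
(the spread of child-level pooled means in excess of their sampling
variances).  Without it, abundant or very precise data anywhere in the
tree would shrink the parent's *sampling* sd toward zero and let the
prior crush local data — the cascade would then be unable to recover
country-level truth even from perfect country surveys.  With it, the
noise-free full-coverage limit recovers true exposures to machine
precision while sparse-coverage worlds still borrow strength correctly.

Supporting operations: the residual-method energy adjustment maps each
intake to its regression residual plus the predicted intake at
2000 kcal/day (identity when energies do not vary); the dietary→urinary
sodium conversion is a regression-through-origin slope `Σxy/Σx²` from
surveys reporting both; the data representativeness index is the
fraction of countries with any exposure datum.

## Uncertainty propagation

Every uncertain parameter gets a named, reproducible draw stream: the
root seed plus a CRC-32 hash of the parameter name seeds a NumPy
`SeedSequence` child, making draws bit-identical across runs and
invariant to parameter ordering.  Laws: exposure mean ~
normal(posterior mean, posterior sd); log-RR and mediator slope ~
normal(estimate, SE); TMREL ~ uniform(±20%).  Parameters shared between
the two reporting periods (RRs, slopes, TMRELs) use one stream across
years so period contrasts are properly correlated; exposure means are
per-stratum parameters.  Envelopes are treated as fixed, since the
bundle format carries no envelope UIs.  Summaries are the draw mean with
a 95% UI from the empirical 2.5th/97.5th percentiles (1000 draws by
default).

## Burden accounting and reporting

Attributable counts are `Σ_o envelope_o × PAF_o` per stratum and metric;
outcomes without a PAF contribute zero with a warning.  Combination
across risks assumes independence (`1 − Π(1 − PAF_i)`), which is why the
per-risk attribution table sums to more than the combined total.  Crude
rates are per 100,000; age-standardization uses a config standard
population (default: equal weights over the modelled age groups — the
results are internally consistent but not comparable to any specific
external standard).  NCD and all-cause denominators for the share
columns are multiplicative factors over the modelled-outcome envelope
total (config `ncd_factor`, `allcause_factor`).

All internal arithmetic is unrounded; the trend report rounds counts and
rates to integers and percentages to one decimal at format time, and
computes change columns from unrounded values.  Cells whose printed
change cannot be recomputed from their own rounded neighbours are listed
in a flags file rather than silently absorbed — published tables contain
such cells, and the report makes them visible instead of targeting them.

## Synthetic world

The generator emulates the data landscape the pipeline is designed for:
a 4-level hierarchy (default 2 super-regions × 2 regions × 3 countries),
true country exposure means as global means times lognormal
super-region/region/country effects (log-sds 0.10/0.08/0.12), a mild age
gradient (0.9→1.1 across five age groups 25–80) and a male/female intake
ratio of 1.1.  Four risks (fruits, vegetables, red meat direct; sodium
mediated through blood pressure) cover both directions, with per-risk
survey coverage spanning the observed representativeness range
(0.17–0.94).  Surveys report the true stratum mean plus
normal(0, cv·mean/√n) noise with n = 500 and the matching SE (floored at
1e-9 so SEs stay positive; a `survey_noise_scale` of 0 is the noise-free
limit of perfectly precise surveys).  RR and TMREL tables carry the true
values with their SEs — meta-analytic uncertainty enters through the
Monte Carlo draws, not a perturbed point — which keeps UI coverage
nominal and the noise-free limit exact.  Burden envelopes are
multiplicative: baseline outcome rates times an age ratio (1.9 per
group), sex ratio (1.2), optional per-year population growth and rate
trends; YLLs are deaths times an age-declining life-expectancy factor,
YLDs 5% of YLLs, DALYs their sum.  The bundle includes the exact true
PAF per risk-outcome-stratum computed by quadrature from the true
parameters, so recovery and coverage are checkable end to end, and
round-trips losslessly through a directory of TSVs plus YAML config and
checksum manifest (`%.17g` floats and round-trip parsing make staged
re-runs byte-identical to chained ones).

What the generator does not emulate: non-lognormal intake shapes and
ensemble-distribution averaging, covariate-driven exposure differences,
correlated risk factors, envelope uncertainty, and real survey-format
quirks.  Passing tests therefore demonstrate correctness of the
estimation, integration and accounting machinery under the stated
generative model, not fidelity to any real country's data.

## Problem sizes used in validation

Oracle agreement uses a 20-point parameter grid with 10⁶-point trapezoid
grids and 10⁶-draw Monte Carlo samples; coverage uses 100 replicates of
a 2-country world at 250 draws; cascade recovery uses 20 replicates of
the default 12-country world; pipeline demonstrations use 100–250 draws.
These sizes give stable verdicts in about a minute each while the
default production setting remains 1000 draws.

## Known limitations

- Independence across risks is optimistic; real dietary risks are
  correlated and partially mediated through shared metabolic pathways.
- The cascade is a two-moment approximation; it has no age-pattern
  smoothing, covariate selection or MCMC posterior.
- TMRELs are risk-level, not outcome-specific.
- Envelope uncertainty is not propagated.
- The age-standardized rows use the configured standard population and
  are not numerically comparable to externally published standardized
  rates.
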