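# Data dictionary

All tables are tab-separated text with a header row.  Age groups are
half-open intervals `[age_lower, age_upper)` in years; `sex` is
`female`/`male`; `year` is the calendar year of the estimate.

## Bundle inputs

### hierarchy.tsv
| column | type | meaning |
|---|---|---|
| name | text | location identifier |
| level | enum | `global`, `super_region`, `region`, `country` |
| parent | text | parent location (empty for the global root) |

### surveys.tsv — tabulated exposure observations
| column | type | meaning |
|---|---|---|
| risk | text | dietary risk factor name |
| location | text | hierarchy node the survey represents |
| level | enum | hierarchy level of `location` |
| year, sex, age_lower, age_upper | | stratum selectors |
| mean | exposure units | reported stratum intake mean |
| se | exposure units | standard error of the mean (> 0) |
| n | integer | survey sample size |
| energy | kcal/day | mean total energy intake (2000 = already adjusted) |

Exposure units are per risk (g/day for foods; g/day urinary equivalent
for sodium; mg/day or percent of energy for nutrients) and declared in
the risk registry / world config.

### relative_risks.tsv — one row per diet-disease pair
| column | type | meaning |
|---|---|---|
| risk, outcome | text | the pair |
| log_rr_per_unit | 1/exposure unit | exposure-scale log relative risk per unit of excess beyond the TMREL (for mediated rows: slope × mediator log-RR) |
| se | 1/exposure unit | SE of log_rr_per_unit (blank for mediated rows) |
| mediator | enum | `sbp`, `bmi`, or blank for direct effects |
| slope | mediator units per exposure unit | stage-1 mediator shift |
| slope_se | same | SE of the slope |
| mediator_log_rr_per_unit | 1/mediator unit | stage-2 log-RR per mediator unit |
| mediator_se | same | SE of the stage-2 log-RR |

### tmrels.tsv
| column | type | meaning |
|---|---|---|
| risk | text | risk name |
| optimal | exposure units | TMREL optimal mean; uncertainty is uniform ±20% (config `tmrel_uncertainty`) |

### envelopes.tsv — cause-specific burden
| column | type | meaning |
|---|---|---|
| outcome | text | cause name |
| metric | enum | `deaths`, `dalys`, `ylls`, `ylds` |
| location, year, sex, age_lower, age_upper | | stratum |
| count | persons / person-years | burden envelope count (≥ 0) |
| population | persons | stratum population (> 0) |

### ground_truth_paf.tsv / ground_truth_exposure.tsv (synthetic only)
True PAF per risk-outcome-stratum (`paf_true`) and true exposure
mean/sd per risk-stratum (`true_mean`, `true_sd`), computed from the
generator's true parameters.

### world_config.yaml
Per-risk direction, unit, distribution family and coefficient of
variation, survey coverage, mediator; plus `prior_strength`,
`support_quantiles`, `tmrel_uncertainty`, `ncd_factor`,
`allcause_factor`, years, age groups, sexes and the generator seed.
`manifest.yaml` lists SHA-256 checksums of every bundle file.

## Pipeline outputs

### exposure_estimates.tsv
`risk, location, year, sex, age_lower, age_upper, mean, sd_of_mean,
source_level` — cascaded posterior mean of the stratum exposure mean,
its sd, and the hierarchy level the estimate was informed from.

### paf_estimates.tsv
`risk, outcome, location, year, sex, age_group, age_lower, age_upper,
paf_mean, paf_lower, paf_upper, paf_point` — Monte Carlo mean and 95% UI
plus the deterministic point PAF.

### burden_summary.tsv
Per metric and year: `count`, `rate` (per 100,000), `as_rate`
(age-standardized), `prop_all`, `prop_ncd`, `as_prop_all`, `as_prop_ncd`
— each as `_mean`, `_lower`, `_upper` — plus deterministic `count_point`,
`rate_point`, `as_rate_point`, the `population` and the modelled-outcome
`envelope_total`.

### risk_attribution.tsv
Per risk, metric and year: attributable count mean/UI/point without
cross-risk combination (sums exceed the combined total by design).

### trend_report.tsv, flags.txt, run_log.yaml
The formatted two-period table (counts/rates as integers, percentages to
one decimal, changes from unrounded values); flagged change cells not
reproducible from their rounded neighbours; and the run log (config
SHA-256, seed, draw count, package versions).
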