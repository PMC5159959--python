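# dietcra

Comparative risk assessment (CRA) of dietary risk factors for
non-communicable disease (NCD) burden, in the style of the Global Burden
of Disease dietary-risk analyses: how many deaths, DALYs, YLLs and YLDs
in a population are attributable to diets low in fruits, vegetables or
fibre and high in sodium, red meat or sugar-sweetened beverages?

The package is a library (plus a thin `dietcra` command line) for
epidemiologists and burden-of-disease modellers who want a transparent,
fully seeded desk-scale implementation of the CRA pipeline — and a
synthetic-world generator with known ground truth so every stage can be
validated without access to any proprietary exposure database.

## The model

For one risk, outcome and population stratum (age *a*, sex *s*, year *t*),
the population attributable fraction compares the observed exposure
distribution *P(x)* with a counterfactual at the theoretical minimum risk
exposure level (TMREL):

    PAF = ( ∫ RR(x) P(x) dx  −  RR(TMREL) ) / ∫ RR(x) P(x) dx

with the integral over the exposure support [l, u].  Relative-risk curves
are log-linear in exposure, normalised so RR(TMREL) = 1, and capped at 1
on the no-risk side of the TMREL, so the expression reduces to
`1 − 1/E[RR]` ∈ [0, 1).  Mediated risks (sodium via systolic blood
pressure, sugar-sweetened beverages via body-mass index) compose a
mediator shift per exposure unit with a mediator-scale RR curve.
Attributable burden sums PAF-weighted cause envelopes over outcomes:

    attributable burden_ast = Σ_o Burden_oast · PAF_oast

Exposure means are estimated from sparse tabulated surveys by an
inverse-variance weighted meta-regression plus a four-level cascade
(global → super-region → region → country) in which each node's estimate
serves as a prior for its children; countries without data inherit their
ancestors' estimates.  Uncertainty in exposure means, log relative risks,
mediator slopes and TMRELs (uniform ±20% band) is propagated by seeded
Monte Carlo (1000 draws by default) and summarised as 95% uncertainty
intervals from the empirical 2.5th/97.5th percentiles.

## Worked example

```python
import numpy as np
from dietcra import (Direction, ExposureDistribution, RelativeRiskCurve,
                     RiskFactor, compute_paf)

sodium = RiskFactor("sodium", Direction.harmful_high, exposure_unit="g/day")
intake = ExposureDistribution(mean=4.0, sd=1.0)          # lognormal fit
curve = RelativeRiskCurve(sodium, "stroke", np.log(1.3)) # RR 1.3 per g/day
print(compute_paf(intake, curve, tmrel_value=2.0))
```

prints `0.4286`: with mean urinary sodium at 4 g/day and RR 1.3 per g/day
above an optimum of 2 g/day, 42.9% of stroke burden is attributable to
excess sodium.  Shifting the population mean to 3.0 and 2.5 g/day lowers
the fraction to 0.2471 and 0.1443.

Running the whole pipeline on the default synthetic world
(`examples/04_full_pipeline_on_synthetic_world.py`) prints

```
diet-attributable deaths 2013: 21,955 (95% UI 17,699-27,293)
  = 74 per 100,000 crude, 102 age-standardized, 17.5% of NCD deaths
median |PAF error| vs ground truth: 0.0012
95% UIs cover the true PAF in 100.0% of strata
```

— the per-stratum PAF estimates recover the world's known true values,
and the per-risk table that follows shows why the individual risks sum to
more than their combination (overlap between correlated risk factors is
handled multiplicatively).

The `examples/` directory has one short script per capability: the PAF
integral, the mediated sodium chain, the exposure cascade, the full
pipeline, the two-period trend report, and the published-table trend
arithmetic.  The same stages are available from the shell:

```sh
dietcra simulate --out world --seed 7
dietcra all --in world --out results --seed 7 --n-draws 1000
```

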