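"""Two-period trend report: rising counts with falling rates.

Population growth with declining age-specific cause rates yields the
familiar pattern of attributable counts rising while crude and
age-standardized rates fall.  Death envelopes are calibrated to the
published national totals, so the change column reproduces the published
+61.2%.
"""

from dietcra import WorldSpec, generate_two_period_world
from dietcra.pipeline import run_all
from dietcra.synthetic import calibrate_attributable_deaths

bundle = generate_two_period_world(
    WorldSpec(seed=19), pop_growth=0.025, rate_trend=0.99
)
calibrated = calibrate_attributable_deaths(
    bundle, {1990: 37_465.0, 2013: 60_402.0},
    seed=19, n_draws=100, quantity="count_mean",
)
result = run_all(calibrated, n_draws=100, seed=19)

cols = ["metric", "number_1990", "number_2013", "number_change",
        "rate_1990", "rate_2013", "rate_change"]
block = result.trend[
    (result.trend["standardization"] == "unstandardized")
    & (result.trend["denominator"] == "all_causes")
]
print(block[cols].to_string(index=False))
print(
    "\ndeath counts rise by the calibrated 61.2% while the crude death "
    "rate falls: the population grew faster than age-specific risk."
)
if result.flags:
    print(f"\n{len(result.flags)} change cells flagged as not reproducible "
          "from their rounded neighbours (see result.flags)")
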