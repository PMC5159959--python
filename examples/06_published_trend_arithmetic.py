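"""Recomputing the published Ethiopia trend arithmetic.

The published GBD 2013 dietary-risk tables for Ethiopia print national
attributable counts and rates for 1990 and 2013 together with derived
percentage changes and shares.  Treating the printed counts as inputs,
the accounting operations reproduce every derived cell to its printed
one-decimal precision.
"""

from dietcra import datasets
from dietcra.burden import pct_change, proportion

counts = datasets.ETHIOPIA_ATTRIBUTABLE_COUNTS
rates = datasets.ETHIOPIA_ATTRIBUTABLE_RATES

print("diet-attributable burden, Ethiopia 1990 -> 2013:")
for metric in ("deaths", "dalys", "ylls", "ylds"):
    change = pct_change(counts[(metric, 1990)], counts[(metric, 2013)])
    rchange = pct_change(rates[(metric, 1990)], rates[(metric, 2013)])
    print(
        f"  {metric:<7} {counts[(metric, 1990)]:>11,} -> {counts[(metric, 2013)]:>11,} "
        f"({change:+.1f}%)   rate {rates[(metric, 1990)]:>6.0f} -> "
        f"{rates[(metric, 2013)]:>6.0f} per 100k ({rchange:+.1f}%)"
    )

cvd = datasets.ETHIOPIA_DIET_CVD_DEATHS[2013]
print(
    f"\nof the {counts[('deaths', 2013)]:,} diet-attributable deaths in 2013, "
    f"{cvd:,} were cardiovascular:"
)
print(f"  {proportion(cvd, counts[('deaths', 2013)]):.1f}% of diet-attributable deaths were CVD")
print(f"  {proportion(cvd, datasets.ETHIOPIA_CVD_DEATHS_2013):.1f}% of all CVD deaths were diet-related")
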