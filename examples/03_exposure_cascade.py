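"""Borrowing strength down the location hierarchy.

A country with surveys is estimated mostly from its own data; a country
without surveys inherits the pooled estimate of its region.  The cascade
combines the parent estimate (as a prior) with the local inverse-variance
weighted mean at each level.
"""

import pandas as pd

from dietcra import Hierarchy, HierarchyNode, estimate_exposure_surface

hierarchy = Hierarchy(
    [
        HierarchyNode("global", "global"),
        HierarchyNode("SSA", "super_region", "global"),
        HierarchyNode("East-SSA", "region", "SSA"),
        HierarchyNode("Ethiopia", "country", "East-SSA"),
        HierarchyNode("Kenya", "country", "East-SSA"),
    ]
)

# two fruit-intake surveys in Kenya, none in Ethiopia
surveys = pd.DataFrame(
    [
        {"location": "Kenya", "year": 2013, "sex": "female",
         "age_lower": 25.0, "age_upper": 35.0, "mean": 95.0, "se": 4.0},
        {"location": "Kenya", "year": 2013, "sex": "female",
         "age_lower": 25.0, "age_upper": 35.0, "mean": 105.0, "se": 4.0},
    ]
)

estimates = estimate_exposure_surface(surveys, hierarchy)
print(estimates.to_string(index=False))
print(
    "\nKenya's estimate is driven by its surveys; Ethiopia, with no data, "
    "inherits the region-level estimate (source_level 'region')."
)
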