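"""Published reference numbers used in worked examples and checks.

The GBD 2013 analysis of dietary risks in Ethiopia reports national
diet-attributable burden totals for 1990 and 2013 together with the
derived trend arithmetic (percentage changes, shares).  The published
point estimates below are treated as *inputs*: the package's accounting
operations recompute the derived quantities from them, which exercises
the reporting arithmetic against independently typeset values.
"""

from __future__ import annotations

#: National diet-attributable burden, all causes, by metric and year
#: (point estimates; counts in persons or person-years).
ETHIOPIA_ATTRIBUTABLE_COUNTS = {
    ("deaths", 1990): 37_465,
    ("deaths", 2013): 60_402,
    ("dalys", 1990): 953_087,
    ("dalys", 2013): 1_353_407,
    ("ylls", 1990): 915_402,
    ("ylls", 2013): 1_291_703,
    ("ylds", 1990): 37_685,
    ("ylds", 2013): 61_704,
}

#: Crude diet-attributable rates per 100,000 population.
ETHIOPIA_ATTRIBUTABLE_RATES = {
    ("deaths", 1990): 78.0,
    ("deaths", 2013): 64.0,
    ("dalys", 1990): 1989.0,
    ("dalys", 2013): 1439.0,
    ("ylls", 1990): 1910.0,
    ("ylls", 2013): 1373.0,
    ("ylds", 1990): 79.0,
    ("ylds", 2013): 66.0,
}

#: Cardiovascular disease: total deaths in 2013 and the diet-attributable
#: share of them, plus the diet-attributable CVD deaths per age band for
#: 1990 and 2013.
ETHIOPIA_CVD_DEATHS_2013 = 121_211
ETHIOPIA_DIET_CVD_DEATHS = {1990: 32_790, 2013: 53_375}
ETHIOPIA_DIET_CVD_DEATHS_70PLUS = {1990: 12_426, 2013: 26_411}
ETHIOPIA_DIET_CVD_DEATHS_50_69 = {1990: 16_466, 2013: 23_087}

#: Diet-attributable deaths from diabetes/urogenital/blood/endocrine
#: causes and from cancer, total and per age band.
ETHIOPIA_DIET_DUBE_DEATHS = {1990: 1_672, 2013: 2_558}
ETHIOPIA_DIET_DUBE_DEATHS_50_69 = {1990: 874, 2013: 1_271}
ETHIOPIA_DIET_DUBE_DEATHS_70PLUS = {1990: 451, 2013: 870}
ETHIOPIA_DIET_DUBE_DEATHS_15_49 = {1990: 347, 2013: 417}
ETHIOPIA_DIET_CANCER_DEATHS = {1990: 3_004, 2013: 4_470}
ETHIOPIA_DIET_CANCER_DEATHS_50_69 = {1990: 1_651, 2013: 2_232}
ETHIOPIA_DIET_CANCER_DEATHS_70PLUS = {1990: 867, 2013: 1_635}
ETHIOPIA_DIET_CANCER_DEATHS_15_49 = {1990: 486, 2013: 603}
ETHIOPIA_DIET_CVD_DEATHS_15_49 = {1990: 3_898, 2013: 3_878}

#: Fruit-specific age-standardized DALY rates per 100,000.
ETHIOPIA_FRUIT_DALY_RATES = {1990: 2113.0, 2013: 1632.0}

#: Observed data representativeness index range across dietary risks
#: (fraction of countries with any exposure data).
DRI_RANGE = (0.17, 0.94)
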