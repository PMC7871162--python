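"""Published national inputs for the Iranian male tax-scenario projection.

These are the 2018 stratum populations, household smoking prevalences, smoker
counts, and participation-elasticity magnitudes used as default inputs for
the scenario module, together with the published per-quintile elasticity
decomposition and projected quitter counts used for cross-checks.
"""

from __future__ import annotations

from .scenarios import PopulationStratum

__all__ = [
    "IRAN_MALE_STRATA",
    "DEFAULT_PRICE_INCREASES",
    "PUBLISHED_QUITTERS",
    "PUBLISHED_ELASTICITIES",
]

#: Five expenditure-quintile strata of the male population aged 15+ (2018).
#: Smoker counts are the published ones (computed upstream from unrounded
#: prevalences, hence not exactly population × rounded prevalence).
IRAN_MALE_STRATA = (
    PopulationStratum("Q1", 6_312_000, 0.16, 0.07, smokers=1_041_720),
    PopulationStratum("Q2", 6_312_000, 0.20, 0.11, smokers=1_302_300),
    PopulationStratum("Q3", 6_312_000, 0.21, 0.12, smokers=1_344_040),
    PopulationStratum("Q4", 6_312_000, 0.21, 0.12, smokers=1_337_630),
    PopulationStratum("Q5", 6_312_000, 0.19, 0.11, smokers=1_256_450),
)

DEFAULT_PRICE_INCREASES = (0.25, 0.50, 0.75)

#: Published quitter counts per stratum (rows Q1..Q5) under the 25/50/75%
#: scenarios.  Some cells reflect unrounded elasticities held upstream, so
#: they are retained verbatim for validation rather than recomputed.
PUBLISHED_QUITTERS = {
    0.25: (17_709, 35_162, 40_321, 40_129, 33_924),
    0.50: (35_418, 70_324, 80_642, 80_258, 67_848),
    0.75: (53_127, 105_486, 120_963, 120_387, 101_772),
}

#: Published elasticity decomposition per quintile: for each variable the
#: (participation, conditional, total) triple as printed.  Note the Q1 price
#: total is printed as -0.46 although its printed parts sum to -0.45; the
#: printed values are kept verbatim.
PUBLISHED_ELASTICITIES = {
    "price": {
        1: (-0.07, -0.38, -0.46),
        2: (-0.11, -0.35, -0.46),
        3: (-0.12, -0.35, -0.47),
        4: (-0.12, -0.37, -0.49),
        5: (-0.11, -0.32, -0.43),
    },
    "income": {
        1: (0.02, 0.03, 0.05),
        2: (-0.04, 0.00, -0.04),
        3: (-0.03, 0.00, -0.03),
        4: (-0.06, 0.01, -0.05),
        5: (-0.01, 0.02, 0.01),
    },
}
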