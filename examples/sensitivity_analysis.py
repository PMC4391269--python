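"""Sensitivity of leaf area and plant mass to one-at-a-time input changes.

Runs the standard battery — +/-1% photosynthesis and initial leaf area,
+/-1 percentage point of the starch set-aside and of three partition
coefficients (with a compensating coefficient keeping the phase on the
simplex), +/-1 day of vegetative-phase length — and prints percent changes
at the four checkpoint days.
"""

import pandas as pd

import rosettesim as rs
from rosettesim.sensitivity import sensitivity_table

pd.set_option("display.width", 200)

config = rs.fixture_config("col0", simulation=1)
table = sensitivity_table(config)
cols = ["perturbation", "leaf_area_26", "leaf_area_86", "plant_mass_26",
        "plant_mass_86", "sensitive"]
print(table[cols].round(1).to_string(index=False))
print(
    "\nGrowth is far more sensitive to how leaf carbon is split between area\n"
    "growth and thickening than to the photosynthetic rate itself, and is\n"
    "essentially insensitive to the starch set-aside; early-life partitioning\n"
    "shifts compound with age."
)
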