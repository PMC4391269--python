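"""Simulate 90 days of Arabidopsis growth and report the organ trajectory.

Builds the packaged wild-type configuration (published constants and
partition coefficients, synthetic driver curves), runs the hourly
carbon-balance model, and prints end-of-day state at the study's harvest
days.
"""

import rosettesim as rs
from rosettesim.metrics import growth_summary

config = rs.fixture_config("col0", simulation=1)
result = rs.simulate(config)
summary = growth_summary(result).set_index("das")

print("DAS  leaf area (cm2)  leaf (g)  stem (g)  root (g)  plant (g)  SLA (m2/g)")
for das in (26, 44, 66, 86):
    row = result.at(das)
    print(
        f"{das:3d} {row.leaf_area * 1e4:14.1f} {row.leaf_mass:9.3f} "
        f"{row.infl_mass:9.4f} {row.root_mass:9.4f} {row.plant_mass:10.3f} "
        f"{summary.loc[das, 'sla']:10.4f}"
    )
print(f"\ncarbon ledger residual: {result.ledger_residual():.2e}")
print(
    "\nLeaf area and organ masses follow a logistic-shaped rise; specific leaf\n"
    "area (SLA) falls with age as leaves thicken, and the carbon ledger closes\n"
    "to machine precision (every fixed/mobilized umol C is accounted for in\n"
    "biomass, respiration, exudation or starch)."
)
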