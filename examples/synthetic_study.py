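"""Generate a synthetic growth study: harvest means and SDs for calibration.

Simulates a known ground truth and draws n = 10 lognormal replicates per
observable at each harvest day, mimicking the sparse destructive harvests
(mean +/- SD) the model is calibrated against.  Organs that have not emerged
by a harvest day (no inflorescence before flowering) yield no data point.
"""

import rosettesim as rs
from rosettesim.io import write_measurements_csv

config = rs.fixture_config("col0", simulation=1)
study = rs.SyntheticStudy(cv=0.10, n_replicates=10, seed=7)
measurements = rs.generate_measurements(study, config)

for name, series in measurements.items():
    print(name)
    for das, mean, sd, n in series.points:
        print(f"  DAS {das:2d}: {mean:.4g} +/- {sd:.2g}  (n={n})")
write_measurements_csv(measurements, "synthetic_measurements.csv")
print(
    "\nWrote synthetic_measurements.csv in the calibration input format\n"
    "(observable, das, mean, sd, n).  SDs scale with the mean (multiplicative\n"
    "noise), as in real harvest data."
)
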