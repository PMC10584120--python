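"""Reproductive metrics: hatch-count estimation and clutch summaries.

Walks the bookkeeping chain for one female: estimate daily hatch counts
from dry mass (calibrated with counted 50-larva batches) and from
volumetric subsamples, then summarise a simulated set of clutch outcomes
into fecundity and hatching-success percentages.
"""

import numpy as np

from opilio.reproduction import (clutch_summary, estimate_count_by_mass,
                                 estimate_count_by_volume, percent_area_yolk,
                                 pooled_mean_larval_mass)
from opilio.simulate import gen_clutch_outcomes

# calibration: five counted batches of 50 larvae, dried and weighed
mean_mass = pooled_mean_larval_mass([10.2, 9.8, 10.5, 10.1, 9.9], [50] * 5)
print(f"pooled mean larval dry mass: {mean_mass:.4f} mg")
print(f"a 215 mg batch is ~{estimate_count_by_mass(215.0, mean_mass)} larvae")
print(f"subsamples (12, 14, 13) in 10 mL of a 2 L bucket -> "
      f"{estimate_count_by_volume([12, 14, 13], 10.0, 2000.0)} larvae\n")

print(f"percent area yolk for a 0.05/0.20 mm^2 yolk/egg: "
      f"{percent_area_yolk(0.05, 0.20):.0f}%\n")

outcomes = gen_clutch_outcomes(mean_fecundity=120_000, p_nonviable=0.01,
                               p_unhatched=0.02, n_females=5, seed=1)
print("female  fecundity  success%  nonviable%  unhatched%")
for oc in outcomes:
    s = clutch_summary(oc)
    print(f"{oc.female_id:>6} {s['fecundity']:>10.0f} {s['hatching_success']:>9.2f} "
          f"{s['pct_nonviable']:>11.2f} {s['pct_unhatched']:>11.2f}")
print("\nThe three percentages always partition 100% of the estimated clutch.")
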