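"""Group comparisons on per-animal summary metrics.

Simulates a small two-condition cohort (per-animal rest fractions and
distance-binned co-activity), then runs the two statistical layers: a
Mann-Whitney U test on single per-animal values, and a linear mixed-effects
contrast on correlated per-stratum means with animal as the grouping factor
(beta is the condition effect in the units of the metric).
"""

import numpy as np

from spncoact import stats_report

rng = np.random.default_rng(0)
rows = []
for i in range(10):
    condition = "drug" if i % 2 else "vehicle"
    rest = rng.normal(0.62 if condition == "drug" else 0.33, 0.05)
    rows.append({"animal": f"m{i}", "session": "s1", "condition": condition,
                 "metric": "fraction_rest", "stratum": "all", "value": rest})
    animal_offset = rng.normal(0, 0.2)
    for b in range(6):  # 50 µm distance bins
        value = (1.8 if condition == "drug" else 1.2) - 0.1 * b
        rows.append({"animal": f"m{i}", "session": "s1", "condition": condition,
                     "metric": "normalized_coactivity", "stratum": f"bin{b}",
                     "value": value + animal_offset + rng.normal(0, 0.1)})
table = stats_report.make_cohort_table(rows)

mw = stats_report.compare_groups(table, "fraction_rest", ("vehicle", "drug"))
print(f"rest fraction, vehicle vs drug: U={mw['statistic']:.0f}, p={mw['p']:.4f}")

lmm = stats_report.grouped_slope_contrast(
    table, "normalized_coactivity", condition_ref="vehicle"
)
print(f"co-activity contrast (LMM): beta={lmm.beta:.3f}, SE={lmm.se:.3f}, "
      f"z={lmm.z:.2f}, p={lmm.p:.2g}, CI [{lmm.ci_low:.3f}, {lmm.ci_high:.3f}]")
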