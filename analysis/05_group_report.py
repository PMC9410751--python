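#!/usr/bin/env python
"""Group statistics report: genotype contrasts with the gated test harness.

Reads the per-connection table produced by 02_unitary_quantal.py, compares
WT vs FHM1 amplitudes and failure percentages with the normality-gated
two-group tests, and reports fold changes alongside the published
reference ratios computed from the printed group means.
"""

import os
import sys

import pandas as pd

from synquant import stats

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = "results"
path = os.path.join(OUT, "unitary_connections.csv")
if not os.path.exists(path):
    sys.exit("run analysis/02_unitary_quantal.py first")
df = pd.read_csv(path)

rows = []
for col, label in (("mean_amplitude_mV", "mean uEPSP amplitude"),
                   ("failure_percent", "failure percentage")):
    a = df[df.genotype == "WT"][col].to_numpy()
    b = df[df.genotype == "FHM1"][col].to_numpy()
    cmp = stats.compare_groups(a, b, labels=("WT", "FHM1"))
    ratio, pct, direction = stats.summarize_changes(cmp.means[0],
                                                    cmp.means[1])
    rows.append({"quantity": label, "wt_mean": cmp.means[0],
                 "wt_sem": cmp.sems[0], "fhm1_mean": cmp.means[1],
                 "fhm1_sem": cmp.sems[1], "test": cmp.test,
                 "statistic": cmp.statistic, "p": cmp.p, "ratio": ratio,
                 "percent_change": pct, "direction": direction})
    print(f"{label}: WT {cmp.means[0]:.3g} +/- {cmp.sems[0]:.2g} vs FHM1 "
          f"{cmp.means[1]:.3g} +/- {cmp.sems[1]:.2g} "
          f"({cmp.test}, p={cmp.p:.3g}); {pct:.0f}% {direction}")
pd.DataFrame(rows).to_csv(os.path.join(OUT, "group_report.csv"), index=False)

# reference ratios from the printed group means
for a, b, what in ((0.14, 0.30, "amplitude"), (85.0, 70.0, "failures")):
    r, p, d = stats.summarize_changes(a, b)
    print(f"printed means, {what}: ratio {r:.1f}, {p:.0f}% {d}")
print(f"wrote {OUT}/group_report.csv")
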