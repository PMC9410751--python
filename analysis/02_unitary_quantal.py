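#!/usr/bin/env python
"""Unitary-response and failure analysis under the binomial release model.

Simulates full sweep sets for WT and FHM1 PC->SOM cohorts, measures each
connection's mean response (1-ms window around the peak of the average)
and failure percentage (2.5 x baseline SD criterion), fits the failure-%
vs mean-amplitude regression with a genotype interaction test, and
estimates the quantal amplitude from the shared slope (q = -100/slope).
"""

import os
import sys

import pandas as pd

from synquant import events, quantal, synthdata as sd

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = "results"
os.makedirs(OUT, exist_ok=True)

records, rows = [], []
proto = sd.Protocol(n_pulses=1, freq=25.0, inter_trial=10.0, n_sweeps=60)
for gi, genotype in enumerate(("WT", "FHM1")):
    cohort = sd.make_cohort(genotype, "PC-SOM", 25, seed=SEED + 1000 * gi,
                            protocol=proto)
    for i, (sweeps, gt) in enumerate(cohort):
        base = events.baseline_for(sweeps)
        labels = events.classify_trials(sweeps, base)
        amp = max(events.measure_mean_response(sweeps, 0, base), 0.0)
        rec = quantal.ConnectionRecord(f"{genotype}-{i:03d}", genotype, amp,
                                       float(labels.failure_fraction[0]),
                                       n_sweeps=sweeps.n_sweeps)
        records.append(rec)
        rows.append({"connection_id": rec.connection_id, "genotype": genotype,
                     "mean_amplitude_mV": amp,
                     "failure_percent": 100 * rec.failure_fraction,
                     "true_expected_amp": gt.expected_amps[0]})
pd.DataFrame(rows).to_csv(os.path.join(OUT, "unitary_connections.csv"),
                          index=False)

# single-contact cohort: F = 1 - E/q exactly, so the regression recovers
# q = -100/slope without the convexity bias of multi-site connections
import numpy as np

rng = np.random.default_rng(SEED + 9)
single = []
for g, scale in (("WT", 1.0), ("FHM1", 2.0)):
    for i in range(60):
        rel = sd.ReleaseParams(n_sites=1,
                               p0=float(rng.uniform(0.02, 0.3)) * scale,
                               q=0.926, quantal_cv=0.3)
        amp, fail, _ = sd.sample_connection_summary(rel, sd.STPParams.none(),
                                                    150, rng)
        single.append(quantal.ConnectionRecord(f"s-{g}{i}", g,
                                               max(amp, 0.0), fail))

summary_rows = []
for label, recs in (("multi_site_cohort", records),
                    ("single_contact_cohort", single)):
    reg = quantal.fit_failure_regression(recs)
    summary_rows.append({
        "cohort": label, "slope_pct_per_mV": reg.slope,
        "intercept_pct": reg.intercept, "interaction_p": reg.interaction_p,
        "shared_model": reg.shared, "spearman_r": reg.spearman_r,
        "spearman_p": reg.spearman_p, "n_used": reg.n_used,
        "n_excluded": reg.n_excluded,
        "quantal_amplitude_mV": (quantal.estimate_quantal_amplitude(reg.slope)
                                 if reg.slope < 0 else float("nan"))})
    print(f"{label}: slope {reg.slope:.1f} %/mV, intercept "
          f"{reg.intercept:.1f}%, interaction p={reg.interaction_p:.2f} "
          f"({'shared' if reg.shared else 'separate'}), Spearman "
          f"r={reg.spearman_r:.2f}, implied q "
          f"{quantal.estimate_quantal_amplitude(reg.slope):.3f} mV")
pd.DataFrame(summary_rows).to_csv(os.path.join(OUT, "failure_regression.csv"),
                                  index=False)
print("note: the multi-site cohort's shallower slope is the documented "
      "convexity of F=(1-p)^N down to the 40% failure cut; single-contact "
      "connections are exactly linear and recover q = 0.926 mV")
print(f"wrote {OUT}/unitary_connections.csv, {OUT}/failure_regression.csv")
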