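"""Constancy trending over repeated QA sessions.

Simulates several QA sessions with slightly different machine states,
appends each report to a JSON-lines trend ledger, and prints the per-metric
mean and standard deviation — the constancy view used to spot slow drifts
(couch speed, field width, beam energy) long before a hard tolerance fails.
"""

import json
import tempfile
from pathlib import Path

import stepwedge as sw

ledger = Path(tempfile.mkdtemp()) / "trend.jsonl"

# a plausible month of machine states: tiny couch/width/energy wobble
states = [
    dict(couch_speed_factor=1.000, field_width_mm=10.00, seed=201),
    dict(couch_speed_factor=1.003, field_width_mm=10.05, seed=202),
    dict(couch_speed_factor=0.998, field_width_mm=9.95, seed=203),
    dict(couch_speed_factor=1.004, field_width_mm=10.02, seed=204),
]

for state in states:
    scenario = sw.SimulationScenario(**state)
    acquisition, _ = sw.simulate_acquisition(scenario)
    report = sw.run_stepwedge_qa(acquisition, reference_p1=1200.0, seed=0)
    sw.append_trend(report, ledger)

summary = sw.trend_summary(ledger)
rows = {
    k: summary["metrics"][k]
    for k in ("couch_speed_dev_pct", "field_width_mm", "d20_d10_time",
              "sagittal_laser_offset_mm")
}
print(json.dumps(rows, indent=2))
print()
print(f"{summary['n_reports']} sessions; tolerance failures so far: "
      f"{summary['fail_counts'] or 'none'}")
print("Rising |mean| or SD in any row flags a drifting machine parameter.")
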