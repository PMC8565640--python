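"""Run one modified-Delphi round on a synthetic 15-expert panel.

Six candidate factors get consensus locations on the two scored dimensions
(importance, measurement capability).  The round classifies each factor by
its median bands — selected (>7 on both), eliminated (<4 on either), or
advanced to another round — and reports panel agreement (the fraction of
experts scoring in the median's Likert band); the round terminates the
Delphi once every surviving factor reaches 80% agreement.
"""

import numpy as np

from caaprio.delphi import run_round
from caaprio.fixtures import delphi_panel_scores

locations = {
    "pain_severity":    {"importance": 8.6, "measurement_capability": 8.2},
    "stress_test":      {"importance": 8.2, "measurement_capability": 8.4},
    "age":              {"importance": 5.5, "measurement_capability": 8.8},
    "ability_to_pay":   {"importance": 2.2, "measurement_capability": 6.0},
    "waiting_time":     {"importance": 7.9, "measurement_capability": 8.5},
    "distance_to_site": {"importance": 3.0, "measurement_capability": 7.5},
}

tables = delphi_panel_scores(locations, n_experts=15, spread=0.9,
                             rng=np.random.default_rng(11))
result = run_round(tables, round_number=1)

print(f"{'factor':<18s} {'med(imp)':>8s} {'med(meas)':>9s} {'agree':>6s}  decision")
for d in result.decisions:
    print(f"{d.factor_id:<18s} {d.medians['importance']:>8.1f} "
          f"{d.medians['measurement_capability']:>9.1f} {d.agreement:>6.2f}  {d.decision}")
c = result.counts()
print(f"\n{c['selected']} selected, {c['advance']} advance, {c['eliminated']} eliminated; "
      f"terminated = {result.terminated}")
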