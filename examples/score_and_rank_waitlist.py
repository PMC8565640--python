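"""Score a synthetic referral roster and print the priority waiting list.

Each patient's seven physician-assigned factor scores (0-10) are multiplied
by the consensus weights and scaled to 100 points; totals map to priority
tiers with maximum-wait targets (>=80 points: 4 weeks; >=50: 8 weeks;
otherwise 16 weeks).  The list is ordered by total points, breaking ties by
waiting-time score, referral date, then id.
"""

import numpy as np

from caaprio import default_framework, rank_waitlist
from caaprio.fixtures import synthetic_roster

cfg = default_framework()
roster = synthetic_roster(n_patients=8, config=cfg, rng=np.random.default_rng(3))

ranked = rank_waitlist(roster, cfg)
print(f"{'rank':>4s} {'patient':<8s} {'referred':<12s} {'total':>6s} {'tier':>4s} {'see within':>10s}")
for pos, sp in zip(ranked.positions, ranked):
    print(f"{pos:>4d} {sp.patient_id:<8s} {sp.referral_date.isoformat():<12s} "
          f"{sp.total_points:>6.1f} {sp.tier:>4d} {sp.max_wait_weeks:>7d} wk")
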