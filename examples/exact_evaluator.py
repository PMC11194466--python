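"""Deterministic cohort evaluator vs Monte-Carlo microsimulation.

The package carries two engines for the same cycle model: a per-patient
microsimulation and an exact forward propagation of the occupancy
distribution over the expanded state space.  The evaluator gives the exact
expectation, so the microsimulation mean must land within Monte-Carlo error
of it — a strong internal consistency check, and the fast inner loop for the
probabilistic sensitivity analysis.
"""

from crcprev import (cohort_evaluate, default_parameters, make_life_table,
                     run_cohort, standard_strategies)

params = default_parameters()
life = make_life_table()

print(f"{'strategy':30s} {'exact cost':>10s} {'micro cost':>10s} "
      f"{'exact QALY':>10s} {'micro QALY':>10s}")
for strat in standard_strategies():
    cost, qaly = cohort_evaluate(strat, params, life)
    res = run_cohort(strat, params, life, n=50_000, seed=3)
    print(f"{strat.name:30s} {cost:10.0f} {res.mean_cost:10.0f} "
          f"{qaly:10.3f} {res.mean_qaly:10.3f}")
print("\nExact columns are the evaluator's closed expectations; micro "
      "columns are 50,000-patient Monte-Carlo means (they agree within "
      "sampling error, a few 2022-USD tens and ~0.01 QALY here).")
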