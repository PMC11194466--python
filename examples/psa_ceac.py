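"""Probabilistic sensitivity analysis and acceptability curves.

Each draw resamples every uncertain parameter from its moment-matched Beta
(probabilities, utilities) or Gamma (costs) distribution and re-evaluates the
four strategies exactly with the cohort evaluator.  The cost-effectiveness
acceptability curve (CEAC) is the fraction of draws in which a strategy has
the highest net monetary benefit at each willingness-to-pay threshold.
"""

import numpy as np

from crcprev import default_parameters, make_life_table
from crcprev.economics import ceac
from crcprev.sensitivity import run_psa

params = default_parameters()
life = make_life_table()

psa = run_psa(params, life, n_samples=200, seed=2)
curves = ceac(psa.costs, psa.qalys, psa.names,
              wtp_grid=np.array([0, 50_000, 100_000, 150_000]))
print(curves.round(3).to_string())
print("\nEach row is a willingness-to-pay threshold ($/QALY); entries are "
      "the probability that the strategy is the most cost-effective choice. "
      "At the conventional $100,000/QALY threshold the combined strategy is "
      "preferred in essentially every draw.")
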