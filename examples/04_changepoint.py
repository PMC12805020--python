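"""Locate a proficiency transition with the Pettitt change-point test.

A metric series with an abrupt 25% drop after case 300 is generated and
the test is asked to find the transition.
"""

import numpy as np

from surgmotion import generate_metric_series, pettitt_test

schedule = np.arange(6, 761, 8)
cases, y = generate_metric_series(
    trend=0.0, base=4000.0, schedule=schedule,
    tau=300, shift=-0.25, sigma=0.1, rng=11,
)

res = pettitt_test(y, case_numbers=cases)
print(f"true shift after case 300; detected change-point: case {res.tau_case}")
print(f"  (last pre-change observation, position {res.tau_index} of {res.n})")
print(f"K = {res.K}, approximate p = {res.p:.2e}")
print("K is rank-based: rescaling or log-transforming the metric cannot change it")
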