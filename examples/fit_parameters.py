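"""Biomarker-range parameter optimization (short demonstration run).

Evaluates the weighted SD-band cost at the pre-optimization seeds, then runs
a few Nelder-Mead iterations of the bounded (+/-20%) descent.  A full run
(~130 evaluations) reaches cost zero; this demo caps the budget so it
finishes in about a minute.
"""

import hipsccm as hp
from hipsccm.optimize import (BiomarkerObjective, OptimizationSpec,
                              load_ranges, optimize)

baseline = hp.load_parameters("paci2013-baseline")
ranges = load_ranges()

obj = BiomarkerObjective(baseline, ranges,
                         OptimizationSpec(pre_run=150.0))
start = obj.evaluate(obj.start_vector())
print(f"cost at the pre-optimization seeds: {start.total:.3f}")
print("  out-of-band biomarkers:",
      {k: round(v, 2) for k, v in start.contributions.items() if v > 0})

spec = OptimizationSpec(pre_run=150.0, max_iter=8)
res = optimize(baseline, ranges, spec)
print(f"after {res.n_evaluations} evaluations: cost {res.cost:.3f}")
print("  parameter multipliers so far:",
      {k: round(v, 3) for k, v in res.multipliers.items()})
print()
print("Each unit of cost is one weighted SD of deviation outside an")
print("experimental band; the bounded simplex walks the 12 Ca2+-handling")
print("parameters until every biomarker re-enters its band (cost 0).")
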