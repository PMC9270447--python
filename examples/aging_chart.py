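"""Run a temporal-degradation suite on two scenarios and compare aging.

Builds a stationary process (no drift) and a coefficient-drift process,
simulates 300 randomized deployments of a ridge model on each, and prints
the median relative error E_rel = MSE(t0+dT)/MSE(t0) for young vs old
models.  E_rel ~ 1 means the model still matches its environment; the drift
scenario shows the error ratio growing with model age.
"""

import numpy as np

from agebench import ScenarioConfig, build_plan, generate_scenario, moving_percentiles, run_suite

for kind in ("stationary", "coefficient_drift"):
    ds = generate_scenario(ScenarioConfig(kind=kind, seed=1))
    plan = build_plan(ds, n_experiments=300, seed=1)
    result = run_suite(ds, plan, "RV")
    curve = moving_percentiles(result)
    young = np.abs(result.dT) <= 30
    old = result.dT >= 600
    print(f"{kind}:")
    print(f"  median E_rel at dT <= 30 d : {np.median(result.e_rel[young]):.3f}")
    print(f"  median E_rel at dT >= 600 d: {np.median(result.e_rel[old]):.3f}")
    print(f"  worst-case (75th pct) at the oldest reported age: {curve.p75[-1]:.3f}")
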