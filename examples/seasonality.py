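"""Detect a hidden annual cycle in model error.

The target is driven by an unobserved 365-day sinusoid.  A model trained on a
short (90-day) history locks onto the current season, so its error becomes
periodic in model age dT.  The dominant period of the median aging curve is
recovered by Lomb-Scargle spectral analysis with a permutation test.
"""

from agebench import (
    ScenarioConfig,
    build_plan,
    detect_periodicity,
    generate_scenario,
    moving_percentiles,
    run_suite,
)

ds = generate_scenario(ScenarioConfig(kind="seasonal_latent", seed=1))
plan = build_plan(ds, n_experiments=800, train_span_days=90, seed=1)
result = run_suite(ds, plan, "RV")
curve = moving_percentiles(result)
report = detect_periodicity(curve, period_range=(30, 500), seed=1)

print(f"dominant period: {report.dominant_period_days:.1f} days (true: 365)")
print(f"permutation significance p = {report.significance_p:.4f}")
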