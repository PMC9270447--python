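"""Find error attractors — dense basins of probable (dT, E_rel) outcomes.

On a regime-switch process, deployments that stay inside one regime keep
E_rel ~ 1 while deployments that cross the switch jump to a high error
plateau: the error cloud condenses into separated basins instead of
spreading smoothly.
"""

from agebench import ScenarioConfig, build_plan, find_error_attractors, generate_scenario, run_suite

ds = generate_scenario(ScenarioConfig(kind="regime_switch", seed=1))
plan = build_plan(ds, n_experiments=800, seed=1)
result = run_suite(ds, plan, "RV")
report = find_error_attractors(result)

print(f"{len(report.modes)} dense basins (bandwidths: {report.bandwidths[0]:.1f} d, "
      f"{report.bandwidths[1]:.2f} log-units)")
for m in report.modes:
    print(f"  basin at dT ~ {m['dT_center']:.0f} d, E_rel ~ {m['e_rel_center']:.2f} "
          f"(mass {m['mass_fraction']:.0%})")
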