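"""Track a non-stationary component across intensities with the
graph-theoretic shortest-path method.

The programmed component shifts 0.4 ms earlier per intensity step
(3.6 ms across the 10-step range); the rank-1 Dijkstra path through the
intensity-time firing-rate grid recovers that drift as its
non-stationarity.
"""

from psthcomp import (SyntheticUnitSpec, build_psth, component_paths,
                      generate_unit, validate_component, pooled_mean_rates)

spec = SyntheticUnitSpec(
    unit_id="drift", layer="IV", condition="sham", stimulus="contact",
    n_components=1, component_times=[20.0], peak_rates=[150.0],
    rate_slopes=[3.0], latency_shifts=[0.4],
    baseline_rate=5.0, n_intensities=10, n_trials=20, seed=3,
)
raster, _ = generate_unit(spec)
psth = build_psth(raster)

for path in component_paths(psth, k=3):
    print(f"path {path.rank}: total weight {path.total_weight:.1f}, "
          f"median time bin {path.median_time_bin}, "
          f"non-stationarity {path.nonstationarity_ms:.0f} ms")
    if path.rank == 1:
        print("  per-intensity times:",
              [t for _, t, _ in path.per_row])

print(f"programmed non-stationarity: {spec.true_nonstationarity(0):.1f} ms")

# validate the component the primary path points at
p1 = component_paths(psth, k=1)[0]
v = validate_component(pooled_mean_rates(psth), p1.median_time_bin)
print(f"validation at bin {p1.median_time_bin}: "
      f"peakiness {v.peakiness:.2f}, one-tailed p {v.p_value:.2g}")
# peakiness > 1.25 means the component fires >25% above the quietest bin
# within +/-5 ms; a small p confirms it beats its flanks.
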