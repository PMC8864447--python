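"""Detect response components in a single synthetic unit.

Builds a unit with two programmed firing-rate components (12 ms and
24 ms after stimulus onset, the first shifting 0.3 ms earlier per
intensity step), bins its spikes into a PSTH, and runs the extended
local-maxima analysis.
"""

import numpy as np

from psthcomp import SyntheticUnitSpec, build_psth, generate_unit, unit_components

spec = SyntheticUnitSpec(
    unit_id="demo", layer="IV", condition="sham", stimulus="contact",
    n_components=2,
    component_times=[12.0, 24.0],   # ms after stimulus onset, at intensity 1
    peak_rates=[120.0, 90.0],       # Hz
    rate_slopes=[3.0, 2.0],         # Hz gained per intensity step
    latency_shifts=[0.3, 0.0],      # ms earlier per intensity step
    baseline_rate=5.0, n_intensities=10, n_trials=20, seed=7,
)
raster, ground_truth = generate_unit(spec)
psth = build_psth(raster)

components = unit_components(psth, min_support=9)
print(f"unit {psth.unit_id}: {raster.n_spikes} spikes, "
      f"PSTH {psth.n_intensities} intensities x {psth.n_bins} bins")
print(f"category: {components.category} "
      f"({components.n_components} components)")
for t, support in zip(components.component_times, components.supports):
    print(f"  component at bin {t} (~{t - 0.5:.1f} ms), "
          f"seen at {len(support)}/10 intensities")
print("programmed times at intensity 1:", spec.component_times)
# The detected bins should bracket the programmed 12 ms and 24 ms centres;
# the first component sits slightly earlier than 12 ms because it shifts
# earlier at higher intensities and the unit-level time pools all of them.
print("per-intensity maxima:",
      {z: b for z, b in components.per_intensity_maxima.items()})
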