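"""Print the two whisker-deflection stimulus waveforms.

The Basic stimulus is a trapezoid: a linear on-ramp at one of five
velocities to 3.6 mm, a 20-ms hold, and a 40-ms off-ramp.  The Contact
stimulus is a 100-ms naturalistic deflection (a synthetic proxy here):
an initial peak near 10 ms, a secondary bump near 25 ms and a dip near
40 ms, scaled to a peak amplitude.
"""

import numpy as np

from psthcomp import basic_waveform, contact_waveform
from psthcomp.synthetic import BASIC_VELOCITIES

for v in BASIC_VELOCITIES:
    w = basic_waveform(v)
    ramp_ms = 3.6 / v * 1000
    print(f"basic @ {v:5.0f} mm/s: on-ramp {ramp_ms:6.1f} ms, "
          f"total {w.times_ms[-1]:6.1f} ms, peak {w.amplitudes_mm.max():.1f} mm")

w = contact_waveform(2.0)
t_peak = w.times_ms[np.argmax(w.amplitudes_mm)]
print(f"\ncontact @ 2.0 mm: duration {w.times_ms[-1]:.0f} ms, "
      f"initial deflection peaks at {t_peak:.1f} ms")
sub = w.amplitudes_mm[(w.times_ms >= 35) & (w.times_ms <= 45)]
print(f"dip near 40 ms: {sub.min():.2f} mm "
      f"(vs {w.amplitudes_mm.max():.1f} mm peak)")
# Only the Basic geometry enters any analysis interpretation (component
# times can be read against ramp durations); the Contact proxy is
# illustrative.
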