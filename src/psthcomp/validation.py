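"""Statistical validation of detected components: peakiness and t-test.

Each component is scored on an 11-bin segment of the unit's pooled
(intensity-averaged) mean firing rates, centred on the component bin
(the nominal 6th element): the five 1-ms bins before, the component bin,
and the five bins after.  Two scores are computed per component:

* peakiness — (g_i + 1) / (g_k + 1) with g_i the component bin's rate
  and g_k the minimum rate within the segment; 1 means the component
  fires no more than the quietest surrounding bin, 1.25 means >25% above
  it, and so on.
* a one-tailed two-sample t-test comparing the "component segment"
  (nominal segment positions 5-7) against the remaining 8 bins, with
  alternative "component mean is greater".

Segments are truncated, not zero-padded, at the window edges (padding
would bias g_k toward 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Half-width of the validation segment in bins (5 before + centre + 5 after).
SEGMENT_HALF_WIDTH = 5


@dataclass
class PeakinessSegment:
    """Up to 11 pooled mean firing rates around one component bin."""

    rates: np.ndarray          # available bins, in time order
    center_index: int          # 0-based position of the component bin in rates
    left_truncated: int        # bins lost off the left window edge
    right_truncated: int       # bins lost off the right window edge
    component_bin: int         # 1-based bin in the full profile

    @property
    def g_i(self) -> float:
        """Mean firing rate at the component bin."""
        return float(self.rates[self.center_index])

    @property
    def g_k(self) -> float:
        """Minimum mean firing rate within the segment."""
        return float(np.min(self.rates))


@dataclass
class ComponentValidation:
    peakiness: float
    t_statistic: float
    p_value: float
    computable: bool
    note: str = ""


def extract_segment(pooled_rates, component_bin: int) -> PeakinessSegment:
    """Cut the 11-bin validation segment around ``component_bin`` (1-based).

    Bins [component_bin - 5, component_bin + 5] intersected with the
    profile; the number of bins lost to each window edge is recorded so
    the t-test groups can be clipped consistently.
    """
    r = np.asarray(pooled_rates, dtype=float)
    n = len(r)
    if not 1 <= component_bin <= n:
        raise ValueError(f"component bin {component_bin} outside 1..{n}")
    lo = component_bin - SEGMENT_HALF_WIDTH  # 1-based, may underflow
    hi = component_bin + SEGMENT_HALF_WIDTH
    left_trunc = max(0, 1 - lo)
    right_trunc = max(0, hi - n)
    seg = r[max(lo, 1) - 1: min(hi, n)]
    return PeakinessSegment(
        rates=seg,
        center_index=SEGMENT_HALF_WIDTH - left_trunc,
        left_truncated=left_trunc,
        right_truncated=right_trunc,
        component_bin=component_bin,
    )


def peakiness(seg: PeakinessSegment, variant: str = "literal") -> float:
    """Peakiness score of a component segment.

    ``literal`` (default): (g_i + 1) / (g_k + 1), the printed formula —
    1 at equality, 1.25 when the component rate sits 25% above the
    surrounding minimum (in the large-rate limit), unbounded above.
    ``normalized``: (g_i + 1) / ((g_i + g_k)/2 + 1), an alternative
    bounded reading on a 0-2 scale (1 at equality, approaching 2 as
    g_i/g_k grows); provided behind this flag, never silently used.
    """
    gi, gk = seg.g_i, seg.g_k
    if variant == "literal":
        return (gi + 1.0) / (gk + 1.0)
    if variant == "normalized":
        return (gi + 1.0) / ((gi + gk) / 2.0 + 1.0)
    raise ValueError(f"unknown peakiness variant {variant!r}")


def component_ttest(seg: PeakinessSegment, equal_var: bool = True) -> ComponentValidation:
    """One-tailed two-sample t-test of the component segment vs its flanks.

    The component group is the 3 bins at nominal segment positions 5-7
    (the component bin and its immediate neighbours), clipped by edge
    truncation; the comparison group is all remaining segment bins.
    Pooled-variance t by default (Welch with ``equal_var=False``),
    alternative: component mean > comparison mean.  Returns a record with
    ``computable=False`` when heavy truncation leaves a group with fewer
    than 2 members.  The degenerate all-constant segment yields t=0,
    p=0.5 (flagged ``zero_variance``).
    """
    c = seg.center_index
    comp_idx = [i for i in (c - 1, c, c + 1) if 0 <= i < len(seg.rates)]
    rest_idx = [i for i in range(len(seg.rates)) if i not in comp_idx]
    comp = seg.rates[comp_idx]
    rest = seg.rates[rest_idx]
    if len(comp) < 2 or len(rest) < 2:
        return ComponentValidation(peakiness=math.nan, t_statistic=math.nan,
                                   p_value=math.nan, computable=False,
                                   note="group_too_small")
    if np.ptp(comp) == 0 and np.ptp(rest) == 0:
        if comp[0] == rest[0]:
            return ComponentValidation(math.nan, 0.0, 0.5, True,
                                       note="zero_variance")
        t = math.inf if comp[0] > rest[0] else -math.inf
        return ComponentValidation(math.nan, t, 0.0 if t > 0 else 1.0, True,
                                   note="zero_variance")
    res = stats.ttest_ind(comp, rest, equal_var=equal_var, alternative="greater")
    return ComponentValidation(peakiness=math.nan, t_statistic=float(res.statistic),
                               p_value=float(res.pvalue), computable=True)


def validate_component(pooled_rates, component_bin: int,
                       variant: str = "literal",
                       equal_var: bool = True) -> ComponentValidation:
    """Peakiness + t-test for one component of a unit's pooled profile."""
    seg = extract_segment(pooled_rates, component_bin)
    v = component_ttest(seg, equal_var=equal_var)
    v.peakiness = peakiness(seg, variant=variant)
    return v
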