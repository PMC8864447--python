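"""Independent neural response components analysis (extended local maxima).

A response component is a brief period of elevated firing, separated by
silence from other such periods, within the 50-ms post-stimulus window.
Components are found per intensity by (1) locating local maxima of the
PSTH row, (2) discarding weak isolated maxima (< 25% of the max firing
rate with spike-free neighbouring bins), and (3) iteratively combining
maxima within 5 ms of each other into their median bin, nearest pair
first.  The same combination rule then pools the per-intensity maxima
across all intensities into unit-level component times, from which the
unit is categorised as having 0, 1, 2 or 3+ components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psth import PSTHMatrix, pooled_mean_rates

#: Maxima closer together than this (ms, inclusive) are combined.
MERGE_GAP_MS = 5.0


@dataclass
class ComponentSet:
    """Detected components for one unit."""

    unit_id: str
    per_intensity_maxima: dict[int, list[int]]  # intensity -> time bins
    component_times: list[int]  # unit-level component time bins (1-based, ms)
    supports: list[set[int]] = field(default_factory=list)  # intensities per component
    layer: str = ""
    condition: str = ""
    stimulus: str = ""

    @property
    def n_components(self) -> int:
        return len(self.component_times)

    @property
    def category(self) -> str:
        return classify_count(self.n_components)


def classify_count(n_components: int) -> str:
    """Map a component count to the reported category: 0, 1, 2 or 3plus."""
    if n_components < 0:
        raise ValueError("component count must be >= 0")
    return str(n_components) if n_components < 3 else "3plus"


def local_maxima(rates) -> list[int]:
    """Bins (1-based) that are strict local maxima of a PSTH row.

    A plateau of equal values strictly above both flanking bins counts as
    one maximum at the plateau's median bin (lower median for even plateau
    lengths).  Endpoint bins are never maxima: a local maximum needs two
    neighbours, and the isolation filter references both of them.
    """
    r = np.asarray(rates, dtype=float)
    n = len(r)
    out: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and r[j + 1] == r[i]:
            j += 1
        # run of equal values spans bins i..j (0-based)
        interior = i > 0 and j < n - 1
        if interior and r[i] > r[i - 1] and r[j] > r[j + 1]:
            out.append((i + j) // 2 + 1)  # lower-median bin, 1-based
        i = j + 1
    return out


def filter_maxima(bins, rates) -> list[int]:
    """Discard weak isolated maxima.

    A maximum at bin ``b`` is removed iff its rate is strictly below 25%
    of the row's max firing rate AND both neighbouring 1-ms bins carry no
    spikes (zero rate) — the conjunction as stated, so a strong isolated
    bin or a weak bin with active neighbours both survive.
    """
    r = np.asarray(rates, dtype=float)
    if not len(r):
        return []
    threshold = 0.25 * r.max()
    kept = []
    for b in bins:
        i = b - 1
        weak = r[i] < threshold
        isolated = (i - 1 < 0 or r[i - 1] == 0) and (i + 1 >= len(r) or r[i + 1] == 0)
        if not (weak and isolated):
            kept.append(b)
    return kept


def _merge_items(items, merge_gap):
    """Iterative nearest-pair combination of (time, payload-set) items.

    Repeatedly find the closest pair of times; if their separation is
    <= merge_gap, replace the pair by its lower-median time (floor of the
    mean for two items) carrying the union of the payload sets.  Distance
    ties break toward the earliest (left-most) pair.  Runs until all
    pairwise separations exceed merge_gap.
    """
    items = sorted(items, key=lambda it: it[0])
    while len(items) > 1:
        times = [t for t, _ in items]
        diffs = [times[i + 1] - times[i] for i in range(len(times) - 1)]
        i = int(np.argmin(diffs))  # first occurrence = earliest pair on ties
        if diffs[i] > merge_gap:
            break
        (t1, s1), (t2, s2) = items[i], items[i + 1]
        items[i:i + 2] = [(int((t1 + t2) // 2), s1 | s2)]
        items.sort(key=lambda it: it[0])
    return items


def merge_maxima(bins, merge_gap: float = MERGE_GAP_MS) -> list[int]:
    """Combine maxima occurring within ``merge_gap`` ms of each other.

    Iterative, nearest pair first; each combination replaces the two bins
    by their median 1-ms bin (lower median, keeping times on the 1-ms
    lattice).  Idempotent: the result has all pairwise separations
    strictly greater than ``merge_gap``.
    """
    items = [(int(b), set()) for b in bins]
    return [t for t, _ in _merge_items(items, merge_gap)]


def unit_components(psth: PSTHMatrix, merge_gap: float = MERGE_GAP_MS,
                    min_support: int = 1,
                    max_scope: str = "row") -> ComponentSet:
    """Detect unit-level response components across all intensities.

    Per intensity: ``merge_maxima(filter_maxima(local_maxima(row)))``.
    The per-intensity maxima are then pooled into one multiset and the
    same iterative combination applied; each resulting time keeps the set
    of intensities that contributed maxima to it, and times supported by
    fewer than ``min_support`` distinct intensities are dropped.

    ``max_scope`` selects the reference for the 25%-of-max filter:
    ``"row"`` (each intensity's own max, default) or ``"unit"`` (max over
    the whole matrix).
    """
    if max_scope not in ("row", "unit"):
        raise ValueError("max_scope must be 'row' or 'unit'")
    per_intensity: dict[int, list[int]] = {}
    pooled: list[tuple[int, set[int]]] = []
    unit_max = psth.rates.max()
    for z in range(1, psth.n_intensities + 1):
        row = psth.rates[z - 1]
        bins = local_maxima(row)
        if max_scope == "row":
            bins = filter_maxima(bins, row)
        else:
            bins = _filter_against(bins, row, 0.25 * unit_max)
        bins = merge_maxima(bins, merge_gap)
        per_intensity[z] = bins
        pooled.extend((b, {z}) for b in bins)
    merged = _merge_items(pooled, merge_gap)
    merged = [(t, s) for t, s in merged if len(s) >= min_support]
    return ComponentSet(
        unit_id=psth.unit_id, per_intensity_maxima=per_intensity,
        component_times=[t for t, _ in merged],
        supports=[s for _, s in merged],
        layer=psth.layer, condition=psth.condition, stimulus=psth.stimulus,
    )


def _filter_against(bins, row, threshold) -> list[int]:
    """25% filter with an externally supplied rate threshold (unit-wide max)."""
    r = np.asarray(row, dtype=float)
    kept = []
    for b in bins:
        i = b - 1
        weak = r[i] < threshold
        isolated = (i - 1 < 0 or r[i - 1] == 0) and (i + 1 >= len(r) or r[i + 1] == 0)
        if not (weak and isolated):
            kept.append(b)
    return kept
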