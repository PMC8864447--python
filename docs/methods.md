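# Methods

## Data model

The analysis unit is one online-sorted cortical unit recorded in layer
II or IV of rat barrel cortex while its principal whisker is deflected
at `Z` stimulus intensities (5 on-ramp velocities for the trapezoid
"Basic" stimulus, 10 peak amplitudes for the naturalistic "Contact"
stimulus), with `N` trials per intensity.  Spikes are counted in 1-ms
bins over the first 50 ms post-stimulus; bin `b` (1-based) covers the
half-open interval `[b−1, b)` ms, so a 50-ms window yields exactly 50
bins and no spike is double-counted; spikes at or past the window edge
are dropped.  Rates are stored in Hz (`count / (N · 0.001 s)`), which
keeps the integer counts exactly recoverable; every relative threshold
downstream (the 25%-of-max rule, the edge-weight ratio) is
scale-invariant, so the unit choice is presentational.

## Component detection

Per intensity row: a bin is a local maximum iff it is strictly greater
than both neighbours; a plateau of equal values strictly above both
flanks contributes one maximum at its median bin (lower median for even
lengths).  Endpoint bins are never maxima — a maximum needs two
neighbours, and the isolation test references both.  A maximum is
discarded iff it is **both** below 25% of the max firing rate **and**
flanked by two zero-rate bins (the conjunction as stated; either
strength or a non-silent neighbourhood saves a maximum).  Surviving
maxima within 5 ms of each other (inclusive) are combined iteratively:
always the currently nearest pair (ties broken toward the earliest
pair), replaced by the pair's lower-median bin, until all separations
exceed 5 ms.  The lower median keeps every time on the 1-ms lattice.

Unit-level components then come from pooling all per-intensity maxima
into one multiset and applying the identical combination rule; each
resulting time retains the set of intensities that contributed maxima
to it (its *support*).  `min_support` drops components seen in fewer
than that many distinct intensities; the per-component category is
`0 / 1 / 2 / 3plus` from the count of surviving times.

Two deliberately exposed ambiguities:

* **Filter scope** (`max_scope`): whether "max firing rate" is the
  intensity row's own max (default) or the unit-wide max.
* **`min_support`** (default 1, the literal reading: any single
  intensity's maximum can seed a unit component).

### Calibration of `min_support` for recovery studies

At the synthetic reference conditions (baseline 5 Hz, 20 trials, 10
intensities) a single stray spike produces a 50 Hz bin, and non-responding
units rarely reach the >200 Hz row maximum that would let the 25% rule
remove it; isolated noise maxima therefore survive per row (~3 per row)
and, once pooled, chain-merge into clusters supported by 4–8
intensities.  Scanning both exposed parameters on simulated populations
with known ground truth shows per-unit category accuracy is maximised
(~86%) at `min_support = 9` with row-scope filtering — i.e. a unit
component must be corroborated by essentially every intensity, matching
the observation that genuine components appear "across most amplitudes".
The recovery tests and examples use that setting; the pipeline default
remains the literal `min_support = 1`.  This also documents an honest
limit of the method: at a 5-Hz spontaneous rate the per-bin evidence for
a one-spike noise bin and a genuine sharp component is identical, so
roughly 1 in 7 units is mis-categorised regardless of thresholds, most
of them silent units credited with a spurious component.

## Component validation

For each unit-level component bin `i` of the intensity-averaged
profile, an 11-bin segment (5 before, the bin, 5 after) is cut,
truncated — not zero-padded — at the window edges (padding would bias
the segment minimum toward 0).  With `g_i` the component bin's rate and
`g_k` the segment minimum:

* `peakiness = (g_i + 1) / (g_k + 1)` (default).  Equals 1 iff
  `g_i = g_k`, and 1.25 corresponds (in the large-rate limit) to firing
  >25% above the quietest surrounding bin.  This formula is unbounded
  above; a `normalized` variant,
  `(g_i + 1) / ((g_i + g_k)/2 + 1)`, bounded in (0, 2], is available
  behind a flag for users who prefer a bounded scale.  The two variants
  are never silently substituted.
* A one-tailed two-sample t-test (pooled variance by default, Welch by
  flag) of the 3 central segment bins against the remaining 8, with
  alternative "component mean greater".  Groups clipped below 2 members
  by edge truncation make the test not-computable (flagged, not an
  error).  The degenerate all-constant segment is reported as
  `t = 0, p = 0.5`.  No multiple-testing correction is applied; the
  report echoes raw significance fractions at α = 0.05 and 0.01.

## Graph-theoretic component tracking

The `Z × B` rate matrix becomes a directed graph: one vertex per
`(z, t)`; every existing neighbour at `z±1, t±1` (including diagonals)
sends an edge into `(z, t)` weighted
`w(z, t) = R_max / max(rate(z, t), ε)`, where `R_max` is the unit's
maximum rate and `ε = 1e-3 Hz` is a floor that keeps zero-rate vertices
finite (the literal ratio is infinite at rate 0; the floor preserves
reachability and leaves all ratios among active vertices untouched).
A pseudo start vertex feeds every row-1 vertex at that vertex's weight;
every row-`Z` vertex reaches the goal at weight 0.  The direction
(lowest intensity first) is a convention; the neighbourhood is
symmetric, so the path vertex set does not depend on it.

Rank-1 is Dijkstra's shortest start→goal path (total cost = sum of
entered vertices' weights).  Before each further rank, every edge into
an already-used vertex is re-weighted to
`W_big = 10 · |V| · max finite vertex weight`, which exceeds any
vertex-avoiding path's cost, making "arbitrarily large" concrete and
overflow-safe; a candidate whose total reaches `W_big` must revisit a
used vertex, so it is discarded and the search stops (fewer than `k`
paths can return).  An all-zero unit returns no paths rather than
arbitrary walks through silence.  Path features: lower-median time bin
over all path vertices; per-row lower-median time and mean rate;
non-stationarity = max − min of per-row times (ms).  Pearson
correlations between two paths' per-row rates require ≥3 shared rows
and non-constant profiles.

## Population statistics

Category proportions per (layer, condition, stimulus) cell over
{0, 1, 2, 3+}.  Cells are compared by two-sample KS tests on the
per-unit integer component counts — the only reading under which a
two-sample KS applies to proportion charts — with a chi-square
contingency test emitted alongside for reference.  Timing regressions
are OLS of second-component time on first-component time per cell,
reported as intercept ± SE with non-significant slopes flagged rather
than dropped.  Primary-path non-stationarity is binned 0–4 and 5+ ms
with pairwise KS comparisons.  KS p-values are asymptotic by default
(exact available for small samples).

## Synthetic generator

Each unit draws Poisson spike counts per trial and 1-ms bin around the
expected rate

```
λ(z, t) = baseline + Σ_c max(A_c + s_c·(z−1), 0) ·
          exp(−(t − (τ_c − d_c·(z−1)))² / (2·w²))
```

with per-component peak rate `A_c` (Hz at intensity 1), amplitude slope
`s_c` (Hz per step, may be negative to emulate opposing components;
rates clip at 0, which makes λ non-linear in `z` at extremes), latency
shift `d_c ≥ 0` (ms earlier per step) and width `w = 1 ms` (narrow
enough that the 5-ms merge rule cannot fuse programmed components
≥ 6 ms apart; the sharp observed components motivate the default).
λ is evaluated at bin centres; spike times land uniformly within their
bin.  Defaults: 50-ms window, 10 intensities (5 for the Basic
stimulus), 20 trials, baseline 5 Hz, peak rates 60–150 Hz, amplitude
slopes 0–5 Hz/step, total latency shifts 0–5 ms across the intensity
range.

Populations allocate unit categories by deterministic largest-remainder
apportionment (no multinomial noise, so proportion-recovery tests are
exact), and link multi-component timings by
`second = a + b·first + N(0, σ)` (defaults a = 10 ms, b = 1,
σ = 1.5 ms), resampled to keep components ≥ 8 ms apart and inside the
window; a third component follows ~10 ms after the second.  All
randomness descends from one master seed via spawned seed sequences, so
outputs are byte-reproducible.

What the generator does *not* emulate: bursting and refractoriness
(counts are independent across bins), rate adaptation across trials,
electrode drift, correlated noise across intensities, and the real
Contact waveform (the shipped 100-ms trace is an explicitly synthetic
proxy whose shape influences nothing downstream).  Passing recovery
tests therefore demonstrate correctness of the algorithms under
Poisson variability, not robustness to every property of real
recordings.

## Numerical conventions

Lower medians everywhere a median of an even count is needed (merge
rule, path times), keeping values on the 1-ms lattice.  Merge distance
"within 5 ms" is inclusive (≤ 5).  Distance ties merge the left-most
pair.  The 25% threshold is strict (`< 0.25 · max` discards).  TSV
outputs are UTF-8, tab-separated, '.'-decimal, full float precision;
re-runs are byte-identical.

## Test problem sizes

The recovery suite uses 200 units (2 cells × 100; proportions
0.35/0.30/0.25/0.10; shared timing model a = 10, b = 1, σ = 1.5) at the
reference conditions above — large enough that category accuracy,
median timing error, non-stationarity recovery and intercept SEs are
stable across seeds, while the whole suite stays interactive.  Oracle
checks run 500 random merge sets against an exhaustive all-pairs
simulation and 100 random grids (up to 4×8) against branch-and-bound
path enumeration; t-test null calibration uses 2000 i.i.d. Gaussian
segments.

## Known limitations

* At realistic spontaneous rates the detection stage cannot separate
  single-spike noise bins from genuine 1-ms components (see the
  calibration note above); the paired validation statistics exist
  precisely to flag weak components after the fact.
* Non-stationarity from the rank-1 path is a max−min statistic and
  inherits ±1–2 ms jitter when Poisson gaps push the path off the ridge
  in a single row; about 80% of tracked units recover the programmed
  drift within ±1 ms at the reference conditions.
* The peakiness formula's printed form is unbounded; comparisons with
  descriptions of a 0–2 scale should use the `normalized` variant
  explicitly.
* KS tests on component-count distributions are coarse for 4-category
  data; the chi-square companion is usually the better-powered check.
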