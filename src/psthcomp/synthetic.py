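"""Synthetic spike rasters with programmed response-component structure.

The generator emulates the statistical structure of whisker-deflection
responses in anaesthetised rat barrel cortex: each unit has 0-3 response
components, modelled as narrow Gaussian bumps in the underlying firing
rate, whose amplitude grows (or shrinks) linearly with stimulus
intensity and whose latency shifts earlier with intensity by a fixed
per-step amount (the programmed non-stationarity, 0-5 ms across the
intensity range).  Trial-to-trial spiking is Poisson.  For a unit with
components c = 1..C the expected rate at intensity row z (1-based) and
time t (ms) is

    lambda(z, t) = baseline
        + sum_c max(A_c + slope_c (z-1), 0) * exp(-(t - tau_c + s_c (z-1))^2
                                                  / (2 width^2))

clipped at 0.  Every generated unit is accompanied by ground-truth rows
(true category, per-intensity component times, per-component
non-stationarity) so detection and tracking can be scored exactly.

Population generation allocates unit categories by deterministic
largest-remainder apportionment of the requested proportions (no
multinomial sampling), and links the timings of first and second
components through a linear model second = a + b * first + N(0, sigma),
mirroring the intercept-recovery analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .psth import SpikeRaster, WINDOW_MS


# ---------------------------------------------------------------------------
# stimulus waveforms

@dataclass
class StimulusWaveform:
    """Whisker-deflection trajectory: (time ms, amplitude mm) samples."""

    kind: str
    intensity: float  # velocity mm/s (basic) or peak amplitude mm (contact)
    times_ms: np.ndarray
    amplitudes_mm: np.ndarray


#: Basic stimulus geometry: trapezoid to 3.6 mm, 20 ms hold, 40 ms off-ramp.
BASIC_DISTANCE_MM = 3.6
BASIC_HOLD_MS = 20.0
BASIC_OFFRAMP_MS = 40.0
BASIC_VELOCITIES = (30.0, 60.0, 150.0, 250.0, 400.0)  # mm/s

#: Contact stimulus duration (ms).
CONTACT_DURATION_MS = 100.0


def basic_waveform(velocity: float, dt_ms: float = 0.5) -> StimulusWaveform:
    """Trapezoid whisker deflection: linear on-ramp at ``velocity`` mm/s to
    3.6 mm, a 20-ms hold, then a linear 40-ms off-ramp back to rest."""
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    ramp_ms = BASIC_DISTANCE_MM / velocity * 1000.0
    total = ramp_ms + BASIC_HOLD_MS + BASIC_OFFRAMP_MS
    t = np.arange(0.0, total + dt_ms / 2, dt_ms)
    amp = np.piecewise(
        t,
        [t <= ramp_ms,
         (t > ramp_ms) & (t <= ramp_ms + BASIC_HOLD_MS),
         t > ramp_ms + BASIC_HOLD_MS],
        [lambda x: BASIC_DISTANCE_MM * x / ramp_ms,
         BASIC_DISTANCE_MM,
         lambda x: BASIC_DISTANCE_MM * np.clip(
             1 - (x - ramp_ms - BASIC_HOLD_MS) / BASIC_OFFRAMP_MS, 0, 1)],
    )
    return StimulusWaveform("basic", velocity, t, amp)


def contact_waveform(peak_amplitude: float, dt_ms: float = 0.5) -> StimulusWaveform:
    """Synthetic 100-ms proxy for the naturalistic object-contact stimulus.

    The real trace was reconstructed from high-speed video of a whisker
    contacting and brushing past an object and is not reproduced here;
    this deterministic stand-in keeps its gross features — an initial
    deflection peaking near 10 ms, a secondary bump near 25 ms, a dip
    near 40 ms and a gentle late rebound — scaled linearly so the
    maximum equals ``peak_amplitude`` mm.  It exists for documentation
    and plotting; no analysis result depends on its exact shape.
    """
    if peak_amplitude <= 0:
        raise ValueError("peak_amplitude must be positive")
    t = np.arange(0.0, CONTACT_DURATION_MS + dt_ms / 2, dt_ms)
    shape = (1.00 * np.exp(-((t - 10.0) / 4.0) ** 2 / 2)
             + 0.55 * np.exp(-((t - 25.0) / 5.0) ** 2 / 2)
             + 0.35 * np.exp(-((t - 60.0) / 12.0) ** 2 / 2))
    onset = np.clip(t / 5.0, 0.0, 1.0)          # zero at stimulus onset
    offset = np.clip((CONTACT_DURATION_MS - t) / 10.0, 0.0, 1.0)
    shape = shape * onset * offset
    amp = peak_amplitude * shape / shape.max()
    return StimulusWaveform("contact", peak_amplitude, t, amp)


# ---------------------------------------------------------------------------
# single units

@dataclass
class SyntheticUnitSpec:
    """Programmed parameters for one synthetic unit."""

    unit_id: str
    layer: str
    condition: str
    stimulus: str
    n_components: int
    component_times: list[float]      # tau_c, ms at intensity 1
    peak_rates: list[float]           # A_c, Hz at intensity 1
    rate_slopes: list[float]          # Hz per intensity step (may be negative)
    latency_shifts: list[float]       # s_c >= 0, ms earlier per intensity step
    component_width: float = 1.0      # Gaussian sd, ms
    baseline_rate: float = 5.0        # Hz
    n_intensities: int = 10
    n_trials: int = 20
    window_ms: float = WINDOW_MS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("component_times", "peak_rates", "rate_slopes",
                     "latency_shifts"):
            if len(getattr(self, name)) != self.n_components:
                raise ValueError(f"{name} must have n_components entries")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if any(a <= 0 for a in self.peak_rates):
            raise ValueError("peak_rates must be positive")
        if any(s < 0 for s in self.latency_shifts):
            raise ValueError("latency shifts must be >= 0 (earlier with intensity)")
        for tau, s in zip(self.component_times, self.latency_shifts):
            if tau - s * (self.n_intensities - 1) < 0:
                raise ValueError("component would shift before stimulus onset")

    def expected_rate(self, z: int, t) -> np.ndarray:
        """lambda(z, t) in Hz for intensity row ``z`` (1-based), time ms."""
        t = np.asarray(t, dtype=float)
        lam = np.full_like(t, self.baseline_rate)
        for tau, a, slope, s in zip(self.component_times, self.peak_rates,
                                    self.rate_slopes, self.latency_shifts):
            amp = max(a + slope * (z - 1), 0.0)
            center = tau - s * (z - 1)
            lam = lam + amp * np.exp(-((t - center) ** 2)
                                     / (2.0 * self.component_width ** 2))
        return np.clip(lam, 0.0, None)

    def true_time(self, component: int, z: int) -> float:
        """Programmed centre (ms) of component ``component`` (0-based) at row z."""
        return (self.component_times[component]
                - self.latency_shifts[component] * (z - 1))

    def true_nonstationarity(self, component: int) -> float:
        """Total programmed latency shift (ms) across the intensity range."""
        return self.latency_shifts[component] * (self.n_intensities - 1)


def generate_unit(spec: SyntheticUnitSpec,
                  bin_ms: float = 1.0) -> tuple[SpikeRaster, pd.DataFrame]:
    """Draw Poisson spike trains for one unit and its ground-truth rows.

    Per trial, the spike count in each 1-ms bin is Poisson with mean
    lambda(z, bin centre) * bin_s; spike times are placed uniformly
    within their bin.  Reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_bins = int(round(spec.window_ms / bin_ms))
    centers = (np.arange(n_bins) + 0.5) * bin_ms
    events = []
    for z in range(1, spec.n_intensities + 1):
        lam = spec.expected_rate(z, centers) * (bin_ms / 1000.0)
        counts = rng.poisson(lam[None, :].repeat(spec.n_trials, axis=0))
        trials, bins = np.nonzero(counts)
        for trial, b in zip(trials, bins):
            k = counts[trial, b]
            offsets = rng.random(k) * bin_ms
            for off in offsets:
                events.append((z, trial + 1, (b * bin_ms) + off))
    raster = SpikeRaster(
        unit_id=spec.unit_id, layer=spec.layer, condition=spec.condition,
        stimulus=spec.stimulus, n_intensities=spec.n_intensities,
        n_trials=np.full(spec.n_intensities, spec.n_trials),
        events=np.array(events, dtype=float).reshape(-1, 3),
        window_ms=spec.window_ms,
    )
    rows = []
    for c in range(spec.n_components):
        for z in range(1, spec.n_intensities + 1):
            rows.append({
                "unit_id": spec.unit_id, "category": spec.n_components,
                "component_index": c + 1, "intensity": z,
                "true_time_ms": spec.true_time(c, z),
                "true_nonstationarity_ms": spec.true_nonstationarity(c),
            })
    if not rows:  # non-responders still get one ground-truth row
        rows.append({"unit_id": spec.unit_id, "category": 0,
                     "component_index": 0, "intensity": 0,
                     "true_time_ms": float("nan"),
                     "true_nonstationarity_ms": float("nan")})
    return raster, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# populations

@dataclass
class CellSpec:
    """One (layer, condition) population cell."""

    layer: str
    condition: str
    n_units: int
    proportions: tuple[float, float, float, float] = (0.35, 0.30, 0.25, 0.10)
    timing_a: float = 10.0     # intercept of second-on-first timing model, ms
    timing_b: float = 1.0      # slope
    timing_sigma: float = 1.5  # residual sd, ms


@dataclass
class PopulationSpec:
    """Recipe for a full synthetic population of units."""

    cells: list[CellSpec] = field(default_factory=list)
    stimulus: str = "contact"
    n_intensities: int = 10
    n_trials: int = 20
    baseline_rate: float = 5.0
    component_width: float = 1.0
    first_time_range: tuple[float, float] = (10.0, 20.0)
    peak_rate_range: tuple[float, float] = (60.0, 150.0)
    rate_slope_range: tuple[float, float] = (0.0, 5.0)
    nonstationarity_range: tuple[float, float] = (0.0, 5.0)  # total ms over Z-1
    min_separation_ms: float = 8.0
    third_component_gap_ms: float = 10.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for cell in self.cells:
            if abs(sum(cell.proportions) - 1.0) > 1e-9:
                raise ValueError("category proportions must sum to 1")
            if cell.n_units < 0:
                raise ValueError("unit counts must be >= 0")


def default_population(n_units_per_cell: int = 25, stimulus: str = "contact",
                       master_seed: int = 0) -> PopulationSpec:
    """A study-shaped default: layers II and IV under sham and three
    post-injury timepoints, with category mixes and timing intercepts
    loosely patterned on healthy-vs-injured barrel cortex (fewer
    responsive and multi-component units early after injury)."""
    cells = []
    mixes = {
        "sham": ((0.30, 0.30, 0.28, 0.12), 10.0),
        "tbi_4d": ((0.50, 0.30, 0.15, 0.05), 13.0),
        "tbi_2w": ((0.45, 0.30, 0.18, 0.07), 9.0),
        "tbi_8w": ((0.35, 0.30, 0.25, 0.10), 8.0),
    }
    for layer in ("II", "IV"):
        for cond, (props, a) in mixes.items():
            cells.append(CellSpec(layer=layer, condition=cond,
                                  n_units=n_units_per_cell, proportions=props,
                                  timing_a=a))
    return PopulationSpec(cells=cells, stimulus=stimulus,
                          master_seed=master_seed)


def largest_remainder_counts(proportions, total: int) -> list[int]:
    """Apportion ``total`` into integer counts matching ``proportions``.

    Deterministic largest-remainder (Hamilton) allocation; ties broken by
    category order.  Guarantees the counts sum to ``total`` exactly, so
    proportion-recovery tests carry no sampling noise from allocation.
    """
    quotas = [p * total for p in proportions]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = total - sum(counts)
    order = sorted(range(len(quotas)),
                   key=lambda i: (-(quotas[i] - np.floor(quotas[i])), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _draw_component_times(rng, pop: PopulationSpec, cell: CellSpec,
                          n_components: int) -> list[float]:
    """First time uniform; second via the linear timing model; third a
    fixed-gap follower.  Later components are resampled (truncated
    normal) to keep >= min_separation_ms and fit in the window."""
    lo, hi = pop.first_time_range
    times = [rng.uniform(lo, hi)]
    if n_components >= 2:
        for _ in range(1000):
            t2 = cell.timing_a + cell.timing_b * times[0] + \
                rng.normal(0.0, cell.timing_sigma)
            if times[0] + pop.min_separation_ms <= t2 <= 42.0:
                times.append(t2)
                break
        else:
            times.append(times[0] + pop.min_separation_ms)
    if n_components >= 3:
        for _ in range(1000):
            t3 = times[1] + pop.third_component_gap_ms + \
                rng.normal(0.0, cell.timing_sigma)
            if times[1] + pop.min_separation_ms <= t3 <= 48.0:
                times.append(t3)
                break
        else:
            times.append(min(times[1] + pop.min_separation_ms, 48.0))
    return times


def generate_population(pop: PopulationSpec
                        ) -> tuple[list[SpikeRaster], pd.DataFrame, pd.DataFrame]:
    """Generate all rasters, the ground-truth table and a unit-spec table.

    Category counts per cell follow deterministic largest-remainder
    allocation of the requested proportions.  Returns
    ``(rasters, ground_truth, unit_table)`` where ``unit_table`` has one
    row per unit (unit_id, layer, condition, stimulus, true category and
    the timing-model parameters of its cell) for recovery scoring.
    """
    if not pop.cells:
        raise ValueError("population has no cells")
    root = np.random.SeedSequence(pop.master_seed)
    cell_seeds = root.spawn(len(pop.cells))
    rasters: list[SpikeRaster] = []
    gt_frames = []
    unit_rows = []
    uid_counter = 0
    for cell, cell_seed in zip(pop.cells, cell_seeds):
        rng = np.random.default_rng(cell_seed)
        counts = largest_remainder_counts(cell.proportions, cell.n_units)
        categories = [cat for cat, n in enumerate(counts) for _ in range(n)]
        unit_seeds = cell_seed.spawn(len(categories))
        for cat, useq in zip(categories, unit_seeds):
            uid_counter += 1
            uid = f"u{uid_counter:04d}"
            times = _draw_component_times(rng, pop, cell, cat) if cat else []
            lo_a, hi_a = pop.peak_rate_range
            lo_s, hi_s = pop.rate_slope_range
            lo_n, hi_n = pop.nonstationarity_range
            steps = max(pop.n_intensities - 1, 1)
            spec = SyntheticUnitSpec(
                unit_id=uid, layer=cell.layer, condition=cell.condition,
                stimulus=pop.stimulus, n_components=cat,
                component_times=times,
                peak_rates=[rng.uniform(lo_a, hi_a) for _ in range(cat)],
                rate_slopes=[rng.uniform(lo_s, hi_s) for _ in range(cat)],
                latency_shifts=[rng.uniform(lo_n, hi_n) / steps
                                for _ in range(cat)],
                component_width=pop.component_width,
                baseline_rate=pop.baseline_rate,
                n_intensities=pop.n_intensities, n_trials=pop.n_trials,
                seed=int(useq.generate_state(1)[0] % (2 ** 31)),
            )
            raster, gt = generate_unit(spec)
            rasters.append(raster)
            gt["layer"] = cell.layer
            gt["condition"] = cell.condition
            gt["stimulus"] = pop.stimulus
            gt_frames.append(gt)
            unit_rows.append({
                "unit_id": uid, "layer": cell.layer, "condition": cell.condition,
                "stimulus": pop.stimulus, "category": cat,
                "timing_a": cell.timing_a, "timing_b": cell.timing_b,
                "timing_sigma": cell.timing_sigma,
                "first_time_ms": times[0] if times else float("nan"),
                "second_time_ms": times[1] if len(times) > 1 else float("nan"),
                "third_time_ms": times[2] if len(times) > 2 else float("nan"),
            })
    ground_truth = pd.concat(gt_frames, ignore_index=True)
    unit_table = pd.DataFrame(unit_rows)
    return rasters, ground_truth, unit_table


def population_config_dict(pop: PopulationSpec) -> dict:
    """YAML-serialisable echo of a population spec."""
    d = asdict(pop)
    d["cells"] = [asdict(c) for c in pop.cells]
    return d
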