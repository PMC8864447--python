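"""Spike rasters and peristimulus time histograms (PSTHs).

The analysis unit throughout this package is a single online-sorted unit
recorded in layer II or IV of rat barrel cortex while its principal whisker
was deflected at several stimulus intensities (on-ramp velocities for the
trapezoid "Basic" stimulus, peak amplitudes for the naturalistic "Contact"
stimulus).  Spikes are counted in 1-ms bins over the first 50 ms after
stimulus onset and averaged over trials, yielding one PSTH row per
intensity.  Every downstream analysis consumes the resulting
intensity x time-bin matrix of mean firing rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

LAYERS = ("II", "IV")
CONDITIONS = ("sham", "tbi_4d", "tbi_2w", "tbi_8w")
STIMULI = ("basic", "contact")

#: Default analysis window and bin width (ms).
WINDOW_MS = 50.0
BIN_MS = 1.0


@dataclass
class SpikeRaster:
    """Trial-resolved spike times for one unit.

    ``events`` is a float array of shape (n_spikes, 3) with columns
    (intensity_index, trial_index, spike_time_ms).  Intensity and trial
    indices are 1-based; intensities must form the contiguous range
    ``1..n_intensities``.  ``n_trials`` declares the number of stimulus
    repetitions per intensity (needed because a trial with no spikes leaves
    no trace in ``events``).
    """

    unit_id: str
    layer: str
    condition: str
    stimulus: str
    n_intensities: int
    n_trials: np.ndarray  # shape (Z,), int
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    window_ms: float = WINDOW_MS

    def __post_init__(self) -> None:
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        if self.n_trials.ndim == 0:
            self.n_trials = np.full(self.n_intensities, int(self.n_trials))
        self.events = np.asarray(self.events, dtype=float).reshape(-1, 3)
        self.validate()

    def validate(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.stimulus not in STIMULI:
            raise ValueError(f"unknown stimulus {self.stimulus!r}")
        if self.n_intensities < 1:
            raise ValueError("n_intensities must be >= 1")
        if len(self.n_trials) != self.n_intensities:
            raise ValueError("n_trials must have one entry per intensity")
        if np.any(self.n_trials < 1):
            raise ValueError("trial counts per intensity must be >= 1")
        if len(self.events):
            z = self.events[:, 0]
            if np.any((z < 1) | (z > self.n_intensities) | (z != np.round(z))):
                raise ValueError("intensity indices must be integers in 1..Z")
            if np.any(self.events[:, 2] < 0):
                raise ValueError("spike times must be >= 0")

    @property
    def n_spikes(self) -> int:
        return len(self.events)


@dataclass
class PSTHMatrix:
    """Intensity x time-bin mean firing rates (Hz) for one unit.

    Row ``z`` (1-based) holds the PSTH at intensity ``z``; bin ``b``
    (1-based) covers the half-open interval [b-1, b) ms.  Rates are
    spike_count / (n_trials * bin_s), so the underlying integer spike
    counts are exactly recoverable.
    """

    unit_id: str
    layer: str
    condition: str
    stimulus: str
    rates: np.ndarray  # shape (Z, B), Hz
    n_trials: np.ndarray  # shape (Z,)
    bin_ms: float = BIN_MS
    window_ms: float = WINDOW_MS

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        if self.rates.ndim != 2:
            raise ValueError("rates must be 2-D (intensity x bin)")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")
        b = self.window_ms / self.bin_ms
        if abs(b - round(b)) > 1e-9 or round(b) != self.rates.shape[1]:
            raise ValueError(
                f"window {self.window_ms} ms / bin {self.bin_ms} ms must equal "
                f"the number of columns ({self.rates.shape[1]})"
            )

    @property
    def n_intensities(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    def spike_counts(self) -> np.ndarray:
        """Recover the integer spike-count matrix from the rates."""
        counts = self.rates * self.n_trials[:, None] * (self.bin_ms / 1000.0)
        return np.rint(counts).astype(int)


def build_psth(raster: SpikeRaster, window_ms: float = WINDOW_MS,
               bin_ms: float = BIN_MS) -> PSTHMatrix:
    """Bin a spike raster into an intensity x time PSTH of mean rates (Hz).

    Bin ``b`` (1-based) covers [b-1, b) ms; spikes at or beyond
    ``window_ms`` are excluded (and logged at debug level), matching the
    half-open binning convention.  An empty raster yields an all-zero
    matrix with the raster's declared intensity and trial structure.
    """
    n_bins = window_ms / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("window_ms must be an integer multiple of bin_ms")
    n_bins = int(round(n_bins))
    z_n = raster.n_intensities
    counts = np.zeros((z_n, n_bins), dtype=np.int64)
    if raster.n_spikes:
        t = raster.events[:, 2]
        in_window = t < window_ms
        n_excluded = int(np.sum(~in_window))
        if n_excluded:
            logger.debug("build_psth(%s): excluded %d spike(s) at/after %g ms",
                         raster.unit_id, n_excluded, window_ms)
        ev = raster.events[in_window]
        zi = ev[:, 0].astype(int) - 1
        bi = np.floor(ev[:, 2] / bin_ms).astype(int)
        np.add.at(counts, (zi, bi), 1)
    rates = counts / (raster.n_trials[:, None] * (bin_ms / 1000.0))
    return PSTHMatrix(
        unit_id=raster.unit_id, layer=raster.layer, condition=raster.condition,
        stimulus=raster.stimulus, rates=rates, n_trials=raster.n_trials,
        bin_ms=bin_ms, window_ms=window_ms,
    )


def pooled_mean_rates(psth: PSTHMatrix) -> np.ndarray:
    """Mean firing rate per time bin, averaged across all intensities.

    This is the per-unit activity profile used by the component validation
    statistics (unweighted mean over intensity rows).
    """
    return psth.rates.mean(axis=0)
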