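import numpy as np
import pytest

from psthcomp import PSTHMatrix, SpikeRaster


@pytest.fixture
def make_psth():
    """Factory for ad-hoc PSTH matrices from a rate array."""

    def _make(rates, unit_id="u1", layer="II", condition="sham",
              stimulus="basic", n_trials=10):
        rates = np.asarray(rates, dtype=float)
        return PSTHMatrix(
            unit_id=unit_id, layer=layer, condition=condition,
            stimulus=stimulus, rates=rates,
            n_trials=np.full(rates.shape[0], n_trials),
            bin_ms=1.0, window_ms=float(rates.shape[1]),
        )

    return _make


@pytest.fixture
def make_raster():
    """Factory for ad-hoc spike rasters from (intensity, trial, time) rows."""

    def _make(events, n_intensities=5, n_trials=10, unit_id="u1",
              layer="II", condition="sham", stimulus="basic", window_ms=50.0):
        return SpikeRaster(
            unit_id=unit_id, layer=layer, condition=condition,
            stimulus=stimulus, n_intensities=n_intensities,
            n_trials=np.full(n_intensities, n_trials),
            events=np.array(events, dtype=float).reshape(-1, 3),
            window_ms=window_ms,
        )

    return _make
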