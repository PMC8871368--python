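import numpy as np
import pytest

from prehear.synth.presets import WavePreset


@pytest.fixture
def small_wave_preset():
    """Compact stack preset for fast imaging tests."""
    return WavePreset(
        label="WT", modality="dic", shape=(64, 64), pixel_size=2.0,
        n_frames=60, frame_interval=1.0, baseline_level=2000.0,
        noise_sd=0.012, event_rate=0.0, event_amplitude=0.35,
        area_median=300.0, area_sigma=0.3, area_max=2000.0,
        rise_frames=4, hold_frames=2, decay_frames=4,
        propagation_speed=0.0, band_rows_um=(40.0, 90.0), x_margin_um=20.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
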