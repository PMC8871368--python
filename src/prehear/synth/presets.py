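"""Preset dataclasses and the versioned calibration file loader."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from importlib import resources

import numpy as np
import yaml

__all__ = ["SpikeTrainPreset", "WavePreset", "FRAPreset", "MapPreset",
           "load_preset", "load_preset_file"]


@dataclass(frozen=True)
class SpikeTrainPreset:
    """Generative model of one genotype's spontaneous MNTB discharge.

    A unit fires homogeneous background spikes at ``background_rate`` plus
    burst epochs whose onsets form a Poisson process (``burst_rate_per_100s``).
    A burst is a train of mini-bursts at ``miniburst_interval`` (~0.1 s);
    the mini-burst count per burst is lognormal (right-skewed: most bursts a
    second or two, rare ones lasting many seconds), and each mini-burst holds
    ``1 + Poisson(spikes_per_miniburst_extra)`` spikes at
    ``intra_miniburst_isi`` spacing.  Per-unit multiplicative lognormal
    jitter (``unit_jitter_sd`` in log units) spreads rates across units.
    """

    label: str = "WT"
    duration: float = 100.0
    burst_rate_per_100s: float = 5.0
    miniburst_count_median: float = 16.0
    miniburst_count_sigma: float = 1.1
    miniburst_count_min: int = 1
    miniburst_interval: float = 0.1
    miniburst_interval_sd: float = 0.015
    spikes_per_miniburst_extra: float = 1.6
    spikes_per_miniburst_sigma: float = 0.0   # per-burst lognormal spread
    intra_miniburst_isi: float = 0.025
    intra_isi_sd: float = 0.006
    background_rate: float = 1.0
    unit_jitter_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name in ("burst_rate_per_100s", "background_rate",
                     "miniburst_interval", "intra_miniburst_isi",
                     "spikes_per_miniburst_extra", "unit_jitter_sd",
                     "miniburst_count_median", "miniburst_count_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class WavePreset:
    """Generative model of spontaneous ISC events in an imaging stack.

    Events are discs placed inside a horizontal band (standing in for
    Koelliker's organ) whose amplitude ramps up over ``rise_frames``, holds,
    and decays; the steady ramp keeps the frame-minus-moving-average signal
    of every footprint pixel above the detection threshold at once.  WT
    events are large and drift along the tonotopic (column) axis at
    ``propagation_speed``; cKO events are small and stationary.
    """

    label: str = "WT"
    modality: str = "fura_ratio"  # or "dic"
    shape: tuple[int, int] = (128, 128)
    pixel_size: float = 2.0           # um / px
    n_frames: int = 400
    frame_interval: float = 1.0       # s
    baseline_level: float = 2000.0    # camera counts
    noise_sd: float = 0.012           # multiplicative, per channel
    event_rate: float = 0.05          # attempted events / s (whole band)
    event_amplitude: float = 0.35     # fraction of baseline at peak
    area_median: float = 3300.0       # um^2, lognormal footprint areas
    area_sigma: float = 0.45
    area_max: float = 15000.0
    rise_frames: int = 6
    hold_frames: int = 2
    decay_frames: int = 6
    propagation_speed: float = 3.0    # um / s along columns; 0 = stationary
    band_rows_um: tuple[float, float] = (100.0, 156.0)
    x_margin_um: float = 40.0

    def __post_init__(self) -> None:
        if self.n_frames < 20:
            raise ValueError("n_frames must be >= 20")
        if self.event_amplitude < 0 or self.area_median < 0:
            raise ValueError("amplitude and areas must be >= 0")
        if self.modality not in ("fura_ratio", "dic"):
            raise ValueError("modality must be 'fura_ratio' or 'dic'")
        h_um = self.shape[0] * self.pixel_size
        w_um = self.shape[1] * self.pixel_size
        if not (0 <= self.band_rows_um[0] < self.band_rows_um[1] <= h_um):
            raise ValueError("band geometry does not fit the field")
        if 2 * self.x_margin_um >= w_um:
            raise ValueError("field too small for the x margins")


@dataclass(frozen=True)
class FRAPreset:
    """V-shaped frequency-response-area model.

    The pure-tone threshold rises from (``cf_khz``, ``threshold_db``) with
    constant slopes (dB/octave) on each flank; above local threshold the rate
    ramps from spontaneous to ``max_rate`` over ``dynamic_range_db``.
    """

    cf_khz: float = 15.0
    threshold_db: float = 10.0
    slope_low: float = 60.0       # dB per octave below CF
    slope_high: float = 80.0      # dB per octave above CF
    max_rate: float = 260.0       # AP/s
    spont_rate: float = 5.0       # AP/s
    dynamic_range_db: float = 15.0
    freqs_khz: tuple = tuple(np.geomspace(4.0, 40.0, 61).round(3))
    levels_db: tuple = tuple(range(0, 85, 5))
    reps: int = 5
    window_s: float = 0.1

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_khz, float)
        lv = np.asarray(self.levels_db, float)
        if f.size < 2 or lv.size < 2 or np.any(np.diff(f) <= 0) or np.any(np.diff(lv) <= 0):
            raise ValueError("frequency and level grids must be strictly increasing")
        if self.max_rate < self.spont_rate:
            raise ValueError("max_rate must be >= spont_rate")
        # equality is allowed: a flat surface has no response region and an
        # undefined CF, which the analyzer reports as NoResponseError

    @classmethod
    def with_q10(cls, cf_khz: float, q10: float, **kw) -> "FRAPreset":
        """Symmetric-slope preset whose analytic BW10 equals cf/q10."""
        target = 1.0 / q10
        # solve 2**x - 2**-x = target for x = 10/slope
        x = np.arcsinh(target / 2.0) / np.log(2.0)
        slope = 10.0 / x
        return cls(cf_khz=cf_khz, slope_low=slope, slope_high=slope, **kw)


@dataclass(frozen=True)
class MapPreset:
    """Uncaging-grid model of the MNTB input onto one LSO neuron.

    The MNTB outline is an ellipse-like polygon (area jittered per map); the
    responsive region is an anisotropic Gaussian PSP-amplitude profile whose
    2 mV contour covers ``frac_area_target`` of the outline and whose 10 mV
    contour spans ``width_frac_target`` of the mediolateral (x) extent.
    """

    label: str = "WT"
    grid_spacing: float = 20.0        # um
    mntb_area_um2: float = 63000.0
    mntb_aspect: float = 1.4          # mediolateral / dorsoventral axis ratio
    area_jitter_sd: float = 0.07      # lognormal, per map
    frac_area_target: float = 0.10
    width_frac_target: float = 0.18
    width_pad_um: float = 14.0        # grid-discretization compensation
    peak_mv: float = 30.0
    ap_threshold_mv: float = 22.0
    noise_sd_mv: float = 0.5
    n_polygon_vertices: int = 48

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if not 0 < self.frac_area_target < 1:
            raise ValueError("fractional area target must be in (0, 1)")

    @property
    def site_area(self) -> float:
        return self.grid_spacing ** 2


_PRESET_TYPES = {
    "spikes": SpikeTrainPreset,
    "imaging": WavePreset,
    "fra": FRAPreset,
    "map": MapPreset,
}


def load_preset_file() -> dict:
    text = resources.files("prehear").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def load_preset(modality: str, genotype: str, **overrides):
    """Load a calibrated preset (e.g. ``load_preset("spikes", "wt")``)."""
    table = load_preset_file()
    if modality not in table:
        raise KeyError(f"unknown modality {modality!r}")
    entry = dict(table[modality][genotype.lower()])
    entry.update(overrides)
    cls = _PRESET_TYPES[modality]
    if "freqs_khz" in entry:
        entry["freqs_khz"] = tuple(entry["freqs_khz"])
    if "levels_db" in entry:
        entry["levels_db"] = tuple(entry["levels_db"])
    for key in ("shape", "band_rows_um"):
        if key in entry:
            entry[key] = tuple(entry[key])
    return cls(**entry)


def preset_to_dict(preset) -> dict:
    return asdict(preset)
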