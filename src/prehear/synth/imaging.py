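"""Time-lapse stack generator for spontaneous ISC volume / Ca2+ events."""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..imaging_events import ImagingStack
from .presets import WavePreset

__all__ = ["generate_imaging_stack"]


def _event_amplitude_profile(preset: WavePreset) -> np.ndarray:
    """Per-frame relative amplitude: linear rise, hold, linear decay."""
    rise = np.linspace(0.0, 1.0, preset.rise_frames + 1)[1:]
    hold = np.ones(preset.hold_frames)
    decay = np.linspace(1.0, 0.0, preset.decay_frames + 1)[1:]
    return preset.event_amplitude * np.concatenate([rise, hold, decay])


def generate_imaging_stack(preset: WavePreset, seed: int,
                           forced_events: list[dict] | None = None
                           ) -> tuple[ImagingStack, dict] | tuple[ImagingStack, ImagingStack, dict]:
    """Generate one calibrated stack plus ground truth.

    Returns ``(stack, truth)`` for DIC, and ``(stack340, stack380, truth)``
    for the fura modality, where the event signal rides multiplicatively on
    the 340 nm channel only so the 340/380 ratio carries it.

    Event footprints are discs (area lognormal, clipped to ``area_max``)
    whose amplitude follows a rise/hold/decay profile; WT discs drift along
    the column (tonotopic) axis at ``propagation_speed``.  Ground truth
    records, per event, the onset/offset frames, the rasterized maximal
    footprint area (um^2) and the centroid at peak.

    The event count inverts the Poisson CDF on the stream's first uniform,
    so matched seeds preserve WT >= cKO total event load; per-event size
    draws share the stream order for the same reason.  ``forced_events``
    (dicts with area_um2 / cx_um / cy_um / t0) bypasses the random draws —
    useful for injecting a known event.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x1A)))
    rows, cols = preset.shape
    px = preset.pixel_size
    profile = _event_amplitude_profile(preset)
    life = profile.size

    duration = preset.n_frames * preset.frame_interval
    mu = preset.event_rate * duration
    u = rng.random()
    n_events = int(stats.poisson.ppf(u, mu)) if mu > 0 else 0
    signal = np.zeros((preset.n_frames, rows, cols), dtype=np.float64)

    yy, xx = np.mgrid[0:rows, 0:cols]
    events = []
    lo_t = 6  # leave the subtraction window clear at the start
    hi_t = preset.n_frames - life - 1
    if hi_t <= lo_t:
        raise ValueError("stack too short for the event time course")
    if forced_events is not None:
        n_events = len(forced_events)
    for k_ev in range(n_events):
        if forced_events is not None:
            fe = forced_events[k_ev]
            area = float(fe["area_um2"])
            cy, cx = float(fe["cy_um"]), float(fe["cx_um"])
            t0 = int(fe["t0"])
            direction = float(fe.get("direction", 1.0))
            radius = np.sqrt(area / np.pi)
            max_area_px = 0
            peak_centroid = (cx, cy)
            for k, amp in enumerate(profile):
                cxt = cx + direction * preset.propagation_speed * k * preset.frame_interval
                mask = ((xx * px - cxt) ** 2 + (yy * px - cy) ** 2) <= radius ** 2
                signal[t0 + k][mask] += amp
                npix = int(mask.sum())
                if amp == profile.max() and npix > max_area_px:
                    max_area_px = npix
                    peak_centroid = (float(xx[mask].mean() * px),
                                     float(yy[mask].mean() * px))
            events.append({"onset_frame": t0, "offset_frame": t0 + life - 1,
                           "area_um2": max_area_px * px * px,
                           "centroid_x_um": peak_centroid[0],
                           "centroid_y_um": peak_centroid[1],
                           "amplitude": float(preset.event_amplitude)})
            continue
        area = float(np.clip(rng.lognormal(np.log(preset.area_median),
                                           preset.area_sigma),
                             None, preset.area_max))
        radius = np.sqrt(area / np.pi)  # um
        cy = rng.uniform(preset.band_rows_um[0], preset.band_rows_um[1])
        cx = rng.uniform(preset.x_margin_um, cols * px - preset.x_margin_um)
        t0 = int(rng.integers(lo_t, hi_t))
        direction = rng.choice([-1.0, 1.0])
        max_area_px = 0
        peak_centroid = (cx, cy)
        for k, amp in enumerate(profile):
            cxt = cx + direction * preset.propagation_speed * k * preset.frame_interval
            mask = ((xx * px - cxt) ** 2 + (yy * px - cy) ** 2) <= radius ** 2
            signal[t0 + k][mask] += amp
            npix = int(mask.sum())
            if amp == profile.max() and npix > max_area_px:
                max_area_px = npix
                com = (float(xx[mask].mean() * px), float(yy[mask].mean() * px))
                peak_centroid = com
        events.append({
            "onset_frame": t0,
            "offset_frame": t0 + life - 1,
            "area_um2": max_area_px * px * px,
            "centroid_x_um": peak_centroid[0],
            "centroid_y_um": peak_centroid[1],
            "amplitude": float(preset.event_amplitude),
        })

    truth = {"events": events, "n_events": len(events)}
    meta = dict(pixel_size=px, frame_interval=preset.frame_interval)

    def _to_uint16(arr: np.ndarray) -> np.ndarray:
        return np.clip(np.round(arr), 0, 65535).astype(np.uint16)

    if preset.modality == "dic":
        noise = rng.normal(1.0, preset.noise_sd, size=signal.shape)
        frames = preset.baseline_level * (1.0 + signal) * noise
        stack = ImagingStack(frames=_to_uint16(frames), modality="dic", **meta)
        return stack, truth

    noise340 = rng.normal(1.0, preset.noise_sd, size=signal.shape)
    noise380 = rng.normal(1.0, preset.noise_sd, size=signal.shape)
    ch340 = preset.baseline_level * (1.0 + signal) * noise340
    ch380 = preset.baseline_level * noise380
    s340 = ImagingStack(frames=_to_uint16(ch340), modality="fura_340", **meta)
    s380 = ImagingStack(frames=_to_uint16(ch380), modality="fura_380", **meta)
    return s340, s380, truth
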