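"""Frequency-response-area generator with analytic ground truth."""

from __future__ import annotations

import numpy as np

from ..fra_tuning import FRAMatrix
from .presets import FRAPreset

__all__ = ["generate_fra", "analytic_bandwidth"]


def _local_threshold(preset: FRAPreset, freqs_khz: np.ndarray) -> np.ndarray:
    octaves = np.log2(freqs_khz / preset.cf_khz)
    slope = np.where(octaves >= 0, preset.slope_high, preset.slope_low)
    return preset.threshold_db + slope * np.abs(octaves)


def expected_rate(preset: FRAPreset, freqs_khz: np.ndarray,
                  levels_db: np.ndarray) -> np.ndarray:
    """Noiseless response surface (AP/s), shape (n_levels, n_freqs)."""
    thr = _local_threshold(preset, np.asarray(freqs_khz, float))
    excess = np.asarray(levels_db, float)[:, None] - thr[None, :]
    # the response switches on AT local threshold (small but nonzero drive)
    # and then ramps to saturation over the dynamic range
    drive = np.where(excess >= 0,
                     np.clip((excess + 2.0) / preset.dynamic_range_db, 0.0, 1.0),
                     0.0)
    return preset.spont_rate + (preset.max_rate - preset.spont_rate) * drive


def analytic_bandwidth(preset: FRAPreset, n_db: float) -> float:
    """Width of the suprathreshold region n dB above the CF threshold."""
    f_hi = preset.cf_khz * 2.0 ** (n_db / preset.slope_high)
    f_lo = preset.cf_khz * 2.0 ** (-n_db / preset.slope_low)
    return f_hi - f_lo


def generate_fra(preset: FRAPreset, seed: int,
                 noiseless: bool = False) -> tuple[FRAMatrix, dict]:
    """Draw spike counts per (level, frequency) bin plus analytic truth.

    Counts are Poisson with mean rate x stimulus window x reps; with
    ``noiseless=True`` the expected counts are used directly, which makes
    recovery of CF, threshold and bandwidth exact at grid resolution.
    """
    freqs = np.asarray(preset.freqs_khz, float)
    levels = np.asarray(preset.levels_db, float)
    mean_counts = expected_rate(preset, freqs, levels) * preset.window_s * preset.reps
    if noiseless:
        counts = mean_counts
    else:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xF1)))
        counts = rng.poisson(mean_counts).astype(float)
    fra = FRAMatrix(freqs, levels, counts, reps=preset.reps,
                    window_s=preset.window_s)

    responsive = preset.max_rate > preset.spont_rate
    # expected recovery on this grid: nearest grid frequency to the analytic
    # CF, and the lowest grid level at or above the analytic threshold
    cf_grid = float(freqs[np.argmin(np.abs(freqs - preset.cf_khz))])
    thr_candidates = levels[levels >= preset.threshold_db]
    thr_grid = float(thr_candidates[0]) if thr_candidates.size else None
    truth = {
        "cf_khz": preset.cf_khz if responsive else None,
        "cf_khz_grid": cf_grid if responsive else None,
        "threshold_db_grid": thr_grid if responsive else None,
        "threshold_db": preset.threshold_db if responsive else None,
        "bw_khz": {n: analytic_bandwidth(preset, n) for n in (10, 20, 30)}
        if responsive else {},
        "q": {n: preset.cf_khz / analytic_bandwidth(preset, n)
              for n in (10, 20, 30)} if responsive else {},
        "max_rate": preset.max_rate if responsive else preset.spont_rate,
    }
    return fra, truth
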