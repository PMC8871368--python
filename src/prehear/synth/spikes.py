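"""Spike-train generator: bursts of mini-bursts over sparse background."""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..spike_burst import SpikeTrain
from .presets import SpikeTrainPreset

__all__ = ["generate_spike_trains"]

_MIN_SEP = 5e-4  # s; recordings cannot hold two spikes of one unit closer


def _unit_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(index))))


def _generate_burst(rng: np.random.Generator, onset: float,
                    preset: SpikeTrainPreset) -> np.ndarray:
    n_mb = max(preset.miniburst_count_min, 1,
               int(round(rng.lognormal(np.log(preset.miniburst_count_median),
                                       preset.miniburst_count_sigma))))
    intervals = rng.normal(preset.miniburst_interval,
                           preset.miniburst_interval_sd, size=n_mb - 1)
    intervals = np.clip(intervals, 0.4 * preset.miniburst_interval, None)
    mb_onsets = onset + np.concatenate([[0.0], np.cumsum(intervals)])
    # per-burst spike density: some bursts are dense, some sparse
    extra = preset.spikes_per_miniburst_extra
    if preset.spikes_per_miniburst_sigma > 0:
        extra = extra * rng.lognormal(0.0, preset.spikes_per_miniburst_sigma)
    spikes = []
    for t0 in mb_onsets:
        n_spk = 1 + rng.poisson(extra)
        isis = rng.normal(preset.intra_miniburst_isi, preset.intra_isi_sd,
                          size=n_spk - 1)
        isis = np.clip(isis, 0.2 * preset.intra_miniburst_isi, None)
        spikes.append(t0 + np.concatenate([[0.0], np.cumsum(isis)]))
    return np.concatenate(spikes)


def _merge_windows(windows: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not windows:
        return []
    windows = sorted(windows)
    merged = [list(windows[0])]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(w) for w in merged]


def generate_spike_trains(preset: SpikeTrainPreset, n_units: int, seed: int
                          ) -> list[tuple[SpikeTrain, dict]]:
    """Generate ``n_units`` spike trains with ground-truth burst windows.

    Each unit has its own deterministic stream derived from ``(seed, index)``.
    The burst count is sampled by inverting the Poisson CDF on the stream's
    first uniform, so that for matched seeds a preset with a lower burst rate
    (cKO) never yields more ground-truth bursts than a higher-rate one (WT).
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    out = []
    for i in range(n_units):
        rng = _unit_rng(seed, i)
        # fixed draw order for cross-genotype coupling
        u_jit_burst, u_jit_bg, u_count = rng.random(3)
        jit_burst = float(np.exp(preset.unit_jitter_sd * stats.norm.ppf(u_jit_burst)))
        jit_bg = float(np.exp(preset.unit_jitter_sd * stats.norm.ppf(u_jit_bg)))
        mu_bursts = preset.burst_rate_per_100s * jit_burst * preset.duration / 100.0
        # quasi-periodic onset process (bursts follow recurring Ca2+ waves):
        # count dispersion is sub-Poisson, like a gamma renewal process of
        # shape ~3; the Gaussian-quantile form keeps the count monotone in
        # the rate for a fixed uniform, preserving WT >= cKO coupling
        if mu_bursts > 0:
            z = stats.norm.ppf(u_count)
            n_bursts = max(0, int(round(mu_bursts + z * np.sqrt(mu_bursts / 3.0))))
        else:
            n_bursts = 0

        # stratified onsets with jitter: evenly spread epochs, not clustered
        strata = (np.arange(n_bursts) + rng.uniform(0.1, 0.9, size=n_bursts))
        onsets = np.sort(strata * preset.duration / max(n_bursts, 1))
        burst_spikes = []
        windows = []
        for onset in onsets:
            s = _generate_burst(rng, onset, preset)
            s = s[s < preset.duration]
            if s.size:
                burst_spikes.append(s)
                windows.append((float(s[0]), float(s[-1])))

        bg_rate = preset.background_rate * jit_bg
        n_bg = rng.poisson(bg_rate * preset.duration)
        bg = rng.uniform(0.0, preset.duration, size=n_bg)

        all_spikes = np.sort(np.concatenate(burst_spikes + [bg])
                             if burst_spikes else bg)
        # enforce strictly increasing times at recording resolution
        if all_spikes.size:
            keep = np.concatenate([[True], np.diff(all_spikes) >= _MIN_SEP])
            all_spikes = all_spikes[keep]
        train = SpikeTrain(unit_id=f"{preset.label}-{i:02d}",
                           spike_times=all_spikes, duration=preset.duration)
        # windows merge when epochs overlap; the epoch count preserves the
        # rate ordering between genotypes even when long bursts coalesce
        truth = {"burst_windows": _merge_windows(windows),
                 "n_true_bursts": len(windows)}
        out.append((train, truth))
    return out
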