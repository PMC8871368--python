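"""Generators: determinism, ground-truth consistency, genotype ordering."""

import dataclasses

import numpy as np
import pytest

from prehear.imaging_events import compute_ratio
from prehear.synth import (generate_fra, generate_imaging_stack,
                           generate_input_map, generate_spike_trains,
                           load_preset)
from prehear.synth.presets import (FRAPreset, MapPreset, SpikeTrainPreset,
                                   WavePreset)


class TestDeterminism:
    def test_spike_trains_identical_under_seed(self):
        p = load_preset("spikes", "wt")
        a = generate_spike_trains(p, 4, seed=9)
        b = generate_spike_trains(p, 4, seed=9)
        for (ta, _), (tb, _) in zip(a, b):
            assert np.array_equal(ta.spike_times, tb.spike_times)

    def test_imaging_stack_identical_under_seed(self, small_wave_preset):
        p = dataclasses.replace(small_wave_preset, event_rate=0.05)
        (sa, _), (sb, _) = generate_imaging_stack(p, 5), generate_imaging_stack(p, 5)
        assert np.array_equal(sa.frames, sb.frames)

    def test_fra_and_map_identical_under_seed(self):
        fa, _ = generate_fra(load_preset("fra", "wt"), 3)
        fb, _ = generate_fra(load_preset("fra", "wt"), 3)
        assert np.array_equal(fa.counts, fb.counts)
        ma, _ = generate_input_map(load_preset("map", "wt"), 3)
        mb, _ = generate_input_map(load_preset("map", "wt"), 3)
        assert ma.sites.equals(mb.sites)


class TestSpikeGenerator:
    def test_zero_burst_rate_gives_pure_background(self):
        p = SpikeTrainPreset(burst_rate_per_100s=0.0, background_rate=2.0,
                             unit_jitter_sd=0.0)
        for train, truth in generate_spike_trains(p, 3, seed=1):
            assert truth["burst_windows"] == []
            assert train.n_spikes > 0

    def test_no_background_spikes_all_inside_burst_windows(self):
        p = SpikeTrainPreset(burst_rate_per_100s=3.0, background_rate=0.0,
                             unit_jitter_sd=0.0)
        for train, truth in generate_spike_trains(p, 5, seed=2):
            inside = np.zeros(train.n_spikes, bool)
            for lo, hi in truth["burst_windows"]:
                inside |= (train.spike_times >= lo - 1e-9) \
                    & (train.spike_times <= hi + 1e-9)
            assert inside.all()

    def test_invalid_preset_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrainPreset(background_rate=-1.0)
        with pytest.raises(ValueError):
            SpikeTrainPreset(duration=0.0)

    def test_spike_times_strictly_increasing_within_duration(self):
        p = load_preset("spikes", "wt")
        for train, _ in generate_spike_trains(p, 6, seed=4):
            assert np.all(np.diff(train.spike_times) > 0)
            assert train.spike_times[0] >= 0
            assert train.spike_times[-1] <= p.duration

    def test_genotype_burst_count_ordering(self):
        wt = load_preset("spikes", "wt")
        cko = load_preset("spikes", "cko")
        for seed in range(1, 6):
            a = generate_spike_trains(wt, 10, seed=seed)
            b = generate_spike_trains(cko, 10, seed=seed)
            for (_, twt), (_, tcko) in zip(a, b):
                assert twt["n_true_bursts"] >= tcko["n_true_bursts"]


class TestImagingGenerator:
    def test_zero_rate_noise_only(self, small_wave_preset):
        stack, truth = generate_imaging_stack(small_wave_preset, 1)
        assert truth["n_events"] == 0
        assert abs(stack.frames.mean() - 2000) < 20

    def test_forced_event_ground_truth_area(self, small_wave_preset):
        stack, truth = generate_imaging_stack(
            small_wave_preset, 1,
            forced_events=[{"area_um2": 200.0, "cx_um": 64.0, "cy_um": 64.0,
                            "t0": 20}])
        assert truth["n_events"] == 1
        # rasterized disc area within one pixel ring of the requested area
        assert truth["events"][0]["area_um2"] == pytest.approx(200.0, rel=0.2)

    def test_fura_ratio_carries_signal(self, small_wave_preset):
        p = dataclasses.replace(small_wave_preset, modality="fura_ratio")
        s340, s380, truth = generate_imaging_stack(
            p, 2, forced_events=[{"area_um2": 400.0, "cx_um": 64.0,
                                  "cy_um": 64.0, "t0": 20}])
        ratio = compute_ratio(s340, s380)
        peak = 20 + p.rise_frames + 1
        cy = cx = 32  # px
        assert ratio.frames[peak, cy, cx] > 1.25      # event pixel
        assert abs(ratio.frames[peak, 5, 5] - 1.0) < 0.1  # quiet pixel

    def test_band_must_fit_field(self):
        with pytest.raises(ValueError):
            WavePreset(shape=(32, 32), pixel_size=2.0,
                       band_rows_um=(10.0, 100.0))

    def test_genotype_event_load_ordering(self):
        wt = load_preset("imaging", "wt_ca")
        cko = load_preset("imaging", "cko_ca")
        for seed in range(1, 4):
            _, _, twt = generate_imaging_stack(wt, seed)
            _, _, tcko = generate_imaging_stack(cko, seed)
            a_wt = sum(e["area_um2"] for e in twt["events"])
            a_cko = sum(e["area_um2"] for e in tcko["events"])
            assert a_wt >= a_cko


class TestFRAGenerator:
    def test_flat_surface_has_no_truth_cf(self):
        p = FRAPreset(max_rate=5.0, spont_rate=5.0)
        _, truth = generate_fra(p, 1)
        assert truth["cf_khz"] is None

    def test_counts_scale_with_expected_rate(self):
        p = load_preset("fra", "wt")
        fra, truth = generate_fra(p, 5)
        assert fra.counts.max() > 10 * fra.counts[0].mean()

    def test_rejects_degenerate_grids(self):
        with pytest.raises(ValueError):
            FRAPreset(freqs_khz=(10.0, 10.0, 12.0))


class TestMapGenerator:
    def test_zero_profile_all_unresponsive(self):
        p = MapPreset(peak_mv=0.0, noise_sd_mv=0.0)
        umap, truth = generate_input_map(p, 1)
        assert (umap.sites["amplitude_mv"] <= 2.0).all()
        assert truth["responsive_sites"].size == 0

    def test_truth_matches_noiseless_classification(self):
        p = MapPreset(noise_sd_mv=0.0)
        umap, truth = generate_input_map(p, 2)
        resp = np.flatnonzero(umap.sites["amplitude_mv"] > 2.0)
        assert np.array_equal(resp, truth["responsive_sites"])

    def test_polygon_area_near_preset(self):
        p = load_preset("map", "wt")
        areas = [generate_input_map(p, s)[1]["polygon_area_um2"]
                 for s in range(8)]
        assert np.mean(areas) == pytest.approx(63000, rel=0.12)
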