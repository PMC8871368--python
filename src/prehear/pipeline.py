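"""End-to-end orchestration: synthesize cohorts, analyze, compare, report.

``run_all`` reproduces the full two-genotype study at the original cohort
sizes: spontaneous MNTB spike trains (14 WT / 15 cKO, 100 s), Fura-2 ratio
stacks (14/16, 400 frames), DIC stacks (7/9, 1200 frames), frequency
response areas (25/32) and MNTB-LSO uncaging maps (10/10).  Everything is
deterministic under the root seed; each cohort member draws its own stream
from (root seed, cohort tag, index).
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .fra_tuning import NoResponseError, analyze_fra
from .group_compare import build_report
from .imaging_events import (DetectionConfig, compute_ratio,
                             default_baseline_roi, detect_events,
                             measure_baseline, moving_average_subtract,
                             summarize_events)
from .input_map import analyze_map
from .spike_burst import burst_metrics, compare_isi_distributions, \
    compute_isis, detect_bursts, pool_isis
from .synth import (generate_fra, generate_imaging_stack, generate_input_map,
                    generate_spike_trains, load_preset)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all",
           "spike_cohort_metrics", "imaging_cohort_metrics",
           "fra_cohort_metrics", "map_cohort_metrics"]


@dataclass
class RunConfig:
    """Cohort sizes and seeding for a full run (defaults: study sizes)."""

    seed: int = 1
    n_spikes_wt: int = 14
    n_spikes_cko: int = 15
    n_ca_wt: int = 14
    n_ca_cko: int = 16
    n_dic_wt: int = 7
    n_dic_cko: int = 9
    n_fra_wt: int = 25
    n_fra_cko: int = 32
    n_maps_wt: int = 10
    n_maps_cko: int = 10
    out_dir: str | Path = "results/run"
    write_raw: bool = False
    preset_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name.startswith("n_") and getattr(self, f.name) < 1:
                raise ValueError(f"{f.name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def overrides(self, modality: str, genotype: str) -> dict:
        return self.preset_overrides.get(f"{modality}_{genotype}", {})


def _sub_seed(seed: int, tag: str) -> int:
    """Stable derived seed < 2**31 for one cohort (process-independent)."""
    h = np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())])
    return int(h.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------- spikes

def spike_cohort_metrics(genotype: str, n_units: int, seed: int,
                         overrides: dict | None = None) -> dict:
    """Generate one spike cohort and push it through the burst pipeline."""
    preset = load_preset("spikes", genotype, **(overrides or {}))
    trains = generate_spike_trains(preset, n_units, seed=seed)
    per_unit, pooled = [], {"spikes_per_burst": [], "burst_durations": [],
                            "within_burst_rates": []}
    isis = []
    for train, truth in trains:
        bs = detect_bursts(train)
        m = burst_metrics(bs)
        per_unit.append({"unit_id": m["unit_id"], "cv": m["cv"],
                         "bursts_per_100s": m["bursts_per_100s"],
                         "mean_rate": m["mean_rate"],
                         "median_isi": m["median_isi"],
                         "n_true_bursts": truth["n_true_bursts"]})
        for k in pooled:
            pooled[k].extend(m[k])
        isis.append(compute_isis(train))
    return {"per_unit": pd.DataFrame(per_unit), "pooled": pooled,
            "isis": isis, "trains": trains}


# --------------------------------------------------------------- imaging

def analyze_stack(stack_or_pair, config: DetectionConfig | None = None):
    """Baseline, moving-average subtraction and event detection for one stack."""
    if isinstance(stack_or_pair, tuple):
        stack = compute_ratio(*stack_or_pair)
    else:
        stack = stack_or_pair
    config = config or DetectionConfig()
    baseline = measure_baseline(stack, config.baseline_roi
                                or default_baseline_roi(stack))
    delta = moving_average_subtract(stack, config.window)
    events = detect_events(delta, baseline, config)
    summary = summarize_events(events, stack.duration)
    return events, summary


def imaging_cohort_metrics(preset_key: str, n_stacks: int, seed: int,
                           overrides: dict | None = None) -> pd.DataFrame:
    preset = load_preset("imaging", preset_key, **(overrides or {}))
    rows = []
    for i in range(n_stacks):
        out = generate_imaging_stack(preset, seed=_sub_seed(seed, f"{preset_key}-{i}"))
        if preset.modality == "fura_ratio":
            s340, s380, truth = out
            events, summary = analyze_stack((s340, s380))
        else:
            stack, truth = out
            events, summary = analyze_stack(stack)
        rows.append({"stack": i, "n_events": summary.n_events,
                     "mean_area_um2": summary.mean_area_um2,
                     "frequency_hz": summary.frequency_hz,
                     "n_true_events": truth["n_events"]})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- FRA

def fra_cohort_metrics(genotype: str, n_units: int, seed: int,
                       overrides: dict | None = None) -> pd.DataFrame:
    """FRA cohort with per-unit CF scatter (snapped to the frequency grid)."""
    base = load_preset("fra", genotype, **(overrides or {}))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF2)))
    freqs = np.asarray(base.freqs_khz)
    rows = []
    for i in range(n_units):
        cf = float(np.clip(rng.lognormal(np.log(base.cf_khz), 0.30),
                           freqs[2], freqs[-3]))
        cf = float(freqs[np.argmin(np.abs(freqs - cf))])
        thr = float(np.clip(rng.normal(base.threshold_db, 4.0), 0.0, 30.0))
        sharp = float(np.exp(rng.normal(0.0, 0.25)))  # per-unit tuning spread
        preset = dataclasses.replace(base, cf_khz=cf, threshold_db=thr,
                                     slope_low=base.slope_low * sharp,
                                     slope_high=base.slope_high * sharp)
        fra, truth = generate_fra(preset, seed=_sub_seed(seed, f"fra{genotype}{i}"))
        try:
            m = analyze_fra(fra)
        except NoResponseError:
            logger.warning("unit %d: no response region; skipped", i)
            continue
        rows.append({"unit": i, "cf_khz": m.cf_khz,
                     "threshold_db": m.threshold_db,
                     "q10": m.q.get(10), "q20": m.q.get(20), "q30": m.q.get(30),
                     "max_rate": m.max_rate,
                     "true_cf_khz": truth["cf_khz_grid"],
                     "true_threshold_db": truth["threshold_db_grid"]})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ maps

def map_cohort_metrics(genotype: str, n_maps: int, seed: int,
                       overrides: dict | None = None) -> pd.DataFrame:
    preset = load_preset("map", genotype, **(overrides or {}))
    rows = []
    for i in range(n_maps):
        umap, truth = generate_input_map(preset, seed=_sub_seed(seed, f"map{genotype}{i}"))
        m = analyze_map(umap)
        rows.append({"map": i, "input_area_pct": m.input_area_pct,
                     "input_width_pct": m.input_width_pct,
                     "n_responsive": m.n_responsive, "n_strong": m.n_strong,
                     "mntb_area_um2": m.mntb_area_um2})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- run_all

def run_all(config: RunConfig) -> dict:
    """Full two-genotype study; returns the result bundle and writes tables.

    A failure in one modality aborts only that modality (logged), so a
    partial report is still produced.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    bundle: dict = {"config": dataclasses.asdict(config)}
    metrics_for_report: dict[str, dict] = {}

    # -- spontaneous spiking -------------------------------------------
    try:
        wt = spike_cohort_metrics("wt", config.n_spikes_wt, config.seed,
                                  config.overrides("spikes", "wt"))
        cko = spike_cohort_metrics("cko", config.n_spikes_cko, config.seed + 1,
                                   config.overrides("spikes", "cko"))
        wt["per_unit"].to_csv(out / "spikes_wt_units.csv", index=False)
        cko["per_unit"].to_csv(out / "spikes_cko_units.csv", index=False)
        pooled = pool_isis({"wt": wt["isis"], "cko": cko["isis"]},
                           seed=_sub_seed(config.seed, "pool"))
        isi_cmp = compare_isi_distributions(pooled["wt"], pooled["cko"])
        bundle["spikes"] = {"wt": wt, "cko": cko,
                            "isi_comparison": {k: isi_cmp[k] for k in
                                               ("ks_D", "ks_p", "chi2", "chi2_p")}}
        metrics_for_report.update({
            "CV of ISIs": {"a": wt["per_unit"]["cv"], "b": cko["per_unit"]["cv"],
                           "test": "mann_whitney"},
            "bursts per 100 s": {"a": wt["per_unit"]["bursts_per_100s"],
                                 "b": cko["per_unit"]["bursts_per_100s"],
                                 "test": "mann_whitney"},
            "spikes per burst": {"a": wt["pooled"]["spikes_per_burst"],
                                 "b": cko["pooled"]["spikes_per_burst"],
                                 "test": "mann_whitney"},
            "burst duration (s)": {"a": wt["pooled"]["burst_durations"],
                                   "b": cko["pooled"]["burst_durations"],
                                   "test": "mann_whitney"},
            "within-burst rate (AP/s)": {"a": wt["pooled"]["within_burst_rates"],
                                         "b": cko["pooled"]["within_burst_rates"],
                                         "test": "mann_whitney"},
            "mean firing rate (Hz)": {"a": wt["per_unit"]["mean_rate"],
                                      "b": cko["per_unit"]["mean_rate"],
                                      "test": "unpaired_t"},
        })
        if config.write_raw:
            pio.write_spike_csv([t for t, _ in wt["trains"]], out / "spikes_wt.csv")
            pio.write_spike_csv([t for t, _ in cko["trains"]], out / "spikes_cko.csv")
    except Exception:
        logger.exception("spike modality failed; continuing")

    # -- imaging -------------------------------------------------------
    try:
        tables = {}
        for key, n in (("wt_ca", config.n_ca_wt), ("cko_ca", config.n_ca_cko),
                       ("wt_dic", config.n_dic_wt), ("cko_dic", config.n_dic_cko)):
            tables[key] = imaging_cohort_metrics(key, n, config.seed,
                                                 config.overrides("imaging", key))
            tables[key].to_csv(out / f"imaging_{key}.csv", index=False)
        bundle["imaging"] = tables
        metrics_for_report.update({
            "Ca2+ event area (um^2)": {"a": tables["wt_ca"]["mean_area_um2"],
                                       "b": tables["cko_ca"]["mean_area_um2"],
                                       "test": "unpaired_t"},
            "Ca2+ event frequency (Hz)": {"a": tables["wt_ca"]["frequency_hz"],
                                          "b": tables["cko_ca"]["frequency_hz"],
                                          "test": "unpaired_t"},
            "volume-change area (um^2)": {"a": tables["wt_dic"]["mean_area_um2"],
                                          "b": tables["cko_dic"]["mean_area_um2"],
                                          "test": "unpaired_t"},
            "volume-change frequency (Hz)": {"a": tables["wt_dic"]["frequency_hz"],
                                             "b": tables["cko_dic"]["frequency_hz"],
                                             "test": "unpaired_t"},
        })
    except Exception:
        logger.exception("imaging modality failed; continuing")

    # -- frequency response areas --------------------------------------
    try:
        fra_wt = fra_cohort_metrics("wt", config.n_fra_wt, config.seed,
                                    config.overrides("fra", "wt"))
        fra_cko = fra_cohort_metrics("cko", config.n_fra_cko, config.seed + 1,
                                     config.overrides("fra", "cko"))
        fra_wt.to_csv(out / "fra_wt.csv", index=False)
        fra_cko.to_csv(out / "fra_cko.csv", index=False)
        bundle["fra"] = {"wt": fra_wt, "cko": fra_cko}
        for qn in ("q10", "q20", "q30"):
            metrics_for_report[f"{qn.upper()}"] = {
                "a": fra_wt[qn].dropna(), "b": fra_cko[qn].dropna(),
                "test": "mann_whitney"}
        metrics_for_report["unit threshold (dB SPL)"] = {
            "a": fra_wt["threshold_db"], "b": fra_cko["threshold_db"],
            "test": "mann_whitney"}
        metrics_for_report["max evoked rate (AP/s)"] = {
            "a": fra_wt["max_rate"], "b": fra_cko["max_rate"],
            "test": "unpaired_t"}
    except Exception:
        logger.exception("FRA modality failed; continuing")

    # -- input maps ----------------------------------------------------
    try:
        maps_wt = map_cohort_metrics("wt", config.n_maps_wt, config.seed,
                                     config.overrides("map", "wt"))
        maps_cko = map_cohort_metrics("cko", config.n_maps_cko, config.seed + 1,
                                      config.overrides("map", "cko"))
        maps_wt.to_csv(out / "maps_wt.csv", index=False)
        maps_cko.to_csv(out / "maps_cko.csv", index=False)
        bundle["maps"] = {"wt": maps_wt, "cko": maps_cko}
        metrics_for_report["MNTB input area (%)"] = {
            "a": maps_wt["input_area_pct"], "b": maps_cko["input_area_pct"],
            "test": "unpaired_t"}
        metrics_for_report["MNTB input width (%)"] = {
            "a": maps_wt["input_width_pct"], "b": maps_cko["input_width_pct"],
            "test": "unpaired_t"}
    except Exception:
        logger.exception("map modality failed; continuing")

    report = build_report(metrics_for_report)
    report.to_csv(out / "report.csv", index=False)
    (out / "report.md").write_text(report.to_markdown(index=False)
                                   if len(report) else "(empty report)\n")
    bundle["report"] = report
    logger.info("run_all finished in %.1f s", time.time() - t0)
    return bundle
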