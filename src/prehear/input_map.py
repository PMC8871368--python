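"""MNTB-LSO functional input-map quantification from uncaging grids.

Each uncaging site carries the peak postsynaptic potential (PSP) it evoked
in the recorded LSO neuron.  Sites are classified by amplitude (> 2 mV
responsive, > 10 mV strong, action potential), the summed area of
responsive sites is normalized to the MNTB cross-sectional area, and the
maximal mediolateral extent of strong sites is normalized to the MNTB's
mediolateral length (the tonotopic axis, mapped to x).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "SiteClass",
    "UncagingMap",
    "InputMapMetrics",
    "extract_psp",
    "classify_site",
    "classify_map",
    "input_area",
    "input_width",
    "analyze_map",
]


class SiteClass(IntEnum):
    """Ordered response classes of an uncaging site."""

    UNRESPONSIVE = 0
    RESPONSIVE_2MV = 1      # depolarization > 2 mV
    RESPONSIVE_10MV = 2     # depolarization > 10 mV
    ACTION_POTENTIAL = 3


@dataclass(frozen=True)
class UncagingMap:
    """Grid of uncaging sites plus the MNTB outline polygon.

    ``sites`` columns: site_id, x_um, y_um, amplitude_mv, ap_flag.
    The mediolateral (tonotopic) axis is x; maps are expected pre-rotated
    (set ``swap_axes`` when the tonotopic axis runs along y instead).
    """

    sites: pd.DataFrame
    polygon: Polygon
    grid_spacing: float = 20.0
    swap_axes: bool = False

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if len(self.sites) == 0:
            raise ValueError("empty uncaging grid")
        required = {"x_um", "y_um", "amplitude_mv", "ap_flag"}
        if not required.issubset(self.sites.columns):
            raise ValueError(f"sites table needs columns {sorted(required)}")
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError("MNTB outline must be a simple closed polygon")
        if self.swap_axes:
            s = self.sites.rename(columns={"x_um": "y_um", "y_um": "x_um"})
            object.__setattr__(self, "sites", s)
            x, y = self.polygon.exterior.xy
            object.__setattr__(self, "polygon", Polygon(zip(y, x)))
            object.__setattr__(self, "swap_axes", False)

    @property
    def site_area(self) -> float:
        return self.grid_spacing ** 2


@dataclass(frozen=True)
class InputMapMetrics:
    input_area_pct: float
    input_width_pct: float
    n_responsive: int
    n_strong: int
    mntb_area_um2: float
    mntb_ml_length_um: float


def extract_psp(trace_mv: np.ndarray, fs_hz: float, laser_onset_s: float,
                window_s: float = 0.020, baseline_s: float = 0.050,
                ap_criterion_mv: float = 0.0) -> tuple[float, bool]:
    """Peak depolarization from pre-onset baseline in the response window.

    The baseline is the mean of the 50 ms preceding laser onset; the
    response window is 20 ms from onset.  ``ap_flag`` is set when the
    trace overshoots ``ap_criterion_mv`` (0 mV absolute by default).
    """
    trace = np.asarray(trace_mv, dtype=float)
    i_on = int(round(laser_onset_s * fs_hz))
    i_end = int(round((laser_onset_s + window_s) * fs_hz))
    i_base = int(round((laser_onset_s - baseline_s) * fs_hz))
    if i_base < 0 or i_end > trace.size:
        raise ValueError("analysis window extends outside the trace")
    baseline = float(trace[i_base:i_on].mean()) if i_on > i_base else float(trace[i_on])
    seg = trace[i_on:i_end]
    amplitude = float(seg.max() - baseline)
    ap_flag = bool(seg.max() > ap_criterion_mv)
    return max(amplitude, 0.0), ap_flag


def classify_site(amplitude_mv: float, ap_flag: bool) -> SiteClass:
    """AP beats amplitude; thresholds are strict (2.0 mV is unresponsive)."""
    if ap_flag:
        return SiteClass.ACTION_POTENTIAL
    if amplitude_mv > 10.0:
        return SiteClass.RESPONSIVE_10MV
    if amplitude_mv > 2.0:
        return SiteClass.RESPONSIVE_2MV
    return SiteClass.UNRESPONSIVE


def classify_map(umap: UncagingMap) -> np.ndarray:
    return np.array([classify_site(a, f) for a, f in
                     zip(umap.sites["amplitude_mv"], umap.sites["ap_flag"])])


def input_area(umap: UncagingMap, classes: np.ndarray) -> float:
    """Summed responsive-site area as % of the MNTB cross-sectional area.

    Responsive sites slightly outside the outline still count, matching the
    mapping convention that occasional dorsal/ventral responses are kept.
    """
    if umap.polygon.area <= 0:
        raise ValueError("degenerate MNTB polygon")
    n_resp = int(np.sum(classes >= SiteClass.RESPONSIVE_2MV))
    return 100.0 * n_resp * umap.site_area / umap.polygon.area


def input_width(umap: UncagingMap, classes: np.ndarray) -> float:
    """Max mediolateral separation of strong (>10 mV or AP) sites, as % of
    the MNTB's mediolateral (x) extent.  One or zero qualifying sites give 0.
    """
    x0, _, x1, _ = umap.polygon.bounds
    extent = x1 - x0
    if extent <= 0:
        raise ValueError("MNTB polygon has no mediolateral extent")
    strong = classes >= SiteClass.RESPONSIVE_10MV
    if strong.sum() <= 1:
        return 0.0
    xs = umap.sites["x_um"].to_numpy()[strong]
    return 100.0 * float(xs.max() - xs.min()) / extent


def analyze_map(umap: UncagingMap) -> InputMapMetrics:
    classes = classify_map(umap)
    x0, _, x1, _ = umap.polygon.bounds
    return InputMapMetrics(
        input_area_pct=input_area(umap, classes),
        input_width_pct=input_width(umap, classes),
        n_responsive=int(np.sum(classes >= SiteClass.RESPONSIVE_2MV)),
        n_strong=int(np.sum(classes >= SiteClass.RESPONSIVE_10MV)),
        mntb_area_um2=float(umap.polygon.area),
        mntb_ml_length_um=float(x1 - x0),
    )
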