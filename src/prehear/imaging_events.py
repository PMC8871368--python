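"""Event detection on DIC and Fura-2 ratio time-lapse stacks.

The detection scheme mirrors common practice for slow spontaneous epithelial
events: each frame is compared against the average of the five preceding
frames (so slow drift and static structure cancel), pixels whose increase
exceeds 10% of a baseline level measured in a quiet region become active,
per-frame 8-connected components are linked across frames into
spatiotemporal events, and events smaller than the area of a single inner
supporting cell are discarded.  Areas and frequencies are summarized inside
a fixed analysis region of interest (10,000 um^2 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ImagingStack",
    "Rect",
    "DetectionConfig",
    "EventSummary",
    "compute_ratio",
    "moving_average_subtract",
    "measure_baseline",
    "detect_events",
    "summarize_events",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ImagingStack:
    """Calibrated frame sequence, indexed (frame, row, column)."""

    frames: np.ndarray
    pixel_size: float        # um / px
    frame_interval: float    # s
    modality: str

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        object.__setattr__(self, "frames", f)
        if f.ndim != 3:
            raise ValueError("frames must be (frame, row, col)")
        if f.shape[0] < 6:
            raise ValueError("need at least 6 frames (subtraction window + 1)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.frames.shape[1] * self.pixel_size,
                self.frames.shape[2] * self.pixel_size)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in physical units (um)."""

    row_min: float
    row_max: float
    col_min: float
    col_max: float

    def to_slices(self, pixel_size: float) -> tuple[slice, slice]:
        r0 = int(np.floor(self.row_min / pixel_size))
        r1 = int(np.ceil(self.row_max / pixel_size))
        c0 = int(np.floor(self.col_min / pixel_size))
        c1 = int(np.ceil(self.col_max / pixel_size))
        return slice(r0, r1), slice(c0, c1)

    def contains(self, x_um: float, y_um: float) -> bool:
        return (self.col_min <= x_um <= self.col_max
                and self.row_min <= y_um <= self.row_max)

    @staticmethod
    def centered_square(stack: "ImagingStack", area_um2: float = 10_000.0) -> "Rect":
        h, w = stack.field_um
        side = np.sqrt(area_um2)
        return Rect((h - side) / 2, (h + side) / 2,
                    (w - side) / 2, (w + side) / 2)


@dataclass(frozen=True)
class DetectionConfig:
    window: int = 5
    threshold_fraction: float = 0.10
    min_area_um2: float = 50.0        # one-ISC surface area
    baseline_roi: Rect | None = None  # default: quiet strip at the top
    analysis_roi: Rect | None = None  # default: centered 10,000 um^2 square
    analysis_roi_area_um2: float = 10_000.0
    gap_frames: int = 1               # temporal bridging of flicker

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.min_area_um2 <= 0:
            raise ValueError("min_area_um2 must be positive")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def compute_ratio(stack340: ImagingStack, stack380: ImagingStack,
                  floor: float = 1.0) -> ImagingStack:
    """Per-pixel 340/380 ratio; denominators <= ``floor`` are masked (NaN)."""
    if stack340.frames.shape != stack380.frames.shape:
        raise ValueError("channel stacks must have matching shapes")
    if (stack340.pixel_size != stack380.pixel_size
            or stack340.frame_interval != stack380.frame_interval):
        raise ValueError("channel stacks must share calibration metadata")
    num = stack340.frames.astype(np.float64)
    den = stack380.frames.astype(np.float64)
    ratio = np.where(den > floor, num / np.where(den > floor, den, 1.0), np.nan)
    return ImagingStack(ratio, stack340.pixel_size, stack340.frame_interval,
                        "fura_ratio")


def moving_average_subtract(stack: ImagingStack, window: int = 5) -> ImagingStack:
    """Delta_n = F_n - mean(F_{n-1} .. F_{n-window}); first frames are NaN.

    The first ``window`` frames have no complete preceding window and are
    excluded from downstream detection by marking them NaN.
    """
    f = stack.frames.astype(np.float64)
    n = f.shape[0]
    if n <= window:
        raise ValueError("need more frames than the averaging window")
    csum = np.cumsum(f, axis=0)
    delta = np.full_like(f, np.nan)
    # mean of frames [n-window, n-1] = (csum[n-1] - csum[n-window-1]) / window
    upper = csum[window - 1:n - 1]
    lower = np.concatenate([np.zeros_like(f[:1]), csum[: n - window - 1]])
    delta[window:] = f[window:] - (upper - lower) / window
    return ImagingStack(delta, stack.pixel_size, stack.frame_interval,
                        stack.modality)


def measure_baseline(stack: ImagingStack, baseline_roi: Rect) -> float:
    """Temporal-and-spatial mean intensity (or ratio) inside a quiet ROI."""
    rs, cs = baseline_roi.to_slices(stack.pixel_size)
    region = stack.frames[:, rs, cs]
    if region.size == 0:
        raise ValueError("baseline ROI is empty or outside the field")
    h, w = stack.frames.shape[1:]
    if not (0 <= rs.start < rs.stop <= h and 0 <= cs.start < cs.stop <= w):
        raise ValueError("baseline ROI extends outside the field")
    return float(np.nanmean(region))


def default_baseline_roi(stack: ImagingStack, depth_um: float = 20.0) -> Rect:
    """Quiet strip across the top of the field (outside the ISC band)."""
    return Rect(0.0, depth_um, 0.0, stack.field_um[1])


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, a):
        p = self.parent.setdefault(a, a)
        if p != a:
            self.parent[a] = p = self.find(p)
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def detect_events(delta: ImagingStack, baseline: float,
                  config: DetectionConfig | None = None) -> pd.DataFrame:
    """Assemble spatiotemporal events from a subtracted stack.

    Active pixels exceed ``threshold_fraction * baseline``; per-frame
    8-connected components are linked into events when they overlap in
    space on consecutive frames (gaps up to ``gap_frames`` are bridged,
    since near-threshold events flicker).  An event is kept iff its maximum
    instantaneous component area reaches ``min_area_um2``; the reported
    area is that maximum, the centroid is taken at the peak frame.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    config = config or DetectionConfig()
    px = delta.pixel_size
    px_area = px * px
    thresh = config.threshold_fraction * baseline
    active = delta.frames > thresh  # NaN compares False

    uf = _UnionFind()
    frame_labels: list[np.ndarray] = []
    n_comps: list[int] = []
    for t in range(active.shape[0]):
        lab, n = ndimage.label(active[t], structure=_EIGHT)
        frame_labels.append(lab)
        n_comps.append(n)
        for c in range(1, n + 1):
            uf.find((t, c))

    for t in range(1, active.shape[0]):
        for back in range(1, config.gap_frames + 2):
            t0 = t - back
            if t0 < 0:
                break
            a, b = frame_labels[t0], frame_labels[t]
            both = (a > 0) & (b > 0)
            if not both.any():
                continue
            pairs = np.unique(np.stack([a[both], b[both]]), axis=1)
            for ca, cb in pairs.T:
                uf.union((t0, int(ca)), (t, int(cb)))

    groups: dict = {}
    for t, n in enumerate(n_comps):
        if n == 0:
            continue
        areas = ndimage.sum_labels(np.ones_like(frame_labels[t]),
                                   frame_labels[t], index=np.arange(1, n + 1))
        peaks = ndimage.maximum(np.nan_to_num(delta.frames[t], nan=-np.inf),
                                frame_labels[t], index=np.arange(1, n + 1))
        for c in range(1, n + 1):
            root = uf.find((t, c))
            g = groups.setdefault(root, {"frames": [], "areas": [],
                                         "peaks": [], "labels": []})
            g["frames"].append(t)
            g["areas"].append(float(areas[c - 1]) * px_area)
            g["peaks"].append(float(peaks[c - 1]))
            g["labels"].append((t, c))

    analysis_roi = config.analysis_roi or Rect.centered_square(
        delta, config.analysis_roi_area_um2)

    records = []
    for eid, g in enumerate(groups.values()):
        imax = int(np.argmax(g["areas"]))
        max_area = g["areas"][imax]
        if max_area < config.min_area_um2:
            continue
        t_peak, c_peak = g["labels"][imax]
        mask = frame_labels[t_peak] == c_peak
        cy, cx = ndimage.center_of_mass(mask)
        x_um, y_um = cx * px, cy * px
        records.append({
            "event_id": eid,
            "onset_frame": int(min(g["frames"])),
            "offset_frame": int(max(g["frames"])),
            "area_um2": max_area,
            "centroid_x_um": x_um,
            "centroid_y_um": y_um,
            "peak_rel_amplitude": max(g["peaks"]) / baseline,
            "in_analysis_roi": analysis_roi.contains(x_um, y_um),
        })
    cols = ["event_id", "onset_frame", "offset_frame", "area_um2",
            "centroid_x_um", "centroid_y_um", "peak_rel_amplitude",
            "in_analysis_roi"]
    df = pd.DataFrame.from_records(records, columns=cols)
    return df.sort_values("onset_frame").reset_index(drop=True)


@dataclass(frozen=True)
class EventSummary:
    n_events: int
    mean_area_um2: float
    frequency_hz: float
    duration_s: float


def summarize_events(events: pd.DataFrame, duration: float,
                     roi_only: bool = True) -> EventSummary:
    """Mean event area and frequency (events/s); zero-event case yields 0s."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if roi_only and len(events):
        events = events[events["in_analysis_roi"]]
    n = len(events)
    mean_area = float(events["area_um2"].mean()) if n else 0.0
    return EventSummary(n, mean_area, n / duration, duration)
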