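"""Readers and writers for the pipeline's on-disk formats.

Spike tables, FRA matrices and uncaging maps travel as plain CSV; imaging
stacks as multi-page 16-bit TIFF with a JSON sidecar carrying pixel size,
frame interval and modality; ground truth and metrics as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fra_tuning import FRAMatrix
from .imaging_events import ImagingStack
from .input_map import UncagingMap
from .spike_burst import SpikeTrain

__all__ = [
    "write_spike_csv", "read_spike_csv",
    "write_stack", "read_stack",
    "write_fra_csv", "read_fra_csv",
    "write_map_csv", "read_map_csv",
    "write_json", "read_json",
]


def write_spike_csv(trains: list[SpikeTrain], path) -> None:
    rows = [(t.unit_id, ts) for t in trains for ts in t.spike_times]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)


def read_spike_csv(path, duration: float) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [SpikeTrain(str(uid), np.sort(g["time_s"].to_numpy()), duration)
            for uid, g in df.groupby("unit_id", sort=False)]


def write_stack(stack: ImagingStack, path) -> None:
    path = Path(path)
    frames = stack.frames
    if frames.dtype != np.uint16:
        frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames)
    sidecar = {"pixel_size_um": stack.pixel_size,
               "frame_interval_s": stack.frame_interval,
               "modality": stack.modality}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path) -> ImagingStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ImagingStack(tifffile.imread(path), meta["pixel_size_um"],
                        meta["frame_interval_s"], meta["modality"])


def write_fra_csv(fra: FRAMatrix, path) -> None:
    df = pd.DataFrame(fra.counts, index=fra.levels_db, columns=fra.freqs_khz)
    df.index.name = "level_db"
    df.to_csv(path)


def read_fra_csv(path, reps: int = 1, window_s: float = 0.1) -> FRAMatrix:
    df = pd.read_csv(path, index_col=0)
    return FRAMatrix(df.columns.to_numpy(float), df.index.to_numpy(float),
                     df.to_numpy(float), reps=reps, window_s=window_s)


def write_map_csv(umap: UncagingMap, sites_path, polygon_path) -> None:
    cols = ["site_id", "x_um", "y_um", "amplitude_mv", "ap_flag"]
    umap.sites[cols].to_csv(sites_path, index=False)
    x, y = umap.polygon.exterior.xy
    pd.DataFrame({"x_um": x, "y_um": y}).to_csv(polygon_path, index=False)


def read_map_csv(sites_path, polygon_path, grid_spacing: float = 20.0) -> UncagingMap:
    from shapely.geometry import Polygon

    sites = pd.read_csv(sites_path)
    poly = pd.read_csv(polygon_path)
    return UncagingMap(sites=sites,
                       polygon=Polygon(zip(poly["x_um"], poly["y_um"])),
                       grid_spacing=grid_spacing)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder))


def read_json(path):
    return json.loads(Path(path).read_text())
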