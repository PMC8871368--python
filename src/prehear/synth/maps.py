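"""Uncaging-map generator: elliptical MNTB outline + Gaussian input focus."""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from ..input_map import UncagingMap
from .presets import MapPreset

__all__ = ["generate_input_map"]


def _ellipse_polygon(cx: float, cy: float, a: float, b: float, n: int) -> Polygon:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return Polygon(zip(cx + a * np.cos(th), cy + b * np.sin(th)))


def _profile_sigmas(preset: MapPreset, poly_area: float, ml_extent: float
                    ) -> tuple[float, float]:
    """Gaussian widths whose 2 mV contour hits the fractional-area target
    and whose 10 mV contour spans the mediolateral-width target."""
    A = preset.peak_mv
    if A <= 2.0:
        return 0.0, 0.0
    c2 = np.sqrt(2.0 * np.log(A / 2.0))
    if A > 10.0:
        half10 = (preset.width_frac_target * ml_extent + preset.width_pad_um) / 2.0
        sigma_x = half10 / np.sqrt(2.0 * np.log(A / 10.0))
    else:
        sigma_x = np.sqrt(preset.frac_area_target * poly_area / np.pi) / c2
    target_area = preset.frac_area_target * poly_area
    sigma_y = target_area / (np.pi * (sigma_x * c2) * c2)
    return float(sigma_x), float(sigma_y)


def generate_input_map(preset: MapPreset, seed: int) -> tuple[UncagingMap, dict]:
    """One synthetic MNTB-LSO input map with ground truth.

    The MNTB outline is an ellipse (area lognormally jittered per map) and
    the PSP-amplitude profile an anisotropic Gaussian centered on it, so
    the responsive (>2 mV) contour covers ``frac_area_target`` of the
    outline and the strong (>10 mV) contour spans ``width_frac_target`` of
    its mediolateral length.  The uncaging grid has a random sub-spacing
    origin offset, as real grids are placed without reference to the
    outline.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x3A)))
    scale = float(np.exp(rng.normal(0.0, preset.area_jitter_sd)))
    poly_area = preset.mntb_area_um2 * scale
    a = np.sqrt(poly_area * preset.mntb_aspect / np.pi)   # mediolateral semi-axis
    b = a / preset.mntb_aspect
    margin = 2 * preset.grid_spacing
    cx, cy = a + margin, b + margin
    polygon = _ellipse_polygon(cx, cy, a, b, preset.n_polygon_vertices)

    sigma_x, sigma_y = _profile_sigmas(preset, poly_area, 2 * a)

    sp = preset.grid_spacing
    off_x, off_y = rng.uniform(0.0, sp, size=2)
    xs = np.arange(off_x, cx + a + margin + sp, sp)
    ys = np.arange(off_y, cy + b + margin + sp, sp)
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    if gx.size == 0:
        raise ValueError("empty uncaging grid")

    if sigma_x > 0 and sigma_y > 0:
        clean = preset.peak_mv * np.exp(-((gx - cx) ** 2 / (2 * sigma_x ** 2)
                                          + (gy - cy) ** 2 / (2 * sigma_y ** 2)))
    else:
        clean = np.zeros_like(gx)
    noisy = np.clip(clean + rng.normal(0.0, preset.noise_sd_mv, size=gx.size),
                    0.0, None)
    ap_flag = noisy > preset.ap_threshold_mv

    sites = pd.DataFrame({
        "site_id": np.arange(gx.size),
        "x_um": gx,
        "y_um": gy,
        "amplitude_mv": noisy,
        "ap_flag": ap_flag,
    })
    umap = UncagingMap(sites=sites, polygon=polygon, grid_spacing=sp)
    truth = {
        "responsive_sites": np.flatnonzero(clean > 2.0),
        "strong_sites": np.flatnonzero(clean > 10.0),
        "ap_sites": np.flatnonzero(ap_flag),
        "polygon_area_um2": float(polygon.area),
        "ml_extent_um": 2 * a,
        "frac_area_target": preset.frac_area_target,
        "width_frac_target": preset.width_frac_target,
    }
    return umap, truth
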