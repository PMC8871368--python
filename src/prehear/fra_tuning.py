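"""Frequency-response-area metrics: CF, threshold, Q-factors, rate-level.

A frequency response area (FRA) is a matrix of spike counts over a tone
frequency x sound level grid.  The characteristic frequency (CF) is the
frequency exciting the unit at the lowest level; sharpness of tuning is
quantified by Q_n = CF / BW_n with BW_n the significant bandwidth n dB
above threshold.  Bandwidths are reported at grid resolution (outer
significant columns of the span containing CF), with linear interpolation
between level rows when threshold + n falls off the level grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FRAMatrix",
    "TuningMetrics",
    "NoResponseError",
    "significant_mask",
    "find_cf_threshold",
    "q_factors",
    "rate_level_and_max",
    "analyze_fra",
]


class NoResponseError(ValueError):
    """Raised when an FRA contains no significant response region."""


@dataclass(frozen=True)
class FRAMatrix:
    """Spike counts per (level, frequency) bin with stimulus metadata."""

    freqs_khz: np.ndarray
    levels_db: np.ndarray
    counts: np.ndarray        # shape (n_levels, n_freqs)
    reps: int = 1
    window_s: float = 0.1
    spont_rate: float | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_khz, float)
        lv = np.asarray(self.levels_db, float)
        c = np.asarray(self.counts, float)
        object.__setattr__(self, "freqs_khz", f)
        object.__setattr__(self, "levels_db", lv)
        object.__setattr__(self, "counts", c)
        if np.any(np.diff(f) <= 0) or np.any(np.diff(lv) <= 0):
            raise ValueError("grids must be strictly increasing")
        if c.shape != (lv.size, f.size):
            raise ValueError("counts must be (n_levels, n_freqs)")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")

    @property
    def rates(self) -> np.ndarray:
        """Firing rate per bin (AP/s)."""
        return self.counts / (self.reps * self.window_s)


@dataclass(frozen=True)
class TuningMetrics:
    cf_khz: float
    threshold_db: float
    bw_khz: dict
    q: dict
    max_rate: float
    rate_level: np.ndarray
    levels_db: np.ndarray


def significant_mask(fra: FRAMatrix, c: float = 3.0,
                     spont_rate: float | None = None,
                     spont_sd: float | None = None) -> np.ndarray:
    """Bins whose rate exceeds spontaneous + c * SD of the spontaneous rate.

    Unless supplied, the spontaneous rate and its SD are estimated from the
    lowest-level row, assumed sub-threshold for every frequency.
    """
    rates = fra.rates
    if spont_rate is None:
        spont_rate = fra.spont_rate
    if spont_rate is None:
        spont_rate = float(np.mean(rates[0]))
        if spont_sd is None:
            spont_sd = float(np.std(rates[0], ddof=1)) if rates.shape[1] > 1 else 0.0
    if spont_sd is None:
        spont_sd = 0.0
    return rates > spont_rate + c * spont_sd


def find_cf_threshold(mask: np.ndarray, fra: FRAMatrix,
                      require_support: bool = True) -> tuple[float, float]:
    """CF = frequency of the significant bin at the lowest significant level.

    Ties at the threshold row are broken by larger response, then by lower
    frequency.  With ``require_support`` (default) a bin only counts toward
    threshold when the same frequency is also significant one level higher —
    a genuine V-shaped response region grows with level, whereas an isolated
    noise bin does not, so this suppresses count-noise threshold estimates.
    """
    supported = mask.copy()
    if require_support and mask.shape[0] > 1:
        supported[:-1] &= mask[1:]
    if not supported.any():
        supported = mask  # degenerate: single row or unsupported everywhere
    rows = np.flatnonzero(supported.any(axis=1))
    if rows.size == 0:
        raise NoResponseError("no significant response region")
    r = rows[0]
    cols = np.flatnonzero(supported[r])
    rates = fra.rates[r, cols]
    best = cols[np.flatnonzero(rates == rates.max())]
    cf = float(fra.freqs_khz[best.min()])
    return cf, float(fra.levels_db[r])


def _span_bw(mask_row: np.ndarray, freqs: np.ndarray, cf: float) -> float | None:
    """Bandwidth of the significant span containing CF, at grid resolution."""
    if not mask_row.any():
        return None
    ci = int(np.argmin(np.abs(freqs - cf)))
    if not mask_row[ci]:
        # CF column itself below criterion at this level: use the nearest
        # span that brackets or abuts the CF column, ignoring islands.
        runs = _runs(mask_row)
        runs = [r for r in runs if r[0] - 1 <= ci <= r[1] + 1]
        if not runs:
            logger.warning("no significant span containing CF at this level")
            return None
        lo, hi = runs[0]
    else:
        lo = hi = ci
        while lo > 0 and mask_row[lo - 1]:
            lo -= 1
        while hi < mask_row.size - 1 and mask_row[hi + 1]:
            hi += 1
    if hi == lo:
        return None
    return float(freqs[hi] - freqs[lo])


def _runs(mask_row: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask_row)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], splits + 1])
    ends = np.concatenate([splits, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def q_factors(mask: np.ndarray, fra: FRAMatrix, cf: float, threshold: float,
              n_values: tuple[int, ...] = (10, 20, 30)) -> tuple[dict, dict]:
    """BW_n and Q_n = CF/BW_n at each n dB above threshold.

    When threshold + n falls between level rows the bandwidth is linearly
    interpolated between the bracketing rows; when it lies beyond the grid
    the value is reported missing (None).
    """
    levels = fra.levels_db
    bw: dict[int, float | None] = {}
    q: dict[int, float | None] = {}
    for n in n_values:
        target = threshold + n
        if target > levels[-1] or target < levels[0]:
            bw[n] = q[n] = None
            continue
        exact = np.flatnonzero(np.isclose(levels, target))
        if exact.size:
            val = _span_bw(mask[exact[0]], fra.freqs_khz, cf)
        else:
            hi = int(np.searchsorted(levels, target))
            lo = hi - 1
            b_lo = _span_bw(mask[lo], fra.freqs_khz, cf)
            b_hi = _span_bw(mask[hi], fra.freqs_khz, cf)
            if b_lo is None or b_hi is None:
                val = b_hi if b_lo is None else b_lo
            else:
                w = (target - levels[lo]) / (levels[hi] - levels[lo])
                val = (1 - w) * b_lo + w * b_hi
        bw[n] = val
        q[n] = (cf / val) if val else None
    return bw, q


def rate_level_and_max(fra: FRAMatrix, cf: float) -> tuple[np.ndarray, float]:
    """Rate-level function in the CF column plus the matrix-wide max rate."""
    ci = int(np.argmin(np.abs(fra.freqs_khz - cf)))
    rates = fra.rates
    return rates[:, ci].copy(), float(rates.max())


def analyze_fra(fra: FRAMatrix, c: float = 3.0) -> TuningMetrics:
    """Full tuning analysis of one FRA."""
    mask = significant_mask(fra, c=c)
    cf, threshold = find_cf_threshold(mask, fra)
    bw, q = q_factors(mask, fra, cf, threshold)
    rl, max_rate = rate_level_and_max(fra, cf)
    return TuningMetrics(cf, threshold, bw, q, max_rate, rl,
                         fra.levels_db.copy())
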