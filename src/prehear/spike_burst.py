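"""Interspike-interval statistics and gamma-probability burst detection.

Spontaneous firing of prehearing MNTB neurons alternates between long silent
stretches and bursts built from ~100 ms-spaced "mini-bursts".  Burstiness is
quantified two ways:

* the coefficient of variation (CV) of interspike intervals (ISIs), which is
  ~1 for Poisson-like firing and grows with temporal patterning, and
* an explicit burst test based on the gamma distribution of waiting times.

The burst test treats the unit's overall discharge as a Poisson process with
rate ``lambda`` (estimated as spike count over recording duration).  The
waiting time for ``k`` consecutive ISIs is then gamma(k, lambda) distributed,
and the probability of observing ``k`` ISIs within a window of length ``tau``
is the regularized lower incomplete gamma function, identically the Poisson
tail ``P(Poisson(lambda*tau) >= k)``.  A stretch of firing is a burst when
this probability stays below ``alpha`` (default 0.01) over at least ``k_min``
(default 10) consecutive ISIs: for every window of the ``k_min`` most recent
ISIs ending inside the stretch, the waiting time is shorter than expected at
the 1% level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "GammaBurstConfig",
    "Burst",
    "BurstSet",
    "compute_isis",
    "coefficient_of_variation",
    "gamma_burst_probability",
    "estimate_lambda",
    "detect_bursts",
    "burst_metrics",
    "pool_isis",
    "compare_isi_distributions",
    "log_bin_edges",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (seconds) of one unit over ``duration`` seconds."""

    unit_id: str
    spike_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", t)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if t.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if t.size:
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class GammaBurstConfig:
    """Parameters of the gamma waiting-time burst criterion."""

    alpha: float = 0.01
    k_min: int = 10
    rate_estimator: str = "global"  # spikes / recording duration

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")


@dataclass(frozen=True)
class Burst:
    start_index: int
    end_index: int
    start_time: float
    end_time: float

    @property
    def k(self) -> int:
        """Number of ISIs spanned by the burst."""
        return self.end_index - self.start_index

    @property
    def n_spikes(self) -> int:
        return self.k + 1

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def within_rate(self) -> float:
        return self.n_spikes / self.duration


@dataclass
class BurstSet:
    unit_id: str
    duration: float
    bursts: list[Burst]
    lambda_hat: float
    cv: float | None
    mean_rate: float
    median_isi: float | None
    config: GammaBurstConfig = field(default_factory=GammaBurstConfig)

    @property
    def bursts_per_100s(self) -> float:
        return 100.0 * len(self.bursts) / self.duration


def compute_isis(train: SpikeTrain) -> np.ndarray:
    """Interspike intervals: time between successive spikes of one unit."""
    return np.diff(train.spike_times)


def coefficient_of_variation(isis: np.ndarray) -> float:
    """CV = sd(ISI)/mean(ISI), with the sample (n-1) standard deviation."""
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        raise ValueError("CV requires at least two intervals")
    return float(np.std(isis, ddof=1) / np.mean(isis))


def gamma_burst_probability(k, tau, lam):
    """Probability of encountering ``k`` ISIs within a window ``tau``.

    The waiting time for k ISIs of a Poisson process with rate ``lam`` is
    gamma(k, lam); its CDF at tau is ``gammainc(k, lam*tau)``, identically
    the Poisson tail P(Poisson(lam*tau) >= k).  Small values flag stretches
    of firing far faster than the unit's overall rate.
    """
    k = np.asarray(k)
    tau = np.asarray(tau, dtype=float)
    if np.any(k < 1):
        raise ValueError("k must be >= 1")
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    if np.any(np.asarray(lam) <= 0):
        raise ValueError("rate must be positive")
    out = special.gammainc(k, lam * tau)
    return float(out) if out.ndim == 0 else out


def estimate_lambda(train: SpikeTrain) -> float:
    """Overall firing rate: spike count over recording duration (Hz)."""
    if train.n_spikes < 2:
        raise ValueError("rate estimation requires at least two spikes")
    return train.n_spikes / train.duration


def detect_bursts(train: SpikeTrain, config: GammaBurstConfig | None = None) -> BurstSet:
    """Detect bursts where the gamma waiting-time probability stays < alpha.

    For every spike index ``j >= k_min`` the probability
    ``p_j = gammainc(k_min, lambda * (t_j - t_{j-k_min}))`` is evaluated over
    the ``k_min`` most recent ISIs.  A burst is a maximal run of at least
    ``k_min`` consecutive indices with ``p_j < alpha``; it extends from spike
    ``j_first - k_min`` (the first spike of the first significant window) to
    spike ``j_last``.  Runs are disjoint by construction; if a run's backward
    window would reach into the previous burst, its start is clipped.
    """
    config = config or GammaBurstConfig()
    t = train.spike_times
    n = t.size
    cv = None
    median_isi = None
    if n >= 2:
        isis = compute_isis(train)
        median_isi = float(np.median(isis))
        if isis.size >= 2:
            cv = coefficient_of_variation(isis)
    mean_rate = n / train.duration
    if n < config.k_min + 1:
        return BurstSet(train.unit_id, train.duration, [], mean_rate, cv,
                        mean_rate, median_isi, config)

    lam = estimate_lambda(train)
    k = config.k_min
    tau = t[k:] - t[:-k]  # window ending at spike j = k .. n-1
    p = special.gammainc(k, lam * tau)
    sig = p < config.alpha

    bursts: list[Burst] = []
    prev_end = -1
    j = 0
    m = sig.size
    while j < m:
        if not sig[j]:
            j += 1
            continue
        run_start = j
        while j < m and sig[j]:
            j += 1
        run_len = j - run_start
        if run_len >= config.k_min:
            # window index j covers spikes j .. j+k of t (tau[j] = t[j+k]-t[j])
            start_spike = max(run_start, prev_end + 1)
            end_spike = (j - 1) + k
            bursts.append(Burst(start_spike, end_spike,
                                float(t[start_spike]), float(t[end_spike])))
            prev_end = end_spike
    return BurstSet(train.unit_id, train.duration, bursts, lam, cv,
                    mean_rate, median_isi, config)


def burst_metrics(bs: BurstSet) -> dict:
    """Per-unit burst metrics: counts, spike counts, durations, rates."""
    spikes = np.array([b.n_spikes for b in bs.bursts], dtype=float)
    durations = np.array([b.duration for b in bs.bursts], dtype=float)
    rates = np.array([b.within_rate for b in bs.bursts], dtype=float)
    return {
        "unit_id": bs.unit_id,
        "n_bursts": len(bs.bursts),
        "bursts_per_100s": bs.bursts_per_100s,
        "spikes_per_burst": spikes,
        "burst_durations": durations,
        "within_burst_rates": rates,
        "mean_rate": bs.mean_rate,
        "cv": bs.cv,
        "median_isi": bs.median_isi,
    }


def pool_isis(groups: dict[str, list[np.ndarray]], seed: int) -> dict[str, np.ndarray]:
    """Pool n random ISIs per unit, n = smallest ISI count over all units.

    Equal weight per unit avoids over-representing high-rate cells.  Units
    with no ISIs are excluded with a warning.  Deterministic under ``seed``.
    """
    cleaned: dict[str, list[np.ndarray]] = {}
    counts = []
    for label, units in groups.items():
        kept = []
        for i, isis in enumerate(units):
            isis = np.asarray(isis, dtype=float)
            if isis.size == 0:
                logger.warning("unit %d of group %s has no ISIs; excluded", i, label)
                continue
            kept.append(isis)
            counts.append(isis.size)
        cleaned[label] = kept
    if not counts:
        raise ValueError("no units with ISIs to pool")
    n = int(min(counts))
    rng = np.random.default_rng(seed)
    pooled = {}
    for label, units in cleaned.items():
        parts = []
        for isis in units:
            if isis.size == n:
                parts.append(isis)
            else:
                parts.append(rng.choice(isis, size=n, replace=False))
        pooled[label] = np.concatenate(parts) if parts else np.array([])
    return pooled


def log_bin_edges(lo: float = 1e-3, hi: float = 100.0, per_decade: int = 5) -> np.ndarray:
    """Base-10 logarithmic histogram edges (default 1 ms .. 100 s, 5/decade)."""
    n = int(round(np.log10(hi / lo) * per_decade))
    return np.logspace(np.log10(lo), np.log10(hi), n + 1)


def compare_isi_distributions(group_a: np.ndarray, group_b: np.ndarray,
                              edges: np.ndarray | None = None) -> dict:
    """Two-sample KS test plus chi-square on shared log-binned histograms.

    Chi-square bins with expected counts < 5 are merged with their right
    neighbour; if everything collapses into one bin the chi-square is
    reported as not applicable (None).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ks = stats.ks_2samp(a, b, method="asymp")
    if edges is None:
        edges = log_bin_edges()
    ha, _ = np.histogram(a, bins=edges)
    hb, _ = np.histogram(b, bins=edges)
    # merge sparse bins left-to-right until expected counts are >= 5
    obs = np.stack([ha, hb]).astype(float)
    merged: list[np.ndarray] = []
    acc = np.zeros(2)
    total = obs.sum()
    for col in obs.T:
        acc = acc + col
        # expected count for a 2xN table cell: row_sum * col_sum / total
        exp_cell = acc.sum() * obs.sum(axis=1).min() / total if total else 0.0
        if exp_cell >= 5:
            merged.append(acc.copy())
            acc = np.zeros(2)
    if acc.any():
        if merged:
            merged[-1] += acc
        else:
            merged.append(acc.copy())
    table = np.stack(merged, axis=1)
    chi2_stat = chi2_p = None
    if table.shape[1] >= 2 and (table.sum(axis=1) > 0).all():
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(table)
    return {
        "ks_D": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "chi2": None if chi2_stat is None else float(chi2_stat),
        "chi2_p": None if chi2_p is None else float(chi2_p),
        "edges": edges,
        "hist_a": ha,
        "hist_b": hb,
    }
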