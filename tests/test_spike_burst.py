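"""ISI statistics and the gamma waiting-time burst detector."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prehear.spike_burst import (
    GammaBurstConfig,
    SpikeTrain,
    burst_metrics,
    coefficient_of_variation,
    compare_isi_distributions,
    compute_isis,
    detect_bursts,
    estimate_lambda,
    gamma_burst_probability,
    pool_isis,
)


def poisson_tail(mu: float, k: int) -> float:
    """Independent oracle: P(Poisson(mu) >= k) by direct term summation."""
    term = math.exp(-mu)
    acc = term
    for j in range(1, k):
        term *= mu / j
        acc += term
    return max(0.0, 1.0 - acc)


# ------------------------------------------------------------------ ISIs

class TestISIs:
    def test_basic_intervals(self):
        tr = SpikeTrain("u", [0.0, 0.1, 0.3], 1.0)
        assert np.allclose(compute_isis(tr), [0.1, 0.2])

    def test_single_spike_empty(self):
        assert compute_isis(SpikeTrain("u", [0.5], 1.0)).size == 0

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrain("u", [0.0, 0.0, 1.0], 2.0)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrain("u", [0.5, 0.2], 1.0)


class TestCV:
    def test_identical_intervals_zero(self):
        assert coefficient_of_variation(np.full(10, 0.1)) == 0.0

    def test_hand_computed(self):
        # sd([1,3]) = sqrt(2), mean = 2
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(
            math.sqrt(2) / 2, abs=1e-12)

    def test_exponential_cv_is_one(self, rng):
        isis = rng.exponential(0.2, size=100_000)
        assert coefficient_of_variation(isis) == pytest.approx(1.0, abs=0.01)

    def test_too_few_intervals(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([0.1])


# ------------------------------------------- gamma waiting-time probability

class TestGammaProbability:
    def test_zero_window(self):
        assert gamma_burst_probability(7, 0.0, 3.0) == 0.0

    def test_single_isi_closed_form(self):
        # p = 1 - exp(-lam*tau) for k = 1
        assert gamma_burst_probability(1, math.log(2), 1.0) == pytest.approx(0.5)

    def test_poisson_tail_value(self):
        assert gamma_burst_probability(10, 10.0, 1.0) == pytest.approx(
            poisson_tail(10.0, 10), abs=1e-12)

    def test_matches_poisson_tail_over_grid(self):
        """Gamma CDF equals the Poisson tail identity to 1e-10."""
        ks = np.arange(1, 51)
        mus = np.linspace(0.1, 100.0, 41)
        for k in ks:
            for mu in mus:
                assert gamma_burst_probability(int(k), mu, 1.0) == pytest.approx(
                    poisson_tail(mu, int(k)), abs=1e-10)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            gamma_burst_probability(1, 1.0, 0.0)

    @settings(derandomize=True, max_examples=60)
    @given(k=st.integers(1, 40), tau=st.floats(0.01, 50.0),
           lam=st.floats(0.01, 20.0), dtau=st.floats(0.01, 10.0))
    def test_monotone_in_window_and_rate(self, k, tau, lam, dtau):
        p0 = gamma_burst_probability(k, tau, lam)
        assert 0.0 <= p0 <= 1.0
        assert gamma_burst_probability(k, tau + dtau, lam) >= p0
        assert gamma_burst_probability(k, tau, lam * 1.5) >= p0

    @settings(derandomize=True, max_examples=60)
    @given(k=st.integers(1, 40), mu=st.floats(0.01, 80.0))
    def test_nonincreasing_in_k_at_fixed_mu(self, k, mu):
        assert (gamma_burst_probability(k + 1, mu, 1.0)
                <= gamma_burst_probability(k, mu, 1.0) + 1e-12)


class TestLambda:
    def test_rate_definition(self):
        t = np.linspace(0.01, 99.99, 620)
        assert estimate_lambda(SpikeTrain("u", t, 100.0)) == pytest.approx(6.2)

    def test_two_spikes_ok_one_not(self):
        assert estimate_lambda(SpikeTrain("u", [1.0, 2.0], 50.0)) == pytest.approx(0.04)
        with pytest.raises(ValueError):
            estimate_lambda(SpikeTrain("u", [1.0], 50.0))


# ------------------------------------------------------------- detection

def brute_force_bursts(t, duration, alpha=0.01, k_min=10):
    """Independent re-evaluation: Poisson tail sums + explicit run logic."""
    t = np.asarray(t, float)
    n = t.size
    if n < k_min + 1:
        return []
    lam = n / duration
    sig = [poisson_tail(lam * (t[j] - t[j - k_min]), k_min) < alpha
           for j in range(k_min, n)]
    bursts, prev_end, i = [], -1, 0
    while i < len(sig):
        if not sig[i]:
            i += 1
            continue
        r0 = i
        while i < len(sig) and sig[i]:
            i += 1
        if i - r0 >= k_min:
            start = max(r0, prev_end + 1)
            end = (i - 1) + k_min
            bursts.append((start, end))
            prev_end = end
    return bursts


class TestDetectBursts:
    def test_short_trains_have_no_bursts(self, rng):
        t = np.sort(rng.uniform(0, 10, 10))
        assert detect_bursts(SpikeTrain("u", t, 10.0)).bursts == []

    def test_dense_run_in_regular_background(self):
        """51 spikes at 20 ms ISIs inside a 1 Hz background -> one burst."""
        bg = np.arange(100) + 0.37
        dense = 10.0 + 0.02 * np.arange(51)
        t = np.sort(np.concatenate([bg, dense]))
        bs = detect_bursts(SpikeTrain("u", t, 100.0))
        assert len(bs.bursts) == 1
        b = bs.bursts[0]
        assert b.start_time <= dense[0] and b.end_time >= dense[-1]

    def test_matches_brute_force_oracle(self):
        """Exact agreement with the O(n^2)-style oracle on random trains."""
        master = np.random.default_rng(777)
        for trial in range(100):
            r = np.random.default_rng(master.integers(2**31))
            n = int(r.integers(15, 200))
            t = np.sort(r.uniform(0, 60, n))
            # sprinkle dense clusters into half the trains
            if trial % 2:
                c0 = r.uniform(5, 40)
                t = np.sort(np.concatenate(
                    [t, c0 + np.cumsum(r.uniform(0.004, 0.03, 40))]))
            t = t[np.concatenate([[True], np.diff(t) > 1e-6])]
            bs = detect_bursts(SpikeTrain("u", t, 60.0))
            got = [(b.start_index, b.end_index) for b in bs.bursts]
            assert got == brute_force_bursts(t, 60.0)

    def test_null_poisson_rarely_bursts(self):
        """Homogeneous Poisson firing yields almost no false bursts."""
        total = 0
        for s in range(100):
            r = np.random.default_rng(s)
            t = np.sort(r.uniform(0, 100, r.poisson(500)))
            t = t[np.concatenate([[True], np.diff(t) > 1e-6])]
            total += len(detect_bursts(SpikeTrain("u", t, 100.0)).bursts)
        assert total / 100 <= 0.05

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GammaBurstConfig(alpha=1.5)
        with pytest.raises(ValueError):
            GammaBurstConfig(k_min=0)


class TestBurstMetrics:
    def test_single_burst_arithmetic(self):
        # one 45-spike burst of 1.6 s in a 100 s train
        t = np.concatenate([np.linspace(10.0, 11.6, 45),
                            np.array([30.0, 50.0, 70.0, 90.0])])
        bs = detect_bursts(SpikeTrain("u", np.sort(t), 100.0))
        m = burst_metrics(bs)
        assert m["n_bursts"] == 1
        assert m["bursts_per_100s"] == pytest.approx(1.0)
        assert m["spikes_per_burst"][0] == 45
        assert m["within_burst_rates"][0] == pytest.approx(45 / 1.6, rel=0.01)

    def test_empty_burst_list(self, rng):
        t = np.sort(rng.uniform(0, 100, 30))
        m = burst_metrics(detect_bursts(SpikeTrain("u", t, 100.0)))
        assert m["n_bursts"] == 0
        assert m["bursts_per_100s"] == 0.0
        assert m["spikes_per_burst"].size == 0


# --------------------------------------------------------------- pooling

class TestPooling:
    def test_equal_counts_keep_everything(self, rng):
        units = [rng.exponential(0.1, 20) for _ in range(3)]
        pooled = pool_isis({"g": units}, seed=0)
        assert pooled["g"].size == 60
        assert np.allclose(np.sort(pooled["g"]),
                           np.sort(np.concatenate(units)))

    def test_subsampling_to_smallest_unit(self, rng):
        pooled = pool_isis({"g": [rng.exponential(0.1, 5),
                                  rng.exponential(0.1, 100)]}, seed=3)
        assert pooled["g"].size == 10

    def test_deterministic_under_seed(self, rng):
        units = {"g": [rng.exponential(0.1, 50), rng.exponential(0.1, 9)]}
        a = pool_isis(units, seed=11)
        b = pool_isis(units, seed=11)
        assert np.array_equal(a["g"], b["g"])


class TestISIDistributionComparison:
    def test_identical_samples(self, rng):
        x = rng.exponential(0.1, 500)
        res = compare_isi_distributions(x, x)
        assert res["ks_D"] == 0.0

    def test_disjoint_supports(self):
        res = compare_isi_distributions(np.linspace(0.001, 0.01, 100),
                                        np.linspace(1.0, 10.0, 100))
        assert res["ks_D"] == 1.0
        assert res["ks_p"] < 1e-6

    def test_chi_square_merges_sparse_bins(self, rng):
        a = rng.lognormal(-3.0, 1.0, 400)
        b = rng.lognormal(-2.0, 1.0, 400)
        res = compare_isi_distributions(a, b)
        assert res["chi2"] is not None and res["chi2_p"] < 0.05
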