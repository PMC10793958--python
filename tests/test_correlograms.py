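"""Correlogram machinery: histograms, baselines, deconvolution, Poisson test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spiketrans.core import SpikeTrain
from spiketrans.correlograms import (
    DeconvolutionSolver,
    compute_ach,
    compute_cch,
    deconvolve_transmission,
    hollowed_median_baseline,
    lag_edges,
    poisson_excess_test,
    psth,
)
from spiketrans.simulate import simulate_pair, simulate_refractory_poisson


def _poisson_train(uid, rate, duration, seed):
    rng = np.random.default_rng(seed)
    return SpikeTrain(
        uid, simulate_refractory_poisson(rate, duration, rng, 0.0), "PYR", 1
    )


class TestCCH:
    def test_single_pair_lands_in_closed_right_bin(self):
        # lag of exactly 2.0 ms must land in the (1.5, 2.0] bin
        ref = SpikeTrain("r", np.array([0.0]))
        tgt = SpikeTrain("t", np.array([0.002]))
        cch = compute_cch(ref, tgt, 0.0005, 0.005)
        hit = np.flatnonzero(cch.counts)
        assert hit.tolist() == [np.searchsorted(cch.edges, 0.002) - 1]
        assert cch.edges[hit[0]] == pytest.approx(0.0015)
        assert cch.edges[hit[0] + 1] == pytest.approx(0.0020)

    def test_mirror_symmetry(self):
        a = _poisson_train("a", 20, 50, 1)
        b = _poisson_train("b", 20, 50, 2)
        ab = compute_cch(a, b, 0.001, 0.02)
        ba = compute_cch(b, a, 0.001, 0.02)
        np.testing.assert_array_equal(ab.counts, ba.counts[::-1])

    def test_total_counts_conservation(self):
        a = _poisson_train("a", 30, 20, 3)
        b = _poisson_train("b", 30, 20, 4)
        cch = compute_cch(a, b, 0.001, 0.01)
        brute = sum(
            1
            for ta in a.times
            for tb in b.times
            if -0.01 < tb - ta <= 0.01
        )
        assert cch.counts.sum() == brute

    def test_product_rate_expectation(self):
        # independent 5 and 10 spk/s over 3600 s: ~5·10·T·Δ = 90 counts/bin
        a = _poisson_train("a", 5, 3600, 5)
        b = _poisson_train("b", 10, 3600, 6)
        cch = compute_cch(a, b, 0.0005, 0.03)
        assert cch.counts.mean() == pytest.approx(90, rel=0.05)

    def test_ach_symmetric_and_no_self_pairs(self):
        a = _poisson_train("a", 10, 100, 7)
        ach = compute_ach(a, 0.001, 0.02)
        assert ach.counts.sum() % 2 == 0
        np.testing.assert_array_equal(ach.counts, ach.counts[::-1])
        # zero-lag coincidences can only come from distinct spikes
        sparse = SpikeTrain("s", np.arange(10) * 1.0)
        ach_sparse = compute_ach(sparse, 0.001, 0.02)
        assert ach_sparse.counts.sum() == 0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            compute_cch(SpikeTrain("r", np.array([])), _poisson_train("t", 5, 10, 0))


class TestPSTH:
    def test_flat_for_independent_train(self):
        train = _poisson_train("u", 10, 600, 8)
        onsets = np.arange(1.0, 599.0, 1.0)
        h = psth(train, onsets)
        assert h.conditional_rate.mean() == pytest.approx(10, rel=0.05)

    def test_spike_before_every_event(self):
        onsets = 1.0 + 0.5 * np.arange(100)
        train = SpikeTrain("u", onsets - 0.003)
        h = psth(train, onsets)
        hot = np.flatnonzero(h.counts)
        assert h.counts.sum() == 100
        # all mass within the bins bracketing −3 ms (float-boundary tolerant)
        assert np.all(h.edges[hot] >= -0.004 - 1e-12)
        assert np.all(h.edges[hot + 1] <= -0.002 + 1e-12)

    def test_requires_events(self):
        with pytest.raises(ValueError, match="without events"):
            psth(_poisson_train("u", 5, 10, 0), np.array([]))


class TestHollowedMedian:
    def test_constant_histogram(self):
        assert np.all(hollowed_median_baseline(np.full(30, 7.0), 5) == 7.0)

    def test_single_peak_on_zero_background_is_hollowed(self):
        x = np.zeros(21)
        x[10] = 50
        base = hollowed_median_baseline(x, 5)
        assert base[10] == 0.0

    def test_worked_example(self):
        # counts [1,2,3,4,5], half-width 2, center bin 2: median of {1,2,4,5}
        base = hollowed_median_baseline(np.array([1.0, 2, 3, 4, 5]), 2)
        assert base[2] == 3.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        n=st.integers(4, 40),
        hw=st.integers(1, 10),
        seed=st.integers(0, 10**6),
    )
    def test_matches_brute_force(self, n, hw, seed):
        x = np.random.default_rng(seed).poisson(5, n).astype(float)
        got = hollowed_median_baseline(x, hw)
        for b in range(n):
            window = [
                x[i]
                for i in range(max(0, b - hw), min(n, b + hw + 1))
                if i != b
            ]
            assert got[b] == np.median(window)


class TestDeconvolution:
    def test_flat_ach_equivalence(self):
        # Poisson reference: deconvolved curve ≈ scaled excess CCH (≤1% RMS)
        session, _ = simulate_pair(
            0.1, 0.1, seed=11, pre_rate_spk_s=1.0, epoch_s=1800.0,
            refractory_s=0.0,
        )
        pre = session.epoch_train("pre", "Before")
        post = session.epoch_train("post", "Before")
        cch = compute_cch(pre, post, 0.0005, 0.030)
        ach = compute_ach(pre, 0.0005, 0.030)
        curve = deconvolve_transmission(cch, ach, 0.015)
        scaled = cch.counts / (cch.n_ref * cch.bin_width_s)
        scaled = scaled - hollowed_median_baseline(scaled, 30)
        rms_diff = np.sqrt(np.mean((curve.rate_spk_s - scaled) ** 2))
        rms_ref = np.sqrt(np.mean(scaled**2))
        assert rms_diff <= 0.01 * rms_ref

    def test_bursty_ach_forward_round_trip(self):
        # Forward-convolve a known kernel with a doublet-train ACH, recover it
        rng = np.random.default_rng(12)
        base = simulate_refractory_poisson(2.0, 3600, rng, 0.002)
        doublets = base[rng.random(base.size) < 0.5] + 0.003
        train = SpikeTrain("r", np.unique(np.concatenate([base, doublets])))
        ach = compute_ach(train, 0.0005, 0.030)
        solver = DeconvolutionSolver(ach)
        n = ach.n_bins
        true_curve = np.zeros(n)
        true_curve[n // 2 + 1 : n // 2 + 7] = 30.0  # rate units, 0.5–3.5 ms
        forward = solver._a @ (true_curve * ach.bin_width_s) + 40.0
        cch = compute_cch(train, train, 0.0005, 0.030)
        cch.counts = forward
        recovered = deconvolve_transmission(cch, ach, 0.015)
        # evaluate away from the window edges, where the finite-lag system
        # and the truncated median leave known residuals
        interior = np.abs(recovered.centers) <= 0.015
        rms_err = np.sqrt(
            np.mean((recovered.rate_spk_s - true_curve)[interior] ** 2)
        )
        assert rms_err <= 0.05 * np.sqrt(np.mean(true_curve[interior] ** 2))
        # the doublet echo at ~3 ms past the kernel is suppressed
        echo = (recovered.centers > 0.0035) & (recovered.centers <= 0.0075)
        assert recovered.rate_spk_s[echo].max() < 0.1 * true_curve.max()

    def test_zero_coupling_curve_near_zero(self):
        a = _poisson_train("a", 2, 1200, 13)
        b = _poisson_train("b", 10, 1200, 14)
        cch = compute_cch(a, b, 0.0005, 0.030)
        ach = compute_ach(a, 0.0005, 0.030)
        curve = deconvolve_transmission(cch, ach, 0.015)
        # fluctuations only: compare with the count-noise scale
        noise = np.sqrt(cch.counts.mean()) / (cch.n_ref * cch.bin_width_s)
        assert np.abs(curve.rate_spk_s.mean()) < noise
        assert np.sqrt(np.mean(curve.rate_spk_s**2)) < 3 * noise

    def test_grid_mismatch_rejected(self):
        a = _poisson_train("a", 5, 60, 15)
        with pytest.raises(ValueError, match="bin grid"):
            deconvolve_transmission(
                compute_cch(a, a, 0.0005, 0.030), compute_ach(a, 0.0005, 0.020)
            )


class TestPoissonExcessTest:
    def test_closed_form_examples(self):
        # 1 − F(−1; 1) − 0.5·f(0; 1) = 1 − 0.5e⁻¹
        assert poisson_excess_test(0, 1.0) == pytest.approx(
            1 - 0.5 * np.exp(-1), abs=1e-12
        )
        assert poisson_excess_test(5, 1.0) == pytest.approx(0.0021270, abs=1e-6)

    def test_matches_direct_summation_oracle(self):
        for lam in (0.5, 1.0, 5.0, 20.0, 50.0):
            for n in (0, 1, 3, 10, 40):
                k = np.arange(n, max(200, n + 200))
                tail = stats.poisson.pmf(k, lam).sum()
                oracle = tail - 0.5 * stats.poisson.pmf(n, lam)
                assert poisson_excess_test(n, lam) == pytest.approx(
                    np.clip(oracle, 1e-300, 1), abs=1e-12
                )

    def test_strictly_decreasing_in_observed_count(self):
        ps = [poisson_excess_test(n, 4.0) for n in range(15)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_zero_expectation_with_counts_is_flagged_minimum(self):
        p = poisson_excess_test(3, 0.0)
        assert 0 < p < 1e-300

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_excess_test(-1, 2.0)


def test_lag_edges_require_multiple_of_bin():
    with pytest.raises(ValueError, match="multiple"):
        lag_edges(0.0005, 0.0317)
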