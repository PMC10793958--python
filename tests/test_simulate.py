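"""Generative model: renewal trains, closed loop, coupling, ground truth."""

import numpy as np
import pytest

from spiketrans.core import SpikeTrain, StimulusEvents
from spiketrans.correlograms import compute_cch
from spiketrans.io import write_session
from spiketrans.simulate import (
    PairCoupling,
    SimConfig,
    generate_session,
    run_closed_loop,
    simulate_postsyn_train,
    simulate_presyn_trains,
    simulate_refractory_poisson,
)


class TestRefractoryPoisson:
    def test_rate_matches_nominal(self):
        rng = np.random.default_rng(0)
        t = simulate_refractory_poisson(2.0, 3600, rng, 0.002)
        assert t.size == pytest.approx(7200, rel=0.05)

    def test_no_interval_below_refractory(self):
        rng = np.random.default_rng(1)
        t = simulate_refractory_poisson(30.0, 120, rng, 0.002)
        assert np.diff(t).min() >= 0.002

    def test_seeds_differ_but_statistics_match(self):
        t1 = simulate_refractory_poisson(5.0, 600, np.random.default_rng(2))
        t2 = simulate_refractory_poisson(5.0, 600, np.random.default_rng(3))
        assert t1.size != t2.size or not np.array_equal(t1, t2)
        assert t1.size == pytest.approx(t2.size, rel=0.1)

    def test_unrealizable_rate_rejected(self):
        with pytest.raises(ValueError, match="unrealizable"):
            simulate_refractory_poisson(600.0, 10, np.random.default_rng(0), 0.002)


class TestClosedLoop:
    def _config(self, **kw):
        base = dict(
            n_assemblies=1, presyn_per_assembly=1, before_s=0,
            experience_s=100.0, after_s=0, detection_prob=1.0,
        )
        base.update(kw)
        return SimConfig(**base)

    def test_perfect_detection_no_collisions(self):
        spikes = 0.5 + 0.060 * np.arange(100)  # 60-ms gaps > 53-ms blanking
        trains = {"u": SpikeTrain("u", spikes)}
        ev = run_closed_loop(trains, ["u"], self._config(), 0, window=(0, 100))
        assert ev.n_events == 100
        np.testing.assert_allclose(ev.onsets, spikes + 0.003)

    def test_dead_time_blanks_second_spike(self):
        trains = {"u": SpikeTrain("u", np.array([1.000, 1.010]))}
        ev = run_closed_loop(trains, ["u"], self._config(), 0, window=(0, 100))
        assert ev.onsets.tolist() == [1.003]

    def test_detection_probability_binomial(self):
        spikes = 0.5 + 0.080 * np.arange(1000)
        trains = {"u": SpikeTrain("u", spikes)}
        ev = run_closed_loop(
            trains, ["u"], self._config(detection_prob=0.5, experience_s=100.0),
            7, window=(0, 100),
        )
        assert ev.n_events == pytest.approx(500, abs=50)

    def test_unknown_trigger_rejected(self):
        with pytest.raises(KeyError):
            run_closed_loop({}, ["ghost"], self._config(), 0)


class TestPostsynTrain:
    def _setup(self, p, gain, seed, duration=600.0, stim=False):
        cfg = SimConfig(
            n_assemblies=1, presyn_per_assembly=1, before_s=0,
            experience_s=duration, after_s=0, light_gain=gain,
            detection_prob=1.0,
        )
        rng = np.random.default_rng(seed)
        pre = SpikeTrain(
            "pre", simulate_refractory_poisson(2.0, duration, rng, 0.002)
        )
        if stim:
            events = run_closed_loop(
                {"pre": pre}, ["pre"], cfg, rng, window=(0, duration)
            )
        else:
            events = StimulusEvents(np.array([]))
        post = simulate_postsyn_train(
            {"pre": pre}, [PairCoupling("pre", p, p)], events, cfg, rng,
            base_rate_spk_s=10.0, light_gain=gain,
        )
        return pre, post, events

    def test_decoupled_limit_is_flat(self):
        pre, post, _ = self._setup(0.0, 1.0, 21)
        cch = compute_cch(pre, post, 0.001, 0.02)
        expected = pre.n_spikes * 10.0 * 0.001
        assert cch.counts.mean() == pytest.approx(expected, rel=0.1)
        # causal bins show no excess over the anti-causal side
        half = cch.n_bins // 2
        causal, acausal = cch.counts[half:].sum(), cch.counts[:half].sum()
        assert abs(causal - acausal) < 5 * np.sqrt(causal + acausal)

    def test_excess_spikes_match_transmission_probability(self):
        pre, post, _ = self._setup(0.1, 1.0, 22, duration=1800.0)
        # excess over a shifted-train control within 0–5 ms of presyn spikes
        def _count(post_times, shift):
            hits = 0
            for t in pre.times:
                lo = np.searchsorted(post_times, t + shift)
                hi = np.searchsorted(post_times, t + shift + 0.005)
                hits += hi - lo
            return hits

        excess = _count(post.times, 0.0) - _count(post.times, 0.5)
        assert excess == pytest.approx(0.1 * pre.n_spikes, rel=0.15)

    def test_light_gain_scales_rate_inside_stimuli(self):
        pre, post, ev = self._setup(0.0, 2.0, 23, duration=900.0, stim=True)
        stim_iv = ev.intervals()
        t_stim = sum(b - a for a, b in stim_iv)
        inside = post.restrict(stim_iv).n_spikes / t_stim
        outside = (post.n_spikes - post.restrict(stim_iv).n_spikes) / (900 - t_stim)
        assert inside / outside == pytest.approx(2.0, rel=0.1)

    def test_invalid_gain_rejected(self):
        with pytest.raises(ValueError):
            self._setup(0.0, -1.0, 24)


class TestGenerateSession:
    def _config(self, **kw):
        base = dict(
            n_assemblies=2, presyn_per_assembly=2,
            before_s=120.0, experience_s=120.0, after_s=120.0, seed=5,
        )
        base.update(kw)
        return SimConfig(**base)

    def test_unit_plasticity_gives_zero_true_change(self):
        _, truth = generate_session(self._config(plasticity_factor=1.0))
        assert np.allclose(truth.pairs["true_stg_change"], 0.0)

    def test_halving_factor_gives_minus_one(self):
        _, truth = generate_session(
            self._config(plasticity_factor=(0.5, 1.0))
        )
        a0 = truth.pairs[truth.pairs["assembly"] == 0]
        assert np.allclose(a0["true_stg_change"], -1.0)

    def test_events_confined_to_experience(self):
        session, _ = generate_session(self._config())
        a, b = session.epochs["Experience"]
        if session.events.n_events:
            assert session.events.onsets[0] >= a
            assert session.events.onsets[-1] < b

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = self._config()
        s1, _ = generate_session(cfg, seed=9)
        s2, _ = generate_session(cfg, seed=9)
        p1 = write_session(s1, tmp_path / "a")
        p2 = write_session(s2, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_presyn_rates_within_band(self):
        cfg = self._config(
            presyn_rate_spk_s=(2.0, 2.0), before_s=900.0,
            experience_s=900.0, after_s=900.0,
        )
        trains = simulate_presyn_trains(cfg, 3)
        for t in trains.values():
            assert t.rate(cfg.duration_s) == pytest.approx(2.0, rel=0.1)
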