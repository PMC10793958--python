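"""Cross-validated learners, feature manipulations, virtual closed loop."""

import numpy as np
import pytest

from spiketrans.core import EpochSet, Session, SpikeTrain, StimulusEvents
from spiketrans.prediction import (
    crossval_svm_auc,
    crossval_svr,
    default_cle_sampler,
    shuffle_bins,
    virtual_closed_loop,
    window_scan,
    zscore_vector,
    _group_folds,
)
from spiketrans.simulate import simulate_refractory_poisson
from spiketrans.stim import closed_loop_efficiency


class TestVectorManipulations:
    def test_zscore_mean_zero_sd_one(self):
        z = zscore_vector(np.array([1.0, 2.0, 3.0]))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_zscore_idempotent(self):
        v = np.random.default_rng(0).normal(size=30)
        np.testing.assert_allclose(zscore_vector(zscore_vector(v)), zscore_vector(v))

    def test_zscore_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_vector(np.ones(5))

    def test_shuffle_preserves_multiset_and_is_seeded(self):
        v = np.arange(21.0)
        s1 = shuffle_bins(v, seed=5)
        s2 = shuffle_bins(v, seed=5)
        assert sorted(s1) == sorted(v)
        np.testing.assert_array_equal(s1, s2)
        assert shuffle_bins(np.array([3.0]), seed=0).tolist() == [3.0]


class TestSVR:
    def test_learnable_identity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(80, 3))
        y = x[:, 0]
        r2 = crossval_svr(x, y, repeats=5, seed=0)
        assert r2.mean() > 0.8

    def test_independent_target_near_or_below_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(80, 3))
        y = rng.normal(size=80)
        r2 = crossval_svr(x, y, repeats=5, seed=0)
        assert r2.mean() < 0.15

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            crossval_svr(np.random.default_rng(0).normal(size=(20, 2)),
                         np.ones(20))


class TestSVM:
    def test_separable_labels_near_perfect(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 4))
        y = (x[:, 0] > 0).astype(int)
        auc = crossval_svm_auc(x, y, repeats=5, seed=0)
        assert auc.mean() > 0.9

    def test_shuffled_labels_at_chance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(100, 4))
        y = (x[:, 0] > 0).astype(int)
        auc = crossval_svm_auc(x, y, repeats=20, seed=0, shuffle_labels=True)
        assert abs(auc.mean() - 0.5) < 0.06

    def test_group_folds_never_split_assemblies(self):
        groups = np.repeat(np.arange(10), 3)
        folds = _group_folds(groups, 5, np.random.default_rng(0))
        assert sorted(np.concatenate(folds).tolist()) == list(range(30))
        for fold in folds:
            for g in set(groups[fold]):
                assert set(np.flatnonzero(groups == g)) <= set(fold)

    def test_subsample_scheme_scores_one_auc_per_round(self):
        rng = np.random.default_rng(5)
        groups = np.repeat(np.arange(20), 2)
        x = rng.normal(size=(40, 3))
        y = (x[:, 0] + 0.5 * rng.normal(size=40) > 0).astype(int)
        auc = crossval_svm_auc(
            x, y, repeats=10, seed=0, scheme="subsample_one_per_assembly",
            groups=groups,
        )
        assert auc.shape == (10,)
        assert auc.mean() > 0.6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            crossval_svm_auc(np.zeros((10, 2)), np.zeros(10))


class TestWindowScan:
    def _data(self):
        rng = np.random.default_rng(6)
        centers = np.arange(-50, 51) / 1000.0
        x = rng.normal(size=(60, 101))
        labels = np.where(np.arange(60) % 2 == 0, 1, -1)
        # deterministic signature at +3 ms for the positive class
        bump = np.argmin(np.abs(centers - 0.003))
        x[labels == 1, bump] += 4.0
        return x, centers, labels

    def test_informative_window_beats_remote_offset(self):
        x, centers, labels = self._data()
        out = window_scan(
            x, centers, labels, offsets_s=[0.0, 0.040], repeats=5, seed=0
        )
        near = out.loc[out["offset"] == 0.0, "auc_mean"].item()
        far = out.loc[out["offset"] == 0.040, "auc_mean"].item()
        assert near > far + 0.2

    def test_default_half_width_keeps_21_bins(self):
        x, centers, labels = self._data()
        out = window_scan(
            x, centers, labels, half_widths_s=[0.0105], repeats=2, seed=0
        )
        assert out["n_bins"].item() == 21

    def test_single_bin_window_runs(self):
        x, centers, labels = self._data()
        out = window_scan(
            x, centers, labels, half_widths_s=[0.0004], repeats=2, seed=0
        )
        assert out["n_bins"].item() == 1

    def test_out_of_range_window_rejected(self):
        x, centers, labels = self._data()
        with pytest.raises(ValueError, match="covers no bins"):
            window_scan(x, centers, labels, offsets_s=[0.2], repeats=2, seed=0)


class TestVirtualClosedLoop:
    def _control_session(self, rate=5.0, duration=600.0, seed=0):
        rng = np.random.default_rng(seed)
        trains = {
            "p0": SpikeTrain(
                "p0", simulate_refractory_poisson(rate, duration, rng, 0.002)
            )
        }
        epochs = EpochSet({"Experience": (0.0, duration)})
        return Session(trains=trains, epochs=epochs,
                       events=StimulusEvents(np.array([])), duration_s=duration)

    def test_full_cle_sparse_train_event_per_spike(self):
        session = self._control_session(rate=1.0)
        events, chosen = virtual_closed_loop(
            session, [["p0"]], seed=0, cle_sampler=lambda rng: 1.0
        )
        n_exp = session.trains["p0"].n_spikes
        # dead-time blanking may drop a few closely spaced triggers
        assert events.n_events >= 0.9 * n_exp
        assert chosen["drawn_cle"].item() == 1.0

    def test_realized_cle_matches_drawn(self):
        session = self._control_session(rate=1.0, seed=1)
        events, chosen = virtual_closed_loop(
            session, [["p0"]], seed=2, cle_sampler=lambda rng: 0.4
        )
        cle, _ = closed_loop_efficiency(
            session.trains["p0"], events, period=(0.0, 600.0)
        )
        assert cle == pytest.approx(0.4, abs=0.05)

    def test_requires_stimulus_free_session(self):
        session = self._control_session()
        session.events = StimulusEvents(np.array([10.0]))
        with pytest.raises(ValueError, match="stimulus-free"):
            virtual_closed_loop(session, [["p0"]], seed=0)

    def test_default_sampler_matches_quantiles(self):
        rng = np.random.default_rng(3)
        draws = np.array([default_cle_sampler(rng) for _ in range(4000)])
        assert np.median(draws) == pytest.approx(0.054, rel=0.1)
        assert np.percentile(draws, 25) == pytest.approx(0.013, rel=0.25)
        assert np.percentile(draws, 75) == pytest.approx(0.184, rel=0.25)
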