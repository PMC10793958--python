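"""Assembly construction, peer statistics, CCH differences, permutation cc."""

import numpy as np
import pytest
from scipy import stats

from spiketrans.assembly import (
    Assembly,
    aggregate_cch_difference,
    build_assemblies,
    cch_difference,
    peer_nonpeer_means,
    sham_assemblies,
    spearman_permutation,
    _complement_intervals,
)
from spiketrans.simulate import simulate_stim_feature_cohort


@pytest.fixture(scope="module")
def flat_cohort_item():
    """One assembly with no light effect (gain 1, no timing change)."""
    return simulate_stim_feature_cohort(1, "none", seed=3, experience_s=600.0)[0]


class TestBuildAssemblies:
    PAIRS = [("p1", "PV1"), ("p2", "PV1"), ("p3", "PV1"), ("p4", "PV2"), ("p5", "PV2")]

    def test_partition_by_postsynaptic_unit(self):
        asm = build_assemblies(self.PAIRS)
        sizes = sorted(a.size for a in asm)
        assert sizes == [2, 3]

    def test_union_of_members_is_input(self):
        asm = build_assemblies(self.PAIRS)
        members = sorted(m for a in asm for m in a.members)
        assert members == sorted(self.PAIRS)

    def test_singleton_allowed(self):
        asm = build_assemblies([("p", "PV")])
        assert asm[0].size == 1

    def test_mismatched_post_id_rejected(self):
        with pytest.raises(ValueError):
            Assembly("PV1", (("p1", "PV2"),))


class TestPeerNonPeer:
    def test_worked_example(self):
        asm = build_assemblies([("a", "X"), ("b", "X"), ("c", "X"), ("d", "Y")])
        values = {("a", "X"): 1.0, ("b", "X"): 2.0, ("c", "X"): 3.0, ("d", "Y"): 9.0}
        peer, nonpeer = peer_nonpeer_means(("a", "X"), asm, values)
        assert peer == 2.5
        assert nonpeer == 9.0

    def test_no_other_assemblies_flags_nonpeer(self):
        asm = build_assemblies([("a", "X"), ("b", "X")])
        values = {("a", "X"): 1.0, ("b", "X"): 2.0}
        peer, nonpeer = peer_nonpeer_means(("a", "X"), asm, values)
        assert peer == 2.0
        assert np.isnan(nonpeer)

    def test_matches_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(4)
        pairs = [(f"p{i}", f"PV{rng.integers(4)}") for i in range(30)]
        pairs = list(dict.fromkeys(pairs))
        values = {p: float(rng.normal()) for p in pairs}
        asm = build_assemblies(pairs)
        for pair in pairs:
            peer, nonpeer = peer_nonpeer_means(pair, asm, values)
            same = [values[q] for q in pairs if q[1] == pair[1] and q != pair]
            other = [values[q] for q in pairs if q[1] != pair[1]]
            assert peer == pytest.approx(np.mean(same)) if same else np.isnan(peer)
            assert nonpeer == pytest.approx(np.mean(other))


class TestCCHDifference:
    def test_no_light_effect_gives_flat_difference(self, flat_cohort_item):
        item = flat_cohort_item
        d = cch_difference(item["session"], item["pre_ids"][0], item["post_id"])
        # mean difference consistent with zero at the shot-noise scale
        noise = np.sqrt(
            10.0 / (d.n_ref_stim * 0.001) + 10.0 / (d.n_ref_between * 0.001)
        )
        off_peak = np.abs(d.centers) > 0.006
        assert np.abs(d.difference[off_peak].mean()) < noise / 3

    def test_difference_is_exact_subtraction(self, flat_cohort_item):
        item = flat_cohort_item
        d = cch_difference(item["session"], item["pre_ids"][0], item["post_id"])
        np.testing.assert_array_equal(d.difference, d.stim_rate - d.between_rate)

    def test_complement_intervals(self):
        out = _complement_intervals((0.0, 10.0), [(2.0, 3.0), (5.0, 6.0)])
        assert out == [(0.0, 2.0), (3.0, 5.0), (6.0, 10.0)]

    def test_requires_events(self, flat_cohort_item):
        session = flat_cohort_item["session"]
        from spiketrans.core import StimulusEvents

        quiet = type(session)(
            trains=session.trains, epochs=session.epochs,
            events=StimulusEvents(np.array([])), duration_s=session.duration_s,
        )
        with pytest.raises(ValueError, match="no stimulus events"):
            cch_difference(quiet, flat_cohort_item["pre_ids"][0],
                           flat_cohort_item["post_id"])


class TestAggregation:
    def _diffs(self, item):
        return {
            (pre, item["post_id"]): cch_difference(
                item["session"], pre, item["post_id"]
            )
            for pre in item["pre_ids"]
        }

    def test_peers_plus_own_equals_whole(self, flat_cohort_item):
        diffs = self._diffs(flat_cohort_item)
        asm = build_assemblies(list(diffs))[0]
        pair = asm.members[0]
        whole = aggregate_cch_difference(asm, diffs, "whole_assembly")
        peers = aggregate_cch_difference(asm, diffs, "peers_of", pair=pair)
        np.testing.assert_allclose(whole, peers + diffs[pair].difference)

    def test_member_order_invariance(self, flat_cohort_item):
        diffs = self._diffs(flat_cohort_item)
        asm = build_assemblies(list(diffs))[0]
        flipped = Assembly(asm.post_id, tuple(reversed(asm.members)))
        np.testing.assert_allclose(
            aggregate_cch_difference(asm, diffs),
            aggregate_cch_difference(flipped, diffs),
        )

    def test_empty_selection_rejected(self, flat_cohort_item):
        diffs = self._diffs(flat_cohort_item)
        asm = build_assemblies(list(diffs))[0]
        single = Assembly(asm.post_id, asm.members[:1])
        with pytest.raises(ValueError):
            aggregate_cch_difference(single, diffs, "peers_of", pair=single.members[0])


class TestShamAssemblies:
    PAIRS = [(f"p{i}", f"PV{i % 3}") for i in range(12)]

    def test_size_multiset_preserved(self):
        sham = sham_assemblies(self.PAIRS, [5, 4, 3], seed=0)
        assert sorted(a.size for a in sham) == [3, 4, 5]

    def test_seed_reproducible(self):
        a = sham_assemblies(self.PAIRS, [5, 4, 3], seed=1)
        b = sham_assemblies(self.PAIRS, [5, 4, 3], seed=1)
        assert [x.members for x in a] == [y.members for y in b]

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            sham_assemblies(self.PAIRS, [6, 3], seed=0)

    def test_sham_dilutes_coherent_structure(self):
        # coherent per-assembly values: true grouping has higher spread of
        # group means than random regroupings
        rng = np.random.default_rng(5)
        true_asm = build_assemblies(self.PAIRS)
        values = {}
        for k, a in enumerate(true_asm):
            for m in a.members:
                values[m] = k * 2.0 + rng.normal(0, 0.2)
        # remap values onto the original pair ids for sham lookups
        by_pre = {pre: values[(pre, post)] for pre, post in self.PAIRS}
        true_sd = np.std(
            [np.mean([values[m] for m in a.members]) for a in true_asm]
        )
        sham_sds = []
        for seed in range(30):
            sham = sham_assemblies(self.PAIRS, [4, 4, 4], seed=seed)
            sham_sds.append(
                np.std(
                    [np.mean([by_pre[m[0]] for m in a.members]) for a in sham]
                )
            )
        assert np.mean(sham_sds) < true_sd


class TestSpearmanPermutation:
    def test_perfect_association(self):
        x = np.arange(20.0)
        cc, p = spearman_permutation(x, x, n_perm=500, seed=0)
        assert cc == pytest.approx(1.0)
        assert p == pytest.approx(1 / 501)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=40), rng.normal(size=40)
        cc, _ = spearman_permutation(x, y, n_perm=100, seed=0)
        assert cc == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_independent_vectors_not_significant(self):
        rng = np.random.default_rng(7)
        ps = [
            spearman_permutation(
                rng.normal(size=30), rng.normal(size=30), n_perm=200, seed=k
            )[1]
            for k in range(10)
        ]
        assert np.median(ps) > 0.05

    def test_constant_vector_flagged(self):
        cc, p = spearman_permutation(np.ones(10), np.arange(10.0), seed=0)
        assert np.isnan(cc) and np.isnan(p)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_permutation(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
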