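import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from segqc import ClassSpec, FusionConfig, SegMask, fuse_case, majority_vote, majority_vote_multilabel, simple_fuse


def bmask(bits, source_id="s"):
    arr = np.asarray(bits, dtype=np.int32).reshape(-1, 1, 1)
    return SegMask(voxels=arr, spacing=(1, 1, 1), source_id=source_id)


class TestMajorityVote:
    def test_idempotent_on_identical_candidates(self, mk_mask):
        m = mk_mask([[1, 0], [0, 1]])
        fused = majority_vote([m, m, m])
        np.testing.assert_array_equal(fused.voxels, m.voxels)

    @pytest.mark.parametrize(
        "votes,expected",
        [((1, 1, 0), 1), ((1, 0, 0), 0), ((1, 1, 1), 1), ((0, 0, 0), 0)],
    )
    def test_strict_majority_of_three(self, votes, expected):
        fused = majority_vote([bmask([v]) for v in votes])
        assert fused.voxels.ravel()[0] == expected

    @pytest.mark.parametrize("tie_rule,expected", [("background", 0), ("foreground", 1)])
    def test_even_ensemble_tie_follows_rule(self, tie_rule, expected):
        fused = majority_vote([bmask([v]) for v in (1, 1, 0, 0)], tie_rule=tie_rule)
        assert fused.voxels.ravel()[0] == expected

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        cands = [
            SegMask(voxels=rng.integers(0, 2, (3, 3, 3)).astype(np.int32), spacing=(1, 1, 1))
            for _ in range(4)
        ]
        results = {
            majority_vote([cands[i] for i in perm]).voxels.tobytes()
            for perm in itertools.permutations(range(4))
        }
        assert len(results) == 1

    def test_bounded_by_union_and_intersection(self):
        rng = np.random.default_rng(6)
        cands = [
            SegMask(voxels=rng.integers(0, 2, (4, 4, 4)).astype(np.int32), spacing=(1, 1, 1))
            for _ in range(5)
        ]
        fused = majority_vote(cands).voxels
        union = np.logical_or.reduce([c.voxels for c in cands])
        inter = np.logical_and.reduce([c.voxels for c in cands])
        assert np.all(fused <= union)
        assert np.all(fused >= inter)

    def test_grid_mismatch_rejected(self, mk_mask):
        a = mk_mask(np.zeros((2, 2, 2), dtype=int))
        b = mk_mask(np.zeros((3, 2, 2), dtype=int))
        with pytest.raises(Exception, match="grid"):
            majority_vote([a, b])


class TestMajorityVoteMultilabel:
    spec = ClassSpec([1, 2], ["necrosis", "edema"])

    def test_idempotent_on_identical_maps(self, mk_mask):
        m = mk_mask([[1, 2], [0, 1]])
        fused = majority_vote_multilabel([m, m, m], self.spec)
        np.testing.assert_array_equal(fused.voxels, m.voxels)

    def test_plurality_wins(self):
        cands = [bmask([2]), bmask([2]), bmask([1])]  # edema, edema, necrosis
        fused = majority_vote_multilabel(cands, self.spec)
        assert fused.voxels.ravel()[0] == 2

    def test_class_tie_without_background_votes_uses_precedence(self):
        cands = [bmask([2]), bmask([1])]  # edema vs necrosis, no bg votes
        fused = majority_vote_multilabel(
            cands, self.spec, precedence=["necrosis", "edema"]
        )
        assert fused.voxels.ravel()[0] == 1
        fused = majority_vote_multilabel(
            cands, self.spec, precedence=["edema", "necrosis"]
        )
        assert fused.voxels.ravel()[0] == 2

    def test_background_wins_ties_with_any_class(self):
        cands = [bmask([2]), bmask([0])]  # 1 edema vs 1 background
        fused = majority_vote_multilabel(cands, self.spec)
        assert fused.voxels.ravel()[0] == 0

    def test_composite_class_votes_pool_member_labels(self):
        spec = ClassSpec([{1, 4}, 2], ["core", "edema"])
        # labels 1 and 4 are the same class: 2 core votes beat 1 edema vote
        cands = [bmask([1]), bmask([4]), bmask([2])]
        fused = majority_vote_multilabel(cands, spec)
        assert fused.voxels.ravel()[0] == 1  # representative core label

    def test_permutation_invariant(self):
        rng = np.random.default_rng(7)
        cands = [
            SegMask(voxels=rng.integers(0, 3, (3, 3, 3)).astype(np.int32), spacing=(1, 1, 1))
            for _ in range(3)
        ]
        results = {
            majority_vote_multilabel([cands[i] for i in p], self.spec).voxels.tobytes()
            for p in itertools.permutations(range(3))
        }
        assert len(results) == 1


class TestSimpleFusion:
    def test_fixed_point_on_identical_candidates(self, mk_mask):
        m = mk_mask([[1, 0], [1, 1]])
        res = simple_fuse([m.with_voxels(m.voxels, source_id=f"s{i}") for i in range(3)])
        np.testing.assert_array_equal(res.fused.voxels, m.voxels)
        assert res.retained == {"s0", "s1", "s2"}
        assert len(set(res.weights.values())) == 1

    def test_all_background_candidate_is_discarded(self):
        # hand-traced 5-voxel example: 4 near-identical candidates plus one
        # empty mask whose Dice against the initial majority fusion is 0
        good = [bmask([1, 1, 1, 0, 0], f"g{i}") for i in range(4)]
        bad = bmask([0, 0, 0, 0, 0], "bad")
        res = simple_fuse(good + [bad])
        assert "bad" not in res.retained
        assert res.retained == {"g0", "g1", "g2", "g3"}
        assert res.weights["bad"] == 0.0
        from segqc import majority_vote

        np.testing.assert_array_equal(
            res.fused.voxels, majority_vote(good).voxels
        )

    def test_two_candidates_never_discard(self):
        a = bmask([1, 1, 0, 0], "a")
        b = bmask([0, 0, 1, 1], "b")  # fully disjoint
        res = simple_fuse([a, b])
        assert res.retained == {"a", "b"}

    def test_weighting_prefers_the_consensus_shape(self):
        # 5 candidates: 4 agree on a block, 1 adds a stray voxel; the stray
        # voxel never reaches a weighted majority
        cands = [bmask([1, 1, 1, 0, 0], f"s{i}") for i in range(4)]
        cands.append(bmask([1, 1, 1, 1, 0], "stray"))
        res = simple_fuse(cands)
        np.testing.assert_array_equal(res.fused.voxels.ravel(), [1, 1, 1, 0, 0])

    def test_permutation_invariant(self):
        rng = np.random.default_rng(8)
        cands = [
            SegMask(
                voxels=rng.integers(0, 2, (4, 4, 1)).astype(np.int32),
                spacing=(1, 1, 1),
                source_id=f"s{i}",
            )
            for i in range(4)
        ]
        results = {
            simple_fuse([cands[i] for i in p]).fused.voxels.tobytes()
            for p in itertools.permutations(range(4))
        }
        assert len(results) == 1

    def test_all_empty_candidates_fuse_to_empty(self):
        cands = [bmask([0, 0, 0], f"s{i}") for i in range(3)]
        res = simple_fuse(cands)
        assert res.fused.voxels.sum() == 0
        assert res.retained == {"s0", "s1", "s2"}


class TestFuseCase:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 5), st.sampled_from(["majority", "simple"]))
    def test_idempotence_for_k_copies(self, k, method):
        rng = np.random.default_rng(9)
        m = SegMask(voxels=rng.integers(0, 2, (4, 4, 2)).astype(np.int32), spacing=(1, 1, 1))
        copies = [m.with_voxels(m.voxels, source_id=f"s{i}") for i in range(k)]
        fused = fuse_case(copies, ClassSpec.binary(), FusionConfig(method=method))
        np.testing.assert_array_equal(fused.voxels, m.voxels)

    def test_multilabel_simple_recomposes_per_class(self, mk_mask):
        spec = ClassSpec([1, 2], ["a", "b"])
        m = mk_mask([[1, 2], [0, 2]])
        copies = [m.with_voxels(m.voxels, source_id=f"s{i}") for i in range(3)]
        fused = fuse_case(copies, spec, FusionConfig(method="simple"))
        np.testing.assert_array_equal(fused.voxels, m.voxels)


class TestFusionConfig:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            FusionConfig(method="staple")
        with pytest.raises(ValueError):
            FusionConfig(simple_max_iters=0)
        with pytest.raises(ValueError):
            FusionConfig(simple_discard_sd=-1)
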