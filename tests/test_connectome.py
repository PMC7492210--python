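import numpy as np
import pytest

import tractnet as tn
from tractnet.connectome import (
    CohortStudy,
    SubjectMeta,
    apply_mask_and_normalize,
    build_cohort_study,
    consensus_threshold,
)
from tractnet.core import Group, Weighting


def _constant_fa(lv, value):
    data = np.where(lv.data > 0, value, 0.0)
    return tn.ScalarVolume(data, lv.affine)


class TestAssignStreamline:
    def test_endpoints_in_two_rois(self, small_parcellation):
        v1 = np.argwhere(small_parcellation.data == 1)[0].astype(float)
        v2 = np.argwhere(small_parcellation.data == 2)[0].astype(float)
        assert tn.assign_streamline(np.vstack([v1, v2]), small_parcellation) == (1, 2)

    def test_background_endpoint_dropped(self, small_parcellation):
        v1 = np.argwhere(small_parcellation.data == 1)[0].astype(float)
        bg = np.argwhere(small_parcellation.data == 0)[0].astype(float)
        assert tn.assign_streamline(np.vstack([v1, bg]), small_parcellation) is None

    def test_outside_grid_dropped(self, small_parcellation):
        v1 = np.argwhere(small_parcellation.data == 1)[0].astype(float)
        assert tn.assign_streamline(
            np.vstack([v1, [99.0, 99.0, 99.0]]), small_parcellation) is None

    def test_same_roi_both_ends_dropped(self, small_parcellation):
        vv = np.argwhere(small_parcellation.data == 1)[:2].astype(float)
        assert tn.assign_streamline(vv, small_parcellation) is None


class TestStreamlineMeanFa:
    def test_constant_field(self, small_parcellation):
        fa = _constant_fa(small_parcellation, 0.5)
        s = np.array([[3.0, 3.0, 3.0], [8.2, 7.1, 6.6]])
        assert tn.streamline_mean_fa(s, fa) == pytest.approx(0.5)

    def test_two_voxel_centres_average(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 0.2
        data[2, 1, 1] = 0.4
        fa = tn.ScalarVolume(data, np.eye(4))
        s = np.array([[1.0, 1.0, 1.0], [2.0, 1.0, 1.0]])
        assert tn.streamline_mean_fa(s, fa) == pytest.approx(0.3)

    def test_linear_gradient_matches_analytic_samples(self, rng):
        # trilinear interpolation reproduces a linear field exactly
        shape = (10, 10, 10)
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        data = 0.01 * ii + 0.02 * jj + 0.005 * kk
        fa = tn.ScalarVolume(data, np.eye(4))
        pts = rng.uniform(0.0, 8.9, (25, 3))
        expected = (0.01 * pts[:, 0] + 0.02 * pts[:, 1] + 0.005 * pts[:, 2]).mean()
        assert tn.streamline_mean_fa(pts, fa) == pytest.approx(expected, abs=1e-9)

    def test_point_outside_grid_counts_as_zero(self):
        fa = tn.ScalarVolume(np.full((4, 4, 4), 0.8), np.eye(4))
        s = np.array([[1.0, 1.0, 1.0], [50.0, 1.0, 1.0]])
        assert tn.streamline_mean_fa(s, fa) == pytest.approx(0.4)


class TestBuildMatrices:
    def test_known_counts_and_fa(self, small_subject):
        names = sorted(small_subject.label_volume.labels.values())
        mats = tn.build_matrices(small_subject, names)
        nos = mats[Weighting.NOS].weights
        assert nos[0, 1] == 3 and nos[1, 2] == 1
        assert mats[Weighting.BINARY].weights[0, 1] == 1
        assert mats[Weighting.FA].weights[0, 1] == pytest.approx(0.5)
        for w in Weighting:
            W = mats[w].weights
            assert np.array_equal(W, W.T)
            assert np.all(np.diag(W) == 0)

    def test_empty_tractogram_gives_zero_matrices(self, small_parcellation):
        fa = _constant_fa(small_parcellation, 0.5)
        sub = tn.SubjectData("s", "HC", small_parcellation, fa, tn.Tractogram([]))
        mats = tn.build_matrices(sub, sorted(small_parcellation.labels.values()))
        assert all(np.all(m.weights == 0) for m in mats.values())

    def test_nos_round_trip_random_phantoms(self, rng):
        """Built NOS equals the generator's requested counts, edge for edge."""
        for rep in range(5):
            lv = tn.make_phantom_parcellation(8, (14, 14, 14), seed=rep)
            pairs = [(a, b) for a in range(1, 9) for b in range(a + 1, 9)]
            take = rng.choice(len(pairs), 10, replace=False)
            edges = [pairs[i] for i in take]
            counts = rng.integers(1, 6, 10).tolist()
            tr = tn.make_phantom_tractogram(lv, edges, counts, seed=100 + rep)
            fa = _constant_fa(lv, 0.5)
            sub = tn.SubjectData(f"s{rep}", "HC", lv, fa, tr)
            nos = tn.build_matrices(sub, sorted(lv.labels.values()))[Weighting.NOS].weights
            expected = np.zeros((8, 8))
            for (a, b), c in zip(edges, counts):
                expected[a - 1, b - 1] = expected[b - 1, a - 1] = c
            assert np.array_equal(nos, expected)


def _binary(W, names):
    return tn.ConnectivityMatrix(W, Weighting.BINARY, names)


class TestConsensusThreshold:
    names = ["a", "b", "c"]

    def _mats(self, presence):
        out = []
        for has_edge in presence:
            W = np.zeros((3, 3))
            if has_edge:
                W[0, 1] = W[1, 0] = 1.0
            out.append(_binary(W, self.names))
        return out

    def test_exactly_half_retained(self):
        mask = tn.consensus_threshold(self._mats([1, 1, 0, 0])).mask
        assert mask[0, 1]

    def test_below_half_discarded(self):
        mask = tn.consensus_threshold(self._mats([1, 0, 0, 0])).mask
        assert not mask[0, 1]

    def test_full_cohort_gives_all_offdiagonal_slots(self):
        n = 87
        W = 1.0 - np.eye(n)
        mats = [tn.ConnectivityMatrix(W, Weighting.BINARY, [f"r{i}" for i in range(n)])]
        mask = tn.consensus_threshold(mats * 4).mask
        assert int(mask.sum()) == 87 * 86 == 7482

    def test_monotone_in_fraction(self, rng):
        mats = []
        for _ in range(6):
            A = rng.random((5, 5)) < 0.5
            W = np.triu(A, 1).astype(float)
            W = W + W.T
            mats.append(_binary(W, list("abcde")))
        prev = None
        for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
            m = tn.consensus_threshold(mats, frac).mask
            if prev is not None:
                assert np.all(m <= prev)  # raising the fraction never adds an edge
            prev = m

    def test_mixed_node_sets_rejected(self):
        a = _binary(np.zeros((3, 3)), self.names)
        b = _binary(np.zeros((3, 3)), ["x", "y", "z"])
        with pytest.raises(ValueError, match="node set"):
            tn.consensus_threshold([a, b])


def _study_from_weights(per_subject_fa, names):
    matrices = {}
    metas = []
    for i, W in enumerate(per_subject_fa):
        sid = f"s{i}"
        metas.append(SubjectMeta(sid, Group.HC))
        matrices[sid] = {
            Weighting.FA: tn.ConnectivityMatrix(W, Weighting.FA, names),
            Weighting.NOS: tn.ConnectivityMatrix((W > 0) * 2.0, Weighting.NOS, names),
            Weighting.BINARY: tn.ConnectivityMatrix((W > 0) * 1.0, Weighting.BINARY, names),
        }
    study = CohortStudy(metas, matrices, names)
    study.consensus = tn.consensus_threshold(
        [matrices[f"s{i}"][Weighting.BINARY] for i in range(len(per_subject_fa))])
    return study


class TestNormalization:
    names = ["a", "b", "c"]

    def _weights(self, v01, v12):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = v01
        W[1, 2] = W[2, 1] = v12
        return W

    def test_cohort_max_becomes_one(self):
        study = _study_from_weights(
            [self._weights(0.666, 0.2), self._weights(0.5, 0.3)], self.names)
        out = apply_mask_and_normalize(study)
        fa_max = max(out.matrices[s][Weighting.FA].weights.max() for s in out.matrices)
        assert fa_max == pytest.approx(1.0)
        assert out.norm_constant[Weighting.FA] == pytest.approx(0.666)
        assert out.matrices["s0"][Weighting.FA].weights[0, 1] == pytest.approx(1.0)

    def test_single_subject_divides_by_own_max(self):
        study = _study_from_weights([self._weights(0.4, 0.1)], self.names)
        out = apply_mask_and_normalize(study)
        assert out.norm_constant[Weighting.FA] == pytest.approx(0.4)
        assert out.matrices["s0"][Weighting.FA].weights.max() == pytest.approx(1.0)

    def test_between_subject_ratios_preserved(self):
        a, b = self._weights(0.6, 0.24), self._weights(0.3, 0.12)
        study = _study_from_weights([a, b], self.names)
        out = apply_mask_and_normalize(study)
        Wa = out.matrices["s0"][Weighting.FA].weights
        Wb = out.matrices["s1"][Weighting.FA].weights
        assert Wa[0, 1] / Wb[0, 1] == pytest.approx(0.6 / 0.3, rel=1e-12)
        assert Wa[1, 2] / Wb[1, 2] == pytest.approx(0.24 / 0.12, rel=1e-12)

    def test_all_edges_masked_is_an_error(self):
        # edge in only 1 of 4 subjects -> everything below the 50% threshold
        zero = np.zeros((3, 3))
        study = _study_from_weights(
            [self._weights(0.5, 0.0), zero, zero, zero], self.names)
        study.matrices["s0"][Weighting.FA].weights[1, 2] = 0  # ensure sparse
        with pytest.raises(ValueError, match="masked out"):
            apply_mask_and_normalize(study)

    def test_symmetry_and_zero_diagonal_preserved_through_pipeline(self):
        subs = tn.make_synthetic_cohort(tn.CohortConfig(
            n_pd=3, n_hc=3, n_rois=8, grid_shape=(14, 14, 14),
            edge_density=0.4, streamlines_per_edge=3, seed=5))
        names = sorted(subs[0].label_volume.labels.values())
        study = build_cohort_study(subs, names)
        for per in study.matrices.values():
            for m in per.values():
                assert np.array_equal(m.weights, m.weights.T)
                assert np.all(np.diag(m.weights) == 0)
                assert m.weights.max() <= 1.0 or m.weighting is Weighting.NOS
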