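"""Local normal estimation, MID clustering, bias-corrected overlaps."""

import numpy as np
import pytest

from midpipe import (AttackConfig, DecoderConfig, LinearTaskSpec, MIDSet,
                     cluster_mids, gen_linear_task, local_normals,
                     mid_overlaps, sample_boundary)
from midpipe.boundary import AttackCloud
from midpipe.mids import NormalVector, _smallest_eigvec
from midpipe.patterns import LabeledPatterns


def _cloud(vectors, u, subsample=None):
    vectors = np.asarray(vectors, dtype=float)
    n = len(vectors)
    sub = np.zeros(n, dtype=int) if subsample is None else subsample
    n_subs = int(sub.max()) + 1 if n else 1
    return AttackCloud(
        vectors=vectors,
        source_index=np.arange(n),
        source_label=np.ones(n, dtype=int),
        subsample=sub,
        margins=np.zeros(n),
        subsample_memberships=[np.flatnonzero(sub == s)
                               for s in range(n_subs)],
        decision_vectors=np.tile(np.asarray(u, dtype=float), (n_subs, 1)),
    )


class TestLocalNormals:
    def test_anchors_on_a_line_have_vertical_normals(self):
        xs = np.linspace(-5, 5, 40)
        cloud = _cloud(np.column_stack([xs, np.zeros(40)]), u=[0.0, 1.0])
        normals = local_normals(cloud)
        for nv in normals:
            assert abs(nv.direction @ np.array([1.0, 0.0])) < 1e-6
            assert nv.direction[1] > 0  # oriented into +1 hemispace

    def test_single_difference_vector_orthogonal(self):
        # rank-1 scatter in 2-D: smallest eigenvector is exactly
        # perpendicular to the lone difference vector
        d = np.array([[3.0, 1.0]])
        n = _smallest_eigvec(d)
        assert abs(n @ d[0]) < 1e-9
        assert np.linalg.norm(n) == pytest.approx(1.0)

    def test_eigen_solution_beats_random_directions(self):
        rng = np.random.default_rng(0)
        diffs = rng.standard_normal((12, 4))
        n = _smallest_eigvec(diffs)
        obj = np.sum((diffs @ n) ** 2)
        rand = rng.standard_normal((100_000, 4))
        rand /= np.linalg.norm(rand, axis=1, keepdims=True)
        rand_obj = np.sum((rand @ diffs.T) ** 2, axis=1)
        assert obj <= rand_obj.min()

    def test_label_flip_flips_normals(self):
        xs = np.linspace(-5, 5, 30)
        pts = np.column_stack([xs, np.zeros(30)])
        up = local_normals(_cloud(pts, u=[0.0, 1.0]))
        down = local_normals(_cloud(pts, u=[0.0, -1.0]))
        for a, b in zip(up, down):
            np.testing.assert_allclose(a.direction, -b.direction, atol=1e-12)

    def test_empty_cloud_rejected(self):
        cloud = _cloud(np.empty((0, 2)), u=[1.0, 0.0])
        with pytest.raises(ValueError):
            local_normals(cloud)


class TestClustering:
    def _normals(self, directions, subsamples=None):
        directions = np.asarray(directions, dtype=float)
        if subsamples is None:
            subsamples = np.zeros(len(directions), dtype=int)
        return [
            NormalVector(direction=d / np.linalg.norm(d),
                         anchor=np.zeros(directions.shape[1]),
                         subsample=int(s), neighborhood_size=5)
            for d, s in zip(directions, subsamples)
        ]

    def test_identical_normals_single_full_cluster(self):
        normals = self._normals(np.tile([0.0, 1.0], (50, 1)))
        ms = cluster_mids(normals, n_subsamples=1)
        assert ms.n_clusters == 1
        assert ms.amount[0] == pytest.approx(1.0)
        assert ms.consistency[0] == pytest.approx(1.0)
        np.testing.assert_allclose(ms.representatives[0], [0.0, 1.0])

    def test_orthogonal_bundles_stay_separate(self):
        # two tight bundles 90 degrees apart: unit-vector distance sqrt(2)
        # exceeds eps=0.25, so DBSCAN keeps them distinct
        a = np.tile([1.0, 0.0, 0.0], (30, 1))
        b = np.tile([0.0, 1.0, 0.0], (30, 1))
        ms = cluster_mids(self._normals(np.vstack([a, b])), n_subsamples=1)
        assert ms.n_clusters == 2

    def test_amount_sums_below_one(self):
        rng = np.random.default_rng(1)
        dirs = rng.standard_normal((100, 6))
        subs = np.repeat(np.arange(4), 25)
        ms = cluster_mids(self._normals(dirs, subs), n_subsamples=4)
        assert ms.amount.sum() <= 1.0 + 1e-12
        assert np.all((0 <= ms.consistency) & (ms.consistency <= 1))

    def test_cluster_found_everywhere_has_full_consistency(self):
        dirs = np.tile([0.0, 0.0, 1.0], (40, 1))
        subs = np.repeat(np.arange(4), 10)
        ms = cluster_mids(self._normals(dirs, subs), n_subsamples=4)
        assert ms.n_clusters == 1
        assert ms.consistency[0] == pytest.approx(1.0)


class TestOverlaps:
    def _midset(self, n_vec, bias):
        n_vec = np.asarray(n_vec, dtype=float)[None, :]
        return MIDSet(representatives=n_vec, amount=np.array([1.0]),
                      consistency=np.array([1.0]),
                      bias=np.asarray(bias, dtype=float)[None, :],
                      cluster_members=[np.arange(1)])

    def test_pattern_at_bias_has_zero_overlap(self):
        ms = self._midset([1.0, 0.0], bias=[2.0, 3.0])
        p = LabeledPatterns(matrix=np.array([[2.0, 3.0]]),
                            labels=np.array([1]), bin_width=0.1)
        q = mid_overlaps(ms, p)
        assert q[0, 0] == pytest.approx(0.0)

    def test_unit_offset_along_mid_gives_one(self):
        n = np.array([0.6, 0.8])
        ms = self._midset(n, bias=[1.0, 1.0])
        p = LabeledPatterns(matrix=(np.array([1.0, 1.0]) + n)[None, :],
                            labels=np.array([1]), bin_width=0.1)
        q = mid_overlaps(ms, p)
        assert q[0, 0] == pytest.approx(1.0)

    def test_positive_class_has_larger_mean_overlap(self):
        p, _ = gen_linear_task(LinearTaskSpec(n_dims=10, signal_d=6.0,
                                              n_patterns=300, seed=2))
        cfg = AttackConfig(n_subsamples=8,
                           decoder=DecoderConfig(epochs=400, seed=3), seed=4)
        cloud = sample_boundary(p, cfg)
        ms = cluster_mids(local_normals(cloud), n_subsamples=8)
        q = mid_overlaps(ms, p)
        top = 0  # clusters are ordered by amount
        assert (q[p.labels == 1, top].mean()
                > q[p.labels == -1, top].mean())

    def test_dimension_mismatch_rejected(self):
        ms = self._midset([1.0, 0.0], bias=[0.0, 0.0])
        p = LabeledPatterns(matrix=np.zeros((4, 3)),
                            labels=np.array([1, -1, 1, -1]), bin_width=0.1)
        with pytest.raises(ValueError):
            mid_overlaps(ms, p)


class TestGroundTruthRecovery:
    def test_top_mid_aligns_with_planted_direction(self):
        p, t = gen_linear_task(LinearTaskSpec(n_dims=10, signal_d=6.0,
                                              n_patterns=300, seed=5))
        cfg = AttackConfig(n_subsamples=10,
                           decoder=DecoderConfig(epochs=400, seed=6), seed=7)
        cloud = sample_boundary(p, cfg)
        ms = cluster_mids(local_normals(cloud), n_subsamples=10)
        assert ms.n_clusters >= 1
        assert abs(ms.representatives[0] @ t.weight_vector) > 0.9
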