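"""Most informative directions from boundary-proximal point clouds.

A most informative direction (MID) is a direction in population-vector
space locally orthogonal to the classifier's decision boundary.  At each
attack vector ``a_t`` the local normal is the unit vector minimizing the
summed squared scalar product with the difference vectors to neighbors in a
ring-shaped vicinity — equivalently the eigenvector with the smallest
eigenvalue of ``sum_k d_k d_k^T``.  Normals are oriented to point into the
+1 hemispace (the softmax probability of class +1 increases along them).

Within each data subsample the normals are clustered with DBSCAN; a second
DBSCAN over the per-subsample cluster representatives matches clusters
across subsamples.  Each final cluster carries an *amount* (mean fraction
of a subsample's normals it absorbs) and a *consistency* (fraction of
subsamples in which it reappears), plus a bias vector: the center of
gravity of the attack vectors it is built from.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN

from .boundary import AttackCloud
from .patterns import LabeledPatterns

logger = logging.getLogger(__name__)

__all__ = ["NormalVector", "MIDSet", "local_normals", "cluster_mids",
           "mid_overlaps"]


@dataclass
class NormalVector:
    """Unit normal estimated at one attack-vector anchor."""

    direction: np.ndarray
    anchor: np.ndarray
    subsample: int
    neighborhood_size: int


@dataclass
class MIDSet:
    representatives: np.ndarray     # (C, N) unit vectors
    amount: np.ndarray              # (C,) alpha
    consistency: np.ndarray         # (C,) chi
    bias: np.ndarray                # (C, N)
    cluster_members: list           # per cluster: indices into the normal list
    dbscan_eps: float = 0.25
    dbscan_min_frac: float = 0.03
    n_subsamples: int = 1

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def order_by_amount(self) -> np.ndarray:
        return np.argsort(-self.amount)


def _smallest_eigvec(D: np.ndarray) -> np.ndarray:
    """Unit eigenvector with the smallest eigenvalue of ``D^T D`` scatter."""
    M = D.T @ D
    _, vecs = np.linalg.eigh(M)
    return vecs[:, 0]


def local_normals(cloud: AttackCloud, r_frac: float = 0.02,
                  R_frac: float = 0.35, min_neighbors: int = 3):
    """Estimate a local boundary normal at every attack vector.

    Neighbors of anchor ``a_t`` are the attack vectors of the *same
    subsample* at ring distances ``(r_t, R_t)`` with
    ``r_t = r_frac * max_t' D(a_t, a_t')`` and likewise ``R_t``.  When the
    ring holds fewer than ``min_neighbors`` points (pairwise distances
    concentrate in high dimension once the class separation is weak) the
    anchor falls back to its nearest neighbors beyond ``r_t`` — enough to
    span the local tangent space; anchors that still lack neighbors are
    skipped.

    Neighborhoods are formed over the *distinct* attack-vector positions of
    the subsample: duplicated patterns (common for sparse spike counts)
    yield duplicated attack vectors that add no geometric information but
    would make the neighbor scatter rank-deficient.
    """
    if cloud.n_vectors == 0:
        raise ValueError("attack cloud is empty")
    normals = []
    n_skipped = 0
    n_fallback = 0
    dim = cloud.vectors.shape[1]
    for s in np.unique(cloud.subsample):
        rows = np.flatnonzero(cloud.subsample == s)
        A = cloud.vectors[rows]
        V = np.unique(np.round(A, 9), axis=0)       # distinct positions
        if len(V) < min_neighbors + 1:
            n_skipped += len(A)
            continue
        u = cloud.decision_vectors[s]
        D = cdist(A, V)
        dmax = D.max(axis=1)
        # the eigen-estimate needs the neighbor scatter to span the local
        # tangent space; rings that leave the scatter rank-deficient (all
        # too common for discrete spike counts) are grown with the nearest
        # distinct neighbors beyond r_t until the second-smallest
        # eigenvalue separates from zero
        span_target = max(min_neighbors, dim + 4)
        for i in range(len(A)):
            ring = (D[i] > r_frac * dmax[i]) & (D[i] < R_frac * dmax[i])
            outside = D[i] > r_frac * dmax[i]
            cand = np.flatnonzero(outside & ~ring)
            cand = cand[np.argsort(D[i][cand])]      # nearest first
            sel = ring.copy()
            K = int(sel.sum())
            grown = False
            if K < span_target:
                n_add = min(len(cand), span_target - K)
                sel[cand[:n_add]] = True
                cand = cand[n_add:]
                K += n_add
                grown = n_add > 0
            if K < min_neighbors:
                n_skipped += 1
                continue
            while True:
                diffs = A[i] - V[sel]
                vals, vecs = np.linalg.eigh(diffs.T @ diffs)
                if vals[1] > 1e-9 * max(vals[-1], 1e-300) or not len(cand):
                    break
                n_add = min(len(cand), dim)          # grow and retry
                sel[cand[:n_add]] = True
                cand = cand[n_add:]
                K += n_add
                grown = True
            n_fallback += grown
            n = vecs[:, 0]
            if n @ u < 0:           # orient into the +1 hemispace
                n = -n
            normals.append(NormalVector(direction=n, anchor=A[i],
                                        subsample=int(s),
                                        neighborhood_size=K))
    if not normals:
        raise ValueError(
            f"all {cloud.n_vectors} anchors skipped "
            f"(min_neighbors={min_neighbors}); cloud too sparse"
        )
    if n_fallback:
        logger.info("nearest-neighbor fallback used at %d anchor(s)", n_fallback)
    if n_skipped:
        logger.info("skipped %d anchor(s) with sparse ring neighborhoods",
                    n_skipped)
    return normals


def _dbscan(X: np.ndarray, eps: float, min_frac: float) -> np.ndarray:
    min_samples = max(2, math.ceil(min_frac * len(X)))
    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(X)


def cluster_mids(normals, n_subsamples: Optional[int] = None,
                 eps: float = 0.25, min_frac: float = 0.03) -> MIDSet:
    """Cluster local normals into MIDs with amount and consistency scores.

    Stage 1 runs DBSCAN (Euclidean, ``eps``, ``min_samples`` = ``min_frac``
    of the subsample's normals) within each subsample.  Stage 2 matches
    clusters across subsamples by a second DBSCAN on the pooled
    per-subsample representatives (same parameters).  Amount alpha(c)
    averages, over all subsamples, the fraction of that subsample's normals
    in c; consistency chi(c) is the fraction of subsamples where c was
    found.  The final representative is the renormalized mean of all member
    normals, the bias the centroid of their anchors.
    """
    if not normals:
        raise ValueError("no normal vectors to cluster")
    dirs = np.array([nv.direction for nv in normals])
    anchors = np.array([nv.anchor for nv in normals])
    subs = np.array([nv.subsample for nv in normals])
    uniq_subs = np.unique(subs)
    if n_subsamples is None:
        n_subsamples = len(uniq_subs)

    # stage 1: per-subsample clusters
    reps, rep_sub, rep_frac, rep_members = [], [], [], []
    for s in uniq_subs:
        rows = np.flatnonzero(subs == s)
        lab = _dbscan(dirs[rows], eps, min_frac)
        for c in np.unique(lab[lab >= 0]):
            members = rows[lab == c]
            v = dirs[members].mean(axis=0)
            nrm = np.linalg.norm(v)
            if nrm == 0:
                continue
            reps.append(v / nrm)
            rep_sub.append(s)
            rep_frac.append(len(members) / len(rows))
            rep_members.append(members)

    if not reps:
        logger.info("all normals labeled noise; returning empty MID set")
        return MIDSet(representatives=np.empty((0, dirs.shape[1])),
                      amount=np.empty(0), consistency=np.empty(0),
                      bias=np.empty((0, dirs.shape[1])), cluster_members=[],
                      dbscan_eps=eps, dbscan_min_frac=min_frac,
                      n_subsamples=n_subsamples)

    reps = np.array(reps)
    rep_sub = np.array(rep_sub)
    rep_frac = np.array(rep_frac)

    # stage 2: match clusters across subsamples
    if len(reps) == 1:
        final = np.zeros(1, dtype=int)
    else:
        final = _dbscan(reps, eps, min_frac)
        if np.all(final < 0):      # every representative isolated: keep each
            final = np.arange(len(reps))

    out_rep, out_alpha, out_chi, out_bias, out_members = [], [], [], [], []
    for c in np.unique(final[final >= 0]):
        which = np.flatnonzero(final == c)
        members = np.concatenate([rep_members[i] for i in which])
        v = dirs[members].mean(axis=0)
        nrm = np.linalg.norm(v)
        if nrm == 0:
            continue
        out_rep.append(v / nrm)
        out_alpha.append(rep_frac[which].sum() / n_subsamples)
        out_chi.append(len(np.unique(rep_sub[which])) / n_subsamples)
        out_bias.append(anchors[members].mean(axis=0))
        out_members.append(members)
    order = np.argsort(-np.asarray(out_alpha))
    return MIDSet(
        representatives=np.array(out_rep)[order],
        amount=np.asarray(out_alpha)[order],
        consistency=np.asarray(out_chi)[order],
        bias=np.array(out_bias)[order],
        cluster_members=[out_members[i] for i in order],
        dbscan_eps=eps,
        dbscan_min_frac=min_frac,
        n_subsamples=n_subsamples,
    )


def mid_overlaps(midset: MIDSet, patterns: LabeledPatterns) -> np.ndarray:
    """Bias-corrected overlaps ``q_t(c) = n(c) . (x_t - b(c))``, shape (T, C)."""
    if midset.n_clusters == 0:
        raise ValueError("MID set has no clusters")
    X = patterns.matrix
    if X.shape[1] != midset.representatives.shape[1]:
        raise ValueError("pattern and MID dimensionality differ")
    # q = X n^T - (b . n) per cluster
    proj = X @ midset.representatives.T
    offset = np.einsum("cn,cn->c", midset.bias, midset.representatives)
    return proj - offset[None, :]
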