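"""Decision-boundary sampling with minimal-step FGSM attacks.

The fast gradient sign method perturbs a pattern along the elementwise sign
of the input gradient of the cross-entropy loss.  Applied with the smallest
step that flips the predicted class, it lands a pattern just past the
decision boundary; applying the attack a second time (targeting the class
the first attack reached) re-crosses the boundary, so the doubly attacked
vector ``a_t = A(A(x_t))`` sits within one refinement step of it.

To avoid overfitting a single classifier's boundary, the attack set is
rebuilt over many stratified half-subsamples of the data, each with its own
retrained classifier.  Attack vectors whose softmax output strays more than
a tolerance from 0.5 are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .decoder import DecoderConfig, _train_masked, softmax_probs
from .patterns import LabeledPatterns

logger = logging.getLogger(__name__)

__all__ = ["AttackConfig", "AttackCloud", "fgsm_minimal", "sample_boundary"]


@dataclass(frozen=True)
class AttackConfig:
    n_subsamples: int = 100
    boundary_tol: float = 0.05      # max |softmax - 0.5| for admission
    eps_min: float = 1e-3
    eps_max: float = 10.0
    n_grid: int = 40                # geometric epsilon grid
    refine_tol: float = 1e-4        # bisection resolution
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    seed: int = 0


@dataclass
class AttackCloud:
    """Boundary-proximal vectors with their provenance."""

    vectors: np.ndarray             # (M, N)
    source_index: np.ndarray        # (M,) row in the full pattern matrix
    source_label: np.ndarray        # (M,)
    subsample: np.ndarray           # (M,) subsample id
    margins: np.ndarray             # (M,) |p(+1) - 0.5| under own classifier
    subsample_memberships: list     # per-subsample row index arrays
    decision_vectors: np.ndarray    # (n_subsamples, N) u = W[1] - W[0]
    n_dropped: int = 0

    @property
    def n_vectors(self) -> int:
        return len(self.vectors)


def _attack_batch(u, X, labels, cfg: AttackConfig, refine_tol=None):
    """Minimal-eps FGSM on every row of X at once.

    ``labels`` is the class (+/-1) the attack tries to escape from; rows
    already classified against ``labels`` keep eps = 0.  Rows that no eps in
    ``[eps_min, eps_max]`` flips are marked failed.

    Returns (attacked X, failed mask).
    """
    if refine_tol is None:
        refine_tol = cfg.refine_tol
    g = -labels[:, None] * np.sign(u)[None, :]      # FGSM direction per row
    z = X @ u                                       # decision values
    correct = np.sign(z) == labels                  # z==0 predicts +1: treat
    correct |= (z == 0) & (labels == 1)
    du = g @ u                                      # decision shift per unit eps
    eps_grid = np.geomspace(cfg.eps_min, cfg.eps_max, cfg.n_grid)

    eps_star = np.zeros(len(X))
    failed = np.zeros(len(X), dtype=bool)
    todo = correct.copy()
    if np.any(todo):
        # smallest grid eps whose step flips sign(z)
        znew = z[todo, None] + np.outer(du[todo], eps_grid)
        flipped = np.sign(znew) != labels[todo, None]
        any_flip = flipped.any(axis=1)
        first = np.argmax(flipped, axis=1)
        idx = np.flatnonzero(todo)
        failed[idx[~any_flip]] = True
        ok = idx[any_flip]
        hi = eps_grid[first[any_flip]]
        lo = np.where(first[any_flip] > 0, eps_grid[first[any_flip] - 1], 0.0)
        # bisection refine: keep the smallest flipping eps
        while np.any(hi - lo > refine_tol):
            mid = 0.5 * (hi + lo)
            zf = z[ok] + du[ok] * mid
            f = np.sign(zf) != labels[ok]
            hi = np.where(f, mid, hi)
            lo = np.where(f, lo, mid)
        eps_star[ok] = hi
    return X + eps_star[:, None] * g, failed


def fgsm_minimal(weights: np.ndarray, x: np.ndarray, label: int,
                 config: AttackConfig = AttackConfig()):
    """Attack a single pattern; returns (attacked vector, flipped flag).

    ``label`` is the source class; if ``x`` is already classified against
    it the minimal step is zero and ``x`` is returned unchanged.
    """
    u = weights[1] - weights[0]
    ax, failed = _attack_batch(u, np.atleast_2d(np.asarray(x, dtype=float)),
                               np.asarray([label]), config)
    return ax[0], not failed[0]


def sample_boundary(patterns: LabeledPatterns,
                    config: AttackConfig = AttackConfig()) -> AttackCloud:
    """Collect doubly attacked vectors over stratified half-subsamples.

    Per subsample: draw a stratified half of the bins, retrain the decoder
    on it, attack every member pattern twice (the second attack targets the
    class the first attack reached), and admit the result if its softmax
    margin is below ``config.boundary_tol``.
    """
    X, labels = patterns.matrix, patterns.labels
    T, N = X.shape
    rng = np.random.default_rng(config.seed)
    dec = config.decoder

    vecs, src, slab, ssub, marg = [], [], [], [], []
    memberships, decision = [], np.empty((config.n_subsamples, N))
    n_dropped = 0
    class_idx = [np.flatnonzero(labels == c) for c in (-1, 1)]
    for s in range(config.n_subsamples):
        members = np.concatenate(
            [rng.permutation(idx)[: (len(idx) + 1) // 2] for idx in class_idx]
        )
        members.sort()
        sub_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0xA77, s])
        )
        mask = np.zeros(T, dtype=bool)
        mask[members] = True
        Y01 = ((labels + 1) // 2)[None, :]
        W = _train_masked(X, Y01, mask.astype(float)[None, :],
                          dec.epochs, dec.learning_rate, sub_rng)[0]
        u = W[1] - W[0]
        decision[s] = u

        Xs, ls = X[members], labels[members]
        a1, fail1 = _attack_batch(u, Xs, ls, config)
        # second attack escapes the class the first attack reached; it
        # refines an order of magnitude further so AAx lands strictly
        # closer to the boundary than Ax
        reached = np.where(a1 @ u >= 0, 1, -1)
        a2, fail2 = _attack_batch(u, a1, reached, config,
                                  refine_tol=config.refine_tol / 10.0)
        p1 = softmax_probs(W, a2)[:, 1]
        m = np.abs(p1 - 0.5)
        keep = ~(fail1 | fail2) & (m < config.boundary_tol)
        n_dropped += int((~keep).sum())
        vecs.append(a2[keep])
        src.append(members[keep])
        slab.append(ls[keep])
        ssub.append(np.full(int(keep.sum()), s))
        marg.append(m[keep])
        memberships.append(members)
    if n_dropped:
        logger.info("dropped %d attack vector(s) failing the boundary check",
                    n_dropped)
    return AttackCloud(
        vectors=np.concatenate(vecs) if vecs else np.empty((0, N)),
        source_index=np.concatenate(src),
        source_label=np.concatenate(slab),
        subsample=np.concatenate(ssub),
        margins=np.concatenate(marg),
        subsample_memberships=memberships,
        decision_vectors=decision,
        n_dropped=n_dropped,
    )
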