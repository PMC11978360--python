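"""Linear softmax decoding with cross-validated CCR and permutation nulls.

The classifier is a bias-free linear two-node network ``O = softmax(W x)``
trained by full-batch gradient descent on the cross-entropy loss.  Decoding
performance is the correct classification rate (CCR): the mean test-set
accuracy over repeated stratified 2-fold splits.  Statistical significance
comes from a label-permutation null: the full cross-validation procedure is
repeated on shuffled labels and the p value is the percentile of the real
CCR in the null CCR distribution.

Per-bin prediction scores (PS) record, for every time bin, the fraction of
cross-validation repetitions in which its population vector was classified
correctly while held out.

Class convention: output node 0 <-> label -1 (left), node 1 <-> label +1
(right).  The decision value of a pattern is ``u . x`` with
``u = W[1] - W[0]``; its sign gives the predicted label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .patterns import LabeledPatterns

__all__ = [
    "DecoderConfig",
    "DecoderResult",
    "train_classifier",
    "softmax_probs",
    "crossval_ccr",
    "label_shuffle_pvalue",
]


@dataclass(frozen=True)
class DecoderConfig:
    epochs: int = 1000
    learning_rate: float = 0.001
    n_splits: int = 100
    n_label_shuffles: int = 1000
    shuffle_level: str = "bin"  # "bin" or "trial" (blocked by trial)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.n_splits < 1:
            raise ValueError("epochs and n_splits must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.shuffle_level not in ("bin", "trial"):
            raise ValueError("shuffle_level must be 'bin' or 'trial'")


@dataclass
class DecoderResult:
    weights: np.ndarray            # (2, N) mean over split classifiers
    split_weights: np.ndarray      # (n_splits, 2, N)
    ccr: float
    prediction_scores: np.ndarray  # (T,), NaN where never tested
    ps_test_counts: np.ndarray     # (T,) times each bin appeared in a test fold
    split_assignments: np.ndarray  # (n_splits, T) bool, True = train
    null_ccrs: Optional[np.ndarray] = None
    p_value: Optional[float] = None
    p_value_add_one: Optional[float] = None


def softmax_probs(weights: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Two-class softmax outputs for rows of ``X`` under weight matrix (2, N)."""
    X = np.atleast_2d(X)
    h = X @ weights.T                      # (T, 2)
    h = h - h.max(axis=1, keepdims=True)
    e = np.exp(h)
    return e / e.sum(axis=1, keepdims=True)


def _init_weights(shape, rng):
    return rng.uniform(-0.01, 0.01, size=shape)


def _train_masked(X, Y01, mask, epochs, lr, rng):
    """Train B independent classifiers that share the pattern matrix.

    Parameters
    ----------
    X : (T, N) patterns.
    Y01 : (B, T) class indices in {0, 1} (one label vector per classifier).
    mask : (B, T) float, 1 where the row belongs to that classifier's
        training set.  This lets one batched gradient-descent loop serve
        every (split, shuffle) combination at once.

    Returns
    -------
    (B, 2, N) weight matrices.
    """
    B, T = Y01.shape
    N = X.shape[1]
    W = _init_weights((B, 2, N), rng)
    # The cross-entropy gradient rows satisfy dW0 = -dW1, so the row sum
    # W0 + W1 never moves and the dynamics reduce exactly to logistic
    # regression on the difference U = W1 - W0 with doubled learning rate:
    # softmax node-1 probability is sigma(U . x).
    S0 = W[:, 0, :] + W[:, 1, :]
    U = np.ascontiguousarray(W[:, 1, :] - W[:, 0, :])     # (B, N)
    counts = mask.sum(axis=1)
    step = (2.0 * lr) / counts                            # (B,)
    Y1 = Y01.T.astype(float)                              # (T, B)
    Mt = np.ascontiguousarray(mask.T)                     # (T, B)
    Xt = np.ascontiguousarray(X)
    for _ in range(epochs):
        Z = Xt @ U.T                                      # (T, B)
        P = expit(Z)
        G = (P - Y1) * Mt
        dU = G.T @ Xt                                     # (B, N)
        U -= step[:, None] * dU
    W[:, 0, :] = (S0 - U) / 2.0
    W[:, 1, :] = (S0 + U) / 2.0
    return W


def train_classifier(patterns: LabeledPatterns, config: DecoderConfig = DecoderConfig(),
                     train_mask: Optional[np.ndarray] = None,
                     rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Train one linear softmax classifier; returns the (2, N) weight matrix."""
    X, labels = patterns.matrix, patterns.labels
    if train_mask is None:
        train_mask = np.ones(len(labels), dtype=bool)
    tl = labels[train_mask]
    if np.unique(tl).size < 2:
        raise ValueError("training set must contain both classes")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    Y01 = ((labels + 1) // 2)[None, :]
    W = _train_masked(X, Y01, train_mask.astype(float)[None, :],
                      config.epochs, config.learning_rate, rng)
    return W[0]


def stratified_half_splits(labels: np.ndarray, n_splits: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Boolean train masks (n_splits, T); test = ~train.

    Each split preserves the class ratio; with an odd class count the extra
    pattern goes to training.
    """
    T = len(labels)
    masks = np.zeros((n_splits, T), dtype=bool)
    class_idx = [np.flatnonzero(labels == c) for c in (-1, 1)]
    for s in range(n_splits):
        for idx in class_idx:
            perm = rng.permutation(idx)
            n_train = (len(idx) + 1) // 2
            masks[s, perm[:n_train]] = True
    return masks


def _cv_ccr_batch(X, labels_batch, n_splits, config, rng):
    """CCR (and optionally PS bookkeeping) for B label vectors at once.

    For each label vector an independent set of stratified half splits is
    drawn; all (label vector x split) classifiers are trained in a single
    batched gradient-descent pass.

    Returns (ccrs (B,), correct_counts (B, T), test_counts (B, T),
    split_weights (B, n_splits, 2, N), train_masks (B, n_splits, T)).
    """
    B, T = labels_batch.shape
    N = X.shape[1]
    train = np.empty((B, n_splits, T), dtype=bool)
    for b in range(B):
        train[b] = stratified_half_splits(labels_batch[b], n_splits, rng)
    flat_train = train.reshape(B * n_splits, T)
    Y01 = np.repeat((labels_batch + 1) // 2, n_splits, axis=0)   # (B*S, T)
    W = _train_masked(X, Y01, flat_train.astype(float),
                      config.epochs, config.learning_rate, rng)  # (B*S, 2, N)
    u = W[:, 1, :] - W[:, 0, :]                                  # (B*S, N)
    scores = X @ u.T                                             # (T, B*S)
    pred = np.where(scores.T >= 0, 1, -1)                        # (B*S, T)
    correct = pred == np.repeat(labels_batch, n_splits, axis=0)
    test = ~flat_train
    correct_test = correct & test
    frac = correct_test.sum(axis=1) / test.sum(axis=1)           # (B*S,)
    ccrs = frac.reshape(B, n_splits).mean(axis=1)
    correct_counts = correct_test.reshape(B, n_splits, T).sum(axis=1)
    test_counts = test.reshape(B, n_splits, T).sum(axis=1)
    return ccrs, correct_counts, test_counts, W.reshape(B, n_splits, 2, N), train


def crossval_ccr(patterns: LabeledPatterns,
                 config: DecoderConfig = DecoderConfig()) -> DecoderResult:
    """CCR over repeated stratified 2-fold cross-validation, with PS per bin."""
    X, labels = patterns.matrix, patterns.labels
    counts = [int((labels == c).sum()) for c in (-1, 1)]
    if min(counts) < 2:
        raise ValueError("each class needs at least 2 patterns")
    if len(labels) < 4:
        raise ValueError("need at least 4 patterns for 2-fold cross-validation")
    rng = np.random.default_rng(config.seed)
    ccrs, cc, tc, W, train = _cv_ccr_batch(
        X, labels[None, :], config.n_splits, config, rng
    )
    with np.errstate(invalid="ignore"):
        ps = np.where(tc[0] > 0, cc[0] / np.maximum(tc[0], 1), np.nan)
    return DecoderResult(
        weights=W[0].mean(axis=0),
        split_weights=W[0],
        ccr=float(ccrs[0]),
        prediction_scores=ps,
        ps_test_counts=tc[0],
        split_assignments=train[0],
    )


def _shuffle_labels(labels, bin_origin, level, rng, size):
    """Uniform label permutations, at bin level or blocked by trial."""
    T = len(labels)
    out = np.empty((size, T), dtype=labels.dtype)
    if level == "bin":
        for i in range(size):
            out[i] = labels[rng.permutation(T)]
    else:
        trials = bin_origin[:, 0]
        uniq = np.unique(trials)
        trial_label = np.array([labels[trials == t][0] for t in uniq])
        for i in range(size):
            perm = trial_label[rng.permutation(len(uniq))]
            lab = np.empty(T, dtype=labels.dtype)
            for t, l in zip(uniq, perm):
                lab[trials == t] = l
            out[i] = lab
    return out


def label_shuffle_pvalue(patterns: LabeledPatterns,
                         config: DecoderConfig = DecoderConfig(),
                         result: Optional[DecoderResult] = None,
                         batch_size: int = 25):
    """Permutation null for the CCR.

    Labels are permuted uniformly (``config.n_label_shuffles`` times) and the
    full cross-validation CCR recomputed per shuffle.  The p value is the
    fraction of null CCRs >= the observed CCR; the add-one variant
    ``(r + 1) / (n + 1)`` is reported alongside.

    Returns the ``DecoderResult`` with ``null_ccrs`` and p values filled in.
    """
    if config.n_label_shuffles < 1:
        raise ValueError("n_label_shuffles must be >= 1")
    if result is None:
        result = crossval_ccr(patterns, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5D]))
    X, labels = patterns.matrix, patterns.labels
    null = np.empty(config.n_label_shuffles)
    done = 0
    while done < config.n_label_shuffles:
        b = min(batch_size, config.n_label_shuffles - done)
        lab = _shuffle_labels(labels, patterns.bin_origin,
                              config.shuffle_level, rng, b)
        ccrs, *_ = _cv_ccr_batch(X, lab, config.n_splits, config, rng)
        null[done:done + b] = ccrs
        done += b
    r = int((null >= result.ccr).sum())
    result.null_ccrs = null
    result.p_value = r / len(null)
    result.p_value_add_one = (r + 1) / (len(null) + 1)
    return result
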