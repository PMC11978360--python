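"""Synthetic validation data with planted ground truth.

Two generative models mirror the validation settings the decoding pipeline
is designed for:

* a linearly separable Gaussian task, where class means sit at ``+/- d/2``
  along a sparse unit ground-truth direction ``w`` in standard-normal noise;
* a homogeneous-Poisson spiking model, where a binary weight vector ``w``
  (one extra spike in ``round(s*n)`` neurons) is added to a random fraction
  ``1 - p_fail`` of the positive-label bins.

A third generator assembles full sessions (spike times, trial delay windows,
balanced labels, optional sinusoid-plus-noise LFP) with the same bin-level
statistics, so the whole pipeline from raw spike times onward is testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .patterns import LabeledPatterns, SpikeSession

__all__ = [
    "LinearTaskSpec",
    "SpikingTaskSpec",
    "GroundTruth",
    "SessionConfig",
    "gen_linear_task",
    "gen_spiking_task",
    "gen_session",
]


@dataclass(frozen=True)
class LinearTaskSpec:
    """Parameters of the linearly separable Gaussian task."""

    n_dims: int
    signal_d: float
    n_patterns: int
    sparseness_s: Optional[float] = None  # defaults to 1/n (one active dim)
    seed: int = 0

    def __post_init__(self):
        if self.n_dims < 2:
            raise ValueError("n_dims must be >= 2")
        if self.signal_d < 0:
            raise ValueError("signal_d must be nonnegative")
        if self.n_patterns < 2:
            raise ValueError("n_patterns must be >= 2")
        s = self.sparseness_s
        if s is None:
            object.__setattr__(self, "sparseness_s", 1.0 / self.n_dims)
        elif not 0 < s <= 1:
            raise ValueError("sparseness_s must be in (0, 1]")

    @property
    def n_active(self) -> int:
        return max(1, round(self.sparseness_s * self.n_dims))


@dataclass(frozen=True)
class SpikingTaskSpec:
    """Parameters of the Poisson spiking task with a planted binary pattern."""

    n_neurons: int
    rate_lambda: float
    sparseness_s: float
    p_fail: float
    n_patterns: int
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if self.rate_lambda < 0:
            raise ValueError("rate_lambda must be nonnegative")
        if not 0 < self.sparseness_s <= 1:
            raise ValueError("sparseness_s must be in (0, 1]")
        if not 0 <= self.p_fail <= 1:
            raise ValueError("p_fail must be in [0, 1]")
        if self.n_patterns < 2:
            raise ValueError("n_patterns must be >= 2")
        if round(self.sparseness_s * self.n_neurons) < 1:
            raise ValueError("sparseness_s * n_neurons must round to >= 1")

    @property
    def n_active(self) -> int:
        return round(self.sparseness_s * self.n_neurons)


@dataclass
class GroundTruth:
    """Planted structure: true direction, planted bins, labels."""

    weight_vector: np.ndarray
    planted_bin_indices: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.weight_vector = np.asarray(self.weight_vector, dtype=float)
        self.planted_bin_indices = np.asarray(self.planted_bin_indices, dtype=int)
        self.labels = np.asarray(self.labels)
        if not np.any(self.weight_vector):
            raise ValueError("weight_vector must be nonzero")
        if self.planted_bin_indices.size and not np.all(
            self.labels[self.planted_bin_indices] == 1
        ):
            raise ValueError("planted bins must carry label +1")


def _balanced_labels(T: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly balanced +/-1 labels in random order; odd T favors +1."""
    labels = np.empty(T, dtype=int)
    labels[: (T + 1) // 2] = 1
    labels[(T + 1) // 2:] = -1
    rng.shuffle(labels)
    return labels


def gen_linear_task(spec: LinearTaskSpec):
    """Draw the linearly separable Gaussian task.

    Each pattern is ``label * (d/2) * w + xi`` with ``xi ~ N(0, I)`` and
    ``w`` a unit vector with ``round(s*n)`` equal nonzero entries on
    seed-chosen dimensions.

    Returns
    -------
    (LabeledPatterns, GroundTruth)
    """
    rng = np.random.default_rng(spec.seed)
    n, T = spec.n_dims, spec.n_patterns
    active = rng.choice(n, size=spec.n_active, replace=False)
    w = np.zeros(n)
    w[active] = 1.0 / math.sqrt(spec.n_active)
    labels = _balanced_labels(T, rng)
    X = labels[:, None] * (spec.signal_d / 2.0) * w[None, :] + rng.standard_normal(
        (T, n)
    )
    patterns = LabeledPatterns(matrix=X, labels=labels, bin_width=1.0,
                               standardized=True)
    truth = GroundTruth(weight_vector=w, planted_bin_indices=np.array([], dtype=int),
                        labels=labels)
    return patterns, truth


def gen_spiking_task(spec: SpikingTaskSpec):
    """Draw Poisson counts and plant a binary pattern in positive bins.

    Counts are Poisson with mean ``lambda`` per neuron per unit-width bin.
    A binary vector with ``round(s*n)`` ones is added to the counts of a
    uniformly sampled subset of ``round((1-p_fail) * T+)`` positive-label
    bins; those bin indices are recorded as ground truth.

    Returns
    -------
    (LabeledPatterns, GroundTruth)
    """
    rng = np.random.default_rng(spec.seed)
    n, T = spec.n_neurons, spec.n_patterns
    labels = _balanced_labels(T, rng)
    X = rng.poisson(spec.rate_lambda, size=(T, n)).astype(float)
    active = rng.choice(n, size=spec.n_active, replace=False)
    w = np.zeros(n)
    w[active] = 1.0
    pos = np.flatnonzero(labels == 1)
    n_plant = round((1.0 - spec.p_fail) * pos.size)
    planted = rng.choice(pos, size=n_plant, replace=False) if n_plant else np.array([], dtype=int)
    X[planted] += w
    patterns = LabeledPatterns(matrix=X, labels=labels, bin_width=1.0,
                               standardized=False)
    truth = GroundTruth(weight_vector=w, planted_bin_indices=np.sort(planted),
                        labels=labels)
    return patterns, truth


@dataclass(frozen=True)
class SessionConfig:
    """Shape of a simulated recording session.

    ``rate_hz`` is the background rate per unit; with a plant, ``round(s*n)``
    units fire one extra spike in each planted bin of width ``bin_width``.
    """

    n_units: int = 20
    n_trials: int = 8
    delay_s: float = 60.0
    rate_hz: float = 1.0
    bin_width: float = 0.1
    plant_sparseness: Optional[float] = None
    plant_p_fail: float = 0.5
    inter_trial_gap_s: float = 5.0
    lfp_rate_hz: Optional[float] = None
    lfp_theta_hz: float = 8.0
    lfp_theta_amp: float = 1.0
    lfp_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_units < 1 or self.n_trials < 1:
            raise ValueError("need at least one unit and one trial")
        if self.delay_s <= 0 or self.bin_width <= 0 or self.inter_trial_gap_s < 0:
            raise ValueError("durations must be positive")
        if self.rate_hz < 0:
            raise ValueError("rate_hz must be nonnegative")
        if self.plant_sparseness is not None and not 0 < self.plant_sparseness <= 1:
            raise ValueError("plant_sparseness must be in (0, 1]")


def gen_session(config: SessionConfig):
    """Simulate a full session of spike times with delay windows and labels.

    Per-bin counts follow the Poisson model above (rate ``rate_hz * L`` per
    bin); spike times are placed uniformly inside their bin, so re-binning
    the session at ``config.bin_width`` reproduces the counts exactly.

    Returns
    -------
    (SpikeSession, GroundTruth)
        Ground-truth planted indices refer to rows of the binned pattern
        matrix (trials concatenated in order).
    """
    rng = np.random.default_rng(config.seed)
    n, L = config.n_units, config.bin_width
    bins_per_trial = int(math.floor(config.delay_s / L + 1e-9))
    period = config.delay_s + config.inter_trial_gap_s
    starts = period * np.arange(config.n_trials)
    trial_labels = _balanced_labels(config.n_trials, rng)

    T = bins_per_trial * config.n_trials
    labels = np.repeat(trial_labels, bins_per_trial)
    counts = rng.poisson(config.rate_hz * L, size=(T, n)).astype(float)

    w = np.zeros(n)
    planted = np.array([], dtype=int)
    if config.plant_sparseness is not None:
        n_active = max(1, round(config.plant_sparseness * n))
        active = rng.choice(n, size=n_active, replace=False)
        w[active] = 1.0
        pos = np.flatnonzero(labels == 1)
        n_plant = round((1.0 - config.plant_p_fail) * pos.size)
        if n_plant:
            planted = np.sort(rng.choice(pos, size=n_plant, replace=False))
            counts[planted] += w
    else:
        w = np.ones(n)  # no plant: ground truth degenerates to uniform

    unit_spikes = {}
    bin_start = np.repeat(starts, bins_per_trial) + L * np.tile(
        np.arange(bins_per_trial), config.n_trials
    )
    for j in range(n):
        c = counts[:, j].astype(int)
        # keep spikes off the bin edges so binning (and microsecond-precision
        # file round trips) assign them unambiguously
        offsets = (0.01 + 0.98 * rng.random(c.sum())) * L
        times = np.repeat(bin_start, c) + offsets
        unit_spikes[f"u{j:03d}"] = np.sort(times)

    lfp = None
    if config.lfp_rate_hz:
        fs = config.lfp_rate_hz
        duration = starts[-1] + period
        t = np.arange(int(duration * fs)) / fs
        trace = config.lfp_theta_amp * np.sin(
            2 * np.pi * config.lfp_theta_hz * t
        ) + config.lfp_noise_sd * rng.standard_normal(t.size)
        lfp = (trace, fs)

    session = SpikeSession(
        unit_spikes=unit_spikes,
        delay_windows=[
            (float(s), float(s + config.delay_s), int(lab))
            for s, lab in zip(starts, trial_labels)
        ],
        lfp=lfp,
        session_id=f"synthetic-{config.seed}",
    )
    truth = GroundTruth(weight_vector=w, planted_bin_indices=planted, labels=labels)
    return session, truth
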