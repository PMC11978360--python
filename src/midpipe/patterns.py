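"""Population vectors from spike sessions.

Spikes of all simultaneously recorded neurons are counted in time bins of
width ``L`` restricted to the delay windows of a session.  Each bin inherits
the binary behavioral label (+1 right / -1 left) of its trial.  Counts are
then standardized per neuron (z-scored over all delay bins of the session),
which puts every neuron on the same footing regardless of its mean rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeSession",
    "LabeledPatterns",
    "bin_delay_activity",
    "standardize_patterns",
]


@dataclass
class SpikeSession:
    """Raw per-unit spike times plus trial delay windows.

    Parameters
    ----------
    unit_spikes
        Mapping from unit id to a sorted 1-D array of spike times in seconds.
    delay_windows
        One ``(start_s, end_s, label)`` triple per trial, label in {-1, +1}.
    lfp
        Optional ``(trace, sample_rate_hz)`` tuple with a uniformly sampled
        local field potential.
    speed
        Optional per-bin running speed, aligned downstream.
    session_id
        Free-form identifier carried through to outputs.
    """

    unit_spikes: dict
    delay_windows: list
    lfp: Optional[tuple] = None
    speed: Optional[np.ndarray] = None
    session_id: str = "session"

    def __post_init__(self):
        for uid, st in self.unit_spikes.items():
            st = np.asarray(st, dtype=float)
            if st.size and (np.any(st < 0) or np.any(np.diff(st) < 0)):
                raise ValueError(
                    f"unit {uid!r}: spike times must be nonnegative and sorted"
                )
            self.unit_spikes[uid] = st
        windows = sorted(self.delay_windows, key=lambda w: w[0])
        for i, (s, e, lab) in enumerate(windows):
            if e <= s:
                raise ValueError(f"trial {i}: empty or inverted window ({s}, {e})")
            if lab not in (-1, 1):
                raise ValueError(f"trial {i}: label must be -1 or +1, got {lab!r}")
            if i and s < windows[i - 1][1]:
                raise ValueError(f"trial {i}: delay windows overlap")
        self.delay_windows = windows

    @property
    def n_units(self) -> int:
        return len(self.unit_spikes)

    @property
    def n_trials(self) -> int:
        return len(self.delay_windows)


@dataclass
class LabeledPatterns:
    """T x N matrix of per-bin per-neuron values with +/-1 labels.

    ``bin_origin`` records ``(trial index, within-delay bin index)`` per row
    so downstream statistics can place each bin inside its delay period.
    """

    matrix: np.ndarray
    labels: np.ndarray
    bin_width: float
    bin_origin: np.ndarray = field(default=None)
    neuron_ids: Sequence = field(default=None)
    standardized: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (bins x neurons)")
        if self.labels.shape[0] != self.matrix.shape[0]:
            raise ValueError("labels length must match number of rows")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be -1 or +1")
        if self.bin_origin is None:
            self.bin_origin = np.column_stack(
                [np.zeros(len(self.labels), dtype=int), np.arange(len(self.labels))]
            )
        else:
            self.bin_origin = np.asarray(self.bin_origin, dtype=int)
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.matrix.shape[1])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[1]


def bin_delay_activity(session: SpikeSession, bin_width: float) -> LabeledPatterns:
    """Count spikes per unit per bin inside the delay windows.

    The bin grid is anchored at each window start; a trailing partial bin is
    discarded.  Spikes on a bin edge belong to the later bin (half-open
    ``[t, t+L)`` intervals).  Units with zero spikes across all delay bins
    are removed.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not session.unit_spikes or not session.delay_windows:
        raise ValueError("session has no units or no delay windows")

    unit_ids = list(session.unit_spikes)
    blocks, labels, origin = [], [], []
    for trial, (start, end, lab) in enumerate(session.delay_windows):
        n_bins = int(math.floor((end - start) / bin_width + 1e-9))
        if n_bins == 0:
            continue
        edges = start + bin_width * np.arange(n_bins + 1)
        counts = np.empty((n_bins, len(unit_ids)))
        for j, uid in enumerate(unit_ids):
            counts[:, j], _ = np.histogram(session.unit_spikes[uid], bins=edges)
        blocks.append(counts)
        labels.extend([lab] * n_bins)
        origin.extend((trial, b) for b in range(n_bins))
    if not blocks:
        raise ValueError("no complete bins inside any delay window")

    matrix = np.concatenate(blocks, axis=0)
    active = matrix.sum(axis=0) > 0
    if not np.any(active):
        raise ValueError("all units are inactive in the delay windows")
    n_dropped = int((~active).sum())
    if n_dropped:
        logger.info("excluding %d unit(s) with no delay-period spikes", n_dropped)
    return LabeledPatterns(
        matrix=matrix[:, active],
        labels=np.asarray(labels),
        bin_width=bin_width,
        bin_origin=np.asarray(origin),
        neuron_ids=np.asarray(unit_ids, dtype=object)[active],
        standardized=False,
    )


def standardize_patterns(raw: LabeledPatterns) -> LabeledPatterns:
    """Z-score each neuron over all delay bins of the session.

    Uses the population (1/T) standard deviation.  Constant columns are
    excluded with a warning — the transform is undefined for them.
    """
    if raw.standardized:
        return raw
    mean = raw.matrix.mean(axis=0)
    sd = raw.matrix.std(axis=0)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("every column is constant; nothing to standardize")
    if not np.all(keep):
        logger.warning(
            "excluding %d constant column(s) from standardization", int((~keep).sum())
        )
    z = (raw.matrix[:, keep] - mean[keep]) / sd[keep]
    return replace(
        raw,
        matrix=z,
        neuron_ids=np.asarray(raw.neuron_ids)[keep],
        standardized=True,
    )
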