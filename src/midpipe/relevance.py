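"""Relevant time bins from neuron-index shuffle nulls.

A time bin is *relevant* for a MID when its bias-corrected overlap ``q_t(c)``
falls outside the central 95% of a null distribution obtained by shuffling
the neuron indices of its own population vector.  Bins above the 97.5th
percentile are predictive of "right" (+1), bins below the 2.5th percentile
of "left" (-1).  The null preserves each pattern's value multiset, so the
flags isolate *which neurons* carry the overlap, not how much total
activity a bin has.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .mids import MIDSet, mid_overlaps
from .patterns import LabeledPatterns

__all__ = ["RelevanceMask", "RelevanceStats", "relevance_mask",
           "relevance_stats"]


@dataclass
class RelevanceMask:
    overlaps: np.ndarray        # (T, C)
    lower: np.ndarray           # (T, C) null 2.5th percentile
    upper: np.ndarray           # (T, C) null 97.5th percentile
    flags: np.ndarray           # (T, C) int: +1 right, -1 left, 0 none
    n_shuffles: int
    percentiles: tuple

    @property
    def any_flag(self) -> np.ndarray:
        """Per-bin flag combined over clusters (+1/-1/0; right wins ties)."""
        right = np.any(self.flags == 1, axis=1)
        left = np.any(self.flags == -1, axis=1)
        return np.where(right, 1, np.where(left, -1, 0))


@dataclass
class RelevanceStats:
    fraction_relevant: dict     # percentages keyed 'left'/'right'/'any'
    rate_relevant_hz: float
    rate_nonrelevant_hz: float
    active_frac_relevant: float
    active_frac_nonrelevant: float
    ps_relevant: np.ndarray
    ps_nonrelevant: np.ndarray
    temporal_histogram: np.ndarray
    tests: dict


def relevance_mask(patterns: LabeledPatterns, midset: MIDSet,
                   n_shuffles: int = 1000, seed: int = 0,
                   percentiles: tuple = (2.5, 97.5)) -> RelevanceMask:
    """Flag bins whose MID overlap escapes its own neuron-shuffle null.

    Each bin draws a fresh set of ``n_shuffles`` uniform permutations of its
    pattern's entries; null overlaps use the same bias correction as the
    observed one.  Percentiles are linearly interpolated.
    """
    if midset.n_clusters == 0:
        raise ValueError("need at least one MID cluster")
    X = patterns.matrix
    T, N = X.shape
    if N < 3:
        raise ValueError("shuffle null degenerate with fewer than 3 neurons")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    q = mid_overlaps(midset, patterns)                     # (T, C)
    n_mat = midset.representatives.T                       # (N, C)
    offset = np.einsum("cn,cn->c", midset.bias, midset.representatives)

    lower = np.empty_like(q)
    upper = np.empty_like(q)
    p_lo, p_hi = percentiles
    for t in range(T):
        idx = rng.random((n_shuffles, N)).argsort(axis=1)
        null_q = X[t][idx] @ n_mat - offset[None, :]       # (S, C)
        lower[t] = np.percentile(null_q, p_lo, axis=0)
        upper[t] = np.percentile(null_q, p_hi, axis=0)

    flags = np.zeros(q.shape, dtype=int)
    flags[q > upper] = 1
    flags[q < lower] = -1
    return RelevanceMask(overlaps=q, lower=lower, upper=upper, flags=flags,
                         n_shuffles=n_shuffles, percentiles=percentiles)


def relevance_stats(mask: RelevanceMask, raw_counts: LabeledPatterns,
                    prediction_scores: Optional[np.ndarray] = None,
                    n_delay_segments: int = 10) -> RelevanceStats:
    """Population statistics of relevant vs non-relevant bins.

    Firing rates are per-bin means over neurons of ``count / L`` in Hz from
    the *raw* (unstandardized) counts; the fraction of active cells is the
    per-bin fraction of neurons with at least one spike.  Prediction scores
    are compared against chance (Wilcoxon signed-rank of PS - 0.5 in
    relevant bins) and between relevant and non-relevant bins
    (Mann-Whitney U).  The temporal histogram counts relevant bins in
    ``n_delay_segments`` equal segments of the delay period, with a
    chi-squared uniformity test.
    """
    if raw_counts.standardized:
        raise ValueError("relevance_stats needs raw (unstandardized) counts")
    flag = mask.any_flag
    T = len(flag)
    if T != raw_counts.n_bins:
        raise ValueError("mask and counts are misaligned")
    rel = flag != 0
    frac = {
        "right": 100.0 * float((flag == 1).mean()),
        "left": 100.0 * float((flag == -1).mean()),
        "any": 100.0 * float(rel.mean()),
    }
    L = raw_counts.bin_width
    rates = raw_counts.matrix.mean(axis=1) / L
    active = (raw_counts.matrix > 0).mean(axis=1)
    tests: dict = {}

    if not np.any(rel):
        return RelevanceStats(
            fraction_relevant=frac, rate_relevant_hz=float("nan"),
            rate_nonrelevant_hz=float(rates.mean()),
            active_frac_relevant=float("nan"),
            active_frac_nonrelevant=float(active.mean()),
            ps_relevant=np.empty(0), ps_nonrelevant=np.empty(0),
            temporal_histogram=np.zeros(n_delay_segments, dtype=int),
            tests={"note": "no relevant bins; comparisons undefined"},
        )

    if np.any(~rel):
        tests["rate_mannwhitney"] = stats.mannwhitneyu(
            rates[rel], rates[~rel], alternative="greater"
        )
        tests["active_mannwhitney"] = stats.mannwhitneyu(
            active[rel], active[~rel], alternative="greater"
        )

    ps_rel = np.empty(0)
    ps_non = np.empty(0)
    if prediction_scores is not None:
        ps = np.asarray(prediction_scores, dtype=float)
        ok = ~np.isnan(ps)
        ps_rel = ps[rel & ok]
        ps_non = ps[~rel & ok]
        d = ps_rel - 0.5
        if np.any(d != 0):
            tests["ps_wilcoxon_above_chance"] = stats.wilcoxon(
                d, alternative="greater"
            )
        if ps_non.size:
            tests["ps_mannwhitney"] = stats.mannwhitneyu(
                ps_rel, ps_non, alternative="greater"
            )

    # position of each relevant bin inside its delay period
    within = raw_counts.bin_origin[:, 1]
    n_per_trial = within.max() + 1
    seg = np.minimum(
        (within * n_delay_segments) // max(n_per_trial, 1), n_delay_segments - 1
    )
    hist = np.bincount(seg[rel], minlength=n_delay_segments)
    if hist.sum() >= n_delay_segments:
        tests["temporal_uniformity_chi2"] = stats.chisquare(hist)

    return RelevanceStats(
        fraction_relevant=frac,
        rate_relevant_hz=float(rates[rel].mean()),
        rate_nonrelevant_hz=float(rates[~rel].mean()) if np.any(~rel) else float("nan"),
        active_frac_relevant=float(active[rel].mean()),
        active_frac_nonrelevant=float(active[~rel].mean()) if np.any(~rel) else float("nan"),
        ps_relevant=ps_rel,
        ps_nonrelevant=ps_non,
        temporal_histogram=hist,
        tests=tests,
    )
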