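"""Session-level inference on decoding significance counts.

Groups of recording sessions are compared by the fraction of sessions whose
permutation test was significant: a Pearson chi-squared test of homogeneity
on the 2x2 significant/total table (no continuity correction) and, per
group, an exact one-sided binomial test of the significant-session count
against the nominal false-positive rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupComparison", "chi2_homogeneity", "significant_session_fraction"]


@dataclass(frozen=True)
class GroupComparison:
    k1: int
    n1: int
    k2: int
    n2: int
    chi2: float
    p: float


def chi2_homogeneity(k1: int, n1: int, k2: int, n2: int) -> GroupComparison:
    """Chi-squared homogeneity test on significant-session fractions.

    Builds the 2x2 table ``[[k1, n1-k1], [k2, n2-k2]]`` and computes the
    Pearson statistic without continuity correction (1 df).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("significant counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("degenerate margin; chi-squared statistic set to 0")
        return GroupComparison(k1, n1, k2, n2, 0.0, 1.0)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return GroupComparison(k1, n1, k2, n2, float(chi2), float(p))


def significant_session_fraction(p_values, alpha: float = 0.05):
    """Count significant sessions and test enrichment over the nominal rate.

    Returns ``(k, n, binomial_p)`` where ``k`` is the number of session
    p values <= alpha and ``binomial_p`` the exact one-sided (greater)
    binomial tail for ``k`` successes in ``n`` trials at success
    probability alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no session p values given")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    k = int((p <= alpha).sum())
    n = int(p.size)
    binom_p = stats.binomtest(k, n, alpha, alternative="greater").pvalue
    return k, n, float(binom_p)
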