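"""Shared statistical helpers."""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

EXACT_LIMIT = 12  # full enumeration up to C(12, 6) = 924 label splits


def ranksum_two_sided(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact by full enumeration of group-label assignments for small
    samples (combined n <= 12, correct under ties); the usual
    tie-corrected normal approximation otherwise.
    """
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    if n + m <= EXACT_LIMIT:
        pooled = np.asarray(x + y, dtype=float)
        ranks = rankdata(pooled)
        obs = ranks[:n].sum()
        centre = n * (n + m + 1) / 2.0
        null = [ranks[list(idx)].sum()
                for idx in combinations(range(n + m), n)]
        dev = abs(obs - centre)
        hits = sum(1 for s in null if abs(s - centre) >= dev - 1e-12)
        return hits / len(null)
    return float(mannwhitneyu(x, y, alternative="two-sided")[1])
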