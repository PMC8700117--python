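"""Compiled inner loops for template matching.

Hard (threshold) counting is done pairwise in a single pass so that very long
series (N ~ 2e4, ~2e8 template pairs) never materialise a distance matrix.
Fuzzy estimators need the actual distances, which are emitted as condensed
(upper-triangle) blocks so the caller can stream membership sums with bounded
memory.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def hard_match_counts(u, m, delta, r, min_sep):
    """Count template pairs matching within r at dimensions m and m+1.

    Templates are the N - m*delta delay-embedded vectors shared by both
    dimensions; pairs (i, j) with j - i < min_sep are excluded (min_sep=1
    excludes only self-matches). Returns (B, A, pairs) where B and A are the
    numbers of unordered matching pairs at dimensions m and m+1 and pairs is
    the number of unordered pairs considered.
    """
    count = u.size - m * delta
    b = 0
    a = 0
    pairs = 0
    for i in range(count):
        for j in range(i + min_sep, count):
            pairs += 1
            d = 0.0
            for k in range(m):
                t = abs(u[i + k * delta] - u[j + k * delta])
                if t > d:
                    d = t
                if d > r:
                    break
            if d <= r:
                b += 1
                if abs(u[i + m * delta] - u[j + m * delta]) <= r:
                    a += 1
    return b, a, pairs


@njit(cache=True, fastmath=True)
def chebyshev_condensed_block(x, row_start, row_stop, min_sep, out):
    """Chebyshev distances for template rows [row_start, row_stop) against all
    later rows, skipping pairs closer than min_sep in index.

    Writes into ``out`` and returns the number of distances written.
    """
    n = x.shape[0]
    m = x.shape[1]
    idx = 0
    for i in range(row_start, row_stop):
        for j in range(i + min_sep, n):
            d = 0.0
            for k in range(m):
                t = abs(x[i, k] - x[j, k])
                if t > d:
                    d = t
            out[idx] = d
            idx += 1
    return idx
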