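"""Numba hot loops for anchor chaining."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def chain_dp(rs, re, qs, qe, weight, max_gap, lookback, max_overlap):
    """Collinear chaining DP over match fragments sorted by (rs, qs).

    Score of extending chain ending at j with fragment i:
    score[j] + weight[i] - 0.5*|diag shift| - 0.01*gap, with chains
    terminated when either coordinate gap exceeds ``max_gap``.
    Ties break toward the earlier (smaller-index, i.e. earlier reference
    start, then earlier contig start) predecessor because strictly-greater
    comparison keeps the first best.
    """
    n = rs.size
    score = np.empty(n, dtype=np.float64)
    prev = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        best = float(weight[i])
        bp = -1
        j0 = i - lookback
        if j0 < 0:
            j0 = 0
        for j in range(j0, i):
            dr = rs[i] - re[j]
            dq = qs[i] - qe[j]
            if dr > max_gap or dq > max_gap:
                continue
            if dr < -max_overlap or dq < -max_overlap:
                continue
            if rs[i] <= rs[j] or qs[i] <= qs[j]:
                continue
            diag_shift = dr - dq
            if diag_shift < 0:
                diag_shift = -diag_shift
            g = dr if dr < dq else dq
            if g < 0:
                g = 0
            s = score[j] + weight[i] - 0.5 * diag_shift - 0.01 * g
            if s > best:
                best = s
                bp = j
        score[i] = best
        prev[i] = bp
    return score, prev
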