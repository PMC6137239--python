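"""Independent affine-gap global alignment oracle (Gotoh dynamic program)."""

from __future__ import annotations

import numpy as np

from magscreen.linking import AlignScoring

NEG_INF = -1e18


def gotoh_score(a: str, b: str, scoring: AlignScoring = AlignScoring()) -> float:
    """Optimal global alignment score; a gap of length L costs open + (L-1)*extend."""
    n, m = len(a), len(b)
    go, ge, ma, mi = scoring.gap_open, scoring.gap_extend, scoring.match, scoring.mismatch
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = ma if a[i - 1] == b[j - 1] else mi
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, Y[i, j - 1] + ge, X[i, j - 1] + go)
    return float(max(M[n, m], X[n, m], Y[n, m]))
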