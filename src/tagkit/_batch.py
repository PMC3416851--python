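"""Vectorized batch Levenshtein distances for equal-length candidate pools.

The design pipeline needs distances from one key to hundreds of thousands of
candidates. Rather than calling the scalar dynamic program per pair, the DP
is run once with every cell vectorized across the candidate axis: ``prev``
and ``cur`` are rows of shape ``(n_candidates,)`` and the recurrence is
evaluated with numpy element-wise minima. Results are exactly the scalar
Levenshtein distances.
"""

from __future__ import annotations

import numpy as np

__all__ = ["encode_pool", "levenshtein_to_pool"]


def encode_pool(sequences: list[str]) -> np.ndarray:
    """Pack equal-length sequences into a uint8 matrix of byte codes."""
    if not sequences:
        return np.empty((0, 0), dtype=np.uint8)
    n = len(sequences[0])
    if any(len(s) != n for s in sequences):
        raise ValueError("pool sequences must all have the same length")
    buf = "".join(sequences).encode("ascii")
    return np.frombuffer(buf, dtype=np.uint8).reshape(len(sequences), n)


def levenshtein_to_pool(key: str, pool: np.ndarray) -> np.ndarray:
    """Levenshtein distances from ``key`` to every row of an encoded pool.

    ``pool`` is the output of :func:`encode_pool`. Returns an int array of
    shape ``(pool.shape[0],)``.
    """
    m = len(key)
    nrows, n = pool.shape
    if nrows == 0:
        return np.zeros(0, dtype=np.int64)
    a = np.frombuffer(key.encode("ascii"), dtype=np.uint8)
    prev = np.broadcast_to(np.arange(n + 1, dtype=np.int64), (nrows, n + 1)).copy()
    cur = np.empty_like(prev)
    for i in range(1, m + 1):
        cur[:, 0] = i
        mismatch = pool != a[i - 1]  # (nrows, n) booleans
        for j in range(1, n + 1):
            np.minimum(prev[:, j] + 1, prev[:, j - 1] + mismatch[:, j - 1],
                       out=cur[:, j])
            np.minimum(cur[:, j], cur[:, j - 1] + 1, out=cur[:, j])
        prev, cur = cur, prev
    return prev[:, n].copy()
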