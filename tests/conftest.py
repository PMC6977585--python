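import numpy as np
import pytest

from olcasm.readstore import SubRead
from olcasm.simulate import simulate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    return simulate_genome(20_000, seed=7)


def make_read(seq: str, rid: str = "r1", zmw: str | None = None) -> SubRead:
    return SubRead(rid, zmw or rid, 0, seq)


def edit_distance_dp(a: str, b: str) -> int:
    """Independent O(n*m) dynamic-programming edit distance (test oracle)."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        ai = a[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (ai != b[j - 1]))
        prev = cur
    return prev[m]


def edit_distance_dp_fast(a: str, b: str) -> int:
    """The same full DP recurrence evaluated along anti-diagonals with numpy
    (still independent of any alignment library)."""
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return max(n, m)
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)
    # D[k] holds the anti-diagonal i+j = k, indexed by i (0..n)
    big = n + m + 1
    prev2 = np.array([0], dtype=np.int64)            # diagonal k=0: D[0,0]
    prev1 = np.array([1, 1], dtype=np.int64)         # k=1: D[0,1], D[1,0]
    if n + m == 1:
        return 1
    for k in range(2, n + m + 1):
        i_lo = max(0, k - m)
        i_hi = min(n, k)
        i = np.arange(i_lo, i_hi + 1)
        cur = np.full(len(i), big, dtype=np.int64)
        # deletion from a: D[i-1, j] on prev1 (same i-1 index offset)
        p1_lo = max(0, (k - 1) - m)
        valid = i >= 1
        idx = i - 1 - p1_lo
        ok = valid & (idx >= 0) & (idx < len(prev1))
        cur[ok] = np.minimum(cur[ok], prev1[idx[ok]] + 1)
        # insertion: D[i, j-1] on prev1
        idx = i - p1_lo
        ok = (i <= k - 1) & (idx >= 0) & (idx < len(prev1)) & (k - 1 - i <= m)
        cur[ok] = np.minimum(cur[ok], prev1[idx[ok]] + 1)
        # match/mismatch: D[i-1, j-1] on prev2
        p2_lo = max(0, (k - 2) - m)
        j = k - i
        ok = (i >= 1) & (j >= 1)
        idx = i - 1 - p2_lo
        ok &= (idx >= 0) & (idx < len(prev2))
        sub = np.where(ok, (A[np.clip(i - 1, 0, n - 1)] !=
                            B[np.clip(j - 1, 0, m - 1)]).astype(np.int64), 0)
        cur[ok] = np.minimum(cur[ok], prev2[idx[ok]] + sub[ok])
        # boundary cells D[0, k] = k and D[k, 0] = k
        if i_lo == 0:
            cur[0] = k if k <= m else cur[0]
        if i_hi == k:
            cur[-1] = k
        prev2, prev1 = prev1, cur
    return int(prev1[-1])
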