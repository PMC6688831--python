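"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity from its definition by a different route
than the package (explicit pair loops, scipy distance matrices, per-cell
median arithmetic) so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist


def sampen_counts_bruteforce(x, m: int, r: float) -> tuple[int, int]:
    """Ordered (B, A) template-match counts from explicit distance matrices."""
    x = np.asarray(x, dtype=float)
    n = x.size
    nt = n - m  # templates that admit an (m+1)-length extension
    tm = sliding_window_view(x, m)[:nt]
    tm1 = sliding_window_view(x, m + 1)[:nt]
    dm = cdist(tm, tm, metric="chebyshev")
    dm1 = cdist(tm1, tm1, metric="chebyshev")
    off = ~np.eye(nt, dtype=bool)
    b = int(np.sum((dm <= r) & off))
    a = int(np.sum((dm1 <= r) & off))
    return b, a


def prsa_bruteforce(x) -> tuple[float, float, int, int]:
    """DC/AC by explicit anchor loops and segment accumulation."""
    x = np.asarray(x, dtype=float)
    n = x.size

    def one(direction: str) -> tuple[float, int]:
        segs = []
        for i in range(2, n - 1):
            if direction == "dec" and x[i] > x[i - 1]:
                segs.append([x[i - 2], x[i - 1], x[i], x[i + 1]])
            if direction == "acc" and x[i] < x[i - 1]:
                segs.append([x[i - 2], x[i - 1], x[i], x[i + 1]])
        if not segs:
            return float("nan"), 0
        mean = np.mean(segs, axis=0)
        return float((mean[2] + mean[3] - mean[1] - mean[0]) / 4.0), len(segs)

    dc, ndec = one("dec")
    ac, nacc = one("acc")
    return dc, ac, ndec, nacc


def hvg_edges_bruteforce(x) -> set[tuple[int, int]]:
    """All-pairs application of the horizontal visibility criterion."""
    x = np.asarray(x, dtype=float)
    n = x.size
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if all(x[k] < min(x[i], x[j]) for k in range(i + 1, j)):
                edges.add((i, j))
    return edges


# the six possible chord-indicator triples, lexicographic (independent copy)
_ORACLE_TRIPLES = [
    (False, False, False),
    (False, False, True),
    (False, True, False),
    (False, True, True),
    (True, False, False),
    (True, False, True),
]


def motif_counts_bruteforce(x) -> np.ndarray:
    """Classify every consecutive quadruple via a from-scratch 4-node HVG."""
    x = np.asarray(x, dtype=float)
    counts = np.zeros(6, dtype=int)
    for i in range(x.size - 3):
        quad = x[i : i + 4]
        edges = hvg_edges_bruteforce(quad)
        triple = ((0, 2) in edges, (1, 3) in edges, (0, 3) in edges)
        counts[_ORACLE_TRIPLES.index(triple)] += 1
    return counts


def mad_bruteforce(values) -> float:
    """Median absolute deviation from the median, by sorting."""
    v = sorted(float(x) for x in values)

    def med(s):
        k = len(s)
        return s[k // 2] if k % 2 else 0.5 * (s[k // 2 - 1] + s[k // 2])

    m = med(v)
    return med(sorted(abs(x - m) for x in v))


def sd_two_pass(values) -> float:
    """Sample standard deviation by the explicit two-pass formula."""
    v = [float(x) for x in values]
    mean = sum(v) / len(v)
    return math.sqrt(sum((x - mean) ** 2 for x in v) / (len(v) - 1))
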