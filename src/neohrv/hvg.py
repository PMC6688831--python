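"""Horizontal visibility graphs and 4-node sequential motif profiles.

Two samples i < j of the RR series are connected in the horizontal
visibility graph (HVG) iff every sample strictly between them is strictly
lower than both: ``x[k] < min(x[i], x[j])`` for all i < k < j.  Consecutive
samples are therefore always connected.

The 4-node sequential motif of a consecutive quadruple is the HVG of those
four values taken in isolation, summarized by the indicator triple
(edge(1,3), edge(2,4), edge(1,4)) in 1-based positions.  (For consecutive
quadruples this coincides with the induced subgraph of the full-series HVG,
since every sample between two quadruple members is itself a member.)

Exactly six of the eight triples are possible: edge(1,3) forces
x2 < x3 while edge(2,4) forces x3 < x2, so no quadruple realizes both short
chords, ruling out (T,T,F) and (T,T,T).  Of the six possible triples, five
occur for strict orderings of distinct values; the sixth, (F,F,T), needs
the tie x2 == x3 below both endpoints and so has zero frequency on
continuous data.  The canonical labels Z1..Z6 order the six possible
triples lexicographically (absent before present).  This labelling is the
package's own convention; it is not claimed to match any particular
published numbering of the motif shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .rr import RRSeries

__all__ = [
    "HVGraph",
    "MotifProfile4",
    "MOTIF_TRIPLES",
    "MOTIF_NAMES",
    "build_hvg",
    "motif_profile_4",
    "classify_quadruple",
]

#: The six possible (edge13, edge24, edge14) indicator triples, in
#: lexicographic order (False < True); index k corresponds to Z(k+1).
MOTIF_TRIPLES: tuple[tuple[bool, bool, bool], ...] = (
    (False, False, False),
    (False, False, True),
    (False, True, False),
    (False, True, True),
    (True, False, False),
    (True, False, True),
)

MOTIF_NAMES = tuple(f"z{k + 1}" for k in range(6))

_TRIPLE_TO_CLASS = {t: k for k, t in enumerate(MOTIF_TRIPLES)}


def _series_values(window) -> np.ndarray:
    if isinstance(window, RRSeries):
        return window.rr_ms
    return np.asarray(window, dtype=float)


@dataclass(frozen=True)
class HVGraph:
    """Horizontal visibility graph as an explicit edge set (i < j)."""

    n_nodes: int
    edges: frozenset[tuple[int, int]]

    def to_frame(self) -> pd.DataFrame:
        """Edge list as a two-column DataFrame (for CSV export)."""
        e = sorted(self.edges)
        return pd.DataFrame(e, columns=["i", "j"])


def build_hvg(window) -> HVGraph:
    """Construct the HVG of a series under the strict visibility criterion."""
    x = _series_values(window)
    n = x.size
    if n < 2:
        raise InsufficientDataError("build_hvg requires at least 2 samples")
    edges = set()
    for i in range(n - 1):
        edges.add((i, i + 1))
        run_max = x[i + 1]
        for j in range(i + 2, n):
            if run_max < x[i] and run_max < x[j]:
                edges.add((i, j))
            if x[j] >= x[i]:
                # nothing beyond j can see i over x[j]
                break
            run_max = max(run_max, x[j])
    return HVGraph(n_nodes=n, edges=frozenset(edges))


def classify_quadruple(x0: float, x1: float, x2: float, x3: float) -> int:
    """Motif class (0-5) of four consecutive values."""
    e13 = x1 < x0 and x1 < x2
    e24 = x2 < x1 and x2 < x3
    e14 = x1 < x0 and x1 < x3 and x2 < x0 and x2 < x3
    return _TRIPLE_TO_CLASS[(e13, e24, e14)]


@dataclass(frozen=True)
class MotifProfile4:
    """Frequencies and counts of the six 4-node sequential motifs."""

    z: np.ndarray  # six frequencies, summing to 1
    counts: np.ndarray  # six integer counts, summing to n - 3
    n_windows: int
    n_ties: int  # quadruples containing tied values (flagged, still counted)


def motif_profile_4(window) -> MotifProfile4:
    """Classify every consecutive 4-sample sub-window by its local HVG.

    The strict visibility criterion is applied as-is to tied values;
    quadruples containing ties are counted normally but flagged via
    ``n_ties`` (ties have measure zero for continuous data but are common
    in integer-quantized RR series).
    """
    x = _series_values(window)
    n = x.size
    if n < 4:
        raise InsufficientDataError("motif_profile_4 requires at least 4 beats")
    x0, x1, x2, x3 = x[:-3], x[1:-2], x[2:-1], x[3:]
    e13 = (x1 < x0) & (x1 < x2)
    e24 = (x2 < x1) & (x2 < x3)
    e14 = (x1 < x0) & (x1 < x3) & (x2 < x0) & (x2 < x3)
    # lexicographic code on the triple; codes 6 and 7 (both short chords)
    # are logically impossible
    code = 4 * e13.astype(int) + 2 * e24.astype(int) + e14.astype(int)
    counts_by_code = np.bincount(code, minlength=8)
    counts = counts_by_code[[0, 1, 2, 3, 4, 5]]
    ties = (
        (x0 == x1) | (x0 == x2) | (x0 == x3)
        | (x1 == x2) | (x1 == x3) | (x2 == x3)
    )
    total = counts.sum()
    z = counts / total if total else np.zeros(6)
    return MotifProfile4(
        z=z,
        counts=counts.astype(int),
        n_windows=int(n - 3),
        n_ties=int(ties.sum()),
    )
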