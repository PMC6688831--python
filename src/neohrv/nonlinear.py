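"""Non-linear HRV features: Poincaré geometry, sample entropy, DFA, PRSA.

SD1 follows the root-mean-square convention on successive differences,
``sd1 = sqrt(mean(diff^2)/2)``, which makes the identity ``sd1 = rmssd/√2``
exact (SD1 and rMSSD are mathematically identical short-term variability
metrics).  SD2 is the dispersion of lagged sums around their mean.

Sample entropy uses templates of length m with Chebyshev distance and a
tolerance expressed as a fraction of the window SD; DFA fits the log-log
slope of detrended fluctuations of the integrated series over 4-40 beats
(α1) and 40 beats to a quarter of the window (α2); phase-rectified signal
averaging yields deceleration and acceleration capacity through the
four-term slope estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .rr import RRSeries

__all__ = [
    "PoincareResult",
    "SampEnResult",
    "DFAResult",
    "PRSAResult",
    "poincare",
    "sample_entropy",
    "select_sampen_params",
    "dfa",
    "prsa",
]


def _values(window) -> np.ndarray:
    if isinstance(window, RRSeries):
        return window.rr_ms
    return np.asarray(window, dtype=float)


# ---------------------------------------------------------------------------
# Poincaré plot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoincareResult:
    sd1_ms: float
    sd2_ms: float
    ratio: float  # SD2/SD1; NaN for degenerate windows


def poincare(window) -> PoincareResult:
    """SD1, SD2 and SD2/SD1 of the lag-1 Poincaré plot."""
    x = _values(window)
    if x.size < 3:
        raise InsufficientDataError("poincare requires at least 3 beats")
    d = x[1:] - x[:-1]
    s = x[1:] + x[:-1]
    sd1 = math.sqrt(np.mean(d * d) / 2.0)
    sd2 = math.sqrt(np.var(s) / 2.0)
    ratio = sd2 / sd1 if sd1 > 0 else float("nan")
    return PoincareResult(sd1_ms=sd1, sd2_ms=sd2, ratio=ratio)


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampEnResult:
    m: int
    r_frac: float
    sampen: float  # NaN when either match count is zero
    matches_m: int  # ordered template pairs matching at length m   (B)
    matches_m1: int  # ordered template pairs matching at length m+1 (A)


def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Ordered pair counts (B at length m, A at length m+1), self-matches
    excluded, templates restricted to the N-m starting points that admit an
    (m+1)-length extension."""
    n = x.size
    nt = n - m
    if nt < 2:
        return 0, 0
    # Chebyshev distance built up coordinate by coordinate
    within = np.ones((nt, nt), dtype=bool)
    for k in range(m):
        xk = x[k : k + nt]
        within &= np.abs(xk[:, None] - xk[None, :]) <= r
    np.fill_diagonal(within, False)
    b = int(within.sum())
    xk = x[m : m + nt]
    within &= np.abs(xk[:, None] - xk[None, :]) <= r
    a = int(within.sum())
    return b, a


def sample_entropy(window, m: int = 3, r_frac: float = 0.25) -> SampEnResult:
    """Sample entropy: -ln(A/B) with tolerance ``r_frac`` × window SD.

    A and B are ordered template-pair counts (i ≠ j) at lengths m+1 and m
    under Chebyshev distance; both template sets use the same N-m starting
    points so that strictly periodic series give SampEn = 0 exactly.  When
    either count is zero the value is NaN (undefined), not an exception.
    """
    x = _values(window)
    if x.size < m + 2:
        raise InsufficientDataError(f"sample_entropy requires >= {m + 2} beats")
    sd = float(x.std())
    if sd <= 0:
        raise InsufficientDataError("sample_entropy requires a non-constant window")
    b, a = _match_counts(x, m, r_frac * sd)
    val = -math.log(a / b) if a > 0 and b > 0 else float("nan")
    return SampEnResult(m=m, r_frac=r_frac, sampen=val, matches_m=b, matches_m1=a)


def select_sampen_params(
    corpus: Iterable,
    m_grid: Sequence[int] = (2, 3, 4),
    r_grid: Sequence[float] = (0.1, 0.15, 0.2, 0.25, 0.3),
) -> tuple[int, float, float]:
    """Pick (m, r) minimizing the median relative error of the CP estimate.

    For each window the conditional probability CP = A/B is estimated from
    the match counts; its standard error is approximated binomially over the
    distinct (unordered) template pairs, giving a relative error
    ``sqrt(CP(1-CP)/(B/2)) / CP``.  The efficiency score of a parameter pair
    is the median of this relative error over the corpus; the minimizing
    (m, r) and its score are returned.  Windows with zero counts are skipped
    for that pair; a pair undefined on every window is dropped.
    """
    corpus = list(corpus)
    if not corpus or not m_grid or not r_grid:
        raise ParameterError("corpus and parameter grids must be non-empty")
    best: tuple[int, float, float] | None = None
    for m in m_grid:
        for r in r_grid:
            errs = []
            for w in corpus:
                try:
                    res = sample_entropy(w, m=m, r_frac=r)
                except InsufficientDataError:
                    continue
                if res.matches_m1 == 0 or res.matches_m == 0:
                    continue
                cp = res.matches_m1 / res.matches_m
                pairs = res.matches_m / 2.0
                se = math.sqrt(max(cp * (1.0 - cp), 0.0) / pairs)
                errs.append(se / cp)
            if errs:
                score = float(np.median(errs))
                if best is None or score < best[2]:
                    best = (m, r, score)
    if best is None:
        raise ParameterError("all (m, r) combinations were undefined on the corpus")
    return best


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DFAResult:
    alpha1: float  # NaN when not estimable
    alpha2: float  # NaN when the window is too short
    box_sizes: np.ndarray
    fluctuations: np.ndarray


def _box_sizes(lo: int, hi: int, n_sizes: int = 10) -> np.ndarray:
    if hi < lo:
        return np.array([], dtype=int)
    sizes = np.unique(
        np.round(np.geomspace(lo, hi, num=n_sizes)).astype(int)
    )
    return sizes[(sizes >= lo) & (sizes <= hi)]


def _fluctuation(y: np.ndarray, n: int) -> float:
    """RMS residual of per-box linear detrending of the integrated series."""
    nbox = y.size // n
    z = y[: nbox * n].reshape(nbox, n)
    t = np.arange(n, dtype=float)
    t_mean = t.mean()
    tc = t - t_mean
    denom = float(tc @ tc)
    zm = z.mean(axis=1, keepdims=True)
    slope = (z @ tc)[:, None] / denom
    resid = z - zm - slope * tc
    return math.sqrt(float(np.mean(resid * resid)))


def dfa(
    window,
    range1: tuple[int, int] = (4, 40),
    n_sizes: int = 10,
    finite_size_correction: bool = True,
) -> DFAResult:
    """Detrended fluctuation analysis of an RR window (or plain series).

    The mean-centred series is integrated, partitioned into non-overlapping
    boxes of log-spaced sizes, linearly detrended per box, and the RMS
    residual F(n) recorded.  α1 is the least-squares slope of log F vs log n
    over ``range1`` (default 4-40 beats, needing >= 80 beats and >= 3 sizes);
    α2 covers 40 beats to a quarter of the window length and is NaN when
    N/4 <= 44.

    First-order DFA is biased at small box sizes: for uncorrelated data the
    expected fluctuation is ``sigma * sqrt(n/15) * sqrt(1 - 4/n**2)``, so
    the raw slope over boxes of 4-40 samples overshoots 0.5 by about 0.05.
    By default each F(n) is divided by ``sqrt(1 - 4/n**2)``, the exact
    finite-size factor for uncorrelated data (a first-order correction for
    correlated signals), which restores the textbook calibration values
    (0.5 white noise, ~1 for 1/f, ~1.5 Brownian) at these small scales.
    """
    x = _values(window)
    N = x.size
    y = np.cumsum(x - x.mean())
    sizes1 = _box_sizes(range1[0], min(range1[1], N // 2), n_sizes) if N >= 80 else np.array([], int)
    hi2 = N // 4
    sizes2 = _box_sizes(range1[1], hi2, n_sizes) if hi2 > int(range1[1] * 1.1) else np.array([], int)
    all_sizes = np.unique(np.concatenate([sizes1, sizes2])).astype(int)
    fl = np.array([_fluctuation(y, int(n)) for n in all_sizes])
    if finite_size_correction and all_sizes.size:
        fl = fl / np.sqrt(1.0 - 4.0 / all_sizes.astype(float) ** 2)

    def _slope(sizes: np.ndarray) -> float:
        if sizes.size < 3:
            return float("nan")
        f = fl[np.searchsorted(all_sizes, sizes)]
        if np.any(f <= 0):
            return float("nan")
        return float(np.polyfit(np.log(sizes), np.log(f), 1)[0])

    return DFAResult(
        alpha1=_slope(sizes1),
        alpha2=_slope(sizes2),
        box_sizes=all_sizes,
        fluctuations=fl,
    )


# ---------------------------------------------------------------------------
# Phase-rectified signal averaging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRSAResult:
    dc_ms: float  # NaN when no deceleration anchors
    ac_ms: float  # NaN when no acceleration anchors
    n_dec_anchors: int
    n_acc_anchors: int


def prsa(window) -> PRSAResult:
    """Deceleration/acceleration capacity via phase-rectified averaging.

    Anchors are interior beats strictly longer (DC) or strictly shorter
    (AC) than their predecessor (ties anchor neither); segments of the four
    beats at offsets -2..+1 around each anchor are averaged and the
    four-term slope ``(X(0) + X(1) - X(-1) - X(-2)) / 4`` is the capacity.
    """
    x = _values(window)
    if x.size < 5:
        raise InsufficientDataError("prsa requires at least 5 beats")

    def _capacity(anchors: np.ndarray) -> float:
        if anchors.size == 0:
            return float("nan")
        seg = np.array(
            [x[anchors - 2], x[anchors - 1], x[anchors], x[anchors + 1]]
        ).mean(axis=1)
        return float((seg[2] + seg[3] - seg[1] - seg[0]) / 4.0)

    i = np.arange(2, x.size - 1)
    dec = i[x[i] > x[i - 1]]
    acc = i[x[i] < x[i - 1]]
    return PRSAResult(
        dc_ms=_capacity(dec),
        ac_ms=_capacity(acc),
        n_dec_anchors=int(dec.size),
        n_acc_anchors=int(acc.size),
    )
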