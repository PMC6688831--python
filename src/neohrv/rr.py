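"""RR-interval series: data model, CSV I/O, quality screening, windowing.

The atomic object is :class:`RRSeries` — one recording's beat onset times
(seconds) and RR intervals (milliseconds) with subject metadata (gestational
age at birth, post-menstrual age at recording).  Analysis windows of the four
canonical length classes (US = 2 min, S5 = 5 min, S10 = 10 min, L = 15 min)
are extracted consecutively with 50 % overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ParseError, QualityError, ValidationError

__all__ = [
    "RRSeries",
    "WindowSpec",
    "WINDOW_SPECS",
    "LENGTH_CLASSES",
    "PMA_CLASSES",
    "pma_class",
    "read_rr_series",
    "write_rr_series",
    "screen_rr",
    "ScreeningReport",
    "extract_windows",
]

#: Canonical window-length classes, shortest to longest.
LENGTH_CLASSES = ("US", "S5", "S10", "L")

#: Post-menstrual age classes (weeks); lower edges are closed.
PMA_CLASSES = ("<28", "28-32", "32-36", ">=36")

_ONSET_TOL_S = 1e-9


def pma_class(pma_weeks: float) -> str:
    """Categorize a post-menstrual age (weeks) into the four study classes."""
    if pma_weeks < 28:
        return "<28"
    if pma_weeks < 32:
        return "28-32"
    if pma_weeks < 36:
        return "32-36"
    return ">=36"


@dataclass(frozen=True)
class RRSeries:
    """One recording (or one analysis window) of RR intervals.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    ga_weeks : float
        Completed gestational age at birth, weeks.
    pma_weeks : float
        Post-menstrual age at recording, weeks; must be >= ``ga_weeks``.
    onset_s : ndarray
        Strictly increasing cumulative beat-onset times, seconds.  The first
        onset is an arbitrary anchor (0 for series built from RR values
        alone); successive differences must equal ``rr_ms[1:] / 1000``.
    rr_ms : ndarray
        Positive RR intervals, milliseconds, same length as ``onset_s``.
    length_class : str or None
        Window-length class (``US``/``S5``/``S10``/``L``) when this series is
        an extracted window.
    window_index : int or None
        Index of the window within its parent recording.
    """

    subject_id: str
    ga_weeks: float
    pma_weeks: float
    onset_s: np.ndarray
    rr_ms: np.ndarray
    length_class: str | None = None
    window_index: int | None = None

    def __post_init__(self) -> None:
        onset = np.asarray(self.onset_s, dtype=float)
        rr = np.asarray(self.rr_ms, dtype=float)
        object.__setattr__(self, "onset_s", onset)
        object.__setattr__(self, "rr_ms", rr)
        if onset.ndim != 1 or rr.ndim != 1 or onset.size != rr.size:
            raise ValidationError("onset_s and rr_ms must be 1-d and equal length")
        if rr.size:
            bad = np.flatnonzero(rr <= 0)
            if bad.size:
                raise ValidationError(f"non-positive RR interval at index {bad[0]}")
            d = np.diff(onset)
            bad = np.flatnonzero(d <= 0)
            if bad.size:
                raise ValidationError(
                    f"onset_s not strictly increasing at index {bad[0] + 1}"
                )
            mism = np.flatnonzero(np.abs(d - rr[1:] / 1000.0) > _ONSET_TOL_S)
            if mism.size:
                raise ValidationError(
                    "onset differences disagree with rr_ms/1000 at index "
                    f"{mism[0] + 1}"
                )
        if self.pma_weeks < self.ga_weeks:
            raise ValidationError("pma_weeks must be >= ga_weeks")

    @property
    def n_beats(self) -> int:
        return int(self.rr_ms.size)

    @property
    def duration_s(self) -> float:
        """Time span covered by the recording, including the final interval."""
        if self.rr_ms.size == 0:
            return 0.0
        return float(self.onset_s[-1] - self.onset_s[0] + self.rr_ms[-1] / 1000.0)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_beats


@dataclass(frozen=True)
class WindowSpec:
    """Length class, window length in seconds, and fractional overlap."""

    length_class: str
    length_s: float
    overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.length_class not in LENGTH_CLASSES:
            raise ValidationError(f"unknown length class {self.length_class!r}")
        if self.length_s not in (120.0, 300.0, 600.0, 900.0):
            raise ValidationError("length_s must be one of 120, 300, 600, 900")
        if not 0 <= self.overlap_frac < 1:
            raise ValidationError("overlap_frac must lie in [0, 1)")

    @property
    def step_s(self) -> float:
        return self.length_s * (1.0 - self.overlap_frac)


#: The study's four window specifications (50 % overlap throughout).
WINDOW_SPECS = {
    "US": WindowSpec("US", 120.0),
    "S5": WindowSpec("S5", 300.0),
    "S10": WindowSpec("S10", 600.0),
    "L": WindowSpec("L", 900.0),
}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_rr_series(
    path,
    subject_id: str = "",
    ga_weeks: float = 0.0,
    pma_weeks: float = 0.0,
) -> RRSeries:
    """Read an RR recording from CSV.

    Accepts either the two-column dialect ``onset_s,rr_ms`` or a single
    column of RR intervals (ms), in which case onsets are reconstructed by
    cumulative summation anchored at 0 s.
    """
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ParseError(f"{path}: {exc}") from exc
    cols = [c.strip() for c in df.columns]
    df.columns = cols

    def _numeric(col: pd.Series, name: str) -> np.ndarray:
        vals = pd.to_numeric(col, errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            # +2: one for the header line, one for 1-based numbering
            raise ParseError(
                f"{path}: malformed value in column {name!r} at line {bad[0] + 2}"
            )
        return vals.to_numpy(dtype=float)

    if {"onset_s", "rr_ms"} <= set(cols):
        onset = _numeric(df["onset_s"], "onset_s")
        rr = _numeric(df["rr_ms"], "rr_ms")
    elif len(cols) == 1:
        rr = _numeric(df[cols[0]], cols[0])
        onset = np.concatenate([[0.0], np.cumsum(rr[1:]) / 1000.0]) if rr.size else rr
    else:
        raise ParseError(
            f"{path}: expected columns 'onset_s,rr_ms' or a single RR column, "
            f"got {cols}"
        )
    return RRSeries(subject_id, ga_weeks, pma_weeks, onset, rr)


def write_rr_series(series: RRSeries, path) -> None:
    """Write a recording as two-column CSV (full double precision)."""
    df = pd.DataFrame({"onset_s": series.onset_s, "rr_ms": series.rr_ms})
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of the automated beat screen."""

    flagged_indices: np.ndarray
    n_beats: int

    @property
    def n_flagged(self) -> int:
        return int(np.asarray(self.flagged_indices).size)

    @property
    def fraction_flagged(self) -> float:
        return self.n_flagged / self.n_beats if self.n_beats else 0.0


def screen_rr(
    series: RRSeries,
    low_ms: float = 200.0,
    high_ms: float = 750.0,
    max_rel_jump: float = 0.5,
    max_bad_frac: float = 0.2,
) -> tuple[RRSeries, ScreeningReport]:
    """Automated surrogate for manual RR verification.

    Beats outside ``[low_ms, high_ms]`` or whose relative change from the
    preceding beat exceeds ``max_rel_jump`` are flagged and replaced by linear
    interpolation of the nearest unflagged neighbours; onsets are rebuilt by
    cumulative summation from the original first onset.  The default limits
    (200-750 ms, 50 % jump) bracket neonatal heart rates of 80-300 bpm.

    Raises
    ------
    QualityError
        If more than ``max_bad_frac`` of the beats are flagged.
    """
    if not low_ms < high_ms:
        raise ValidationError("low_ms must be < high_ms")
    if max_rel_jump <= 0:
        raise ValidationError("max_rel_jump must be positive")
    rr = series.rr_ms.copy()
    n = rr.size
    flags = (rr < low_ms) | (rr > high_ms)
    if n > 1:
        jump = np.abs(np.diff(rr)) / rr[:-1]
        flags[1:] |= jump > max_rel_jump
    idx = np.flatnonzero(flags)
    report = ScreeningReport(flagged_indices=idx, n_beats=n)
    if report.fraction_flagged > max_bad_frac:
        raise QualityError(
            f"{report.n_flagged}/{n} beats flagged "
            f"({100 * report.fraction_flagged:.1f} % > "
            f"{100 * max_bad_frac:.0f} % allowed)"
        )
    if idx.size == 0:
        return series, report
    good = np.flatnonzero(~flags)
    if good.size == 0:  # pragma: no cover - excluded by max_bad_frac <= 1
        raise QualityError("no valid beats after screening")
    rr[idx] = np.interp(idx.astype(float), good.astype(float), rr[good])
    onset = np.empty(n)
    onset[0] = series.onset_s[0]
    onset[1:] = onset[0] + np.cumsum(rr[1:]) / 1000.0
    cleaned = replace(series, onset_s=onset, rr_ms=rr)
    return cleaned, report


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def extract_windows(series: RRSeries, spec: WindowSpec) -> list[RRSeries]:
    """Extract consecutive overlapping windows of one length class.

    Window k covers the half-open interval ``[k*step, k*step + length_s)``
    of recording time (relative to the first onset); a beat belongs to a
    window iff its onset lies inside that interval.  Returns an empty list
    with a warning when the recording is shorter than the window length.
    """
    dur = series.duration_s
    if dur + _ONSET_TOL_S < spec.length_s:
        warnings.warn(
            f"recording of {dur:.1f} s shorter than {spec.length_class} window "
            f"({spec.length_s:.0f} s); no windows extracted",
            stacklevel=2,
        )
        return []
    rel = series.onset_s - series.onset_s[0]
    windows = []
    k = 0
    while k * spec.step_s + spec.length_s <= dur + _ONSET_TOL_S:
        t0 = k * spec.step_s
        sel = (rel >= t0 - _ONSET_TOL_S) & (rel < t0 + spec.length_s - _ONSET_TOL_S)
        i = np.flatnonzero(sel)
        windows.append(
            replace(
                series,
                onset_s=series.onset_s[i] - series.onset_s[0] - t0,
                rr_ms=series.rr_ms[i],
                length_class=spec.length_class,
                window_index=k,
            )
        )
        k += 1
    return windows
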