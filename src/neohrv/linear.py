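"""Time-domain statistics and autoregressive spectral band powers.

The tachogram is resampled to a uniform 4 Hz grid by cubic-spline
interpolation, an AR(12) model is fitted to the mean-removed series (Burg
method by default), and band powers are obtained by trapezoidal integration
of the one-sided power spectral density over the neonatal LF (0.02-0.2 Hz)
and HF (0.2-2 Hz) bands.  The PSD is normalized so that its integral over
(0, fs/2] equals the series variance; very low frequencies (< 0.02 Hz) are
excluded from the reported powers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from statsmodels.regression.linear_model import burg, yule_walker

from .errors import InsufficientDataError, ParameterError, ValidationError
from .rr import RRSeries

__all__ = [
    "TimeDomainResult",
    "SpectralResult",
    "UniformSeries",
    "time_domain",
    "resample_tachogram",
    "ar_band_powers",
    "LF_BAND",
    "HF_BAND",
]

#: Neonatal spectral bands, Hz.
LF_BAND = (0.02, 0.2)
HF_BAND = (0.2, 2.0)


@dataclass(frozen=True)
class TimeDomainResult:
    mean_ms: float
    sd_ms: float
    rmssd_ms: float


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly resampled tachogram (values in ms at 1/fs_hz spacing)."""

    values: np.ndarray
    fs_hz: float


@dataclass(frozen=True)
class SpectralResult:
    freq_hz: np.ndarray
    psd: np.ndarray
    lf_ms2: float
    hf_ms2: float
    lf_hf: float  # NaN when hf_ms2 == 0


def time_domain(window: RRSeries) -> TimeDomainResult:
    """Mean, SD (sample, divisor n-1) and rMSSD of the RR intervals."""
    rr = window.rr_ms
    if rr.size < 2:
        raise InsufficientDataError("time_domain requires at least 2 beats")
    d = np.diff(rr)
    return TimeDomainResult(
        mean_ms=float(rr.mean()),
        sd_ms=float(rr.std(ddof=1)),
        rmssd_ms=float(np.sqrt(np.mean(d * d))),
    )


def resample_tachogram(window: RRSeries, fs_hz: float = 4.0) -> UniformSeries:
    """Cubic-spline resampling of RR against onset time onto a uniform grid.

    The grid runs from the window's time origin (the first onset, taken as
    t = 0) to the last onset in steps of 1/fs; the output has
    ``floor(span*fs) + 1`` samples.
    """
    rr = window.rr_ms
    t = window.onset_s - window.onset_s[0]
    if rr.size < 4 or t[-1] < 1.0:
        raise InsufficientDataError(
            "resampling requires >= 4 beats spanning >= 1 s"
        )
    if np.any(np.diff(t) <= 0):
        raise ValidationError("duplicate or non-increasing onsets")
    n_out = int(np.floor(t[-1] * fs_hz)) + 1
    grid = np.arange(n_out) / fs_hz
    values = CubicSpline(t, rr)(grid)
    return UniformSeries(values=values, fs_hz=fs_hz)


def _ar_denominator(rho: np.ndarray, freq: np.ndarray, fs: float) -> np.ndarray:
    k = np.arange(1, rho.size + 1)
    z = np.exp(-2j * np.pi * np.outer(freq, k) / fs)
    return np.abs(1.0 - z @ rho) ** 2


def ar_band_powers(
    uniform: UniformSeries,
    order: int = 12,
    lf: tuple[float, float] = LF_BAND,
    hf: tuple[float, float] = HF_BAND,
    method: str = "burg",
    n_freq: int = 4096,
) -> SpectralResult:
    """AR power spectrum of the resampled tachogram and its band powers.

    The AR(order) coefficients are estimated from the mean-removed series
    (``method`` is ``"burg"`` or ``"yule_walker"``).  The one-sided PSD is
    evaluated on a dense grid up to fs/2 and rescaled so its integral equals
    the series variance (population divisor); band powers are trapezoidal
    integrals over the LF and HF bands in ms^2.
    """
    x = np.asarray(uniform.values, dtype=float)
    fs = uniform.fs_hz
    if x.size <= 3 * order:
        raise InsufficientDataError(
            f"AR({order}) fit requires more than {3 * order} samples"
        )
    x = x - x.mean()
    var = float(np.var(x))
    freq = np.linspace(0.0, fs / 2.0, n_freq + 1)[1:]
    if var <= 0:
        psd = np.zeros_like(freq)
        return SpectralResult(freq, psd, 0.0, 0.0, float("nan"))
    if method == "burg":
        rho, _ = burg(x, order=order, demean=False)
    elif method == "yule_walker":
        rho, _ = yule_walker(x, order=order, method="mle", demean=False)
    else:
        raise ParameterError(f"unknown AR method {method!r}")
    denom = _ar_denominator(np.asarray(rho), freq, fs)
    if not np.all(np.isfinite(denom)) or np.any(denom <= 0):
        raise ArithmeticError("unstable AR fit: PSD denominator not positive")
    psd = 1.0 / denom
    total = np.trapezoid(psd, freq)
    if not np.isfinite(total) or total <= 0:
        raise ArithmeticError("unstable AR fit: non-integrable PSD")
    psd *= var / total

    def _band(lo: float, hi: float) -> float:
        m = (freq >= lo) & (freq <= hi)
        return float(np.trapezoid(psd[m], freq[m]))

    lf_ms2 = _band(*lf)
    hf_ms2 = _band(*hf)
    lf_hf = lf_ms2 / hf_ms2 if hf_ms2 > 0 else float("nan")
    return SpectralResult(freq, psd, lf_ms2, hf_ms2, lf_hf)
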