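"""Synthetic preterm RR-series cohort with known ground truth.

The clinical recordings the analysis was designed for (weekly 15-minute
quiet-sleep recordings in infants born at 25-31 weeks gestation, followed to
41 weeks post-menstrual age) are not publicly available, so the package
ships a generative stand-in.  An additive beat-domain model produces each
recording:

    rr[i] = mu + a_lf*sin(2*pi*f_lf*t_i) + a_hf*sin(2*pi*f_hf*t_i)
            + sigma_pink*p_i + sigma_white*eps_i

with ``t_i`` the cumulative onset time, ``p`` a unit-SD 1/f (pink) noise
series generated once per recording at the beat count, and ``eps`` white
Gaussian jitter.  The LF (0.02-0.2 Hz) and HF (0.2-2 Hz) sinusoids give the
spectral features known band-power targets (a^2/2); the pink component
drives the DFA scaling exponent; maturation enters through linear growth of
``a_hf`` and ``mu`` with post-menstrual age plus Gaussian subject-level
intercepts.  This is a deliberate non-physiological simplification: it gives
every feature family a known target without modelling the autonomic control
loops that create real neonatal heart-rate variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .rr import RRSeries

__all__ = [
    "RRModelParams",
    "CohortParams",
    "GA_DISTRIBUTION",
    "gen_white_noise",
    "gen_power_law_noise",
    "gen_rr_series",
    "gen_cohort",
]

#: Gestational-age distribution of the study cohort (GA week -> count,
#: 39 infants in total).
GA_DISTRIBUTION: dict[int, int] = {25: 2, 26: 1, 27: 5, 28: 16, 29: 7, 30: 4, 31: 4}

_MIN_RR_MS = 150.0


@dataclass(frozen=True)
class RRModelParams:
    """Parameters of the additive beat-domain RR model.

    Defaults describe a typical preterm infant in quiet sleep around 30
    weeks post-menstrual age: mean RR 400 ms (150 bpm), an LF oscillation of
    15 ms at 0.05 Hz, an HF oscillation of 8 ms at 0.6 Hz, 10 ms of 1/f
    background and 5 ms of white jitter.
    """

    mu_ms: float = 400.0
    a_lf: float = 15.0
    f_lf: float = 0.05
    a_hf: float = 8.0
    f_hf: float = 0.6
    sigma_pink: float = 10.0
    sigma_white: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.02 < self.f_lf < 0.2:
            raise ParameterError("f_lf must lie in the LF band (0.02, 0.2) Hz")
        if not 0.2 < self.f_hf < 2.0:
            raise ParameterError("f_hf must lie in the HF band (0.2, 2) Hz")
        for name in ("a_lf", "a_hf", "sigma_pink", "sigma_white"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        margin = self.mu_ms - (
            self.a_lf + self.a_hf + 4.0 * (self.sigma_pink + self.sigma_white)
        )
        if margin <= _MIN_RR_MS:
            raise ParameterError(
                "amplitudes too large for mu_ms: RR would not stay above "
                f"{_MIN_RR_MS:.0f} ms (margin {margin:.1f} ms)"
            )


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level design: who is born when, and how they mature.

    ``maturation_slope_hf`` and ``maturation_slope_mu`` are ms of HF
    amplitude / mean RR gained per week of post-menstrual age (both relative
    to a 30-week reference); ``subject_sd_frac`` scales the Gaussian
    subject-level random intercept on mean RR (default 5 % of mu).
    """

    n_subjects: int = 39
    ga_distribution: Mapping[int, int] = field(
        default_factory=lambda: dict(GA_DISTRIBUTION)
    )
    max_pma_weeks: float = 41.0
    dropout_hazard: float = 0.05
    maturation_slope_hf: float = 0.6
    maturation_slope_mu: float = 1.5
    subject_sd_frac: float = 0.05
    recording_duration_s: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ga_distribution:
            raise ParameterError("ga_distribution must not be empty")
        if sum(self.ga_distribution.values()) != self.n_subjects:
            raise ParameterError("ga_distribution counts must sum to n_subjects")
        bad = [g for g in self.ga_distribution if not 25 <= g <= 31]
        if bad:
            raise ParameterError(f"GA keys must lie within 25-31 weeks, got {bad}")
        if not 0 <= self.dropout_hazard < 1:
            raise ParameterError("dropout_hazard must lie in [0, 1)")


def gen_white_noise(n: int, seed: int) -> np.ndarray:
    """i.i.d. standard Gaussian draws, reproducible given the seed."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    return np.random.default_rng(seed).standard_normal(n)


def gen_power_law_noise(n: int, beta: float, seed: int) -> np.ndarray:
    """Zero-mean noise with power spectrum proportional to 1/f**beta.

    Spectral synthesis: the Fourier amplitudes of a white-noise series are
    scaled by f**(-beta/2) and transformed back.  beta = 0 reduces to white
    noise; beta = 1 is 1/f (pink) noise; beta = 2 is statistically
    equivalent to cumulated white noise (Brownian motion increments-wise).
    """
    if n < 16:
        raise ParameterError("n must be >= 16")
    if not 0 <= beta <= 2:
        raise ParameterError("beta must lie in [0, 2]")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freq = np.fft.rfftfreq(n)
    scale = np.ones_like(freq)
    scale[1:] = freq[1:] ** (-beta / 2.0)
    spec = spec * scale
    spec[0] = 0.0  # zero mean
    return np.fft.irfft(spec, n=n)


def gen_rr_series(
    params: RRModelParams,
    duration_s: float,
    subject_id: str = "sim",
    ga_weeks: float = 28.0,
    pma_weeks: float = 30.0,
) -> tuple[RRSeries, dict]:
    """Generate one recording plus its ground-truth record.

    Beats are laid down sequentially: the RR interval for the beat at
    cumulative time ``t`` is evaluated from the model at ``t``, then the
    clock advances by that interval; generation stops when the next onset
    would reach ``duration_s``.  The ground-truth dict stores the parameters
    and the realized variance of every model component.
    """
    if duration_s < 120:
        raise ParameterError("duration_s must be >= 120 s")
    # upper bound on beat count: shortest plausible RR
    rr_floor = max(
        _MIN_RR_MS,
        params.mu_ms
        - params.a_lf
        - params.a_hf
        - 4.0 * (params.sigma_pink + params.sigma_white),
    )
    n_max = int(np.ceil(duration_s * 1000.0 / rr_floor)) + 16
    base_seed = params.seed % (2**31)
    ok = False
    for attempt in range(10):
        rng = np.random.default_rng(base_seed + attempt * 1_000_003)
        pink = gen_power_law_noise(n_max, 1.0, int(rng.integers(2**31)))
        pink = pink / pink.std()
        white = rng.standard_normal(n_max)
        rr = np.empty(n_max)
        onset = np.empty(n_max)

        def _model(t: float, i: int) -> float:
            return (
                params.mu_ms
                + params.a_lf * np.sin(2 * np.pi * params.f_lf * t)
                + params.a_hf * np.sin(2 * np.pi * params.f_hf * t)
                + params.sigma_pink * pink[i]
                + params.sigma_white * white[i]
            )

        ok = True
        rr[0], onset[0] = _model(0.0, 0), 0.0
        if rr[0] <= _MIN_RR_MS:
            ok = False
            continue
        t = 0.0
        i = 1
        while True:
            val = _model(t, i)
            if val <= _MIN_RR_MS:
                ok = False
                break
            nxt = t + val / 1000.0
            if nxt >= duration_s:
                break
            rr[i], onset[i] = val, nxt
            t = nxt
            i += 1
        if ok:
            break
    if not ok:
        raise ParameterError(
            "could not keep RR above the physiological floor after 10 attempts"
        )
    rr, onset = rr[:i], onset[:i]
    series = RRSeries(subject_id, ga_weeks, pma_weeks, onset, rr)
    truth = {
        "subject_id": subject_id,
        "ga_weeks": ga_weeks,
        "pma_weeks": pma_weeks,
        "mu_ms": params.mu_ms,
        "a_lf": params.a_lf,
        "f_lf": params.f_lf,
        "a_hf": params.a_hf,
        "f_hf": params.f_hf,
        "sigma_pink": params.sigma_pink,
        "sigma_white": params.sigma_white,
        "seed": params.seed,
        "n_beats": i,
        "var_pink": float(np.var(params.sigma_pink * pink[:i])) if i else 0.0,
        "var_white": float(np.var(params.sigma_white * white[:i])) if i else 0.0,
    }
    return series, truth


def gen_cohort(
    cparams: CohortParams, base: RRModelParams | None = None
) -> tuple[pd.DataFrame, dict[str, RRSeries], pd.DataFrame]:
    """Generate the full cohort.

    One subject per draw from ``ga_distribution``; each subject is recorded
    weekly from birth (PMA = GA) until ``max_pma_weeks`` or dropout
    (geometric with the weekly hazard).  Per-recording parameters derive
    from ``base`` with ``a_hf`` and ``mu_ms`` increasing linearly in PMA
    around a 30-week reference, plus a subject-level Gaussian intercept on
    mean RR.

    Returns
    -------
    manifest : DataFrame
        Columns ``subject_id, ga_weeks, recording_week, pma_weeks,
        recording_id``.
    series : dict
        ``recording_id -> RRSeries``.
    truth : DataFrame
        Ground-truth parameters of every recording (one row each), plus the
        subject intercept.
    """
    base = base if base is not None else RRModelParams()
    rng = np.random.default_rng(cparams.seed % (2**31))
    manifest_rows = []
    truth_rows = []
    series: dict[str, RRSeries] = {}
    sid = 0
    for ga in sorted(cparams.ga_distribution):
        for _ in range(cparams.ga_distribution[ga]):
            sid += 1
            subject = f"P{sid:03d}"
            intercept = rng.normal(0.0, cparams.subject_sd_frac * base.mu_ms)
            week = 0
            while True:
                pma = ga + week
                if pma > cparams.max_pma_weeks:
                    break
                if week > 0 and rng.random() < cparams.dropout_hazard:
                    break
                p = replace(
                    base,
                    mu_ms=base.mu_ms
                    + intercept
                    + cparams.maturation_slope_mu * (pma - 30.0),
                    a_hf=max(
                        0.0, base.a_hf + cparams.maturation_slope_hf * (pma - 30.0)
                    ),
                    seed=int(rng.integers(2**31)),
                )
                rec_id = f"{subject}_w{pma:02.0f}"
                rec, truth = gen_rr_series(
                    p,
                    cparams.recording_duration_s,
                    subject_id=subject,
                    ga_weeks=float(ga),
                    pma_weeks=float(pma),
                )
                series[rec_id] = rec
                manifest_rows.append(
                    {
                        "subject_id": subject,
                        "ga_weeks": float(ga),
                        "recording_week": week,
                        "pma_weeks": float(pma),
                        "recording_id": rec_id,
                    }
                )
                truth["recording_id"] = rec_id
                truth["subject_intercept_ms"] = intercept
                truth_rows.append(truth)
                week += 1
    manifest = pd.DataFrame(manifest_rows)
    truth_df = pd.DataFrame(truth_rows)
    return manifest, series, truth_df
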