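import numpy as np
import pandas as pd
import pytest

from neohrv.rr import RRSeries, pma_class


def make_window(rr_ms, subject="S", ga=28.0, pma=30.0) -> RRSeries:
    """RRSeries from RR values alone (onsets by cumulative sum from 0)."""
    rr = np.asarray(rr_ms, dtype=float)
    onset = np.concatenate([[0.0], np.cumsum(rr[1:]) / 1000.0])
    return RRSeries(subject, ga, pma, onset, rr)


def random_window(rng: np.random.Generator, n: int, sd: float = 20.0) -> RRSeries:
    """A physiological-looking random window (mean 400 ms, i.i.d. jitter)."""
    rr = 400.0 + sd * rng.standard_normal(n)
    rr = np.clip(rr, 200.0, 700.0)
    return make_window(rr)


def make_feature_table(
    seed: int,
    n_subjects: int = 50,
    n_recordings: int = 4,
    value: float = 20.0,
    subject_sd: float = 1.0,
    recording_sd: float = 0.5,
    window_sd: float = 1.0,
    us_mult: float = 1.0,
    us_shift: float = 0.0,
    feature: str = "f",
) -> pd.DataFrame:
    """Synthetic long-format feature table with a known US distortion.

    One Gaussian 'true' value per recording (subject intercept + recording
    noise), window replicates per length class (14/5/2/1) with i.i.d.
    window noise; US values optionally distorted multiplicatively and/or
    additively.
    """
    rng = np.random.default_rng(seed)
    n_windows = {"US": 14, "S5": 5, "S10": 2, "L": 1}
    rows = []
    for s in range(n_subjects):
        ga = float(rng.integers(25, 32))
        b_s = rng.normal(0.0, subject_sd)
        for w in range(n_recordings):
            pma = ga + float(rng.integers(0, 14))
            true = value + b_s + rng.normal(0.0, recording_sd)
            rec_id = f"P{s:03d}_r{w}"
            for lc, k in n_windows.items():
                for j in range(k):
                    v = true + rng.normal(0.0, window_sd)
                    if lc == "US":
                        v = v * us_mult + us_shift
                    rows.append(
                        {
                            "subject_id": f"P{s:03d}",
                            "ga_weeks": ga,
                            "pma_weeks": pma,
                            "pma_class": pma_class(pma),
                            "recording_id": rec_id,
                            "length_class": lc,
                            "window_index": j,
                            "feature": feature,
                            "value": v,
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
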