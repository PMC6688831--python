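"""Window-length robustness statistics on the long-format feature table.

The feature table holds one row per (recording, length class, window index,
feature).  This module quantifies how window length degrades measurement:

* pooled median-absolute-deviation profiles per (feature, length class, PMA
  class) as a proxy for random measurement error;
* Shapiro-Wilk / quartile summaries and Box-Cox transformation for skewed
  features;
* linear mixed-effects models of feature value on length class (reference =
  the full 15-min window), PMA class and gestational age with a subject
  random intercept, length effects tested by likelihood-ratio;
* mixed-effects percentage bias and limits of agreement of each length
  class against a per-recording reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "FEATURE_TABLE_COLUMNS",
    "validate_feature_table",
    "summarize_distribution",
    "mad_profile",
    "boxcox_transform",
    "LMEResult",
    "lme_length_effect",
    "bias_loa",
    "significance_stars",
]

FEATURE_TABLE_COLUMNS = (
    "subject_id",
    "ga_weeks",
    "pma_weeks",
    "pma_class",
    "recording_id",
    "length_class",
    "window_index",
    "feature",
    "value",
)


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format feature table's structural invariants."""
    missing = set(FEATURE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"feature table lacks columns {sorted(missing)}")
    key = ["recording_id", "length_class", "window_index", "feature"]
    if table.duplicated(subset=key).any():
        raise ValidationError("duplicate (recording, length, window, feature) rows")
    return table


def summarize_distribution(values) -> tuple[float, float, float, float, float]:
    """Median, quartiles (linear interpolation) and the Shapiro-Wilk test.

    Returns ``(median, q1, q3, shapiro_W, shapiro_p)``.  The Shapiro-Wilk
    statistic is computed on at most 5000 values (the test's validity
    range); larger samples are subsampled deterministically.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise InsufficientDataError("summarize_distribution requires >= 3 values")
    med, q1, q3 = (float(np.quantile(v, q)) for q in (0.5, 0.25, 0.75))
    sample = v
    if v.size > 5000:
        sample = np.sort(v)[np.linspace(0, v.size - 1, 5000).astype(int)]
    w, p = stats.shapiro(sample)
    return med, q1, q3, float(w), float(p)


def mad_profile(table: pd.DataFrame, features=None) -> pd.DataFrame:
    """Median absolute deviation from the median, per pooled cell.

    For every (feature, length_class, pma_class) cell all window
    realizations across recordings and subjects are pooled;
    ``MAD = median(|X - median(X)|)`` over the pooled values.  Empty cells
    are omitted (a warning lists the features affected).
    """
    validate_feature_table(table)
    df = table if features is None else table[table["feature"].isin(features)]
    rows = []
    dropped = set()
    for (feat, lc, pc), grp in df.groupby(
        ["feature", "length_class", "pma_class"], observed=True, sort=False
    ):
        v = grp["value"].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            dropped.add((feat, lc, pc))
            continue
        med = np.median(v)
        rows.append(
            {
                "feature": feat,
                "length_class": lc,
                "pma_class": pc,
                "mad": float(np.median(np.abs(v - med))),
                "n": int(v.size),
            }
        )
    if dropped:
        warnings.warn(f"empty MAD cells omitted: {sorted(dropped)}", stacklevel=2)
    return pd.DataFrame(rows)


def boxcox_transform(
    values, grid: tuple[float, float, int] = (-3.0, 3.0, 601)
) -> tuple[np.ndarray, float]:
    """Box-Cox transform with lambda chosen by profile likelihood on a grid.

    All values must be positive and finite; apply a shift beforehand for
    sign-indefinite features (see :func:`lme_length_effect`).
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("boxcox_transform requires finite values")
    if np.any(v <= 0):
        raise ValidationError("boxcox_transform requires positive values")
    lams = np.linspace(*grid)
    llf = np.array([stats.boxcox_llf(l, v) for l in lams])
    lam = float(lams[np.argmax(llf)])
    return stats.boxcox(v, lmbda=lam), lam


@dataclass(frozen=True)
class LMEResult:
    """Mixed-effects fit of one feature.

    ``params``/``bse``/``pvalues`` index the fixed effects; ``lrt_p`` is the
    likelihood-ratio p-value for dropping all length-class contrasts;
    ``var_subject``/``var_resid`` are the variance components.
    """

    feature: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    var_subject: float
    var_resid: float
    boxcox_lambda: float | None
    boxcox_shift: float
    n_obs: int


_FULL_FORMULA = (
    "value ~ C(length_class, Treatment('L')) + C(pma_class) + ga_weeks"
)
_REDUCED_FORMULA = "value ~ C(pma_class) + ga_weeks"


def _fit_mixedlm(formula: str, df: pd.DataFrame, group_col: str = "subject_id"):
    """ML fit with a fallback cascade; singular boundary fits (subject
    variance -> 0) are retried with other optimizers before giving up."""
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[group_col])
        for kwargs in ({}, {"method": "powell"}, {"method": "cg"}):
            try:
                fit = model.fit(reml=False, **kwargs)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if np.isfinite(fit.llf):
                return fit
    raise np.linalg.LinAlgError(
        f"mixed model did not converge: {last_exc}"
    )


def lme_length_effect(
    table: pd.DataFrame,
    feature: str,
    transform: str = "auto",
) -> LMEResult:
    """Mixed model of a feature on length class, PMA class and GA.

    ``value ~ length_class (ref L) + pma_class + ga_weeks`` with a random
    intercept per subject, fitted by maximum likelihood; the joint length
    effect is tested by a likelihood-ratio test against the model without
    length contrasts.  With ``transform='auto'`` the response is Box-Cox
    transformed (after shifting positive if needed) when a Shapiro-Wilk
    test on the untransformed model residuals rejects normality at 5 %;
    ``'never'`` and ``'always'`` force the choice.
    """
    validate_feature_table(table)
    df = table[table["feature"] == feature].dropna(subset=["value"]).copy()
    if df["subject_id"].nunique() < 2:
        raise InsufficientDataError("mixed model requires >= 2 subjects")
    if df["length_class"].nunique() < 2:
        raise InsufficientDataError("mixed model requires >= 2 length classes")

    shift = 0.0
    lam: float | None = None
    fit = _fit_mixedlm(_FULL_FORMULA, df)
    want_transform = transform == "always"
    if transform == "auto":
        # marginal residuals: robust to a singular (zero) random-effect fit
        resid = df["value"].to_numpy() - np.asarray(fit.predict(exog=df))
        if resid.size >= 3:
            sample = resid
            if sample.size > 5000:
                sample = np.sort(sample)[
                    np.linspace(0, sample.size - 1, 5000).astype(int)
                ]
            want_transform = stats.shapiro(sample).pvalue < 0.05
    if want_transform:
        vmin = df["value"].min()
        if vmin <= 0:
            shift = 1.0 - vmin
        df["value"], lam = boxcox_transform(df["value"] + shift)
        fit = _fit_mixedlm(_FULL_FORMULA, df)

    reduced = _fit_mixedlm(_REDUCED_FORMULA, df)
    lrt_df = df["length_class"].nunique() - 1
    lrt = max(0.0, 2.0 * (fit.llf - reduced.llf))
    lrt_p = float(stats.chi2.sf(lrt, lrt_df))
    fe = fit.fe_params
    return LMEResult(
        feature=feature,
        params=fe,
        bse=fit.bse.loc[fe.index],
        pvalues=fit.pvalues.loc[fe.index],
        lrt_stat=float(lrt),
        lrt_df=lrt_df,
        lrt_p=lrt_p,
        var_subject=float(np.asarray(fit.cov_re).ravel()[0]),
        var_resid=float(fit.scale),
        boxcox_lambda=lam,
        boxcox_shift=shift,
        n_obs=int(len(df)),
    )


def bias_loa(
    table: pd.DataFrame,
    feature: str,
    reference: str = "mean",
) -> pd.DataFrame:
    """Mixed-effects percentage bias and limits of agreement per length.

    Window replicates are first averaged within each (recording, length
    class); each length's percentage difference from a per-recording
    reference — the mean across the recording's available length classes
    (``reference='mean'``) or its 15-min value (``reference='L'``) — is
    modelled as ``d ~ length_class + pma_class + ga_weeks`` with a subject
    random intercept.  The bias of a length class is its adjusted marginal
    mean (fixed-effects prediction averaged over the observed covariate
    distribution); LoA = bias ± 1.96·sqrt(subject variance + residual
    variance).  Recordings with a non-positive reference, fewer than two
    length classes, or (for ``reference='L'``) no L value are excluded with
    a warning.
    """
    if reference not in ("mean", "L"):
        raise ValidationError("reference must be 'mean' or 'L'")
    validate_feature_table(table)
    df = table[table["feature"] == feature].dropna(subset=["value"])
    per_len = (
        df.groupby(
            [
                "subject_id",
                "ga_weeks",
                "pma_weeks",
                "pma_class",
                "recording_id",
                "length_class",
            ],
            observed=True,
        )["value"]
        .mean()
        .reset_index()
    )
    rows = []
    excluded = []
    for rec_id, grp in per_len.groupby("recording_id", sort=False):
        if grp["length_class"].nunique() < 2:
            excluded.append((rec_id, "single length class"))
            continue
        if reference == "mean":
            ref = grp["value"].mean()
        else:
            l_rows = grp.loc[grp["length_class"] == "L", "value"]
            if l_rows.empty:
                excluded.append((rec_id, "no L reference"))
                continue
            ref = float(l_rows.iloc[0])
        if not np.isfinite(ref) or ref <= 0:
            excluded.append((rec_id, "non-positive reference"))
            continue
        g = grp.copy()
        g["d"] = 100.0 * (g["value"] - ref) / ref
        rows.append(g)
    if excluded:
        warnings.warn(
            f"bias_loa excluded {len(excluded)} recording(s): {excluded[:5]}...",
            stacklevel=2,
        )
    if not rows:
        raise InsufficientDataError("no recordings usable for bias/LoA")
    dd = pd.concat(rows, ignore_index=True)
    lengths = [c for c in ("US", "S5", "S10", "L") if c in set(dd["length_class"])]
    if float(dd["d"].std()) == 0.0:
        # perfectly consistent lengths: bias is the common difference, LoA
        # collapse (the degenerate model has no estimable variance)
        bias = float(dd["d"].iloc[0])
        return pd.DataFrame(
            [
                {
                    "feature": feature,
                    "length_class": lc,
                    "bias_pct": bias,
                    "loa_low_pct": bias,
                    "loa_high_pct": bias,
                    "n_recordings": int(dd["recording_id"].nunique()),
                }
                for lc in lengths
            ]
        )
    fit = _fit_mixedlm(
        "d ~ C(length_class, Treatment('L')) + C(pma_class) + ga_weeks", dd
    )
    var_subject = float(np.asarray(fit.cov_re).ravel()[0])
    sd_total = float(np.sqrt(max(var_subject, 0.0) + fit.scale))
    out = []
    for lc in lengths:
        counterfactual = dd.copy()
        counterfactual["length_class"] = lc
        bias = float(np.mean(fit.predict(exog=counterfactual)))
        out.append(
            {
                "feature": feature,
                "length_class": lc,
                "bias_pct": bias,
                "loa_low_pct": bias - 1.96 * sd_total,
                "loa_high_pct": bias + 1.96 * sd_total,
                "n_recordings": int(dd["recording_id"].nunique()),
            }
        )
    return pd.DataFrame(out)


def significance_stars(p: float) -> str:
    """Star rendering of p-values at the customary 4 display levels."""
    if not np.isfinite(p):
        return ""
    for thresh, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < thresh:
            return stars
    return ""
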