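"""Box-plot report figures: dispersion and absolute values vs window length.

Styled after the study's summary figures: per feature, box plots of the
absolute deviations from the cell median (the quantity whose median is the
MAD) or of the absolute measurements, grouped by window-length class and
coloured by PMA class, annotated with the mixed-model significance stars.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .rr import LENGTH_CLASSES, PMA_CLASSES  # noqa: E402
from .robustness import significance_stars  # noqa: E402

__all__ = ["plot_feature_boxes", "plot_mad_boxes"]

_PMA_COLORS = {"<28": "#d62728", "28-32": "#2ca02c", "32-36": "#1f77b4", ">=36": "#9467bd"}


def _grouped_boxes(ax, df: pd.DataFrame, value_col: str, title: str, star: str = ""):
    positions, data, colors = [], [], []
    ticks, ticklabels = [], []
    pos = 0.0
    for lc in [c for c in LENGTH_CLASSES if c in set(df["length_class"])]:
        start = pos
        for pc in [c for c in PMA_CLASSES if c in set(df["pma_class"])]:
            v = df.loc[
                (df["length_class"] == lc) & (df["pma_class"] == pc), value_col
            ].dropna()
            if v.empty:
                continue
            data.append(v.to_numpy())
            positions.append(pos)
            colors.append(_PMA_COLORS.get(pc, "gray"))
            pos += 1.0
        ticks.append((start + pos - 1.0) / 2.0)
        ticklabels.append(lc)
        pos += 0.8
    if not data:
        return
    bp = ax.boxplot(data, positions=positions, widths=0.7, patch_artist=True,
                    showfliers=False)
    for patch, c in zip(bp["boxes"], colors):
        patch.set_facecolor(c)
        patch.set_alpha(0.6)
    ax.set_xticks(ticks)
    ax.set_xticklabels(ticklabels)
    ax.set_title(f"{title} {star}".strip())


def plot_feature_boxes(table: pd.DataFrame, features, lme=None, path=None):
    """Absolute measurements per length class, coloured by PMA class."""
    features = list(features)
    ncol = min(3, len(features))
    nrow = int(np.ceil(len(features) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax in axes.ravel()[len(features):]:
        ax.axis("off")
    for ax, f in zip(axes.ravel(), features):
        sub = table[table["feature"] == f]
        star = significance_stars(lme[f].lrt_p) if lme and f in lme else ""
        _grouped_boxes(ax, sub, "value", f, star)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_mad_boxes(table: pd.DataFrame, features, path=None):
    """Absolute deviations from the pooled cell median, per length class."""
    df = table.copy()
    med = df.groupby(["feature", "length_class", "pma_class"], observed=True)[
        "value"
    ].transform("median")
    df["abs_dev"] = (df["value"] - med).abs()
    features = list(features)
    ncol = min(3, len(features))
    nrow = int(np.ceil(len(features) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax in axes.ravel()[len(features):]:
        ax.axis("off")
    for ax, f in zip(axes.ravel(), features):
        _grouped_boxes(ax, df[df["feature"] == f], "abs_dev", f"|{f} - median|")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
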