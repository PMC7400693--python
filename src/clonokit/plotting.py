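"""Minimal static plots for the exported tables.

The primary contract of every analysis is its table; these helpers render
the three views users most often want to glance at. Anything fancier
(alluvial ribbons, themed heatmaps) belongs in a dedicated plotting stack
fed by the exported TSVs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_length_distribution(lengths: pd.DataFrame, ax=None):
    """Histogram of combined CDR3 lengths, one overlaid series per sample."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for sample, sub in lengths.groupby("sample"):
        ax.hist(sub["length"], bins=range(int(lengths["length"].min()),
                                          int(lengths["length"].max()) + 2),
                alpha=0.5, label=str(sample))
    ax.set_xlabel("combined CDR3 length")
    ax.set_ylabel("cells")
    ax.legend(frameon=False)
    return ax


def plot_homeostasis(per_sample: dict[str, dict[str, float]], ax=None):
    """Stacked bars of clonal-space occupancy per sample."""
    df = pd.DataFrame(per_sample).T
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    bottom = pd.Series(0.0, index=df.index)
    for label in df.columns:
        ax.bar(df.index, df[label], bottom=bottom, label=label)
        bottom += df[label]
    ax.set_ylabel("repertoire space")
    ax.legend(frameon=False, fontsize="small")
    return ax


def plot_embedding(meta: pd.DataFrame, color: str = "freq_bin", ax=None):
    """Scatter of the 2-D embedding coloured by a categorical column.

    Cells with a missing value (e.g. no receptor call) are drawn in grey
    underneath the coloured groups.
    """
    for col in ("dim1", "dim2", color):
        if col not in meta.columns:
            raise ValueError(f"metadata has no column {col!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    missing = meta[color].isna()
    ax.scatter(meta.loc[missing, "dim1"], meta.loc[missing, "dim2"],
               s=4, c="lightgrey", label="_none")
    for level, sub in meta[~missing].groupby(color, observed=True):
        ax.scatter(sub["dim1"], sub["dim2"], s=4, label=str(level))
    ax.set_xlabel("dim1")
    ax.set_ylabel("dim2")
    ax.legend(frameon=False, markerscale=3, fontsize="small")
    return ax
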