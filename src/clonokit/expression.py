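"""Join clonotype calls onto per-cell expression metadata.

The metadata side is a plain table keyed by (prefixed) cell barcode — a
cluster label, a sample annotation, optional 2-D embedding coordinates —
exactly what any single-cell framework can export. Joining is a left join:
cells without a receptor call are kept with missing clonotype fields so
they can still be drawn on the embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .combine import CALL_COLUMNS, RepertoireSet
from .counts import CountVector


@dataclass(frozen=True)
class FrequencyBins:
    """Clone-frequency classes for grouping cells.

    Bounds are absolute cell counts by default (a cell in a clone seen 3
    times falls in the first bin with bound >= 3); with ``proportion_mode``
    the bounds are clone proportions of the scope total instead.
    Frequencies beyond the last bound are clamped into the last bin.
    """

    edges: tuple = (
        ("Single", 1),
        ("Small", 5),
        ("Medium", 20),
        ("Large", 100),
        ("Hyperexpanded", 500),
    )
    proportion_mode: bool = False

    def __post_init__(self):
        bounds = [b for _, b in self.edges]
        if not bounds or any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("bounds must be non-empty, strictly increasing")
        object.__setattr__(self, "edges", tuple((str(l), float(b))
                                                for l, b in self.edges))

    @property
    def labels(self):
        return [l for l, _ in self.edges]

    def assign(self, values: pd.Series) -> pd.Series:
        bounds = [b for _, b in self.edges]
        idx = np.searchsorted(bounds, values.to_numpy(dtype=float),
                              side="left")
        idx = np.minimum(idx, len(bounds) - 1)
        labels = [self.labels[i] for i in idx]
        return pd.Series(pd.Categorical(labels, categories=self.labels,
                                        ordered=True), index=values.index)


def combine_expression(rep: RepertoireSet, meta: pd.DataFrame,
                       call_by: str = "aa",
                       bins: FrequencyBins = FrequencyBins(),
                       group_scope: str = "per_sample") -> pd.DataFrame:
    """Left-join clonotype calls and frequencies onto cell metadata.

    Every metadata row is retained; matched cells gain ``clonotype_key``,
    ``frequency`` (number of cells sharing that key within the chosen
    scope: the cell's sample, or the whole set) and an ordered ``freq_bin``
    category. ``freq_bin`` is missing exactly when ``clonotype_key`` is.
    """
    if "barcode" not in meta.columns:
        raise ValueError("metadata must have a 'barcode' column")
    col = CALL_COLUMNS.get(call_by)
    if col is None:
        raise ValueError(f"call_by must be one of {sorted(CALL_COLUMNS)}")
    if group_scope not in ("per_sample", "global"):
        raise ValueError("group_scope must be 'per_sample' or 'global'")

    cells = rep.cells()
    out = meta.copy()
    if cells.empty:
        out["clonotype_key"] = pd.NA
        out["frequency"] = pd.NA
        out["freq_bin"] = pd.Series(
            pd.Categorical([None] * len(out), categories=bins.labels,
                           ordered=True), index=out.index)
        return out

    cells = cells[["barcode", "sample", col]].rename(
        columns={col: "clonotype_key"})
    if group_scope == "per_sample":
        cells["frequency"] = cells.groupby(
            ["sample", "clonotype_key"])["clonotype_key"].transform("size")
        scope_total = cells.groupby("sample")["barcode"].transform("size")
    else:
        cells["frequency"] = cells.groupby(
            "clonotype_key")["clonotype_key"].transform("size")
        scope_total = pd.Series(len(cells), index=cells.index)
    if bins.proportion_mode:
        cells["_bin_value"] = cells["frequency"] / scope_total
    else:
        cells["_bin_value"] = cells["frequency"]

    if len(out) and not set(out["barcode"]) & set(cells["barcode"]):
        raise ValueError(
            "no barcode overlap between metadata and clonotype tables — "
            "check that both sides use the same sample prefixing scheme")

    joined = out.merge(cells[["barcode", "clonotype_key", "frequency",
                              "_bin_value"]],
                       on="barcode", how="left", validate="one_to_one")
    matched = joined["_bin_value"].notna()
    freq_bin = pd.Series(
        pd.Categorical([None] * len(joined), categories=bins.labels,
                       ordered=True), index=joined.index)
    if matched.any():
        freq_bin[matched] = bins.assign(joined.loc[matched, "_bin_value"])
    joined["freq_bin"] = freq_bin
    return joined.drop(columns="_bin_value")


def highlight_clonotypes(meta: pd.DataFrame, sequences: Sequence[str],
                         key_col: str = "clonotype_key") -> pd.DataFrame:
    """Flag cells whose clonotype key matches one of ``sequences``.

    Adds a ``highlight`` column holding the matched sequence (missing for
    all other cells). A sequence matching zero cells raises a warning
    naming it — usually a typo or the wrong ``call_by`` resolution.
    """
    if key_col not in meta.columns:
        raise ValueError(f"metadata has no column {key_col!r}; "
                         "run combine_expression first")
    out = meta.copy()
    out["highlight"] = pd.NA
    for seq in sequences:
        hits = out[key_col] == seq
        if not hits.any():
            warnings.warn(f"highlight sequence matched no cells: {seq!r}",
                          stacklevel=2)
        out.loc[hits, "highlight"] = seq
    return out


def cluster_composition(meta: pd.DataFrame, cluster_col: str,
                        group_col: str, scaled: bool = False) -> pd.DataFrame:
    """Group composition of each cluster (dense; proportions sum to 1).

    With ``scaled``, each group's cell counts are first divided by the
    group's total so groups of unequal size contribute comparably — the
    within-cluster proportions are then of normalised weight, not raw cells.
    """
    for c in (cluster_col, group_col):
        if c not in meta.columns:
            raise ValueError(f"metadata has no column {c!r}")
    counts = pd.crosstab(meta[cluster_col], meta[group_col])
    weights = counts / counts.sum(axis=0) if scaled else counts.astype(float)
    props = weights.div(weights.sum(axis=1), axis=0)
    out = []
    for cluster in counts.index:
        for group in counts.columns:
            out.append({"cluster": cluster, "group": group,
                        "count": int(counts.loc[cluster, group]),
                        "proportion": float(props.loc[cluster, group])})
    return pd.DataFrame(out, columns=["cluster", "group", "count",
                                      "proportion"])


def alluvial_table(meta: pd.DataFrame, axes: Sequence[str],
                   weight: str = "cells",
                   max_levels: int = 1000) -> pd.DataFrame:
    """Flow table across categorical axes for alluvial-style plots.

    One row per observed combination of axis values, weighted by cell count
    or by summed clonotype frequency. Refuses axes with more than
    ``max_levels`` levels (the plot would be unreadable; export the raw
    table instead).
    """
    if len(axes) < 2:
        raise ValueError("alluvial_table needs at least 2 axes")
    for c in axes:
        if c not in meta.columns:
            raise ValueError(f"metadata has no column {c!r}")
        nlev = meta[c].nunique(dropna=True)
        if nlev > max_levels:
            raise ValueError(
                f"axis {c!r} has {nlev} levels (> {max_levels}); an "
                "alluvial plot would be unreadable — export the raw "
                "metadata table instead")
    if weight == "cells":
        out = (meta.groupby(list(axes), observed=True, dropna=True)
               .size().reset_index(name="weight"))
    elif weight == "clonotype_frequency":
        if "frequency" not in meta.columns:
            raise ValueError("weight='clonotype_frequency' requires a "
                             "'frequency' column (run combine_expression)")
        out = (meta.groupby(list(axes), observed=True, dropna=True)
               ["frequency"].sum().reset_index(name="weight"))
    else:
        raise ValueError("weight must be 'cells' or 'clonotype_frequency'")
    return out


def split_by_metadata(meta: pd.DataFrame,
                      column: str) -> dict[str, pd.DataFrame]:
    """Partition cells by the levels of a categorical metadata column.

    Every repertoire statistic can then be computed per level (per cluster,
    per tissue, ...) by converting each subset to a
    :class:`~clonokit.counts.CountVector` with :func:`meta_counts`.
    """
    if column not in meta.columns:
        raise ValueError(f"metadata has no column {column!r}")
    if pd.api.types.is_float_dtype(meta[column]):
        raise TypeError(f"column {column!r} is continuous, not categorical")
    return {level: sub.copy()
            for level, sub in meta.groupby(column, observed=True,
                                           dropna=True)}


def meta_counts(meta: pd.DataFrame,
                key_col: str = "clonotype_key") -> CountVector:
    """Clonotype counts of a (subset of a) joined metadata table."""
    if key_col not in meta.columns:
        raise ValueError(f"metadata has no column {key_col!r}")
    return CountVector.from_keys(meta[key_col].dropna())
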