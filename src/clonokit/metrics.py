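"""Per-sample clonal-architecture statistics.

All operations consume :class:`~clonokit.counts.CountVector` or a
:class:`~clonokit.combine.RepertoireSet` and return plain tables or
mappings, each with a TSV export form (see :func:`export_table`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .combine import CALL_COLUMNS, NA, RepertoireSet
from .counts import CountVector


def quantify_unique(cv: CountVector, scaled: bool = False):
    """Number of unique clonotypes, optionally scaled to library size.

    Returns ``(unique, value)`` where ``value`` is the raw count when
    ``scaled`` is False, else the percentage 100 * unique / total cells.
    """
    unique = cv.richness
    if scaled:
        return unique, 100.0 * unique / cv.total
    return unique, float(unique)


def abundance_table(cv: CountVector) -> pd.DataFrame:
    """Clonotype abundances sorted by descending count (ties: key order).

    Columns: clonotype_key, count, proportion; proportions sum to 1.
    """
    if cv.richness == 0:
        return pd.DataFrame(columns=["clonotype_key", "count", "proportion"])
    df = pd.DataFrame({"clonotype_key": list(cv.keys()),
                       "count": list(cv.values())})
    df["proportion"] = df["count"] / cv.total
    df = df.sort_values(["count", "clonotype_key"],
                        ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def _combined_length(ct: str) -> int:
    # length of real sequence only: drop the locus separator, the "NA"
    # placeholders, and the ";" between same-locus duplicates
    total = 0
    for locus in str(ct).split("_"):
        for seq in locus.split(";"):
            if seq != NA:
                total += len(seq)
    return total


def cdr3_lengths(rep: RepertoireSet, call_by: str = "nt",
                 per_chain: bool = False) -> pd.DataFrame:
    """CDR3 length distribution per sample.

    When ``per_chain``, one row per non-missing chain CDR3 (dual chains are
    counted separately). When combined (default), one row per cell with the
    summed length of its clonotype string, excluding separators and the
    ``"NA"`` placeholder: a single-chain cell contributes only its real
    sequence length, which is what makes the combined distribution bimodal
    in repertoires mixing single- and dual-receptor cells.
    """
    if call_by not in ("nt", "aa"):
        raise ValueError("call_by must be 'nt' or 'aa'")
    rows = []
    chain_cols = (("cdr3_nt1", "cdr3_nt2") if call_by == "nt"
                  else ("cdr3_aa1", "cdr3_aa2"))
    ct_col = CALL_COLUMNS[call_by]
    for name, df in rep.samples.items():
        if per_chain:
            for chain_idx, colname in enumerate(chain_cols, start=1):
                for val in df[colname].dropna():
                    for seq in str(val).split(";"):
                        if seq != NA:
                            rows.append({"sample": name,
                                         "chain": chain_idx,
                                         "sequence": seq,
                                         "length": len(seq)})
        else:
            for ct in df[ct_col]:
                rows.append({"sample": name, "sequence": ct,
                             "length": _combined_length(ct)})
    cols = (["sample", "chain", "sequence", "length"] if per_chain
            else ["sample", "sequence", "length"])
    return pd.DataFrame(rows, columns=cols)


def count_length_modes(lengths: Sequence[int], smooth: int = 5,
                       min_prominence_frac: float = 0.1) -> int:
    """Count modes of an integer length distribution.

    Histogram over the observed range, moving-average smoothing, peaks via
    prominence >= ``min_prominence_frac`` of the tallest bin. Used to test
    the single- vs dual-receptor bimodality of combined CDR3 lengths; pass
    lengths of *distinct* clonotypes, not of cells — a single expanded
    clone otherwise injects a spike at its own length that any smoothing
    window mistakes for a mode.
    """
    lengths = np.asarray(lengths, dtype=int)
    if lengths.size == 0:
        return 0
    lo, hi = lengths.min(), lengths.max()
    hist = np.bincount(lengths - lo, minlength=hi - lo + 1).astype(float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        hist = np.convolve(hist, kernel, mode="same")
    # pad so boundary maxima register as peaks
    padded = np.concatenate([[0.0], hist, [0.0]])
    peaks, _ = find_peaks(padded, prominence=min_prominence_frac * hist.max())
    return int(len(peaks))


@dataclass(frozen=True)
class HomeostasisBins:
    """Clone-proportion classes partitioning (0, 1].

    ``edges`` are (label, upper bound) pairs with strictly increasing
    bounds ending at 1; each clonotype of relative size p falls in the
    first bin with p <= bound (half-open on the left, closed on the right).
    """

    edges: tuple = (
        ("Rare", 1e-4),
        ("Small", 1e-3),
        ("Medium", 0.01),
        ("Large", 0.1),
        ("Hyperexpanded", 1.0),
    )

    def __post_init__(self):
        bounds = [b for _, b in self.edges]
        if not bounds:
            raise ValueError("edges must be non-empty")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("upper bounds must be strictly increasing")
        if bounds[-1] != 1:
            raise ValueError("final upper bound must be 1")
        object.__setattr__(self, "edges", tuple((str(l), float(b))
                                                for l, b in self.edges))

    @property
    def labels(self):
        return [l for l, _ in self.edges]


def clonal_homeostasis(cv: CountVector,
                       bins: HomeostasisBins = HomeostasisBins()
                       ) -> dict[str, float]:
    """Fraction of repertoire space occupied by each clone-size class.

    Each clonotype's proportion p is assigned to the first bin with
    p <= upper bound; the returned value per bin is the summed proportion
    of its members, so values sum to 1 for a non-empty repertoire.
    """
    out = {label: 0.0 for label in bins.labels}
    if cv.richness == 0:
        return out
    props = cv.proportions()
    bounds = np.array([b for _, b in bins.edges])
    idx = np.searchsorted(bounds, props, side="left")
    for i, p in zip(idx, props):
        out[bins.labels[min(i, len(bounds) - 1)]] += float(p)
    return out


DEFAULT_PROPORTION_SPLIT = (10, 100, 1000, 10000, 30000, 100000)


def clonal_proportion(cv: CountVector,
                      split: Sequence[int] = DEFAULT_PROPORTION_SPLIT
                      ) -> dict[str, int]:
    """Cells occupied by clonotypes of given abundance ranks.

    Clonotypes are ranked by descending count (ties broken by key); the
    bin ``[1:10]`` sums the counts of ranks 1-10, ``[11:100]`` ranks
    11-100, and so on per ``split``. Bin totals sum to ``cv.total``.
    """
    split = list(split)
    if any(s2 <= s1 for s1, s2 in zip(split, split[1:])) or split[0] < 1:
        raise ValueError("split must be strictly increasing positive ranks")
    labels = []
    lower = 1
    for upper in split:
        labels.append(f"[{lower}:{upper}]")
        lower = upper + 1
    out = {label: 0 for label in labels}
    counts = abundance_table(cv)["count"].to_numpy() if cv.richness else []
    for rank0, count in enumerate(counts):
        rank = rank0 + 1
        for label, upper in zip(labels, split):
            if rank <= upper:
                out[label] += int(count)
                break
        # ranks beyond the last split bound are not binned; with the default
        # split (up to 1e5) this never happens for single-cell repertoires
    return out


def export_table(result, path, **kwargs) -> None:
    """Write any metric result (table or mapping) as TSV.

    The textual counterpart of every plot: mappings become two-column
    key/value tables, DataFrames are written as-is.
    """
    path = Path(path)
    if isinstance(result, pd.DataFrame):
        result.to_csv(path, sep="\t", index=False, na_rep=NA, **kwargs)
    elif isinstance(result, Mapping):
        pd.DataFrame({"key": list(result.keys()),
                      "value": list(result.values())}).to_csv(
            path, sep="\t", index=False, **kwargs)
    else:
        raise TypeError(f"cannot export {type(result).__name__}")
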