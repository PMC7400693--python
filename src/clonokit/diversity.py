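"""Repertoire diversity indices, pairwise overlap, and clone-size clustering.

Diversity follows the classical ecology estimators applied to clonotype
abundances: Shannon entropy (natural log), inverse Simpson, bias-corrected
Chao1 richness, and the abundance-based coverage estimator (ACE). Overlap
between repertoires uses the overlap coefficient on clonotype sets or the
Morisita-Horn index on relative abundances. Clone-size distributions are
compared with the Jensen-Shannon divergence (base 2, hence bounded by 1)
and clustered hierarchically with average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.special import rel_entr

from .counts import CountVector


def _check_nonempty(cv: CountVector, name: str = "count vector") -> None:
    if cv.richness == 0:
        raise ValueError(f"{name} is empty; diversity is undefined")


def shannon_index(cv: CountVector) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats). Divide by ln 2 for bits."""
    _check_nonempty(cv)
    p = cv.proportions()
    return float(-(p * np.log(p)).sum())


def inverse_simpson(cv: CountVector) -> float:
    """Inverse Simpson index 1 / sum p_i^2; equals k for k equal clones."""
    _check_nonempty(cv)
    p = cv.proportions()
    return float(1.0 / (p ** 2).sum())


def chao1(cv: CountVector) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1/F2 are the numbers of singleton/doubleton clonotypes. The
    bias-corrected form stays defined when no doubletons exist, unlike the
    classic F1^2 / 2 F2 estimator.
    """
    _check_nonempty(cv)
    counts = cv.values_array()
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return float(len(counts) + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def ace(cv: CountVector, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator of clonotype richness.

    S_abund + S_rare / C_ace + (F1 / C_ace) * gamma^2, where the rare class
    holds clonotypes of count <= ``rare_threshold``, C_ace = 1 - F1/N_rare
    is the rare-class sample coverage and gamma^2 the rare-class coefficient
    of variation, floored at 0. When every rare clonotype is a singleton the
    coverage is 0 and the estimator falls back to :func:`chao1`.
    """
    _check_nonempty(cv)
    counts = cv.values_array()
    rare = counts[counts <= rare_threshold]
    s_abund = int((counts > rare_threshold).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return chao1(cv)
    ss = sum(i * (i - 1) * int((rare == i).sum())
             for i in range(1, rare_threshold + 1))
    if n_rare > 1:
        gamma2 = max(s_rare / c_ace * ss / (n_rare * (n_rare - 1.0)) - 1.0,
                     0.0)
    else:
        gamma2 = 0.0
    return float(s_abund + s_rare / c_ace + f1 / c_ace * gamma2)


def diversity_table(reps: Mapping[str, CountVector],
                    rare_threshold: int = 10) -> pd.DataFrame:
    """All four diversity indices per sample, as one table."""
    rows = []
    for name, cv in reps.items():
        rows.append({
            "sample": name,
            "richness": cv.richness,
            "shannon": shannon_index(cv),
            "inv_simpson": inverse_simpson(cv),
            "chao1": chao1(cv),
            "ace": ace(cv, rare_threshold=rare_threshold),
        })
    return pd.DataFrame(rows,
                        columns=["sample", "richness", "shannon",
                                 "inv_simpson", "chao1", "ace"])


def overlap_coefficient(a: CountVector, b: CountVector) -> float:
    """|A ∩ B| / min(|A|, |B|) on clonotype key sets."""
    _check_nonempty(a, "first repertoire")
    _check_nonempty(b, "second repertoire")
    ka, kb = set(a.keys()), set(b.keys())
    return len(ka & kb) / min(len(ka), len(kb))


def morisita_index(a: CountVector, b: CountVector) -> float:
    """Morisita-Horn similarity of two repertoires.

    2 sum x_i y_i / [(sum x_i^2 / X^2 + sum y_i^2 / Y^2) X Y] over the union
    of clonotype keys; 0 for disjoint repertoires, 1 for identical relative
    composition. The Horn variant is used because the classic Morisita
    lambda is undefined on singleton-heavy repertoires.
    """
    _check_nonempty(a, "first repertoire")
    _check_nonempty(b, "second repertoire")
    keys = set(a.keys()) | set(b.keys())
    x = np.array([a.get(k, 0) for k in keys], dtype=float)
    y = np.array([b.get(k, 0) for k in keys], dtype=float)
    bx, by = x.sum(), y.sum()
    num = 2.0 * (x * y).sum()
    den = ((x ** 2).sum() / bx ** 2 + (y ** 2).sum() / by ** 2) * bx * by
    return float(num / den)


_OVERLAP_METHODS = {"overlap_coefficient": overlap_coefficient,
                    "morisita": morisita_index}


def overlap_matrix(reps: Mapping[str, CountVector],
                   method: str = "morisita") -> pd.DataFrame:
    """Pairwise overlap across samples: symmetric, unit diagonal."""
    if len(reps) < 2:
        raise ValueError("overlap requires at least 2 samples")
    fn = _OVERLAP_METHODS.get(method)
    if fn is None:
        raise ValueError(f"method must be one of {sorted(_OVERLAP_METHODS)}")
    names = list(reps.keys())
    n = len(names)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = fn(reps[names[i]], reps[names[j]])
    return pd.DataFrame(mat, index=names, columns=names)


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray,
                              base: float = 2.0) -> float:
    """JSD(P, Q) = 1/2 KL(P||M) + 1/2 KL(Q||M) with M = (P+Q)/2.

    0 log 0 terms are 0; with base 2 the result lies in [0, 1] and equals 1
    exactly for distributions with disjoint support.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    jsd = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    return float(jsd / np.log(base))


@dataclass
class CloneSizeClustering:
    """Pairwise JSD of clone-size distributions plus their dendrogram."""

    distance: pd.DataFrame
    linkage: np.ndarray

    def to_newick(self) -> str:
        """Dendrogram as a Newick string (branch lengths = merge heights)."""
        tree = to_tree(self.linkage)
        names = list(self.distance.index)

        def recurse(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({recurse(tree.left, tree.dist)}," \
               f"{recurse(tree.right, tree.dist)});"


def clone_size_distribution(cv: CountVector,
                            bin_edges: np.ndarray) -> np.ndarray:
    """Histogram of clone sizes over shared bin edges, as probabilities."""
    hist, _ = np.histogram(cv.values_array(), bins=bin_edges)
    total = hist.sum()
    return hist / total if total else hist.astype(float)


def clone_size_jsd(reps: Mapping[str, CountVector],
                   n_bins: int = 30) -> CloneSizeClustering:
    """Cluster samples by the shape of their clone-size distributions.

    Clone sizes are pooled to fix log-spaced bin edges spanning the whole
    observed range; each sample's histogram over those bins becomes a
    probability vector; samples are compared with base-2 Jensen-Shannon
    divergence and clustered with average linkage (samples are processed
    in alphabetical order so leaf order is deterministic).
    """
    if len(reps) < 2:
        raise ValueError("clone-size clustering requires at least 2 samples")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    names = sorted(reps.keys())
    pooled = np.concatenate([reps[n].values_array() for n in names])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        edges = np.array([lo - 0.5, lo + 0.5])
    else:
        edges = np.logspace(np.log10(lo * 0.999), np.log10(hi * 1.001),
                            n_bins + 1)
    dists = {n: clone_size_distribution(reps[n], edges) for n in names}
    k = len(names)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = jensen_shannon_divergence(
                dists[names[i]], dists[names[j]])
    dist_df = pd.DataFrame(mat, index=names, columns=names)
    lk = linkage(squareform(mat, checks=False), method="average")
    return CloneSizeClustering(distance=dist_df, linkage=lk)
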