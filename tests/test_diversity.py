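"""Diversity indices, overlap measures, and clone-size JSD clustering.

Each estimator is checked against an independent brute-force evaluation of
its defining formula, against closed-form limits, and (where available)
against scikit-bio's implementations on the same vectors.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.diversity import alpha as skbio_alpha

from clonokit.counts import CountVector
from clonokit.diversity import (
    ace,
    chao1,
    clone_size_jsd,
    diversity_table,
    inverse_simpson,
    jensen_shannon_divergence,
    morisita_index,
    overlap_coefficient,
    overlap_matrix,
    shannon_index,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (plain-Python transcription of the formulas)


def brute_shannon(counts):
    total = sum(counts)
    return -sum((c / total) * math.log(c / total) for c in counts)


def brute_inv_simpson(counts):
    total = sum(counts)
    return 1.0 / sum((c / total) ** 2 for c in counts)


def brute_chao1(counts):
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    return len(counts) + f1 * (f1 - 1) / (2 * (f2 + 1))


def brute_ace(counts, threshold=10):
    rare = [c for c in counts if c <= threshold]
    s_abund = sum(1 for c in counts if c > threshold)
    if not rare:
        return float(s_abund)
    n_rare = sum(rare)
    f1 = sum(1 for c in rare if c == 1)
    c_ace = 1 - f1 / n_rare
    if c_ace == 0:
        return brute_chao1(counts)
    ss = sum(i * (i - 1) * sum(1 for c in rare if c == i)
             for i in range(1, threshold + 1))
    gamma2 = max(len(rare) / c_ace * ss / (n_rare * (n_rare - 1)) - 1, 0) \
        if n_rare > 1 else 0.0
    return s_abund + len(rare) / c_ace + f1 / c_ace * gamma2


def cv_of(counts):
    return CountVector({f"k{i}": c for i, c in enumerate(counts)})


# 20+ hand-checkable vectors spanning the estimator branches
ORACLE_VECTORS = [
    [5, 3, 2], [1, 1, 2, 3], [50], [1], [1, 1], [2, 2, 2], [10, 10],
    [1, 2, 3, 4, 5], [100, 1, 1, 1], [7, 7, 7, 7, 7, 7, 7],
    [1] * 25, [2] * 12, [11, 12, 13], [1, 10, 100, 1000],
    [3, 3, 2, 2, 1, 1], [9, 8, 7, 6, 5, 4, 3, 2, 1],
    [1, 1, 1, 2, 2, 3, 10, 50], [4, 1], [1, 4], [60, 30, 10],
    [5, 5, 5, 1], [2, 1], [1000, 1], [1] * 3 + [2] * 3 + [11] * 3,
]


class TestDiversityIndices:
    @pytest.mark.parametrize("counts", ORACLE_VECTORS,
                             ids=[str(v)[:30] for v in ORACLE_VECTORS])
    def test_matches_bruteforce_formulas(self, counts):
        cv = cv_of(counts)
        assert shannon_index(cv) == pytest.approx(brute_shannon(counts),
                                                  abs=1e-9)
        assert inverse_simpson(cv) == pytest.approx(
            brute_inv_simpson(counts), abs=1e-9)
        assert chao1(cv) == pytest.approx(brute_chao1(counts), abs=1e-9)
        assert ace(cv) == pytest.approx(brute_ace(counts), abs=1e-9)

    def test_worked_values(self):
        # hand evaluations of the defining formulas
        assert shannon_index(cv_of([5, 3, 2])) == pytest.approx(
            -(0.5 * math.log(0.5) + 0.3 * math.log(0.3)
              + 0.2 * math.log(0.2)), abs=1e-12)
        assert inverse_simpson(cv_of([5, 3, 2])) == pytest.approx(
            1 / 0.38, abs=1e-9)
        assert chao1(cv_of([1, 1, 2, 3])) == pytest.approx(4.5)
        assert ace(cv_of([1, 1, 2, 3])) == pytest.approx(
            5.6 + 2.8 * (5.6 * 8 / 42 - 1), abs=1e-9)

    def test_closed_form_limits(self):
        for k in (2, 5, 17):
            uniform = cv_of([4] * k)
            assert shannon_index(uniform) == pytest.approx(math.log(k))
            assert inverse_simpson(uniform) == pytest.approx(k)
        single = cv_of([50])
        assert shannon_index(single) == 0.0
        assert inverse_simpson(single) == pytest.approx(1.0)
        # no singletons -> chao1 = observed richness
        assert chao1(cv_of([2, 3, 4])) == 3.0
        # all counts above the rare threshold -> ace = observed richness
        assert ace(cv_of([11, 12, 13])) == 3.0
        # all singletons -> ace falls back to chao1: n + n(n-1)/2
        n = 25
        assert chao1(cv_of([1] * n)) == pytest.approx(n + n * (n - 1) / 2)
        assert ace(cv_of([1] * n)) == chao1(cv_of([1] * n))

    @pytest.mark.parametrize("counts", ORACLE_VECTORS[:12],
                             ids=[str(v)[:30] for v in ORACLE_VECTORS[:12]])
    def test_cross_check_against_skbio(self, counts):
        cv = cv_of(counts)
        arr = np.array(counts)
        assert shannon_index(cv) == pytest.approx(
            float(skbio_alpha.shannon(arr, base=math.e)), abs=1e-9)
        assert inverse_simpson(cv) == pytest.approx(
            float(skbio_alpha.enspie(arr)), abs=1e-9)
        assert chao1(cv) == pytest.approx(
            float(skbio_alpha.chao1(arr, bias_corrected=True)), abs=1e-9)

    def test_empty_vector_rejected(self):
        for fn in (shannon_index, inverse_simpson, chao1, ace):
            with pytest.raises(ValueError):
                fn(CountVector({}))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 500), min_size=2, max_size=40))
    def test_invariants_and_schur_concavity(self, counts):
        cv = cv_of(counts)
        h, inv = shannon_index(cv), inverse_simpson(cv)
        assert 0 <= h <= math.log(cv.richness) + 1e-12
        assert 1 - 1e-12 <= inv <= cv.richness + 1e-12
        assert chao1(cv) >= cv.richness - 1e-12
        # concentrate mass: move one cell from the smallest clone to the
        # largest; neither index may increase
        ordered = sorted(counts, reverse=True)
        ordered[0] += 1
        ordered[-1] -= 1
        moved = [c for c in ordered if c > 0]
        assert shannon_index(cv_of(moved)) <= h + 1e-9
        assert inverse_simpson(cv_of(moved)) <= inv + 1e-9

    def test_relabeling_invariance(self, rng):
        counts = list(rng.integers(1, 100, size=20))
        a = CountVector({f"k{i}": int(c) for i, c in enumerate(counts)})
        b = CountVector({f"other{i}": int(c)
                         for i, c in enumerate(reversed(counts))})
        for fn in (shannon_index, inverse_simpson, chao1, ace):
            assert fn(a) == pytest.approx(fn(b), abs=1e-12)


class TestOverlap:
    def test_overlap_coefficient_set_arithmetic(self):
        a = CountVector({"a": 1, "b": 2, "c": 3})
        b = CountVector({"b": 5, "c": 1, "d": 2, "e": 9})
        assert overlap_coefficient(a, b) == pytest.approx(2 / 3)

    def test_subset_gives_one_disjoint_gives_zero(self):
        a = CountVector({"a": 1, "b": 9})
        b = CountVector({"a": 3, "b": 1, "c": 7})
        assert overlap_coefficient(a, b) == 1.0
        assert overlap_coefficient(a, CountVector({"z": 1})) == 0.0
        assert morisita_index(a, CountVector({"z": 1})) == 0.0

    def test_morisita_worked_value(self):
        x = CountVector({"A": 4, "B": 1})
        y = CountVector({"A": 1, "B": 4})
        assert morisita_index(x, y) == pytest.approx(16 / 34, abs=1e-12)

    def test_identical_composition_gives_one(self):
        x = CountVector({"A": 4, "B": 1, "C": 5})
        assert morisita_index(x, x) == pytest.approx(1.0)
        # scale invariance of the Horn variant
        y = CountVector({"A": 8, "B": 2, "C": 10})
        assert morisita_index(x, y) == pytest.approx(1.0)

    def test_random_vectors_match_sum_arithmetic(self, rng):
        for _ in range(50):
            nk = int(rng.integers(1, 8))
            keys = [f"k{i}" for i in range(nk + 2)]
            a = {k: int(rng.integers(1, 20))
                 for k in rng.choice(keys, size=nk, replace=False)}
            b = {k: int(rng.integers(1, 20))
                 for k in rng.choice(keys, size=nk, replace=False)}
            cva, cvb = CountVector(a), CountVector(b)
            inter = set(a) & set(b)
            assert overlap_coefficient(cva, cvb) == pytest.approx(
                len(inter) / min(len(a), len(b)))
            bx, by = sum(a.values()), sum(b.values())
            num = 2 * sum(a[k] * b[k] for k in inter)
            den = (sum(v * v for v in a.values()) / bx ** 2
                   + sum(v * v for v in b.values()) / by ** 2) * bx * by
            assert morisita_index(cva, cvb) == pytest.approx(num / den,
                                                             abs=1e-12)
            assert morisita_index(cva, cvb) == pytest.approx(
                morisita_index(cvb, cva), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            morisita_index(CountVector({}), CountVector({"a": 1}))
        with pytest.raises(ValueError):
            overlap_coefficient(CountVector({"a": 1}), CountVector({}))

    def test_matrix_symmetric_unit_diagonal(self, rng):
        reps = {}
        keys = [f"k{i}" for i in range(30)]
        for s in range(6):
            chosen = rng.choice(keys, size=10, replace=False)
            reps[f"S{s}"] = CountVector(
                {k: int(rng.integers(1, 50)) for k in chosen})
        for method in ("morisita", "overlap_coefficient"):
            mat = overlap_matrix(reps, method=method)
            arr = mat.to_numpy()
            assert np.allclose(arr, arr.T, atol=1e-12)
            assert np.allclose(np.diag(arr), 1.0)
            assert ((arr >= 0) & (arr <= 1 + 1e-12)).all()
            # each off-diagonal entry equals the direct pair computation
            fn = (morisita_index if method == "morisita"
                  else overlap_coefficient)
            for i in mat.index:
                for j in mat.columns:
                    if i != j:
                        assert mat.loc[i, j] == pytest.approx(
                            fn(reps[i], reps[j]), abs=1e-12)

    def test_matrix_needs_two_samples(self):
        with pytest.raises(ValueError):
            overlap_matrix({"only": CountVector({"a": 1})})


class TestJensenShannon:
    def test_identity_and_worked_value(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jensen_shannon_divergence(p, p) == pytest.approx(0.0,
                                                                abs=1e-15)
        # hand evaluation: P=(1,0), Q=(1/2,1/2), M=(3/4,1/4)
        got = jensen_shannon_divergence(np.array([1.0, 0.0]),
                                        np.array([0.5, 0.5]))
        expect = 0.5 * math.log2(4 / 3) \
            + 0.5 * (0.5 * math.log2(2 / 3) + 0.5 * math.log2(2))
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(0.3113, abs=1e-4)

    def test_disjoint_support_is_one(self):
        assert jensen_shannon_divergence(
            np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        from scipy.spatial.distance import jensenshannon
        for _ in range(20):
            p = rng.random(8)
            q = rng.random(8)
            assert jensen_shannon_divergence(p, q) == pytest.approx(
                jensenshannon(p, q, base=2) ** 2, abs=1e-10)

    def test_symmetry_and_sqrt_triangle_inequality(self, rng):
        for _ in range(1000):
            p, q, r = rng.random((3, 6))
            dpq = jensen_shannon_divergence(p, q)
            dqr = jensen_shannon_divergence(q, r)
            dpr = jensen_shannon_divergence(p, r)
            assert dpq == pytest.approx(jensen_shannon_divergence(q, p),
                                        abs=1e-12)
            assert 0 <= dpq <= 1 + 1e-12
            assert math.sqrt(dpr) <= math.sqrt(dpq) + math.sqrt(dqr) + 1e-9


class TestCloneSizeClustering:
    def reps(self, rng):
        out = {}
        for s in range(4):
            sizes = rng.zipf(2.0, size=200)
            out[f"S{s}"] = CountVector(
                {f"S{s}k{i}": int(min(c, 500))
                 for i, c in enumerate(sizes)})
        return out

    def test_matrix_properties_and_newick(self, rng):
        clust = clone_size_jsd(self.reps(rng), n_bins=20)
        arr = clust.distance.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)
        assert ((arr >= 0) & (arr <= 1 + 1e-12)).all()
        nwk = clust.to_newick()
        assert nwk.endswith(");")
        for name in clust.distance.index:
            assert name in nwk
        # the newick is parseable by a tree library
        import dendropy
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 4

    def test_identical_samples_zero_distance(self):
        cv1 = CountVector({"a": 10, "b": 5, "c": 1})
        cv2 = CountVector({"x": 10, "y": 5, "z": 1})
        clust = clone_size_jsd({"A": cv1, "B": cv2})
        assert clust.distance.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_samples_and_two_bins(self):
        cv = CountVector({"a": 1})
        with pytest.raises(ValueError):
            clone_size_jsd({"A": cv})
        with pytest.raises(ValueError):
            clone_size_jsd({"A": cv, "B": cv}, n_bins=1)


def test_diversity_table_shape():
    reps = {"A": cv_of([5, 3, 2]), "B": cv_of([1, 1, 2, 3])}
    df = diversity_table(reps)
    assert df.columns.tolist() == ["sample", "richness", "shannon",
                                   "inv_simpson", "chao1", "ace"]
    assert df.set_index("sample").loc["B", "chao1"] == pytest.approx(4.5)
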