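"""Synthetic single-cell V(D)J repertoires with planted ground truth.

The generator emits contig annotation tables in the 10x CSV schema (and the
AIRR TSV rendering of the same cells) together with a truth table mapping
every barcode to its planted clone and clone size, so the whole pipeline
can be exercised and checked for exact recovery without any real data.

What it emulates: heavy-tailed clone-size distributions, paired alpha/beta
chains, dual-alpha T cells, per-locus chain dropout, occasional spurious
extra contigs, realistic CDR3 lengths (8-20 amino acids peaked near 14,
always in frame, starting with the canonical Cys and ending with Phe).
What it does not: real V(D)J recombination (gene segments and junctions are
drawn independently), sequencing errors, or cross-cell barcode collisions.

Dropout, dual-alpha status and CDR3 sequences are properties of the clone,
not of individual cells: all cells of a clone share one chain
configuration, so the planted clone structure is recoverable exactly from
the clonotype keys. Spurious extra contigs are added only to dual-alpha
cells and always with a single UMI, so the top-2-by-UMI retention rule of
chain pairing provably removes them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import contigs as cio

_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple("".join(c) for c in itertools.product("TCAG", repeat=3)
                     if "".join(c) not in _STOPS)
_CYS = ("TGT", "TGC")
_PHE = ("TTT", "TTC")

#: CDR3 amino-acid length support and weights: 8-20 aa, peaked near 14
#: (discretised Gaussian, sd 2) — matches observed repertoire length ranges.
CDR3_AA_LENGTHS = np.arange(8, 21)
_len_w = np.exp(-((CDR3_AA_LENGTHS - 14.0) ** 2) / (2 * 2.0 ** 2))
CDR3_LENGTH_WEIGHTS = _len_w / _len_w.sum()


@dataclass(frozen=True)
class SimSpec:
    """Conditions of one simulated sample.

    Defaults describe a typical 10x T-cell run: a power-law clone-size
    distribution (exponent 2.5), ~10% dual-alpha clones, ~8% per-locus
    chain dropout, and rare (2%) spurious third contigs.
    """

    n_cells: int = 2000
    clone_size_model: str = "power_law"  # power_law | lognormal | uniform
    power_exponent: float = 2.5
    lognormal_mu: float = 1.0
    lognormal_sigma: float = 1.0
    uniform_max: int = 10
    dual_alpha_rate: float = 0.10
    chain_dropout_rate: float = 0.08
    multi_contig_rate: float = 0.02
    seed: int = 0
    sample_name: str = "S1"

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        for name in ("dual_alpha_rate", "chain_dropout_rate",
                     "multi_contig_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.clone_size_model == "power_law" and self.power_exponent <= 1:
            raise ValueError("power_exponent must be > 1")
        if self.clone_size_model not in ("power_law", "lognormal", "uniform"):
            raise ValueError(
                f"unknown clone_size_model: {self.clone_size_model!r}")


def _draw_clone_sizes(spec: SimSpec, rng: np.random.Generator) -> list[int]:
    sizes: list[int] = []
    total = 0
    while total < spec.n_cells:
        if spec.clone_size_model == "power_law":
            s = int(min(rng.zipf(spec.power_exponent), spec.n_cells))
        elif spec.clone_size_model == "lognormal":
            s = max(int(round(rng.lognormal(spec.lognormal_mu,
                                            spec.lognormal_sigma))), 1)
        else:
            s = int(rng.integers(1, spec.uniform_max + 1))
        sizes.append(s)
        total += s
    excess = total - spec.n_cells
    if excess:
        sizes[-1] -= excess
        if sizes[-1] == 0:
            sizes.pop()
    return sizes


def _random_cdr3_nt(rng: np.random.Generator) -> str:
    n_aa = int(rng.choice(CDR3_AA_LENGTHS, p=CDR3_LENGTH_WEIGHTS))
    middle = rng.choice(len(SENSE_CODONS), size=n_aa - 2)
    codons = [str(rng.choice(_CYS))] + [SENSE_CODONS[i] for i in middle] \
        + [str(rng.choice(_PHE))]
    return "".join(codons)


def _unique_cdr3(rng, used_nt: set, used_aa: set) -> tuple[str, str]:
    while True:
        nt = _random_cdr3_nt(rng)
        aa = str(Seq(nt).translate())
        if nt not in used_nt and aa not in used_aa:
            used_nt.add(nt)
            used_aa.add(aa)
            return nt, aa


def _random_barcode(rng, used: set) -> str:
    while True:
        bc = "".join(rng.choice(list("ACGT"), size=16)) + "-1"
        if bc not in used:
            used.add(bc)
            return bc


def _tra_genes(rng) -> str:
    return f"TRAV{rng.integers(1, 21)}.TRAJ{rng.integers(1, 31)}.TRAC"


def _trb_genes(rng) -> str:
    return (f"TRBV{rng.integers(1, 21)}.TRBD{rng.integers(1, 3)}"
            f".TRBJ{rng.integers(1, 13)}.TRBC{rng.integers(1, 3)}")


def simulate_repertoire(spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one sample: a contig table plus its planted truth.

    Returns ``(contigs, truth)`` where ``contigs`` follows the internal
    contig schema (write it with :func:`clonokit.contigs.write_contigs` in
    either dialect) and ``truth`` has one row per cell: barcode, clone_id,
    clone_size, and the expected CTaa / CTnt clonotype strings. Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _draw_clone_sizes(spec, rng)

    used_nt: set[str] = set()
    used_aa: set[str] = set()
    clones = []
    for i, size in enumerate(sizes):
        has_tra = rng.random() >= spec.chain_dropout_rate
        has_trb = rng.random() >= spec.chain_dropout_rate
        if not (has_tra or has_trb):
            has_trb = True
        alphas = []
        if has_tra:
            n_alpha = 2 if rng.random() < spec.dual_alpha_rate else 1
            for _ in range(n_alpha):
                nt, aa = _unique_cdr3(rng, used_nt, used_aa)
                alphas.append({"nt": nt, "aa": aa, "genes": _tra_genes(rng)})
            # chain pairing joins same-locus duplicates in lexicographic
            # CDR3-nt order; mirror that here so truth keys match
            alphas.sort(key=lambda c: (c["nt"], c["aa"], c["genes"]))
        beta = None
        if has_trb:
            nt, aa = _unique_cdr3(rng, used_nt, used_aa)
            beta = {"nt": nt, "aa": aa, "genes": _trb_genes(rng)}
        aa1 = ";".join(c["aa"] for c in alphas) if alphas else "NA"
        nt1 = ";".join(c["nt"] for c in alphas) if alphas else "NA"
        aa2 = beta["aa"] if beta else "NA"
        nt2 = beta["nt"] if beta else "NA"
        clones.append({
            "clone_id": f"clone{i:05d}", "size": size,
            "alphas": alphas, "beta": beta,
            "CTaa": f"{aa1}_{aa2}", "CTnt": f"{nt1}_{nt2}",
        })

    used_bc: set[str] = set()
    contig_rows = []
    truth_rows = []
    for clone in clones:
        for _ in range(clone["size"]):
            barcode = _random_barcode(rng, used_bc)
            truth_rows.append({
                "barcode": barcode,
                "clone_id": clone["clone_id"],
                "clone_size": clone["size"],
                "CTaa": clone["CTaa"],
                "CTnt": clone["CTnt"],
            })
            k = 0

            def emit(chain, genes, nt, aa, umis, reads):
                nonlocal k
                k += 1
                segs = genes.split(".")
                v_gene = segs[0]
                d_gene = segs[1] if len(segs) == 4 else pd.NA
                j_gene = segs[-2]
                c_gene = segs[-1]
                contig_rows.append({
                    "barcode": barcode,
                    "contig_id": f"{barcode}_contig_{k}",
                    "chain": chain,
                    "v_gene": v_gene, "d_gene": d_gene,
                    "j_gene": j_gene, "c_gene": c_gene,
                    "cdr3_aa": aa, "cdr3_nt": nt,
                    "reads": reads, "umis": umis,
                    "is_cell": True, "high_confidence": True,
                    "productive": True, "full_length": True,
                })

            for alpha in clone["alphas"]:
                umis = int(rng.integers(2, 61))
                emit("TRA", alpha["genes"], alpha["nt"], alpha["aa"],
                     umis, umis * int(rng.integers(10, 100)))
            if clone["beta"]:
                umis = int(rng.integers(2, 61))
                emit("TRB", clone["beta"]["genes"], clone["beta"]["nt"],
                     clone["beta"]["aa"], umis,
                     umis * int(rng.integers(10, 100)))
            if len(clone["alphas"]) == 2 and rng.random() < spec.multi_contig_rate:
                # spurious third alpha at UMI 1: trimmed by top-2 retention
                nt = _random_cdr3_nt(rng)
                emit("TRA", _tra_genes(rng), nt, str(Seq(nt).translate()),
                     1, 5)

    contig_df = pd.DataFrame(contig_rows, columns=cio.CONTIG_COLUMNS)
    truth_df = pd.DataFrame(truth_rows, columns=["barcode", "clone_id",
                                                 "clone_size", "CTaa",
                                                 "CTnt"])
    return contig_df, truth_df


def simulate_metadata(truth: pd.DataFrame, sample_name: str,
                      n_clusters: int = 8, seed: int = 0,
                      group: str | None = None) -> pd.DataFrame:
    """Synthetic per-cell metadata matching a simulated sample.

    Random cluster labels plus a 2-D Gaussian-mixture embedding (one
    component per cluster). Barcodes carry the same prefix that chain
    pairing applies, so the table joins directly onto the pipeline output.
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    centers = rng.normal(0.0, 5.0, size=(n_clusters, 2))
    assignment = rng.integers(0, n_clusters, size=n)
    coords = centers[assignment] + rng.normal(0.0, 0.7, size=(n, 2))
    prefix = (f"{sample_name}_" if group is None
              else f"{sample_name}_{group}_")
    return pd.DataFrame({
        "barcode": prefix + truth["barcode"],
        "sample": sample_name,
        "cluster": [f"C{i}" for i in assignment],
        "dim1": coords[:, 0],
        "dim2": coords[:, 1],
    })


def write_sample(spec: SimSpec, outdir, n_clusters: int = 8,
                 group: str | None = None) -> dict[str, Path]:
    """Simulate one sample and write its files.

    Emits the contig table in both dialects plus the truth table and a
    synthetic metadata table; returns the paths keyed by kind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contig_df, truth_df = simulate_repertoire(spec)
    meta = simulate_metadata(truth_df, spec.sample_name,
                             n_clusters=n_clusters, seed=spec.seed + 1,
                             group=group)
    paths = {
        "tenx_csv": outdir / f"{spec.sample_name}.filtered_contig_annotations.csv",
        "airr_tsv": outdir / f"{spec.sample_name}.airr.tsv",
        "truth": outdir / f"{spec.sample_name}.truth.tsv",
        "metadata": outdir / f"{spec.sample_name}.metadata.tsv",
    }
    cio.write_contigs(contig_df, paths["tenx_csv"], dialect="tenx_csv")
    cio.write_contigs(contig_df, paths["airr_tsv"], dialect="airr_tsv")
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    return paths
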