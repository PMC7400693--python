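"""Pair receptor chains per cell barcode and build clonotype identifiers.

Each cell barcode in a filtered contig table becomes one record carrying
four alternative clonotype keys of increasing stringency:

* ``CTgene``   — V(D)JC gene segments of both loci,
* ``CTnt``     — CDR3 nucleotide sequences of both loci,
* ``CTaa``     — CDR3 amino-acid sequences of both loci,
* ``CTstrict`` — gene string and nucleotide sequence combined per locus.

A missing locus is encoded as the literal ``"NA"`` inside the key
(e.g. a beta-only T cell has ``CTaa == "NA_CATSATLRVVAEKLFF"``). The two
loci are joined by ``"_"``; multiple retained chains of one locus (dual
alpha) are joined by ``";"``; gene segments within a chain by ``"."``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .counts import CountVector

NA = "NA"

#: locus-1 / locus-2 assignment per receptor mode
LOCUS_SLOTS = {
    "TCR": ({"TRA", "TRG"}, {"TRB", "TRD"}),
    "BCR": ({"IGH"}, {"IGK", "IGL"}),
}

#: clonotype key name -> column of the cell table
CALL_COLUMNS = {"gene": "CTgene", "nt": "CTnt", "aa": "CTaa",
                "strict": "CTstrict"}

#: fixed column order of per-sample clonotype tables (on disk and in memory)
CELL_COLUMNS = [
    "barcode", "sample", "group",
    "chain1_genes", "cdr3_nt1", "cdr3_aa1",
    "chain2_genes", "cdr3_nt2", "cdr3_aa2",
    "CTgene", "CTnt", "CTaa", "CTstrict",
]


@dataclass
class RepertoireSet:
    """Named collection of per-sample clonotype tables.

    ``samples`` maps sample name -> cell table (columns :data:`CELL_COLUMNS`);
    ``sample_labels`` maps sample name -> (sample, group) annotation.
    Barcodes are globally unique because they are sample-prefixed.
    """

    samples: dict[str, pd.DataFrame] = field(default_factory=dict)
    sample_labels: dict[str, tuple[str, Optional[str]]] = field(
        default_factory=dict)

    def __len__(self):
        return len(self.samples)

    def cells(self) -> pd.DataFrame:
        """All cells of all samples as one table."""
        if not self.samples:
            return pd.DataFrame(columns=CELL_COLUMNS)
        return pd.concat(self.samples.values(), ignore_index=True)

    def n_cells(self) -> int:
        return sum(len(df) for df in self.samples.values())

    def save(self, outdir) -> None:
        """Write one TSV per sample plus a manifest TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for name, df in self.samples.items():
            fn = f"{name}.clonotypes.tsv"
            df[CELL_COLUMNS].to_csv(outdir / fn, sep="\t", index=False,
                                    na_rep=NA)
            sample, group = self.sample_labels[name]
            manifest.append({"sample": name, "group": "" if group is None
                             else group, "file": fn})
        pd.DataFrame(manifest).to_csv(outdir / "repertoire_manifest.tsv",
                                      sep="\t", index=False)

    @classmethod
    def load(cls, indir) -> "RepertoireSet":
        indir = Path(indir)
        manifest = pd.read_csv(indir / "repertoire_manifest.tsv", sep="\t",
                               dtype=str, keep_default_na=False)
        rep = cls()
        for _, row in manifest.iterrows():
            df = pd.read_csv(indir / row["file"], sep="\t", dtype=str,
                             keep_default_na=False)
            df = df.replace({NA: pd.NA})
            group = row["group"] or None
            df["group"] = group
            rep.samples[row["sample"]] = df[CELL_COLUMNS]
            rep.sample_labels[row["sample"]] = (row["sample"], group)
        return rep


def _gene_string(row: pd.Series) -> object:
    parts = [row[c] for c in ("v_gene", "d_gene", "j_gene", "c_gene")
             if pd.notna(row[c])]
    return ".".join(parts) if parts else pd.NA


def _join_locus(contigs: pd.DataFrame):
    """Collapse the retained contigs of one locus into per-field strings.

    Contigs are ordered lexicographically by (CDR3-nt, CDR3-aa, gene string)
    so that cells carrying the same chain set always yield the same strings
    regardless of per-cell UMI noise.
    """
    if contigs.empty:
        return pd.NA, pd.NA, pd.NA, NA
    genes = contigs.apply(_gene_string, axis=1)
    order = sorted(
        range(len(contigs)),
        key=lambda i: (
            str(contigs["cdr3_nt"].iloc[i]) if pd.notna(contigs["cdr3_nt"].iloc[i]) else "~",
            str(contigs["cdr3_aa"].iloc[i]) if pd.notna(contigs["cdr3_aa"].iloc[i]) else "~",
            str(genes.iloc[i]) if pd.notna(genes.iloc[i]) else "~",
        ),
    )

    def joined(series):
        vals = [series.iloc[i] for i in order]
        if all(pd.isna(v) for v in vals):
            return pd.NA
        return ";".join(NA if pd.isna(v) else str(v) for v in vals)

    gene_s = joined(genes)
    nt_s = joined(contigs["cdr3_nt"])
    aa_s = joined(contigs["cdr3_aa"])
    strict_parts = []
    for i in order:
        g = genes.iloc[i]
        n = contigs["cdr3_nt"].iloc[i]
        strict_parts.append(
            f"{NA if pd.isna(g) else g}:{NA if pd.isna(n) else n}")
    return gene_s, nt_s, aa_s, ";".join(strict_parts)


def _ct(a, b) -> str:
    return f"{NA if pd.isna(a) else a}_{NA if pd.isna(b) else b}"


def combine_receptors(
    contigs_per_sample: Sequence[pd.DataFrame],
    sample_names: Sequence[str],
    group_names: Optional[Sequence[str]] = None,
    mode: str = "TCR",
    remove_na: bool = False,
    remove_multi: bool = False,
) -> RepertoireSet:
    """Merge contigs by cell barcode into per-sample clonotype tables.

    Parameters
    ----------
    contigs_per_sample
        Filtered contig tables (see :func:`clonokit.contigs.filter_contigs`),
        one per sample, in the same order as ``sample_names``.
    sample_names
        Distinct sample identifiers; used to prefix barcodes.
    group_names
        Optional per-sample group labels (e.g. tissue of origin), appended
        to the barcode prefix.
    mode
        ``"TCR"`` (locus 1 = TRA/TRG, locus 2 = TRB/TRD) or ``"BCR"``
        (locus 1 = IGH, locus 2 = IGK/IGL).
    remove_na
        Drop cells missing either locus.
    remove_multi
        Drop cells with more than two contigs of one locus instead of
        keeping the top two by UMI count (ties: reads, then contig_id).
    """
    if mode not in LOCUS_SLOTS:
        raise ValueError(f"unknown mode: {mode!r}")
    if len(contigs_per_sample) != len(sample_names):
        raise ValueError("contigs_per_sample and sample_names differ in length")
    if len(set(sample_names)) != len(sample_names):
        raise ValueError("duplicate sample names")
    if group_names is not None and len(group_names) != len(sample_names):
        raise ValueError("group_names and sample_names differ in length")

    locus1, locus2 = LOCUS_SLOTS[mode]
    rep = RepertoireSet()
    for idx, (contigs, sample) in enumerate(zip(contigs_per_sample,
                                                sample_names)):
        group = group_names[idx] if group_names is not None else None
        prefix = f"{sample}_" if group is None else f"{sample}_{group}_"
        if len(contigs) and contigs["barcode"].str.contains("_").any():
            warnings.warn(
                f"sample {sample!r}: some barcodes already contain the "
                "prefix separator '_'; prefixed barcodes may be ambiguous "
                "to split", stacklevel=2)

        rows = []
        relevant = contigs[contigs["chain"].isin(locus1 | locus2)]
        for barcode, cell in relevant.groupby("barcode", sort=True):
            drop = False
            per_locus = []
            for locus in (locus1, locus2):
                sub = cell[cell["chain"].isin(locus)]
                if len(sub) > 2:
                    if remove_multi:
                        drop = True
                        break
                    sub = sub.sort_values(
                        ["umis", "reads", "contig_id"],
                        ascending=[False, False, True],
                        kind="mergesort").head(2)
                per_locus.append(sub)
            if drop:
                continue
            g1, nt1, aa1, strict1 = _join_locus(per_locus[0])
            g2, nt2, aa2, strict2 = _join_locus(per_locus[1])
            if remove_na and (per_locus[0].empty or per_locus[1].empty):
                continue
            rows.append({
                "barcode": prefix + str(barcode),
                "sample": sample,
                "group": group,
                "chain1_genes": g1, "cdr3_nt1": nt1, "cdr3_aa1": aa1,
                "chain2_genes": g2, "cdr3_nt2": nt2, "cdr3_aa2": aa2,
                "CTgene": _ct(g1, g2),
                "CTnt": _ct(nt1, nt2),
                "CTaa": _ct(aa1, aa2),
                "CTstrict": f"{strict1}_{strict2}",
            })
        df = pd.DataFrame(rows, columns=CELL_COLUMNS)
        rep.samples[sample] = df
        rep.sample_labels[sample] = (sample, group)
    return rep


def clonotype_key(cell, call_by: str = "aa") -> str:
    """Return the clonotype identifier of one cell at the chosen resolution.

    ``call_by`` is one of ``gene``, ``nt``, ``aa``, ``strict``.
    """
    if call_by not in CALL_COLUMNS:
        raise ValueError(f"call_by must be one of {sorted(CALL_COLUMNS)}")
    return cell[CALL_COLUMNS[call_by]]


def count_clonotypes(rep: RepertoireSet, call_by: str = "aa",
                     scope: str = "per_sample") -> dict[str, CountVector]:
    """Tally clonotypes into one :class:`CountVector` per scope unit.

    ``scope="per_sample"`` returns one vector per sample;
    ``scope="per_group"`` pools samples sharing a group label (samples with
    no group label form their own unit named after the sample).
    """
    if not rep.samples:
        raise ValueError("empty RepertoireSet")
    col = CALL_COLUMNS.get(call_by)
    if col is None:
        raise ValueError(f"call_by must be one of {sorted(CALL_COLUMNS)}")
    if scope == "per_sample":
        units = {name: [name] for name in rep.samples}
    elif scope == "per_group":
        units = {}
        for name, (_, group) in rep.sample_labels.items():
            units.setdefault(group if group is not None else name,
                             []).append(name)
    else:
        raise ValueError(f"unknown scope: {scope!r}")
    out = {}
    for unit, members in units.items():
        keys = pd.concat([rep.samples[m][col] for m in members])
        out[unit] = CountVector.from_keys(keys)
    return out
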