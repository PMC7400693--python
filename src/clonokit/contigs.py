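"""Reading, writing and filtering of V(D)J contig annotation tables.

Two on-disk dialects are supported, selected explicitly (never sniffed):

* ``tenx_csv`` — the 10x Genomics Cell Ranger ``filtered_contig_annotations.csv``
  schema (comma-separated, ``barcode``/``chain``/``cdr3``/``cdr3_nt`` columns,
  tri-state booleans printed as ``True``/``False``/``None``).
* ``airr_tsv`` — the AIRR Rearrangement schema rendered as a tab-separated
  table (``cell_id``/``locus``/``junction``/``junction_aa``/``duplicate_count``).

Both are normalised into one internal table of contig records with a fixed
column set; downstream code never sees dialect differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

#: Recognised immune-receptor loci. Anything else parses to "None".
CHAINS = ("TRA", "TRB", "TRG", "TRD", "IGH", "IGK", "IGL")
#: Special chain values Cell Ranger emits for ambiguous / unassigned contigs.
CHAIN_MULTI = "Multi"
CHAIN_NONE = "None"

#: Canonical column order of the internal contig table.
CONTIG_COLUMNS = [
    "barcode",
    "contig_id",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "cdr3_aa",
    "cdr3_nt",
    "reads",
    "umis",
    "is_cell",
    "high_confidence",
    "productive",
    "full_length",
]

TENX_REQUIRED = [
    "barcode", "chain", "v_gene", "j_gene", "c_gene",
    "cdr3", "cdr3_nt", "reads", "umis", "productive",
]
AIRR_REQUIRED = [
    "cell_id", "locus", "v_call", "j_call",
    "junction", "junction_aa", "duplicate_count",
]

#: Column order used when writing the tenx_csv dialect (bit-exact on round trip).
TENX_WRITE_COLUMNS = [
    "barcode", "is_cell", "contig_id", "high_confidence", "chain",
    "v_gene", "d_gene", "j_gene", "c_gene", "full_length", "productive",
    "cdr3", "cdr3_nt", "reads", "umis",
]
AIRR_WRITE_COLUMNS = [
    "cell_id", "sequence_id", "locus", "v_call", "d_call", "j_call", "c_call",
    "junction", "junction_aa", "duplicate_count", "consensus_count",
    "productive", "complete_vdj",
]

_MISSING_TOKENS = {"", "none", "na", "nan", "null"}
_TRUE_TOKENS = {"true", "t", "1", "yes"}


class SchemaError(ValueError):
    """A mandatory column is absent from an input file."""


def _parse_bool(value, default: bool = False) -> bool:
    """Case-insensitive tri-state boolean: true-ish -> True, everything else
    (including Cell Ranger's literal "None") -> False. Missing -> ``default``."""
    if pd.isna(value):
        return default
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in _TRUE_TOKENS


def _parse_str(value):
    """Normalise the many on-disk encodings of 'missing' to pd.NA."""
    if pd.isna(value):
        return pd.NA
    s = str(value).strip()
    return pd.NA if s.lower() in _MISSING_TOKENS else s


def _parse_chain(value) -> str:
    s = _parse_str(value)
    if s is pd.NA:
        return CHAIN_NONE
    if s in CHAINS or s == CHAIN_MULTI:
        return s
    return CHAIN_NONE


def _parse_int(value) -> int:
    if pd.isna(value):
        return 0
    try:
        return max(int(float(value)), 0)
    except (TypeError, ValueError):
        return 0


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )


def _empty_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in CONTIG_COLUMNS})
    for c in ("reads", "umis"):
        df[c] = df[c].astype("int64")
    for c in ("is_cell", "high_confidence", "productive", "full_length"):
        df[c] = df[c].astype(bool)
    return df


def read_contigs(path, dialect: str = "tenx_csv") -> pd.DataFrame:
    """Read a contig annotation file into the internal contig table.

    Parameters
    ----------
    path
        CSV (tenx_csv) or TSV (airr_tsv) file with a header row.
    dialect
        ``"tenx_csv"`` or ``"airr_tsv"``. Never sniffed from content.

    Returns
    -------
    pandas.DataFrame with :data:`CONTIG_COLUMNS`, one row per input contig.
    An empty file (header only, or zero bytes) yields an empty table.
    """
    path = Path(path)
    if dialect == "tenx_csv":
        sep, required = ",", TENX_REQUIRED
    elif dialect == "airr_tsv":
        sep, required = "\t", AIRR_REQUIRED
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                          na_values=[])
    except pd.errors.EmptyDataError:
        return _empty_table()
    if raw.empty and len(raw.columns) == 0:
        return _empty_table()
    _require_columns(raw, required, path)
    if raw.empty:
        return _empty_table()

    def col(name):
        return raw[name] if name in raw.columns else pd.Series(
            [pd.NA] * len(raw), index=raw.index)

    if dialect == "tenx_csv":
        out = pd.DataFrame({
            "barcode": col("barcode").map(_parse_str),
            "contig_id": col("contig_id").map(_parse_str),
            "chain": col("chain").map(_parse_chain),
            "v_gene": col("v_gene").map(_parse_str),
            "d_gene": col("d_gene").map(_parse_str),
            "j_gene": col("j_gene").map(_parse_str),
            "c_gene": col("c_gene").map(_parse_str),
            "cdr3_aa": col("cdr3").map(_parse_str),
            "cdr3_nt": col("cdr3_nt").map(_parse_str),
            "reads": col("reads").map(_parse_int),
            "umis": col("umis").map(_parse_int),
            "is_cell": col("is_cell").map(lambda v: _parse_bool(v, default=True)),
            "high_confidence": col("high_confidence").map(
                lambda v: _parse_bool(v, default=True)),
            "productive": col("productive").map(_parse_bool),
            "full_length": col("full_length").map(
                lambda v: _parse_bool(v, default=True)),
        })
    else:
        umis = col("duplicate_count").map(_parse_int)
        reads_col = ("consensus_count" if "consensus_count" in raw.columns
                     else "duplicate_count")
        out = pd.DataFrame({
            "barcode": col("cell_id").map(_parse_str),
            "contig_id": col("sequence_id").map(_parse_str),
            "chain": col("locus").map(_parse_chain),
            "v_gene": col("v_call").map(_parse_str),
            "d_gene": col("d_call").map(_parse_str),
            "j_gene": col("j_call").map(_parse_str),
            "c_gene": col("c_call").map(_parse_str),
            "cdr3_aa": col("junction_aa").map(_parse_str),
            "cdr3_nt": col("junction").map(_parse_str),
            "reads": col(reads_col).map(_parse_int),
            "umis": umis,
            # AIRR core schema has no cell-calling / confidence flags; a
            # Rearrangement TSV is assumed to contain called cells.
            "is_cell": col("is_cell").map(lambda v: _parse_bool(v, default=True)),
            "high_confidence": col("high_confidence").map(
                lambda v: _parse_bool(v, default=True)),
            "productive": col("productive").map(
                lambda v: _parse_bool(v, default=True)),
            "full_length": col("complete_vdj").map(
                lambda v: _parse_bool(v, default=True)),
        })
    return out[CONTIG_COLUMNS]


def write_contigs(records: pd.DataFrame, path, dialect: str = "tenx_csv") -> None:
    """Write an internal contig table back to disk in the chosen dialect.

    Round trips: ``read_contigs(write_contigs(read_contigs(f)))`` is
    field-for-field identical to the first parse, for both dialects.
    """
    path = Path(path)
    df = records.copy()

    def enc_str(s, missing="None"):
        return s.map(lambda v: missing if pd.isna(v) else str(v))

    if dialect == "tenx_csv":
        out = pd.DataFrame({
            "barcode": enc_str(df["barcode"]),
            "is_cell": df["is_cell"].map(lambda v: "True" if v else "False"),
            "contig_id": enc_str(df["contig_id"]),
            "high_confidence": df["high_confidence"].map(
                lambda v: "True" if v else "False"),
            "chain": df["chain"],
            "v_gene": enc_str(df["v_gene"]),
            "d_gene": enc_str(df["d_gene"]),
            "j_gene": enc_str(df["j_gene"]),
            "c_gene": enc_str(df["c_gene"]),
            "full_length": df["full_length"].map(
                lambda v: "True" if v else "False"),
            "productive": df["productive"].map(
                lambda v: "True" if v else "False"),
            "cdr3": enc_str(df["cdr3_aa"]),
            "cdr3_nt": enc_str(df["cdr3_nt"]),
            "reads": df["reads"].astype(int),
            "umis": df["umis"].astype(int),
        })[TENX_WRITE_COLUMNS]
        out.to_csv(path, index=False)
    elif dialect == "airr_tsv":
        out = pd.DataFrame({
            "cell_id": enc_str(df["barcode"], missing=""),
            "sequence_id": enc_str(df["contig_id"], missing=""),
            "locus": df["chain"],
            "v_call": enc_str(df["v_gene"], missing=""),
            "d_call": enc_str(df["d_gene"], missing=""),
            "j_call": enc_str(df["j_gene"], missing=""),
            "c_call": enc_str(df["c_gene"], missing=""),
            "junction": enc_str(df["cdr3_nt"], missing=""),
            "junction_aa": enc_str(df["cdr3_aa"], missing=""),
            "duplicate_count": df["umis"].astype(int),
            "consensus_count": df["reads"].astype(int),
            "productive": df["productive"].map(lambda v: "T" if v else "F"),
            "complete_vdj": df["full_length"].map(lambda v: "T" if v else "F"),
        })[AIRR_WRITE_COLUMNS]
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


@dataclass(frozen=True)
class FilterSpec:
    """Predicates applied to a contig table before clonotype calling.

    Defaults mirror the conventional quality gates for 10x V(D)J data: keep
    productive, high-confidence contigs from called cells with at least one
    UMI, restricted to the loci of the receptor under study.
    """

    require_productive: bool = True
    require_high_confidence: bool = True
    require_is_cell: bool = True
    allowed_chains: frozenset = frozenset({"TRA", "TRB"})
    min_umis: int = 1

    def __post_init__(self):
        if not self.allowed_chains:
            raise ValueError("allowed_chains must be non-empty")
        object.__setattr__(self, "allowed_chains",
                           frozenset(self.allowed_chains))

    @classmethod
    def default(cls, mode: str = "TCR") -> "FilterSpec":
        """Default filters for TCR (alpha/beta) or BCR (heavy/light) mode."""
        if mode == "TCR":
            chains = frozenset({"TRA", "TRB"})
        elif mode == "BCR":
            chains = frozenset({"IGH", "IGK", "IGL"})
        else:
            raise ValueError(f"unknown mode: {mode!r}")
        return cls(allowed_chains=chains)


def filter_contigs(records: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Return the rows of ``records`` satisfying every enabled predicate.

    Row order is preserved and the input table is not modified. An empty
    result is legal.
    """
    mask = pd.Series(True, index=records.index)
    if spec.require_productive:
        mask &= records["productive"]
    if spec.require_high_confidence:
        mask &= records["high_confidence"]
    if spec.require_is_cell:
        mask &= records["is_cell"]
    mask &= records["chain"].isin(spec.allowed_chains)
    mask &= records["umis"] >= spec.min_umis
    return records.loc[mask].copy()
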