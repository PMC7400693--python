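import numpy as np
import pandas as pd
import pytest

from clonokit.contigs import CONTIG_COLUMNS


def make_contig(barcode, chain, cdr3_aa=None, cdr3_nt=None, v_gene=None,
                d_gene=None, j_gene=None, c_gene=None, umis=5, reads=100,
                contig_id=None, productive=True, is_cell=True,
                high_confidence=True, full_length=True):
    return {
        "barcode": barcode,
        "contig_id": contig_id or f"{barcode}_contig_{chain}",
        "chain": chain,
        "v_gene": v_gene if v_gene is not None else pd.NA,
        "d_gene": d_gene if d_gene is not None else pd.NA,
        "j_gene": j_gene if j_gene is not None else pd.NA,
        "c_gene": c_gene if c_gene is not None else pd.NA,
        "cdr3_aa": cdr3_aa if cdr3_aa is not None else pd.NA,
        "cdr3_nt": cdr3_nt if cdr3_nt is not None else pd.NA,
        "reads": reads,
        "umis": umis,
        "is_cell": is_cell,
        "high_confidence": high_confidence,
        "productive": productive,
        "full_length": full_length,
    }


def contig_table(rows):
    return pd.DataFrame(rows, columns=CONTIG_COLUMNS)


@pytest.fixture
def paper_cells_contigs():
    """Two cells matching the worked clonotype examples: one fully paired
    alpha/beta cell and one beta-only cell."""
    return contig_table([
        make_contig("cell1", "TRA", cdr3_aa="CAVNGGSQGNLIF",
                    cdr3_nt="TGTGCTGTGAAT", v_gene="TRAV1", j_gene="TRAJ3",
                    c_gene="TRAC"),
        make_contig("cell1", "TRB", cdr3_aa="CSAEREDTDTQYF",
                    cdr3_nt="TGTAGTGCTGAA", v_gene="TRBV2", d_gene="TRBD1",
                    j_gene="TRBJ2", c_gene="TRBC1"),
        make_contig("cell2", "TRB", cdr3_aa="CATSATLRVVAEKLFF",
                    cdr3_nt="TGTGCCACCAGT", v_gene="TRBV5", d_gene="TRBD2",
                    j_gene="TRBJ1", c_gene="TRBC2"),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
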