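"""Shared fixtures: toy contig tables and small chain-set builders."""

import numpy as np
import pandas as pd
import pytest

from eclipse_tcr import io_contigs
from eclipse_tcr.io_contigs import CellChainSet


def make_cell(barcode, alpha=(), beta=(), sample="S1", umis=None):
    """CellChainSet builder; ``umis`` optionally maps cdr3 -> umi count."""
    cell = CellChainSet(barcode, sample, set(alpha), set(beta))
    for chain_type, chains in (("TRA", alpha), ("TRB", beta)):
        for cdr3 in chains:
            cell.chain_meta[(chain_type, cdr3)] = {
                "cdr3_nt": "",
                "v_gene": "",
                "d_gene": "",
                "j_gene": "",
                "c_gene": "",
                "umis": (umis or {}).get(cdr3, 1),
                "reads": 10,
                "contig_id": f"{barcode}_{cdr3}",
            }
    return cell


def contig_row(barcode, chain, cdr3, *, contig_id, umis=5, reads=50, high_confidence=True,
               v_gene="", d_gene="", j_gene="", c_gene="", cdr3_nt=""):
    return {
        "barcode": barcode,
        "is_cell": True,
        "contig_id": contig_id,
        "high_confidence": high_confidence,
        "length": 500,
        "chain": chain,
        "v_gene": v_gene,
        "d_gene": d_gene,
        "j_gene": j_gene,
        "c_gene": c_gene,
        "full_length": True,
        "productive": True,
        "cdr3": cdr3,
        "cdr3_nt": cdr3_nt,
        "reads": reads,
        "umis": umis,
        "raw_clonotype_id": "",
        "raw_consensus_id": "",
    }


@pytest.fixture
def toy_contig_df():
    """12 contigs exercising every chain-level filtering rule."""
    long_cdr3 = "C" + "A" * 29 + "F"  # 31 aa -> dropped
    rows = [
        contig_row("BC1", "TRA", "CAVRF", contig_id="t01"),
        contig_row("BC1", "TRB", "CASSLF", contig_id="t02"),
        contig_row("BC2", "TRA", long_cdr3, contig_id="t03"),
        contig_row("BC2", "TRB", "CASS*LF", contig_id="t04"),
        contig_row("BC3", "Multi", "CALWEVF", contig_id="t05",
                   v_gene="TRDV1", j_gene="TRAJ29", c_gene="TRAC"),
        contig_row("BC3", "TRB", "CASSTF", contig_id="t06"),
        contig_row("BC4", "TRA", "CAVRF", contig_id="t07", umis=3),
        contig_row("BC4", "TRA", "CAVRF", contig_id="t08", umis=7, cdr3_nt="TGTGCC"),
        contig_row("BC4", "TRB", "CASSLF", contig_id="t09", high_confidence=False),
        contig_row("BC5", "TRG", "CATWDF", contig_id="t10"),
        contig_row("BCX", "TRA", "CAVSF", contig_id="t11"),  # not whitelisted
        contig_row("BC5", "TRA", "", contig_id="t12"),
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def toy_whitelist():
    return {"BC1", "BC2", "BC3", "BC4", "BC5"}


@pytest.fixture
def toy_table(toy_contig_df):
    return io_contigs.from_dataframe(toy_contig_df, dialect="all_contig", sample="S1")


@pytest.fixture
def fixed_point_cells():
    """3 cells (α1,β1), 1 cell (α2,β1), 1 β1-only cell."""
    cells = [make_cell(f"c{i}", alpha={"CAAAF"}, beta={"CBBBF"}) for i in range(3)]
    cells.append(make_cell("c3", alpha={"CACCF"}, beta={"CBBBF"}))
    cells.append(make_cell("c4", beta={"CBBBF"}))
    return cells


def random_compat_instance(rng, max_cells=6, max_clonotypes=4):
    """Random small candidate-set structure for EM property tests."""
    from eclipse_tcr.em_core import CompatibilityRecord

    k = int(rng.integers(2, max_clonotypes + 1))
    n = int(rng.integers(2, max_cells + 1))
    records = []
    for i in range(n):
        size = int(rng.integers(1, k + 1))
        cands = tuple(sorted(rng.choice(k, size=size, replace=False).tolist()))
        records.append(
            CompatibilityRecord(f"c{i}", cands, ambiguous=len(cands) != 1, terminal=False)
        )
    return records, k
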