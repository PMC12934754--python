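"""Reading, validation and filtering of Cell Ranger VDJ contig annotation tables.

Chains are identified by their CDR3 amino-acid sequence throughout the
package; nucleotide CDR3 and gene segments are carried as metadata only.
Two input dialects are supported: ``all_contig`` (the full table, including
non-cell barcodes and low-confidence contigs) and ``filtered_contig``
(pre-filtered upstream, so the high-confidence test is skipped by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

DIALECTS = ("all_contig", "filtered_contig")

#: columns that must be present in the input CSV (Cell Ranger names)
MANDATORY_COLUMNS = ("barcode", "chain", "cdr3", "high_confidence")

#: optional Cell Ranger columns and the sentinel used when absent
OPTIONAL_COLUMNS: Mapping[str, object] = {
    "contig_id": "",
    "cdr3_nt": "",
    "v_gene": "",
    "d_gene": "",
    "j_gene": "",
    "c_gene": "",
    "umis": 0,
    "reads": 0,
    "productive": True,
    "full_length": True,
    "is_cell": True,
    "length": 0,
    "raw_clonotype_id": "",
    "raw_consensus_id": "",
}

#: canonical column order used internally (cdr3 is renamed to cdr3_aa)
CANONICAL_COLUMNS = (
    "barcode",
    "sample",
    "chain",
    "cdr3_aa",
    "cdr3_nt",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "umis",
    "reads",
    "high_confidence",
    "productive",
    "full_length",
    "contig_id",
)

MAX_CDR3_AA_LENGTH = 30


class ContigFormatError(ValueError):
    """Raised when an input table violates the expected CSV layout."""


def _as_bool(series: pd.Series) -> pd.Series:
    """Cell Ranger writes booleans as 'true'/'false' (v≥4) or 'True'/'False'."""
    if series.dtype == bool:
        return series
    return (
        series.astype(str).str.strip().str.lower().map({"true": True, "false": False}).fillna(False).astype(bool)
    )


@dataclass
class ContigTable:
    """One assembled TCR chain observation per row, in canonical columns."""

    df: pd.DataFrame
    dialect: str = "all_contig"

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}; expected one of {DIALECTS}")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "ContigTable":
        return ContigTable(self.df.copy(), self.dialect)


@dataclass
class CellChainSet:
    """Per-barcode deduplicated TRA/TRB chain identities plus carried metadata.

    ``chain_meta`` maps ``(chain_type, cdr3_aa)`` to a dict with the winning
    contig's cdr3_nt, gene segments, umis and reads.
    """

    barcode: str
    sample: str
    alpha: set = field(default_factory=set)
    beta: set = field(default_factory=set)
    chain_meta: dict = field(default_factory=dict)

    def chains(self) -> set:
        """All observed chains as ``(chain_type, cdr3_aa)`` tuples."""
        return {("TRA", a) for a in self.alpha} | {("TRB", b) for b in self.beta}

    @property
    def n_chains(self) -> int:
        return len(self.alpha) + len(self.beta)

    def copy(self) -> "CellChainSet":
        return CellChainSet(
            self.barcode, self.sample, set(self.alpha), set(self.beta), dict(self.chain_meta)
        )


def from_dataframe(raw: pd.DataFrame, dialect: str = "all_contig", sample: str = "") -> ContigTable:
    """Canonicalize a Cell Ranger-style contig annotation DataFrame.

    Unknown extra columns are ignored; missing optional columns are filled
    with sentinel empty values. Raises :class:`ContigFormatError` if a
    mandatory column is absent or contig ids are duplicated.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ContigFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    df = raw.copy()
    for col, sentinel in OPTIONAL_COLUMNS.items():
        if col not in df.columns:
            df[col] = sentinel
    df = df.rename(columns={"cdr3": "cdr3_aa"})
    for col in ("high_confidence", "productive", "full_length"):
        df[col] = _as_bool(df[col])
    for col in ("umis", "reads"):
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
    if (df["umis"] < 0).any() or (df["reads"] < 0).any():
        raise ContigFormatError("negative umis/reads count")
    for col in ("barcode", "chain", "cdr3_aa", "cdr3_nt", "v_gene", "d_gene", "j_gene", "c_gene", "contig_id"):
        df[col] = df[col].fillna("").astype(str)
        df.loc[df[col].isin(("nan", "None")), col] = ""
    nonempty_ids = df.loc[df["contig_id"] != "", "contig_id"]
    if nonempty_ids.duplicated().any():
        dup = nonempty_ids[nonempty_ids.duplicated()].iloc[0]
        raise ContigFormatError(f"duplicate contig_id in input: {dup!r}")
    df["sample"] = sample
    df = df[list(CANONICAL_COLUMNS)].reset_index(drop=True)
    return ContigTable(df, dialect)


def read_contigs(path, dialect: str = "all_contig", sample: str = "") -> ContigTable:
    """Read a Cell Ranger ``*_contig_annotations.csv`` file.

    Row order is preserved; extra columns are tolerated and dropped.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        raw = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except OSError as exc:  # pragma: no cover - unusual I/O failures
        raise OSError(f"cannot read contig file {path}: {exc}") from exc
    return from_dataframe(raw, dialect=dialect, sample=sample)


def read_airr(path):  # pragma: no cover - stub by design
    """AIRR rearrangement TSV ingestion is not supported."""
    raise NotImplementedError("AIRR rearrangement TSV input is unsupported; provide a Cell Ranger contig CSV")


def reannotate_trdv(contig: pd.Series) -> pd.Series:
    """Relabel a TRDV–TRAJ–TRAC contig as a TCRα chain.

    Some TRDV segments (notably human TRDV1) recombine with TRAJ/TRAC to form
    productive α chains that Cell Ranger labels TRD or Multi; the chain type
    is corrected to TRA when all three segment prefixes match. Only the
    ``chain`` field is ever modified.
    """
    if (
        str(contig["v_gene"]).startswith("TRDV")
        and str(contig["j_gene"]).startswith("TRAJ")
        and str(contig["c_gene"]).startswith("TRAC")
    ):
        contig = contig.copy()
        contig["chain"] = "TRA"
    return contig


def _reannotate_frame(df: pd.DataFrame) -> pd.DataFrame:
    mask = (
        df["v_gene"].str.startswith("TRDV")
        & df["j_gene"].str.startswith("TRAJ")
        & df["c_gene"].str.startswith("TRAC")
    )
    if mask.any():
        df = df.copy()
        df.loc[mask, "chain"] = "TRA"
    return df


def filter_contigs(
    table: ContigTable,
    barcode_whitelist: Iterable[str] | None,
    sample: str = "",
    *,
    require_high_confidence: bool | None = None,
    allow_all_barcodes: bool = False,
) -> ContigTable:
    """Apply the chain-level quality filters and per-cell deduplication.

    Retained contigs are high-confidence (for the ``all_contig`` dialect,
    unless overridden), whitelisted, carry a non-empty CDR3 of ≤ 30 amino
    acids with no internal stop codon (``*``), and are TRA/TRB after
    TRDV reannotation. Duplicates of (barcode, chain, cdr3_aa) keep the copy
    with the most UMIs (ties: reads, then lexicographic contig_id).
    Idempotent: filtering a filtered table is the identity.
    """
    if not allow_all_barcodes:
        whitelist = set(barcode_whitelist or ())
        if not whitelist:
            raise ValueError("barcode whitelist is empty; pass allow_all_barcodes=True to accept all barcodes")
    df = _reannotate_frame(table.df)
    n_in = len(df)
    cdr3 = df["cdr3_aa"].str.upper()
    keep = (
        (cdr3 != "")
        & (cdr3.str.len() <= MAX_CDR3_AA_LENGTH)
        & ~cdr3.str.contains(r"\*", regex=True)
        & df["chain"].isin(("TRA", "TRB"))
    )
    n_chain_dropped = int((~df["chain"].isin(("TRA", "TRB"))).sum())
    if require_high_confidence is None:
        require_high_confidence = table.dialect == "all_contig"
    if require_high_confidence:
        keep &= df["high_confidence"]
    if not allow_all_barcodes:
        keep &= df["barcode"].isin(whitelist)
    df = df.loc[keep].copy()
    df["cdr3_aa"] = df["cdr3_aa"].str.upper()
    if sample:
        df["sample"] = sample
    # dedup: winner by umis desc, reads desc, contig_id asc; stable row order
    order = df.sort_values(
        ["umis", "reads", "contig_id"], ascending=[False, False, True], kind="mergesort"
    )
    winners = order.drop_duplicates(subset=["barcode", "chain", "cdr3_aa"], keep="first")
    df = winners.sort_index().reset_index(drop=True)
    logger.info(
        "filter_contigs: %d -> %d contigs (%d non-TRA/TRB dropped)", n_in, len(df), n_chain_dropped
    )
    return ContigTable(df, table.dialect)


def collapse_to_cells(table: ContigTable) -> list[CellChainSet]:
    """Collapse a filtered contig table into one :class:`CellChainSet` per barcode.

    Assumes :func:`filter_contigs` has already deduplicated rows; barcodes
    with no surviving contig are simply absent.
    """
    cells: dict[str, CellChainSet] = {}
    for row in table.df.itertuples(index=False):
        cell = cells.get(row.barcode)
        if cell is None:
            cell = cells[row.barcode] = CellChainSet(row.barcode, row.sample)
        if row.chain == "TRA":
            cell.alpha.add(row.cdr3_aa)
        elif row.chain == "TRB":
            cell.beta.add(row.cdr3_aa)
        else:  # pragma: no cover - filtered upstream
            continue
        cell.chain_meta[(row.chain, row.cdr3_aa)] = {
            "cdr3_nt": row.cdr3_nt,
            "v_gene": row.v_gene,
            "d_gene": row.d_gene,
            "j_gene": row.j_gene,
            "c_gene": row.c_gene,
            "umis": int(row.umis),
            "reads": int(row.reads),
            "contig_id": row.contig_id,
        }
    return [cells[b] for b in sorted(cells)]


def write_chain_table(cells: Iterable[CellChainSet], path) -> None:
    """Write the canonical long-form chain table as TSV."""
    rows = []
    for cell in cells:
        for chain_type, cdr3 in sorted(cell.chains()):
            meta = cell.chain_meta.get((chain_type, cdr3), {})
            rows.append(
                {
                    "barcode": cell.barcode,
                    "sample": cell.sample,
                    "chain": chain_type,
                    "cdr3_aa": cdr3,
                    "cdr3_nt": meta.get("cdr3_nt", ""),
                    "v_gene": meta.get("v_gene", ""),
                    "d_gene": meta.get("d_gene", ""),
                    "j_gene": meta.get("j_gene", ""),
                    "c_gene": meta.get("c_gene", ""),
                    "umis": meta.get("umis", 0),
                    "reads": meta.get("reads", 0),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
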