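"""Decision layer: convert EM posteriors into final per-cell clonotype calls.

A cell is fully assigned to the top clonotype C1 only when the posterior
is confident enough — p1 ≥ 0.8, or p1 ≥ 0.7 with p1/p2 > 5, or p1 > 0.5
with p1/p2 > 10 — and its evidence is not a single contig seen in no other
cell. Unassigned cells keep their observed chains as the final label.
Cells carrying two of a detected 3-chain clone's chains (one bitypic + the
monotypic) are joined to the full clone, mitigating chain dropout.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import em_core, io_contigs, special_clones
from .em_core import Clonotype, clonotype_label
from .io_contigs import CellChainSet, ContigTable
from .special_clones import SpecialClone

logger = logging.getLogger(__name__)

RULES = ("P80", "P70R5", "P50R10", "none")

#: canonical human semi-invariant TRA segment combinations
MAIT_SEGMENTS = {("TRAV1-2", "TRAJ33"), ("TRAV1-2", "TRAJ20"), ("TRAV1-2", "TRAJ12")}
INKT_SEGMENTS = {("TRAV10", "TRAJ18")}


@dataclass
class EclipseConfig:
    """Tunables for the full pipeline (thresholds per the assignment rules)."""

    epsilon: float = em_core.DEFAULT_EPSILON
    max_iter: int = em_core.DEFAULT_MAX_ITER
    p1_hi: float = 0.8
    p1_mid: float = 0.7
    r_mid: float = 5.0
    p1_lo: float = 0.5
    r_lo: float = 10.0
    detect_special: bool = True
    dialect: str = "all_contig"
    require_high_confidence: bool | None = None
    doublet_filter: bool = False
    doublet_max_total: int = 4
    doublet_max_per_type: int = 2
    doublet_min_umis: int | None = None
    size_bin_cuts: tuple = (1e-4, 1e-3, 1e-2, 1e-1)


@dataclass
class AssignmentDecision:
    barcode: str
    c1: int | None = None
    p1: float = 0.0
    p2: float = 0.0
    ratio: float = 0.0
    rule_fired: str = "none"
    assigned: bool = False
    final_alpha: frozenset = frozenset()
    final_beta: frozenset = frozenset()

    @property
    def final_label(self) -> str:
        return clonotype_label(self.final_alpha, self.final_beta)


def assignment_rule(
    p1: float, p2: float, config: EclipseConfig | None = None
) -> str:
    """Which confidence rule (if any) the (p1, p2) pair satisfies.

    The ratio r = p1/p2 is +inf when p2 = 0. Boundary semantics: p1 bounds
    for the first two rules are inclusive, the p1 > 0.5 bound and both ratio
    bounds are strict.
    """
    config = config or EclipseConfig()
    r = math.inf if p2 == 0 else p1 / p2
    if p1 >= config.p1_hi:
        return "P80"
    if p1 >= config.p1_mid and r > config.r_mid:
        return "P70R5"
    if p1 > config.p1_lo and r > config.r_lo:
        return "P50R10"
    return "none"


def decide(
    posterior_row: Mapping[int, float],
    *,
    singleton_guard: bool = False,
    barcode: str = "",
    config: EclipseConfig | None = None,
) -> AssignmentDecision:
    """Apply the confidence thresholds to one cell's posterior row.

    ``singleton_guard`` is True when the cell's only observed contig is a
    chain seen in no other cell of the sample; such cells are treated as if
    no threshold were met. An empty posterior row marks a terminal cell.
    """
    config = config or EclipseConfig()
    if not posterior_row:
        return AssignmentDecision(barcode=barcode)
    items = sorted(posterior_row.items(), key=lambda kv: (-kv[1], kv[0]))
    c1, p1 = items[0]
    p2 = items[1][1] if len(items) > 1 else 0.0
    ratio = math.inf if p2 == 0 else p1 / p2
    rule = assignment_rule(p1, p2, config)
    if singleton_guard:
        rule = "none"
    return AssignmentDecision(
        barcode=barcode,
        c1=c1,
        p1=float(p1),
        p2=float(p2),
        ratio=float(ratio),
        rule_fired=rule,
        assigned=rule != "none",
    )


def join_partial_cells(
    decisions: Sequence[AssignmentDecision], special: Sequence[SpecialClone]
) -> tuple[list[AssignmentDecision], list[str]]:
    """Join 1α+1β calls matching two of a 3-chain clone's chains to the clone.

    A final call consisting of exactly one bitypic chain plus the monotypic
    chain of a detected clone is relabelled to the full 3-chain clonotype.
    A pair matching two distinct clones is ambiguous and left unchanged.
    """
    pair_map: dict = {}
    for sp in special:
        for b in (sp.bitypic_major, sp.bitypic_minor):
            if sp.bitypic_type == "TRA":
                key = (frozenset({b}), frozenset({sp.monotypic_cdr3}))
            else:
                key = (frozenset({sp.monotypic_cdr3}), frozenset({b}))
            pair_map.setdefault(key, []).append(sp)
    out: list[AssignmentDecision] = []
    ambiguous: list[str] = []
    for dec in decisions:
        if len(dec.final_alpha) == 1 and len(dec.final_beta) == 1:
            matches = pair_map.get((dec.final_alpha, dec.final_beta), [])
            if len(matches) == 1:
                sp = matches[0]
                dec = replace(dec, final_alpha=frozenset(sp.alpha), final_beta=frozenset(sp.beta))
            elif len(matches) > 1:
                logger.warning(
                    "cell %s: pair matches %d special clones; left unchanged",
                    dec.barcode,
                    len(matches),
                )
                ambiguous.append(dec.barcode)
        out.append(dec)
    return out, ambiguous


def doublet_filter(
    cells: Sequence[CellChainSet],
    max_total: int = 4,
    max_per_type: int = 2,
    min_umis: int | None = None,
) -> tuple[list[CellChainSet], list[CellChainSet]]:
    """Remove probable doublets: cells with too many TCR chains.

    A cell is removed when it has more than ``max_total`` chains in total or
    more than ``max_per_type`` of either type. When ``min_umis`` is set,
    chains below that UMI count are ignored for the tally.
    """
    kept, removed = [], []
    for cell in cells:
        alpha, beta = cell.alpha, cell.beta
        if min_umis is not None:
            alpha = {a for a in alpha if cell.chain_meta.get(("TRA", a), {}).get("umis", 0) >= min_umis}
            beta = {b for b in beta if cell.chain_meta.get(("TRB", b), {}).get("umis", 0) >= min_umis}
        if len(alpha) + len(beta) > max_total or len(alpha) > max_per_type or len(beta) > max_per_type:
            removed.append(cell)
        else:
            kept.append(cell)
    return kept, removed


def flag_invariant_t(cell: CellChainSet) -> str:
    """MAIT/iNKT prediction from TRA segment usage (allele suffixes ignored)."""
    flags = set()
    for a in cell.alpha:
        meta = cell.chain_meta.get(("TRA", a), {})
        v = str(meta.get("v_gene", "")).split("*")[0]
        j = str(meta.get("j_gene", "")).split("*")[0]
        if (v, j) in MAIT_SEGMENTS:
            flags.add("MAIT")
        elif (v, j) in INKT_SEGMENTS:
            flags.add("iNKT")
    if "MAIT" in flags:
        return "MAIT"
    if "iNKT" in flags:
        return "iNKT"
    return "none"


@dataclass
class SampleResult:
    sample: str
    cells: list
    special: list
    universe: list
    em: em_core.EMResult | None
    decisions: dict
    rescued: list = field(default_factory=list)
    join_ambiguities: list = field(default_factory=list)
    removed_doublets: list = field(default_factory=list)


@dataclass
class EclipseResult:
    annotations: pd.DataFrame
    samples: dict
    config: EclipseConfig


def _run_sample(
    cells: list[CellChainSet], sample: str, config: EclipseConfig
) -> SampleResult:
    removed: list[CellChainSet] = []
    special: list[SpecialClone] = []
    if config.detect_special:
        special = special_clones.detect_special_clones(cells, "two_alpha")
        special += special_clones.detect_special_clones(cells, "two_beta")
        cells, rescued = special_clones.rescue_bitypic_orphans(cells, special)
    else:
        rescued = []

    universe, chain_index = em_core.build_universe(cells, special)
    records = [em_core.compatibility(c, universe, chain_index) for c in cells]

    carrier = Counter()
    for cell in cells:
        for ch in cell.chains():
            carrier[ch] += 1

    decisions: dict[str, AssignmentDecision] = {}
    em_result = None
    if universe and any(not r.terminal for r in records):
        em_result = em_core.run_em(records, len(universe), config.epsilon, config.max_iter)
    for i, (cell, rec) in enumerate(zip(cells, records)):
        if rec.terminal or em_result is None:
            dec = AssignmentDecision(barcode=cell.barcode)
        else:
            row = em_result.assignment.getrow(i)
            posterior = {int(k): float(v) for k, v in zip(row.indices, row.data)}
            guard = cell.n_chains == 1 and all(carrier[ch] == 1 for ch in cell.chains())
            dec = decide(posterior, singleton_guard=guard, barcode=cell.barcode, config=config)
        if dec.assigned and dec.c1 is not None:
            ct = universe[dec.c1]
            dec = replace(dec, final_alpha=frozenset(ct.alpha), final_beta=frozenset(ct.beta))
        else:
            dec = replace(dec, final_alpha=frozenset(cell.alpha), final_beta=frozenset(cell.beta))
        decisions[cell.barcode] = dec

    joined, ambiguities = join_partial_cells(list(decisions.values()), special)
    decisions = {d.barcode: d for d in joined}

    if config.doublet_filter:
        kept, removed = doublet_filter(
            cells, config.doublet_max_total, config.doublet_max_per_type, config.doublet_min_umis
        )
        removed_barcodes = {c.barcode for c in removed}
    else:
        removed_barcodes = set()

    return SampleResult(
        sample=sample,
        cells=cells,
        special=special,
        universe=universe,
        em=em_result,
        decisions=decisions,
        rescued=rescued,
        join_ambiguities=ambiguities,
        removed_doublets=sorted(removed_barcodes),
    )


def run_eclipse(
    contigs: ContigTable | Mapping[str, ContigTable],
    cell_meta: pd.DataFrame,
    config: EclipseConfig | None = None,
) -> EclipseResult:
    """Run the full pipeline: filter, detect 3-chain clones, EM, decide, annotate.

    ``cell_meta`` must have columns ``barcode`` and ``sample`` (optionally
    ``cluster``); it defines the barcode whitelist and the per-sample
    grouping — the EM runs independently within each sample. Every metadata
    barcode yields one annotation row, TCR-less cells included.
    """
    config = config or EclipseConfig()
    if not {"barcode", "sample"} <= set(cell_meta.columns):
        raise ValueError("cell_meta requires 'barcode' and 'sample' columns")

    results: dict[str, SampleResult] = {}
    for sample, meta in cell_meta.groupby("sample", sort=True):
        table = contigs[sample] if isinstance(contigs, Mapping) else contigs
        filtered = io_contigs.filter_contigs(
            table,
            set(meta["barcode"]),
            sample=sample,
            require_high_confidence=config.require_high_confidence,
        )
        cells = io_contigs.collapse_to_cells(filtered)
        results[sample] = _run_sample(cells, sample, config)

    annotations = _annotate(results, cell_meta, config)
    return EclipseResult(annotations=annotations, samples=results, config=config)


def _annotate(
    results: Mapping[str, SampleResult], cell_meta: pd.DataFrame, config: EclipseConfig
) -> pd.DataFrame:
    from . import repertoire

    cells_by_sample = {
        sample: {c.barcode: c for c in res.cells} for sample, res in results.items()
    }
    rows = []
    for _, meta_row in cell_meta.iterrows():
        sample = meta_row["sample"]
        barcode = meta_row["barcode"]
        res = results[sample]
        cell = cells_by_sample[sample].get(barcode)
        dec = res.decisions.get(barcode)
        removed = barcode in res.removed_doublets
        if cell is None or dec is None:
            rows.append(_empty_row(barcode, sample))
            continue
        n_final = len(dec.final_alpha) + len(dec.final_beta)
        annotated = bool(dec.final_alpha and dec.final_beta) and not removed
        rows.append(
            {
                "barcode": barcode,
                "sample": sample,
                "final_clonotype": dec.final_label if annotated or n_final else "",
                "n_chains_called": n_final,
                "assigned": dec.assigned,
                "predicted": frozenset(cell.alpha) != dec.final_alpha
                or frozenset(cell.beta) != dec.final_beta,
                "annotated": annotated,
                "rule_fired": dec.rule_fired,
                "p1": dec.p1,
                "p2": dec.p2,
                "ratio": dec.ratio,
                "observed_alpha": "/".join(sorted(cell.alpha)),
                "observed_beta": "/".join(sorted(cell.beta)),
                "observed_cdr3_nt": "/".join(
                    cell.chain_meta.get(ch, {}).get("cdr3_nt", "") for ch in sorted(cell.chains())
                ),
                "observed_v_genes": "/".join(
                    cell.chain_meta.get(ch, {}).get("v_gene", "") for ch in sorted(cell.chains())
                ),
                "observed_j_genes": "/".join(
                    cell.chain_meta.get(ch, {}).get("j_gene", "") for ch in sorted(cell.chains())
                ),
                "invariant_t_flag": flag_invariant_t(cell),
                "removed_reason": "doublet_filter" if removed else "",
                "clone_size": 0,
                "clone_proportion": 0.0,
                "size_bin": "",
            }
        )
    df = pd.DataFrame(rows)
    # per-sample clone sizes/proportions over annotated cells
    for sample in df["sample"].unique():
        mask = (df["sample"] == sample) & df["annotated"]
        counts = df.loc[mask, "final_clonotype"].value_counts()
        total = int(counts.sum())
        if total == 0:
            continue
        df.loc[mask, "clone_size"] = df.loc[mask, "final_clonotype"].map(counts).astype(int)
        df.loc[mask, "clone_proportion"] = df.loc[mask, "clone_size"] / total
        df.loc[mask, "size_bin"] = df.loc[mask, "clone_proportion"].map(
            lambda p: repertoire.size_bin(p, config.size_bin_cuts)
        )
    return df


def _empty_row(barcode: str, sample: str) -> dict:
    return {
        "barcode": barcode,
        "sample": sample,
        "final_clonotype": "",
        "n_chains_called": 0,
        "assigned": False,
        "predicted": False,
        "annotated": False,
        "rule_fired": "none",
        "p1": 0.0,
        "p2": 0.0,
        "ratio": 0.0,
        "observed_alpha": "",
        "observed_beta": "",
        "observed_cdr3_nt": "",
        "observed_v_genes": "",
        "observed_j_genes": "",
        "invariant_t_flag": "none",
        "removed_reason": "",
        "clone_size": 0,
        "clone_proportion": 0.0,
        "size_bin": "",
    }


_STRING_COLS = (
    "barcode",
    "sample",
    "final_clonotype",
    "rule_fired",
    "observed_alpha",
    "observed_beta",
    "observed_cdr3_nt",
    "observed_v_genes",
    "observed_j_genes",
    "invariant_t_flag",
    "removed_reason",
    "size_bin",
)
_BOOL_COLS = ("assigned", "predicted", "annotated")
_INT_COLS = ("n_chains_called", "clone_size")
_FLOAT_COLS = ("p1", "p2", "ratio", "clone_proportion")


def export_annotations(annotations: pd.DataFrame, path) -> None:
    """Write the per-cell annotation table as TSV (one row per barcode)."""
    annotations.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read a table written by :func:`export_annotations` (lossless round trip)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    for col in _STRING_COLS:
        df[col] = df[col].astype(str)
    for col in _BOOL_COLS:
        df[col] = df[col].astype(str).str.lower().map({"true": True, "false": False}).astype(bool)
    for col in _INT_COLS:
        df[col] = pd.to_numeric(df[col]).astype(int)
    for col in _FLOAT_COLS:
        df[col] = pd.to_numeric(df[col]).astype(float)
    return df
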