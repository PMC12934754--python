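"""Detection of clonotypes that biologically express three TCR chains.

T cells can carry a second rearranged α (commonly) or β (rarely) chain.
Technical artifacts — doublets, ambient contamination — are very unlikely
to reproduce the exact same 3-chain combination across multiple cells, so
repeated co-observation of a chain triple is treated as evidence of a real
dual-chain clone. Detected clones are protected from being coerced to two
chains by the EM. In a 3-chain clone the chain type with two distinct
sequences is "bitypic" (major = the sequence observed in more cells) and
the single-sequence type is "monotypic".
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_contigs import CellChainSet

logger = logging.getLogger(__name__)

MIN_IDENTICAL_CELLS = 3  # rule A: cells with the identical 3-chain set
MONOTYPIC_BOTH_FRACTION = 0.10  # filter 1: of cells with m, fraction with both b's
ORPHAN_DOMINANCE_FRACTION = 0.80  # rescue rule threshold

MODES = ("two_alpha", "two_beta")

CELL_CLASSES = ("both_bitypic", "major_only", "minor_only", "monotypic_only")


@dataclass
class SpecialClone:
    """A detected 3-chain clonotype with its supporting evidence."""

    alpha: frozenset
    beta: frozenset
    bitypic_type: str  # "TRA" for 2α+1β, "TRB" for 1α+2β
    monotypic_cdr3: str
    bitypic_major: str
    bitypic_minor: str
    rule: str  # "A" or "B"
    support_cells: tuple = ()
    stats: dict = field(default_factory=dict)

    @property
    def monotypic_type(self) -> str:
        return "TRB" if self.bitypic_type == "TRA" else "TRA"

    def chains(self) -> frozenset:
        return frozenset({("TRA", a) for a in self.alpha} | {("TRB", b) for b in self.beta})

    @property
    def label(self) -> str:
        from .em_core import clonotype_label

        return clonotype_label(self.alpha, self.beta)


def _typed_sets(cell: CellChainSet, bitypic_type: str) -> tuple[frozenset, frozenset]:
    """(bitypic-type chains, monotypic-type chains) of a cell."""
    if bitypic_type == "TRA":
        return frozenset(cell.alpha), frozenset(cell.beta)
    return frozenset(cell.beta), frozenset(cell.alpha)


def detect_special_clones(
    cells: Sequence[CellChainSet], mode: str
) -> list[SpecialClone]:
    """Detect dual-chain (3-chain) clonotypes within one sample.

    A candidate triple {b1, b2, m} (bitypic pair + monotypic chain) is
    called iff one firing rule holds:

    * rule A — at least 3 cells whose full chain set is exactly {b1, b2, m};
    * rule B — at least one cell with exactly {b1, b2, m}, one with exactly
      {b1, m} and one with exactly {b2, m} (three distinct cells);

    and both artifact filters pass:

    * filter 1 — ≥ 10% of the sample's cells containing m carry both b1
      and b2;
    * filter 2 — m is the strictly most frequent opposite-type partner of
      b1 and of b2 (co-occurrence counted per cell; ties fail).

    Run with ``mode="two_alpha"`` first, then ``mode="two_beta"``; detection
    is non-destructive, so dual-α calls do not hide chains from dual-β
    detection.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    bt = "TRA" if mode == "two_alpha" else "TRB"

    exact_sets = Counter()  # (frozenset bitypic, frozenset monotypic) -> n cells
    cells_by_exact: dict = defaultdict(list)
    carrier_count = Counter()  # chain (type, cdr3) -> n cells containing it
    partner_counts: dict = defaultdict(Counter)  # chain -> Counter of opposite-type chains
    mono_with: dict = defaultdict(list)  # monotypic cdr3 -> list of bitypic sets of its cells
    for cell in cells:
        b_set, m_set = _typed_sets(cell, bt)
        exact_sets[(b_set, m_set)] += 1
        cells_by_exact[(b_set, m_set)].append(cell.barcode)
        for ch in cell.chains():
            carrier_count[ch] += 1
        for b in b_set:
            for m in m_set:
                partner_counts[(bt, b)][m] += 1
                partner_counts[(_other(bt), m)][b] += 1
        for m in m_set:
            mono_with[m].append(b_set)

    candidates: set = set()
    for (b_set, m_set) in exact_sets:
        if len(b_set) == 2 and len(m_set) == 1:
            candidates.add((b_set, next(iter(m_set))))

    out: list[SpecialClone] = []
    for b_set, m in sorted(candidates, key=lambda c: (c[1], tuple(sorted(c[0])))):
        b1, b2 = sorted(b_set)
        full_key = (b_set, frozenset({m}))
        n_full = exact_sets.get(full_key, 0)
        rule = None
        support = list(cells_by_exact.get(full_key, []))
        if n_full >= MIN_IDENTICAL_CELLS:
            rule = "A"
        else:
            k1 = (frozenset({b1}), frozenset({m}))
            k2 = (frozenset({b2}), frozenset({m}))
            if n_full >= 1 and exact_sets.get(k1, 0) >= 1 and exact_sets.get(k2, 0) >= 1:
                rule = "B"
                support += cells_by_exact[k1][:1] + cells_by_exact[k2][:1]
        if rule is None:
            continue

        # filter 1: among cells containing m, fraction with both bitypic chains
        m_cells = mono_with[m]
        n_both = sum(1 for bs in m_cells if b_set <= bs)
        frac_both = n_both / len(m_cells) if m_cells else 0.0
        if frac_both < MONOTYPIC_BOTH_FRACTION:
            logger.debug("triple %s/%s+%s rejected by 10%% filter (%.3f)", b1, b2, m, frac_both)
            continue

        # filter 2: m must be the strict modal partner of both bitypic chains
        ok = True
        for b in (b1, b2):
            counts = partner_counts[(bt, b)]
            best = counts.most_common()
            if not best or best[0][0] != m or (len(best) > 1 and best[1][1] == best[0][1]):
                ok = False
                break
        if not ok:
            logger.debug("triple %s/%s+%s rejected by modal-partner filter", b1, b2, m)
            continue

        n1 = carrier_count[(bt, b1)]
        n2 = carrier_count[(bt, b2)]
        if n1 > n2 or (n1 == n2 and b1 < b2):
            major, minor = b1, b2
            n_major, n_minor = n1, n2
        else:
            major, minor = b2, b1
            n_major, n_minor = n2, n1
        alpha = b_set if bt == "TRA" else frozenset({m})
        beta = frozenset({m}) if bt == "TRA" else b_set
        out.append(
            SpecialClone(
                alpha=alpha,
                beta=beta,
                bitypic_type=bt,
                monotypic_cdr3=m,
                bitypic_major=major,
                bitypic_minor=minor,
                rule=rule,
                support_cells=tuple(sorted(set(support))),
                stats={
                    "n_identical_cells": n_full,
                    "pct_monotypic_with_both": 100.0 * frac_both,
                    "n_cells_major": n_major,
                    "n_cells_minor": n_minor,
                },
            )
        )
    return out


def _other(chain_type: str) -> str:
    return "TRB" if chain_type == "TRA" else "TRA"


def verify_special_clone(clone: SpecialClone, cells: Sequence[CellChainSet]) -> bool:
    """Re-check a detected clone's firing rule and filters against the input."""
    redetected = detect_special_clones(
        cells, "two_alpha" if clone.bitypic_type == "TRA" else "two_beta"
    )
    return any(sp.alpha == clone.alpha and sp.beta == clone.beta for sp in redetected)


def rescue_bitypic_orphans(
    cells: Sequence[CellChainSet], special: Sequence[SpecialClone]
) -> tuple[list[CellChainSet], list[str]]:
    """Relabel bitypic-only cells so the EM can consider the 3-chain clone.

    For each detected clone, when ≥ 80% of the sample's cells carrying any
    of its bitypic chains have chain sets consistent with the clone (bitypic
    chains within {b1, b2}, monotypic chains within {m}), cells holding 1–2
    bitypic chains and no monotypic-type chain are given the full bitypic
    pair. Returns updated copies of the cells and the rescued barcodes.
    """
    cells = [c.copy() for c in cells]
    rescued: list[str] = []
    for clone in special:
        bt = clone.bitypic_type
        b_set = frozenset({clone.bitypic_major, clone.bitypic_minor})
        bearing = []
        for cell in cells:
            cb, cm = _typed_sets(cell, bt)
            if cb & b_set:
                bearing.append((cell, cb, cm))
        if not bearing:
            continue
        n_consistent = sum(
            1 for _, cb, cm in bearing if cb <= b_set and cm <= {clone.monotypic_cdr3}
        )
        if n_consistent / len(bearing) < ORPHAN_DOMINANCE_FRACTION:
            continue
        for cell, cb, cm in bearing:
            if not cm and cb <= b_set and cb != b_set:
                if bt == "TRA":
                    cell.alpha = set(b_set)
                else:
                    cell.beta = set(b_set)
                rescued.append(cell.barcode)
    return cells, rescued


def classify_cell_in_special_clone(cell: CellChainSet, clone: SpecialClone) -> str:
    """Classify a clone member by which bitypic chains it exhibits."""
    if not (cell.chains() & clone.chains()):
        raise ValueError(
            f"cell {cell.barcode} shares no chain with clone {clone.label}; inconsistent assignment"
        )
    cb, _ = _typed_sets(cell, clone.bitypic_type)
    has_major = clone.bitypic_major in cb
    has_minor = clone.bitypic_minor in cb
    if has_major and has_minor:
        return "both_bitypic"
    if has_major:
        return "major_only"
    if has_minor:
        return "minor_only"
    return "monotypic_only"


def write_special_report(special: Iterable[SpecialClone], path) -> None:
    """Special-clone report TSV with rule and filter statistics."""
    import pandas as pd

    rows = []
    for sp in special:
        rows.append(
            {
                "clonotype": sp.label,
                "bitypic_type": sp.bitypic_type,
                "monotypic_chain": sp.monotypic_cdr3,
                "bitypic_major": sp.bitypic_major,
                "bitypic_minor": sp.bitypic_minor,
                "rule": sp.rule,
                "n_support_cells": len(sp.support_cells),
                **{k: v for k, v in sp.stats.items()},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
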