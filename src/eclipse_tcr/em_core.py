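"""EM-based probabilistic clonotype assignment.

A clonotype is an identity of 2 chains (1 TCRα + 1 TCRβ) or, for dual-chain
clones, 3 chains (2α+1β or 1α+2β), each chain identified by its CDR3
amino-acid sequence. Cells are modelled as i.i.d. draws from a marginal
clonotype distribution θ; a cell's observed chain set censors the draw down
to the candidate clonotypes consistent with it. The EM algorithm alternates
posterior responsibility computation (E-step) with re-estimation of θ as the
mean responsibility (M-step) until θ stabilizes, yielding a per-cell
posterior assignment matrix over the clonotype universe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .io_contigs import CellChainSet

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-6
DEFAULT_MAX_ITER = 10_000


@dataclass(frozen=True)
class Clonotype:
    """A clone identity of 1–2 α and 1–2 β CDR3-aa chains (2 or 3 total)."""

    id: int
    alpha: frozenset
    beta: frozenset

    @property
    def n_chains(self) -> int:
        return len(self.alpha) + len(self.beta)

    def chains(self) -> frozenset:
        return frozenset({("TRA", a) for a in self.alpha} | {("TRB", b) for b in self.beta})

    @property
    def label(self) -> str:
        return clonotype_label(self.alpha, self.beta)


def clonotype_label(alpha: Iterable[str], beta: Iterable[str]) -> str:
    """Canonical string for a chain set: sorted α CDR3s ``|`` sorted β CDR3s."""
    return "/".join(sorted(alpha)) + "|" + "/".join(sorted(beta))


@dataclass
class CompatibilityRecord:
    """The candidate clonotypes consistent with one cell's observed chains."""

    barcode: str
    candidate_ids: tuple
    ambiguous: bool
    terminal: bool  # no candidate at all; bypasses EM


@dataclass
class EMTrace:
    iterations: int = 0
    theta_delta_history: list = field(default_factory=list)
    loglik_history: list = field(default_factory=list)
    converged: bool = False
    epsilon: float = DEFAULT_EPSILON


@dataclass
class EMResult:
    theta: np.ndarray
    assignment: sparse.csr_matrix  # rows follow the record order passed in
    records: list
    trace: EMTrace


def build_universe(
    cells: Sequence[CellChainSet], special: Sequence = ()
) -> tuple[list[Clonotype], dict]:
    """Enumerate the candidate clonotype universe from within-cell pairings.

    The universe is the provided 3-chain (special) clonotypes plus every
    (α, β) pair co-observed inside a single cell — a pairing never seen
    together in one cell is not a candidate. Cells whose full chain set is
    contained in a special clone are considered claimed by it and do not
    contribute 2-chain sub-pairs; if independent pair evidence exists in
    other cells, both entries coexist and the EM arbitrates.

    Returns the universe and a chain index mapping ``(chain_type, cdr3_aa)``
    to the set of clonotype ids containing that chain.
    """
    special_chain_sets = [frozenset(sp.chains()) for sp in special]
    pairs: set[tuple[str, str]] = set()
    any_paired = False
    for cell in cells:
        if not cell.alpha or not cell.beta:
            continue
        any_paired = True
        observed = cell.chains()
        if any(observed <= sp for sp in special_chain_sets):
            continue
        for a in cell.alpha:
            for b in cell.beta:
                pairs.add((a, b))
    universe: list[Clonotype] = []
    for sp in special:
        universe.append(Clonotype(len(universe), frozenset(sp.alpha), frozenset(sp.beta)))
    for a, b in sorted(pairs):
        universe.append(Clonotype(len(universe), frozenset({a}), frozenset({b})))
    if not universe and cells and not any_paired:
        warnings.warn("no cell has both chain types; clonotype universe is empty", stacklevel=2)
    chain_index: dict = {}
    for ct in universe:
        for chain in ct.chains():
            chain_index.setdefault(chain, set()).add(ct.id)
    return universe, chain_index


def compatibility(
    cell: CellChainSet, universe: Sequence[Clonotype], chain_index: dict
) -> CompatibilityRecord:
    """Candidate clonotypes consistent with a cell's observed chains.

    A cell with both chain types is compatible with clonotypes containing
    *all* its observed chains; if none exists (an extra chain not part of
    any dual-chain clone), the true clonotype must be composed of observed
    chains with the surplus explained by contamination, so candidates are
    the clonotypes whose chains are a *subset* of the observed set. Only if
    that is also empty does the cell fall back to the union of clonotypes
    sharing at least one observed chain. A cell with a single chain type is
    compatible with every clonotype containing at least one of its chains.
    Cells with no candidates are terminal and bypass the EM.
    """
    observed = sorted(cell.chains())
    observed_set = frozenset(observed)
    cands: set[int] = set()
    if cell.alpha and cell.beta:
        sets = [chain_index.get(ch, set()) for ch in observed]
        cands = set.intersection(*sets) if sets else set()
        if not cands:
            union: set[int] = set()
            for ch in observed:
                union |= chain_index.get(ch, set())
            cands = {k for k in union if universe[k].chains() <= observed_set}
            if not cands:
                cands = union
    else:
        for ch in observed:
            cands |= chain_index.get(ch, set())
    complete_pair = len(cell.alpha) == 1 and len(cell.beta) == 1
    ambiguous = len(cands) != 1 or not complete_pair
    return CompatibilityRecord(
        barcode=cell.barcode,
        candidate_ids=tuple(sorted(cands)),
        ambiguous=ambiguous,
        terminal=not cands,
    )


def _membership_matrix(records: Sequence[CompatibilityRecord], n_clonotypes: int) -> sparse.csr_matrix:
    rows, cols = [], []
    for i, rec in enumerate(records):
        for k in rec.candidate_ids:
            rows.append(i)
            cols.append(k)
    data = np.ones(len(rows))
    return sparse.csr_matrix((data, (rows, cols)), shape=(len(records), n_clonotypes))


def observed_loglik(records: Sequence[CompatibilityRecord], theta: np.ndarray) -> float:
    """Observed-data log-likelihood Σ_i log Σ_{k∈candidates(i)} θ_k."""
    total = 0.0
    for rec in records:
        if rec.terminal:
            continue
        mass = float(sum(theta[k] for k in rec.candidate_ids))
        total += np.log(mass) if mass > 0 else -np.inf
    return total


def run_em(
    records: Sequence[CompatibilityRecord],
    n_clonotypes: int,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int = DEFAULT_MAX_ITER,
) -> EMResult:
    """Iterate E/M steps to the converged marginal clonotype distribution θ.

    Initialization splits each cell's unit mass evenly over its candidates.
    E-step: a_ik = θ_k / Σ_{k'∈candidates(i)} θ_k'. M-step: θ_k = Σ_i a_ik/N.
    Convergence when max_k |θ_k(t+1) − θ_k(t)| < ε. Terminal records receive
    an all-zero assignment row and do not enter the likelihood.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be positive")
    records = list(records)
    em_idx = [i for i, r in enumerate(records) if not r.terminal]
    if not em_idx:
        raise ValueError("no non-terminal cells to run EM on")
    em_records = [records[i] for i in em_idx]
    C = _membership_matrix(em_records, n_clonotypes)
    n = C.shape[0]
    row_sizes = np.asarray(C.sum(axis=1)).ravel()

    # even-split initialization, then M-step for θ(0)
    A = sparse.diags(1.0 / row_sizes) @ C
    theta = np.asarray(A.sum(axis=0)).ravel() / n
    trace = EMTrace(epsilon=epsilon)
    trace.loglik_history.append(observed_loglik(em_records, theta))

    for _ in range(max_iter):
        W = C.multiply(theta).tocsr()  # E-step numerators
        denom = np.asarray(W.sum(axis=1)).ravel()
        degenerate = denom <= 0.0
        if degenerate.any():
            # all candidate mass exactly zero: re-split evenly for those cells
            W = W.tolil()
            for i in np.flatnonzero(degenerate):
                for k in em_records[i].candidate_ids:
                    W[i, k] = 1.0 / len(em_records[i].candidate_ids)
            W = W.tocsr()
            denom = np.asarray(W.sum(axis=1)).ravel()
        A = sparse.diags(1.0 / denom) @ W
        new_theta = np.asarray(A.sum(axis=0)).ravel() / n
        delta = float(np.max(np.abs(new_theta - theta)))
        theta = new_theta
        trace.iterations += 1
        trace.theta_delta_history.append(delta)
        trace.loglik_history.append(observed_loglik(em_records, theta))
        if delta < epsilon:
            trace.converged = True
            break
    if not trace.converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations (last Δθ={trace.theta_delta_history[-1]:.3g})",
            stacklevel=2,
        )

    # final E-step responsibilities at the converged θ, expanded to all records
    A = A.tocoo()
    full = sparse.csr_matrix(
        (A.data, ([em_idx[i] for i in A.row], A.col)), shape=(len(records), n_clonotypes)
    )
    return EMResult(theta=theta, assignment=full, records=records, trace=trace)


def export_theta(theta: np.ndarray, universe: Sequence[Clonotype], path) -> None:
    """Write θ as a two-column TSV (clonotype label, theta)."""
    import pandas as pd

    pd.DataFrame(
        {"clonotype": [ct.label for ct in universe], "theta": theta}
    ).to_csv(path, sep="\t", index=False)


def export_assignment_mtx(result: EMResult, universe: Sequence[Clonotype], prefix) -> None:
    """Write the assignment matrix as MTX plus row/column label TSVs."""
    from pathlib import Path

    from scipy.io import mmwrite

    prefix = Path(prefix)
    mmwrite(str(prefix) + ".mtx", result.assignment)
    with open(str(prefix) + ".rows.tsv", "w") as fh:
        fh.write("barcode\n")
        for rec in result.records:
            fh.write(rec.barcode + "\n")
    with open(str(prefix) + ".cols.tsv", "w") as fh:
        fh.write("clonotype\n")
        for ct in universe:
            fh.write(ct.label + "\n")
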