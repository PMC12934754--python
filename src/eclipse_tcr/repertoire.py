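"""Clone-level statistics: comparator callers, clone sizes, diversity indices.

The three comparator methods are the standard clonotype-calling baselines:
``keep_all`` keeps every cell and chain as observed; ``top_umi_pair`` keeps
the highest-UMI chain of each type and drops cells with a single detected
chain type; ``strict_1to1`` keeps only cells with exactly one TRA and one
TRB. Diversity indices operate on clone proportions over annotated cells.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .em_core import clonotype_label
from .io_contigs import CellChainSet

METHODS = ("eclipse", "keep_all", "top_umi_pair", "strict_1to1")

SIZE_BINS = ("Rare", "Small", "Medium", "Large", "Hyperexpanded")

DIVERSITY_INDICES = ("shannon", "inv_simpson", "norm_entropy", "gini_simpson")


def _top_umi_chain(cell: CellChainSet, chain_type: str, chains: Iterable[str]) -> str:
    """Highest-UMI chain; ties by reads, then lexicographically smaller CDR3."""

    def key(cdr3: str):
        meta = cell.chain_meta.get((chain_type, cdr3), {})
        return (-meta.get("umis", 0), -meta.get("reads", 0), cdr3)

    return min(chains, key=key)


def call_comparator(cells: Sequence[CellChainSet], method: str) -> dict:
    """Per-cell clonotype labels under a comparator method.

    Returns a mapping barcode → label, with ``None`` for unannotated cells.
    """
    if method not in ("keep_all", "top_umi_pair", "strict_1to1"):
        raise ValueError(f"unknown comparator method {method!r}")
    labels: dict = {}
    for cell in cells:
        if method == "keep_all":
            labels[cell.barcode] = (
                clonotype_label(cell.alpha, cell.beta) if cell.n_chains else None
            )
        elif method == "top_umi_pair":
            if cell.alpha and cell.beta:
                a = _top_umi_chain(cell, "TRA", cell.alpha)
                b = _top_umi_chain(cell, "TRB", cell.beta)
                labels[cell.barcode] = clonotype_label({a}, {b})
            else:
                labels[cell.barcode] = None
        else:  # strict_1to1
            if len(cell.alpha) == 1 and len(cell.beta) == 1:
                labels[cell.barcode] = clonotype_label(cell.alpha, cell.beta)
            else:
                labels[cell.barcode] = None
    return labels


def clone_sizes(labels: Mapping[str, str | None] | Iterable[str | None]) -> pd.DataFrame:
    """Clone table (clonotype, size, proportion), descending size then label."""
    values = list(labels.values()) if isinstance(labels, Mapping) else list(labels)
    annotated = [v for v in values if v is not None]
    if not annotated:
        return pd.DataFrame(columns=["clonotype", "size", "proportion"])
    counts = pd.Series(annotated).value_counts()
    df = pd.DataFrame({"clonotype": counts.index, "size": counts.to_numpy()})
    df = df.sort_values(["size", "clonotype"], ascending=[False, True], kind="mergesort")
    df["proportion"] = df["size"] / df["size"].sum()
    return df.reset_index(drop=True)


def pct_unannotated(labels: Mapping[str, str | None] | Iterable[str | None]) -> float:
    """Percentage of cells without a clonotype label."""
    values = list(labels.values()) if isinstance(labels, Mapping) else list(labels)
    if not values:
        return 0.0
    return 100.0 * sum(v is None for v in values) / len(values)


def mean_top_clone_size(clone_table: pd.DataFrame, top: int = 30, rank_from: int = 1) -> float:
    """Mean size of the clones ranked ``rank_from``..``rank_from+top-1``."""
    sizes = clone_table["size"].iloc[rank_from - 1 : rank_from - 1 + top]
    return float(sizes.mean()) if len(sizes) else 0.0


def size_bin(proportion: float, cuts: Sequence[float] = (1e-4, 1e-3, 1e-2, 1e-1)) -> str:
    """Relative clone-size bin; right-closed intervals over (0, 1]."""
    if not 0.0 < proportion <= 1.0:
        raise ValueError(f"clone proportion must be in (0, 1], got {proportion}")
    for cut, name in zip(cuts, SIZE_BINS):
        if proportion <= cut:
            return name
    return SIZE_BINS[len(cuts)]


def diversity(
    clone_table: pd.DataFrame,
    index: str,
    n_boot: int | None = None,
    boot_size: int | None = None,
    seed: int | None = None,
) -> float:
    """A repertoire diversity index from clone proportions.

    shannon = −Σ p_i ln p_i; inv_simpson = 1/Σ p_i²; gini_simpson = 1−Σ p_i²;
    norm_entropy = shannon/ln(S) (0 when a single clone). With ``n_boot``
    set, the value is the mean over bootstrap resamples of ``boot_size``
    cells drawn from the clone distribution (seeded).
    """
    if index not in DIVERSITY_INDICES:
        raise ValueError(f"unknown diversity index {index!r}")
    if clone_table is None or len(clone_table) == 0:
        raise ValueError("empty clone table")
    p = np.asarray(clone_table["proportion"], dtype=float)
    if n_boot is None:
        return _diversity_value(p, index)
    if boot_size is None:
        boot_size = int(clone_table["size"].sum())
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_boot):
        draw = rng.multinomial(boot_size, p)
        q = draw[draw > 0] / boot_size
        vals.append(_diversity_value(q, index))
    return float(np.mean(vals))


def _diversity_value(p: np.ndarray, index: str) -> float:
    shannon = float(-(p * np.log(p)).sum())
    if index == "shannon":
        return shannon
    if index == "inv_simpson":
        return float(1.0 / (p**2).sum())
    if index == "gini_simpson":
        return float(1.0 - (p**2).sum())
    s = len(p)
    return 0.0 if s == 1 else shannon / np.log(s)


def summarize(
    labels: Mapping[str, str | None], sample: str, method: str
) -> dict:
    """Per-sample, per-method repertoire summary row."""
    table = clone_sizes(labels)
    row = {
        "sample": sample,
        "method": method,
        "n_cells": len(labels),
        "n_clones": len(table),
        "pct_unannotated": pct_unannotated(labels),
        "mean_top30_size": mean_top_clone_size(table, 30),
    }
    for index in DIVERSITY_INDICES:
        row[index] = diversity(table, index) if len(table) else float("nan")
    return row


def paired_compare(
    values_by_method: Mapping[str, Sequence[float]], correction: str = "fdr_bh"
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon signed-rank tests across methods with FDR.

    Input: per-sample paired values for each method (equal-length vectors).
    Identical vectors give p = 1. Fewer than 3 pairs triggers a warning and
    an exact test on the available pairs.
    """
    from statsmodels.stats.multitest import multipletests

    methods = list(values_by_method)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    lengths = {len(v) for v in values_by_method.values()}
    if len(lengths) != 1:
        raise ValueError("value vectors must be paired (equal length)")
    (n,) = lengths
    if n < 3:
        warnings.warn(f"only {n} paired samples; exact test on available pairs", stacklevel=2)
    rows = []
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1 :]:
            x = np.asarray(values_by_method[m1], dtype=float)
            y = np.asarray(values_by_method[m2], dtype=float)
            diff = x - y
            if np.all(diff == 0):
                stat, p = 0.0, 1.0
            else:
                res = stats.wilcoxon(x, y, alternative="two-sided", method="auto")
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append({"method_a": m1, "method_b": m2, "statistic": stat, "pvalue": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["pvalue"], method=correction)[1]
    return df
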