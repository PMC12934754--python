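"""Validation machinery: chain removal/addition simulations and permutation tests.

The perturbation simulations delete or graft chains onto cells with a
ground-truth clonotype (exactly 1 TRA + 1 TRB) and classify whether the
pipeline recovers the original call, invents a new clonotype, or declines
to predict. The permutation test quantifies phenotypic consistency of
clones via the total variation distance between cluster-usage
distributions, against a null of randomly paired same-donor clones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_contigs import ContigTable

AFFECTED_OUTCOMES = ("same_call", "new_clonotype", "no_prediction")

TV_NORMALIZATION_TOL = 1e-6


@dataclass
class PerturbationRecord:
    kind: str  # "removal" | "addition"
    affected_barcodes: list
    removed_or_added: list  # contig_ids removed, or (donor contig_id, target) pairs
    seed: int


@dataclass
class OutcomeTable:
    affected: pd.Series  # barcode -> outcome in AFFECTED_OUTCOMES
    unaffected_changed: pd.Series  # barcode -> bool
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.counts:
            self.counts = {
                **{k: int((self.affected == k).sum()) for k in AFFECTED_OUTCOMES},
                "unaffected_changed": int(self.unaffected_changed.sum()),
                "n_affected": len(self.affected),
                "n_unaffected": len(self.unaffected_changed),
            }


def _ground_truth_barcodes(table: ContigTable) -> list[str]:
    """Barcodes with exactly one TRA and one TRB contig (after dedup)."""
    df = table.df
    counts = df.pivot_table(index="barcode", columns="chain", values="contig_id", aggfunc="count").fillna(0)
    for ch in ("TRA", "TRB"):
        if ch not in counts.columns:
            return []
    ok = counts[(counts.get("TRA", 0) == 1) & (counts.get("TRB", 0) == 1)]
    extra = set(df["chain"].unique()) - {"TRA", "TRB"}
    if extra:
        other = df[df["chain"].isin(extra)].groupby("barcode").size()
        ok = ok[~ok.index.isin(other.index)]
    return sorted(ok.index)


def perturb_remove(
    table: ContigTable, n: int, seed: int
) -> tuple[ContigTable, PerturbationRecord]:
    """Delete one chain (α or β, uniformly) from n distinct ground-truth cells."""
    eligible = _ground_truth_barcodes(table)
    if len(eligible) < n:
        raise ValueError(f"only {len(eligible)} eligible 1:1 cells; cannot perturb {n}")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(eligible, size=n, replace=False)) if n else []
    df = table.df
    drop_ids = []
    for barcode in chosen:
        chain = "TRA" if rng.random() < 0.5 else "TRB"
        row = df[(df["barcode"] == barcode) & (df["chain"] == chain)].iloc[0]
        drop_ids.append(row["contig_id"])
    out = df[~df["contig_id"].isin(drop_ids)].reset_index(drop=True)
    record = PerturbationRecord("removal", sorted(chosen), drop_ids, seed)
    return ContigTable(out, table.dialect), record


def perturb_add(
    table: ContigTable, n: int, seed: int
) -> tuple[ContigTable, PerturbationRecord]:
    """Graft one foreign chain onto each of n ground-truth cells.

    Donor contigs come from n *other* ground-truth cells (targets and donors
    disjoint); the copied contig's barcode and contig_id are rewritten to
    the target. A donor whose chain collides with an identical chain already
    in the target is re-drawn.
    """
    eligible = _ground_truth_barcodes(table)
    if len(eligible) < 2 * n:
        raise ValueError(f"need ≥ {2 * n} eligible cells, found {len(eligible)}")
    rng = np.random.default_rng(seed)
    df = table.df
    added = []
    new_rows = []
    if n:
        picked = list(rng.choice(eligible, size=2 * n, replace=False))
        targets, donors = picked[:n], picked[n:]
        donor_pool = list(donors)
        by_barcode = {b: df[df["barcode"] == b] for b in set(targets) | set(donors)}
        for i, target in enumerate(targets):
            tgt_rows = by_barcode[target]
            for _ in range(100):
                donor = donor_pool[i]
                donor_rows = by_barcode[donor]
                contig = donor_rows.iloc[int(rng.integers(len(donor_rows)))]
                collides = (
                    (tgt_rows["chain"] == contig["chain"])
                    & (tgt_rows["cdr3_aa"] == contig["cdr3_aa"])
                ).any()
                if not collides:
                    break
                # redraw the donor from the unused remainder of the pool
                swap = int(rng.integers(i, n))
                donor_pool[i], donor_pool[swap] = donor_pool[swap], donor_pool[i]
            new = contig.copy()
            new["barcode"] = target
            new["contig_id"] = f"{target}_sim_add_{i}"
            new_rows.append(new)
            added.append((contig["contig_id"], target))
    out = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True) if new_rows else df.copy()
    record = PerturbationRecord("addition", sorted(r[1] for r in added), added, seed)
    return ContigTable(out, table.dialect), record


def classify_outcomes(
    before: pd.DataFrame, after: pd.DataFrame, record: PerturbationRecord
) -> OutcomeTable:
    """Three-way outcome per perturbed cell; changed/unchanged for the rest.

    ``before``/``after`` are annotation tables (from the pipeline) covering
    the same barcodes. An affected cell is ``same_call`` when its final
    clonotype is identical, ``new_clonotype`` when a different clonotype was
    confidently assigned, and ``no_prediction`` when the final label is the
    observed chains only.
    """
    b = before.set_index("barcode")
    a = after.set_index("barcode")
    if set(b.index) != set(a.index):
        raise ValueError("annotation tables cover different barcodes")
    a = a.reindex(b.index)
    affected = pd.Index(record.affected_barcodes)
    missing = affected.difference(b.index)
    if len(missing):
        raise ValueError(f"affected barcodes missing from annotations: {list(missing)[:3]}")
    outcomes = {}
    for barcode in affected:
        same = a.loc[barcode, "final_clonotype"] == b.loc[barcode, "final_clonotype"]
        if same:
            outcomes[barcode] = "same_call"
        elif a.loc[barcode, "assigned"]:
            outcomes[barcode] = "new_clonotype"
        else:
            outcomes[barcode] = "no_prediction"
    rest = b.index.difference(affected)
    changed = a.loc[rest, "final_clonotype"] != b.loc[rest, "final_clonotype"]
    return OutcomeTable(
        affected=pd.Series(outcomes, dtype=object),
        unaffected_changed=changed,
    )


def total_variation(a, b) -> float:
    """Total variation distance ½ Σ_x |A(x) − B(x)| between two distributions.

    Accepts aligned arrays or label→probability mappings over the same
    cluster set; 0 means identical cluster usage, 1 disjoint.
    """
    if isinstance(a, Mapping) or isinstance(b, Mapping):
        if set(a) != set(b):
            raise ValueError("distributions are over different cluster label sets")
        keys = sorted(a)
        a = np.array([a[k] for k in keys], dtype=float)
        b = np.array([b[k] for k in keys], dtype=float)
    else:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("distributions have different lengths")
    for name, p in (("A", a), ("B", b)):
        if (p < 0).any() or abs(p.sum() - 1.0) > TV_NORMALIZATION_TOL:
            raise ValueError(f"distribution {name} is not normalized")
    return float(0.5 * np.abs(a - b).sum())


def cluster_distribution(labels: Sequence, cluster_set: Sequence) -> np.ndarray:
    """Empirical cluster-usage distribution of a group of cells."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty cell group")
    idx = {c: i for i, c in enumerate(cluster_set)}
    out = np.zeros(len(cluster_set))
    for lab in labels:
        out[idx[lab]] += 1
    return out / out.sum()


def permutation_test(
    observed_pairs: Sequence[tuple],
    null_clones: Mapping[object, Sequence[Sequence]],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, np.ndarray, float]:
    """Permutation test of clonal phenotypic consistency via mean dTV.

    ``observed_pairs`` holds, per test clone, the cluster labels of its two
    cell groups (e.g. bitypic-major vs bitypic-minor expressing cells).
    ``null_clones`` maps donor → list of per-clone cluster-label lists for
    the 1:1 reference clones. Each null replicate pairs as many random
    same-donor clone pairs (without replacement within a pair) as there are
    test clones and averages their dTV. Returns (observed mean dTV,
    permuted means, p) with p = (1 + #{permuted ≤ observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    cluster_set = sorted(
        {l for a, b in observed_pairs for l in list(a) + list(b)}
        | {l for clones in null_clones.values() for labels in clones for l in labels}
    )
    pairs = []
    for a, b in observed_pairs:
        if not len(a) or not len(b):
            warnings.warn("clone with an empty comparison group skipped", stacklevel=2)
            continue
        pairs.append(
            total_variation(
                cluster_distribution(a, cluster_set), cluster_distribution(b, cluster_set)
            )
        )
    if not pairs:
        raise ValueError("no clone supplied two non-empty comparison groups")
    observed = float(np.mean(pairs))
    n_clones = len(pairs)

    donors = [d for d, clones in null_clones.items() if len(clones) >= 2]
    if not donors:
        raise ValueError("no donor provides ≥ 2 reference clones")
    mats = {d: np.stack([cluster_distribution(l, cluster_set) for l in null_clones[d]]) for d in donors}

    rng = np.random.default_rng(seed)
    total = n_perm * n_clones
    donor_idx = rng.integers(len(donors), size=total)
    dtv_flat = np.empty(total)
    for di, d in enumerate(donors):
        mask = donor_idx == di
        m = mats[d].shape[0]
        k = int(mask.sum())
        if not k:
            continue
        i = rng.integers(m, size=k)
        j = rng.integers(m - 1, size=k)
        j = j + (j >= i)
        dtv_flat[mask] = 0.5 * np.abs(mats[d][i] - mats[d][j]).sum(axis=1)
    permuted = dtv_flat.reshape(n_perm, n_clones).mean(axis=1)
    p = (1.0 + float((permuted <= observed).sum())) / (1.0 + n_perm)
    return observed, permuted, p
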