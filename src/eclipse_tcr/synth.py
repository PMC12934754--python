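"""Synthetic scTCR-seq generator with full ground truth.

Emulates the statistical structure the pipeline assumes: a clone-size
spectrum with a heavy expanded tail, dual-chain (3-chain) clones, per-chain
dropout, ambient contamination drawn from the sample's own chain pool,
cellular doublets, and clone-linked phenotype cluster labels. Output is an
``all_contig_annotations.csv``-dialect table plus a cell metadata table and
a ground-truth sidecar, so every emitted contig traces to a true chain, an
ambient event, or a doublet partner.

Defaults encode the reference simulation conditions used throughout the
test-bench: 200 clones with geometric sizes of mean 8 and ~20% of cells in
a few expanded clones, α/β dropout of 0.15/0.10, ambient rate 0.02 and
doublet rate 0.005.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_contigs
from .em_core import clonotype_label
from .io_contigs import ContigTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

# V/J segment pools; TRAV1-2 and TRAV10 are excluded so random draws never
# collide with the semi-invariant MAIT/iNKT definitions
_TRAV_POOL = [f"TRAV{i}" for i in (2, 3, 4, 5, 6, 8, 9, 12, 13, 16, 17, 19, 21, 22, 25, 26, 27, 29, 30, 35, 38, 41)]
_TRAJ_POOL = [f"TRAJ{i}" for i in (4, 6, 9, 11, 13, 15, 16, 17, 21, 23, 26, 28, 29, 31, 34, 37, 39, 42, 45, 49, 53, 57)]
_TRBV_POOL = [f"TRBV{i}" for i in (2, 3, 4, 5, 6, 7, 9, 10, 11, 12, 13, 14, 15, 18, 19, 20, 24, 25, 27, 28, 29, 30)]
_TRBJ_POOL = [f"TRBJ{i}-{j}" for i in (1, 2) for j in (1, 2, 3, 4, 5, 6)]


@dataclass
class SimConfig:
    """Simulation conditions; probabilities are per event, per cell/chain."""

    n_clones: int = 200
    clone_size_dist: str = "geometric"  # or "zipf"
    clone_size_param: float = 8.0  # mean size (geometric) / exponent (zipf)
    expanded_cell_frac: float = 0.2  # fraction of cells placed in expanded clones
    n_expanded: int = 5
    frac_triple_alpha: float = 0.0
    frac_triple_beta: float = 0.0
    min_triple_clone_size: int = 3
    dropout_alpha: float = 0.15
    dropout_beta: float = 0.10
    ambient_rate: float = 0.02
    doublet_rate: float = 0.005
    n_clusters: int = 8
    cluster_concentration: float = 0.5
    umi_mean: float = 4.0  # mean of the shifted negative binomial (min 1)
    umi_shape: float = 2.0
    cdr3_collisions: bool = False  # stress mode: allow CDR3 reuse across clones
    sample: str = "S1"
    seed: int = 1

    def validate(self) -> None:
        probs = {
            "frac_triple_alpha": self.frac_triple_alpha,
            "frac_triple_beta": self.frac_triple_beta,
            "dropout_alpha": self.dropout_alpha,
            "dropout_beta": self.dropout_beta,
            "ambient_rate": self.ambient_rate,
            "doublet_rate": self.doublet_rate,
            "expanded_cell_frac": self.expanded_cell_frac,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_clones < 1:
            raise ValueError("n_clones must be ≥ 1")
        if self.frac_triple_alpha + self.frac_triple_beta > 1.0:
            raise ValueError("frac_triple_alpha + frac_triple_beta must be ≤ 1")
        if self.clone_size_dist not in ("geometric", "zipf"):
            raise ValueError(f"unknown clone_size_dist {self.clone_size_dist!r}")
        if self.umi_mean < 1.0:
            raise ValueError("umi_mean must be ≥ 1 (UMIs are shifted, min 1)")


@dataclass
class SimResult:
    contigs: ContigTable
    cells: pd.DataFrame  # barcode, sample, cluster
    truth: dict
    config: SimConfig = field(repr=False, default=None)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        raw = self.contigs.df.rename(columns={"cdr3_aa": "cdr3"})
        raw.drop(columns=["sample"]).to_csv(outdir / "all_contig_annotations.csv", index=False)
        self.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def _random_cdr3(rng: np.random.Generator, used: set, allow_collisions: bool) -> str:
    """Random CDR3 amino-acid string, C…F convention, length 8–20."""
    for _ in range(10_000):
        length = int(rng.integers(8, 21))
        body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 2))
        cdr3 = "C" + body + "F"
        if allow_collisions or cdr3 not in used:
            used.add(cdr3)
            return cdr3
    raise RuntimeError("could not draw a collision-free CDR3")  # pragma: no cover


def _umi_draw(rng: np.random.Generator, mean: float, shape: float) -> int:
    """Shifted negative binomial, minimum 1."""
    excess = mean - 1.0
    if excess <= 0:
        return 1
    p = shape / (shape + excess)
    return 1 + int(rng.negative_binomial(shape, p))


def _clone_sizes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.clone_size_dist == "geometric":
        sizes = rng.geometric(1.0 / config.clone_size_param, size=config.n_clones)
    else:
        sizes = rng.zipf(config.clone_size_param, size=config.n_clones)
    sizes = sizes.astype(int)
    f = config.expanded_cell_frac
    k = min(config.n_expanded, config.n_clones)
    if f > 0 and k > 0:
        base_total = int(sizes.sum())
        extra_total = int(np.ceil(f * base_total / (1.0 - f))) if f < 1 else base_total * 10
        order = np.argsort(sizes)[::-1][:k]
        per = extra_total // k
        for idx in order:
            sizes[idx] += per
        sizes[order[0]] += extra_total - per * k
    return sizes


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate one sample of synthetic contigs with ground truth.

    Generation order: clone sizes → clone chain sets and segments → clone
    cluster-usage distributions and cell cluster labels → per-cell contig
    emission with UMI counts → dropout → ambient addition → doublet merging
    → serialization in the ``all_contig`` dialect.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    sizes = _clone_sizes(config, rng)

    # clone chain sets
    n_ta = int(round(config.frac_triple_alpha * config.n_clones))
    n_tb = int(round(config.frac_triple_beta * config.n_clones))
    triple_kind = ["alpha"] * n_ta + ["beta"] * n_tb + [None] * (config.n_clones - n_ta - n_tb)
    rng.shuffle(triple_kind)
    used: set = set()
    clones = []
    for cid in range(config.n_clones):
        kind = triple_kind[cid]
        if kind is not None:
            sizes[cid] = max(sizes[cid], config.min_triple_clone_size)
        n_alpha = 2 if kind == "alpha" else 1
        n_beta = 2 if kind == "beta" else 1
        alpha = [_random_cdr3(rng, used, config.cdr3_collisions) for _ in range(n_alpha)]
        beta = [_random_cdr3(rng, used, config.cdr3_collisions) for _ in range(n_beta)]
        segs = {}
        for a in alpha:
            segs[("TRA", a)] = {
                "v_gene": str(rng.choice(_TRAV_POOL)),
                "d_gene": "",
                "j_gene": str(rng.choice(_TRAJ_POOL)),
                "c_gene": "TRAC",
            }
        for b in beta:
            segs[("TRB", b)] = {
                "v_gene": str(rng.choice(_TRBV_POOL)),
                "d_gene": "TRBD1",
                "j_gene": str(rng.choice(_TRBJ_POOL)),
                "c_gene": "TRBC1",
            }
        nts = {
            key: "".join(rng.choice(list(NUCLEOTIDES), size=3 * len(key[1]))) for key in segs
        }
        usage = rng.dirichlet(np.full(config.n_clusters, config.cluster_concentration))
        clones.append(
            {
                "id": cid,
                "alpha": alpha,
                "beta": beta,
                "triple": kind,
                "size": int(sizes[cid]),
                "cluster_usage": usage,
                "segments": segs,
                "cdr3_nt": nts,
            }
        )

    # cells
    cell_records = []
    for clone in clones:
        labels = rng.choice(config.n_clusters, size=clone["size"], p=clone["cluster_usage"])
        for lab in labels:
            cell_records.append({"clone_id": clone["id"], "cluster": int(lab), "events": []})
    n_cells = len(cell_records)
    for i, rec in enumerate(cell_records):
        rec["barcode"] = f"CELL{i:06d}-1"

    # chain pool for ambient contamination, weighted by clone size
    pool = []
    weights = []
    for clone in clones:
        for a in clone["alpha"]:
            pool.append((clone["id"], "TRA", a))
            weights.append(clone["size"])
        for b in clone["beta"]:
            pool.append((clone["id"], "TRB", b))
            weights.append(clone["size"])
    weights = np.array(weights, dtype=float)
    weights /= weights.sum()

    # per-cell chain emission with dropout and ambient events
    cell_chains: list[list] = []  # per cell: (clone_id, chain_type, cdr3, origin)
    for rec in cell_records:
        clone = clones[rec["clone_id"]]
        chains = []
        for a in clone["alpha"]:
            if rng.random() < config.dropout_alpha:
                rec["events"].append(f"dropout:TRA:{a}")
            else:
                chains.append((clone["id"], "TRA", a, "true"))
        for b in clone["beta"]:
            if rng.random() < config.dropout_beta:
                rec["events"].append(f"dropout:TRB:{b}")
            else:
                chains.append((clone["id"], "TRB", b, "true"))
        if rng.random() < config.ambient_rate:
            for _ in range(50):
                src, ct, cdr3 = pool[int(rng.choice(len(pool), p=weights))]
                if all(c[2] != cdr3 for c in chains):
                    chains.append((src, ct, cdr3, "ambient"))
                    rec["events"].append(f"ambient:{ct}:{cdr3}")
                    break
        cell_chains.append(chains)

    # doublets: merge pairs of cells under the host barcode
    n_doublets = int(round(config.doublet_rate * n_cells))
    if n_doublets > 0 and n_cells < 2:
        raise ValueError("doublet_rate requires at least 2 cells")
    doublet_partner = {}
    if n_doublets:
        picks = rng.choice(n_cells, size=2 * n_doublets, replace=False)
        hosts, guests = picks[:n_doublets], picks[n_doublets:]
        for h, g in zip(hosts, guests):
            host, guest = cell_records[h], cell_records[g]
            for chain in cell_chains[g]:
                if all(c[2] != chain[2] for c in cell_chains[h]):
                    cell_chains[h].append((chain[0], chain[1], chain[2], "doublet"))
            host["events"].append(f"doublet:{guest['clone_id']}")
            doublet_partner[h] = guest["clone_id"]
            cell_chains[g] = None  # guest barcode no longer exists
            cell_records[g] = None

    # serialization
    rows = []
    meta_rows = []
    truth_cells = []
    contig_no = 0
    for rec_idx, (rec, chains) in enumerate(zip(cell_records, cell_chains)):
        if rec is None:
            continue
        meta_rows.append({"barcode": rec["barcode"], "sample": config.sample, "cluster": rec["cluster"]})
        truth_cells.append(
            {
                "barcode": rec["barcode"],
                "clone_id": rec["clone_id"],
                "cluster": rec["cluster"],
                "events": rec["events"],
                "doublet_partner_clone": doublet_partner.get(rec_idx, None),
            }
        )
        for src_clone, chain_type, cdr3, origin in chains:
            seg = clones[src_clone]["segments"][(chain_type, cdr3)]
            nt = clones[src_clone]["cdr3_nt"][(chain_type, cdr3)]
            umis = _umi_draw(rng, config.umi_mean, config.umi_shape)
            rows.append(
                {
                    "barcode": rec["barcode"],
                    "is_cell": True,
                    "contig_id": f"{rec['barcode']}_contig_{contig_no}",
                    "high_confidence": True,
                    "length": 420 + len(nt),
                    "chain": chain_type,
                    "v_gene": seg["v_gene"],
                    "d_gene": seg["d_gene"],
                    "j_gene": seg["j_gene"],
                    "c_gene": seg["c_gene"],
                    "full_length": True,
                    "productive": True,
                    "cdr3": cdr3,
                    "cdr3_nt": nt,
                    "reads": umis * int(rng.integers(8, 25)),
                    "umis": umis,
                    "raw_clonotype_id": f"clonotype{src_clone}",
                    "raw_consensus_id": "",
                }
            )
            contig_no += 1

    contig_df = pd.DataFrame(
        rows,
        columns=[
            "barcode", "is_cell", "contig_id", "high_confidence", "length", "chain",
            "v_gene", "d_gene", "j_gene", "c_gene", "full_length", "productive",
            "cdr3", "cdr3_nt", "reads", "umis", "raw_clonotype_id", "raw_consensus_id",
        ],
    )
    table = io_contigs.from_dataframe(contig_df, dialect="all_contig", sample=config.sample)
    cells_df = pd.DataFrame(meta_rows, columns=["barcode", "sample", "cluster"])

    truth = {
        "config": asdict(config),
        "clones": [
            {
                "id": c["id"],
                "alpha": sorted(c["alpha"]),
                "beta": sorted(c["beta"]),
                "label": clonotype_label(c["alpha"], c["beta"]),
                "triple": c["triple"],
                "size": c["size"],
                "cluster_usage": [float(x) for x in c["cluster_usage"]],
            }
            for c in clones
        ],
        "cells": truth_cells,
    }
    return SimResult(contigs=table, cells=cells_df, truth=truth, config=config)


def marginal_check(result: SimResult, alpha: float = 0.01) -> pd.DataFrame:
    """Empirical artifact rates with binomial CIs against the configured values.

    Each row reports one rate (α dropout, β dropout, ambient, doublet), its
    empirical frequency, a Clopper–Pearson ``1 − alpha`` CI, and whether the
    configured value falls outside the CI.
    """
    from statsmodels.stats.proportion import proportion_confint

    config = SimConfig(**result.truth["config"])
    clones = {c["id"]: c for c in result.truth["clones"]}

    n_alpha_true = n_beta_true = 0
    drop_a = drop_b = ambient = doublets = 0
    n_cells = len(result.truth["cells"])
    for cell in result.truth["cells"]:
        clone = clones[cell["clone_id"]]
        n_alpha_true += len(clone["alpha"])
        n_beta_true += len(clone["beta"])
        for ev in cell["events"]:
            if ev.startswith("dropout:TRA"):
                drop_a += 1
            elif ev.startswith("dropout:TRB"):
                drop_b += 1
            elif ev.startswith("ambient:"):
                ambient += 1
            elif ev.startswith("doublet:"):
                doublets += 1

    rows = []
    for name, k, n, target in (
        ("dropout_alpha", drop_a, n_alpha_true, config.dropout_alpha),
        ("dropout_beta", drop_b, n_beta_true, config.dropout_beta),
        ("ambient_rate", ambient, n_cells, config.ambient_rate),
        ("doublet_rate", doublets, n_cells + doublets, config.doublet_rate),
    ):
        if n == 0:
            continue
        lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
        rows.append(
            {
                "rate": name,
                "configured": target,
                "empirical": k / n,
                "n": n,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "flagged": not (lo <= target <= hi),
            }
        )
    return pd.DataFrame(rows)
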