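"""Recurrence-stratified seed-gene co-expression networks.

Networks are anchored on a fixed seed-gene set: Spearman rank correlations
are computed between every seed and every other gene (candidate edges are
seed-gene pairs only), edges below a correlation threshold are discarded,
and each node keeps at most its two most associative candidate edges (the
kept edge set is the union of these per-node nominations, so an edge
survives if either endpoint ranks it in its top two).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import ExpressionMatrix, SeedGeneSet

__all__ = [
    "CoexpressionNetwork",
    "spearman_profile",
    "build_gcn",
    "network_gene_union",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
    "read_graphml",
]

STRATA = ("recurrence", "no_recurrence", "all")


@dataclass
class CoexpressionNetwork:
    """A pruned seed-anchored co-expression network for one outcome stratum.

    ``edges`` are (seed, partner, rho) triples with |rho| >= threshold_r;
    ``nodes`` is the union of incident genes and all seed genes (seeds stay
    as nodes even when isolated).
    """

    stratum: str
    threshold_r: float
    edges: frozenset[tuple[str, str, float]]
    nodes: frozenset[str]
    seed_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}")
        if not (0 < self.threshold_r <= 1):
            raise ValueError("threshold_r must be in (0, 1]")

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.edges}

    def nomination_counts(self) -> dict[str, int]:
        """How many kept edges each node nominated (<= 2 by construction)."""
        return dict(self._nominations)

    _nominations: dict = field(default_factory=dict, repr=False)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for a, b, rho in sorted(self.edges):
            g.add_edge(a, b, rho=float(rho))
        g.graph["stratum"] = self.stratum
        g.graph["threshold_r"] = float(self.threshold_r)
        return g


def spearman_profile(
    m: ExpressionMatrix,
    seeds: SeedGeneSet,
    sample_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Spearman rank correlation of every seed against every gene.

    Returns a seeds x genes DataFrame over the masked samples; diagonal
    (seed vs itself) entries are NaN and never become edge candidates.
    Midranks are used for ties, so this equals Pearson correlation of the
    tied-rank transforms.
    """
    missing = seeds.missing_from(m)
    if missing:
        raise KeyError(f"seed genes absent from matrix: {missing}")
    if sample_mask is None:
        sample_mask = np.ones(m.n_samples, dtype=bool)
    sample_mask = np.asarray(sample_mask, dtype=bool)
    if sample_mask.sum() < 3:
        raise ValueError("need at least 3 masked samples for rank correlation")
    vals = m.values[:, sample_mask]
    ranks = np.apply_along_axis(stats.rankdata, 1, vals)
    z = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((z**2).sum(axis=1))
    norm[norm == 0] = np.nan  # constant gene: correlation undefined
    z = z / norm[:, None]
    seed_idx = m.gene_index(seeds.gene_ids)
    rho = z[seed_idx] @ z.T
    rho = np.clip(rho, -1.0, 1.0)
    df = pd.DataFrame(rho, index=seeds.gene_ids, columns=m.gene_ids)
    for s in seeds.gene_ids:
        df.loc[s, s] = np.nan
    return df


def build_gcn(
    rho: pd.DataFrame,
    threshold_r: float,
    stratum: str = "all",
    *,
    use_abs: bool = True,
) -> CoexpressionNetwork:
    """Threshold the seed-gene correlation profile and prune to top-2 edges.

    Candidate edges are (seed, gene) pairs with |rho| >= threshold_r (signed
    rho >= threshold_r when ``use_abs`` is False).  Every node — seed or
    partner — nominates its two most associative candidate edges (largest
    |rho|, ties broken by the partner identifier); the kept set is the union
    of nominations, which makes the rule monotone in the threshold.
    """
    if not (0 < threshold_r <= 1):
        raise ValueError("threshold_r must be in (0, 1]")
    seeds = [str(s) for s in rho.index]
    genes = [str(g) for g in rho.columns]
    vals = rho.to_numpy(dtype=float)
    strength = np.abs(vals) if use_abs else vals
    with np.errstate(invalid="ignore"):
        cand = np.argwhere(strength >= threshold_r)
    seed_set = set(seeds)
    # canonical key so a seed-seed pair counted once
    candidates: dict[tuple[str, str], float] = {}
    for i, j in cand:
        a, b = seeds[i], genes[j]
        if a == b:
            continue
        key = (min(a, b), max(a, b)) if b in seed_set else (a, b)
        r = float(vals[i, j])
        if key not in candidates or abs(r) > abs(candidates[key]):
            candidates[key] = r
    incident: dict[str, list[tuple[float, str, tuple[str, str]]]] = {}
    for (a, b), r in candidates.items():
        s = abs(r) if use_abs else r
        incident.setdefault(a, []).append((s, b, (a, b)))
        incident.setdefault(b, []).append((s, a, (a, b)))
    kept: set[tuple[str, str]] = set()
    nominations: dict[str, int] = {}
    for node, lst in incident.items():
        lst.sort(key=lambda e: (-e[0], e[1]))
        top = lst[:2]
        nominations[node] = len(top)
        for _, _, key in top:
            kept.add(key)
    edges = frozenset((a, b, candidates[(a, b)]) for a, b in kept)
    nodes = frozenset(seeds) | {a for a, _, _ in edges} | {b for _, b, _ in edges}
    net = CoexpressionNetwork(
        stratum=stratum,
        threshold_r=float(threshold_r),
        edges=edges,
        nodes=nodes,
        seed_ids=tuple(seeds),
    )
    net._nominations = nominations
    return net


def network_gene_union(networks: Sequence[CoexpressionNetwork]) -> list[str]:
    """Deduplicated lexicographically sorted union of node sets."""
    if not networks:
        raise ValueError("need at least one network")
    out: set[str] = set()
    for net in networks:
        out |= net.nodes
    return sorted(out)


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------


def write_edge_list(net: CoexpressionNetwork, path: str | Path) -> None:
    df = pd.DataFrame(sorted(net.edges), columns=["seed", "partner", "rho"])
    df.to_csv(path, sep="\t", index=False)
    # metadata and isolated nodes as comment lines so readers can round-trip
    isolated = sorted(net.nodes - {a for a, _, _ in net.edges} - {b for _, b, _ in net.edges})
    with open(path, "a") as fh:
        fh.write(f"#stratum\t{net.stratum}\n")
        fh.write(f"#threshold_r\t{net.threshold_r!r}\n")
        fh.write(f"#seeds\t{','.join(net.seed_ids)}\n")
        for node in isolated:
            fh.write(f"#node\t{node}\n")


def read_edge_list(path: str | Path) -> CoexpressionNetwork:
    lines = Path(path).read_text().splitlines()
    meta = dict(
        ln[1:].split("\t", 1) for ln in lines if ln.startswith("#") and "\t" in ln and not ln.startswith("#node\t")
    )
    extra_nodes = [ln.split("\t")[1] for ln in lines if ln.startswith("#node\t")]
    seeds = tuple(s for s in meta.get("seeds", "").split(",") if s)
    body = [ln for ln in lines if ln and not ln.startswith("#")]
    edges = set()
    for ln in body[1:]:
        a, b, r = ln.split("\t")
        edges.add((a, b, float(r)))
    nodes = set(extra_nodes) | {a for a, _, _ in edges} | {b for _, b, _ in edges} | set(seeds)
    return CoexpressionNetwork(
        stratum=meta.get("stratum", "all"),
        threshold_r=float(meta.get("threshold_r", 1.0)),
        edges=frozenset(edges),
        nodes=frozenset(nodes),
        seed_ids=seeds,
    )


def write_graphml(net: CoexpressionNetwork, path: str | Path) -> None:
    g = net.to_graph()
    g.graph["seeds"] = ",".join(net.seed_ids)
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> CoexpressionNetwork:
    g = nx.read_graphml(path)
    seeds = tuple(s for s in str(g.graph.get("seeds", "")).split(",") if s)
    seed_set = set(seeds)
    edges = set()
    for a, b, data in g.edges(data=True):
        if a in seed_set or b not in seed_set:
            s, p = a, b
        else:
            s, p = b, a
        if s in seed_set and p in seed_set:
            s, p = min(s, p), max(s, p)
        edges.add((s, p, float(data["rho"])))
    return CoexpressionNetwork(
        stratum=str(g.graph.get("stratum", "all")),
        threshold_r=float(g.graph.get("threshold_r", 1.0)),
        edges=frozenset(edges),
        nodes=frozenset(g.nodes),
        seed_ids=seeds,
    )
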