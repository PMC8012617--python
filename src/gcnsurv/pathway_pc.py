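"""Constraint-based predictive-pathway discovery over a gene panel.

Runs the order-independent (stable) variant of the PC algorithm with
Fisher-z partial-correlation tests to recover an undirected skeleton, then
orients v-structures and applies Meek's rules to produce a CPDAG — the
Markov-equivalence class of directed acyclic graphs consistent with the
observed conditional independencies.  Also ranks genes by their share of
the Wald chi-square within each fitted prognostic model, the importance
measure used to choose which genes enter the pathway graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import ExpressionMatrix
from .model_pipeline import GcnModelResult

__all__ = [
    "PredictivePathway",
    "pc_skeleton",
    "orient_edges",
    "gene_importance",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictivePathway:
    """Skeleton or CPDAG over a gene panel.

    ``undirected`` holds frozenset pairs {a, b}; ``directed`` holds (a, b)
    meaning a -> b.  ``sepsets`` records, for every removed pair, the
    conditioning set that rendered it independent.
    """

    nodes: list[str]
    undirected: set[frozenset]
    directed: set[tuple[str, str]]
    alpha: float
    sepsets: dict[frozenset, tuple[str, ...]]
    max_order: int = 3
    conflicts: list[frozenset] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in self.directed:
            if a == b:
                raise ValueError("self-loop in directed edges")
        for e in self.undirected:
            if len(e) != 2:
                raise ValueError("undirected edge must join two distinct nodes")

    def adjacent(self, a: str) -> set[str]:
        out = {next(iter(e - {a})) for e in self.undirected if a in e}
        out |= {b for x, b in self.directed if x == a}
        out |= {x for x, b in self.directed if b == a}
        return out

    @property
    def n_edges(self) -> int:
        return len(self.undirected) + len(self.directed)


def _partial_corr(corr: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    idx = [i, j, *S]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(sub)
    denom = np.sqrt(prec[0, 0] * prec[1, 1])
    if denom == 0:
        return 0.0
    return float(np.clip(-prec[0, 1] / denom, -1.0, 1.0))


def _fisher_z_p(r: float, n: int, k: int) -> float:
    df = n - k - 3
    if df <= 0:
        return 1.0
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(r) * np.sqrt(df)
    return float(2.0 * stats.norm.sf(abs(z)))


def pc_skeleton(
    m: ExpressionMatrix | pd.DataFrame | np.ndarray,
    *,
    alpha: float = 0.01,
    max_order: int = 3,
    names: Sequence[str] | None = None,
) -> PredictivePathway:
    """PC-stable skeleton from panel expression (samples x genes).

    Starts from the complete graph; at each conditioning order the
    neighborhoods are frozen, and an edge (a, b) is removed when some subset
    S of a frozen neighborhood (|S| = order) yields a Fisher-z partial
    correlation p-value above ``alpha``.  Freezing the neighborhoods per
    order makes the result independent of node ordering.
    """
    if isinstance(m, ExpressionMatrix):
        X = m.values.T
        names = list(m.gene_ids)
    elif isinstance(m, pd.DataFrame):
        X = m.to_numpy(dtype=float)
        names = [str(c) for c in m.columns]
    else:
        X = np.asarray(m, dtype=float)
        names = list(names) if names is not None else [f"g{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if n <= p + max_order:
        raise ValueError("need more samples than panel size + max_order")
    corr = np.corrcoef(X, rowvar=False)
    off = corr - np.eye(p)
    if np.any(np.abs(off) > 1 - 1e-12):
        i, j = np.argwhere(np.abs(off) > 1 - 1e-12)[0]
        raise ValueError(f"collinear genes: {names[i]!r} and {names[j]!r}")

    adj: dict[int, set[int]] = {i: set(range(p)) - {i} for i in range(p)}
    sepsets: dict[frozenset, tuple[str, ...]] = {}
    for order in range(max_order + 1):
        frozen = {i: set(nb) for i, nb in adj.items()}
        any_left = False
        for i in range(p):
            for j in sorted(frozen[i]):
                if j <= i or j not in adj[i]:
                    continue
                removed = False
                for side_i, side_j in ((i, j), (j, i)):
                    nbrs = sorted(frozen[side_i] - {side_j})
                    if len(nbrs) < order:
                        continue
                    any_left = True
                    for S in combinations(nbrs, order):
                        r = _partial_corr(corr, side_i, side_j, S)
                        if _fisher_z_p(r, n, order) > alpha:
                            adj[i].discard(j)
                            adj[j].discard(i)
                            sepsets[frozenset((names[i], names[j]))] = tuple(
                                names[s] for s in S
                            )
                            removed = True
                            break
                    if removed:
                        break
        if not any_left and order > 0:
            break
    undirected = {
        frozenset((names[i], names[j])) for i in range(p) for j in adj[i] if i < j
    }
    return PredictivePathway(
        nodes=list(names),
        undirected=undirected,
        directed=set(),
        alpha=alpha,
        sepsets=sepsets,
        max_order=max_order,
    )


def orient_edges(skel: PredictivePathway) -> PredictivePathway:
    """Orient v-structures and close under Meek's rules, yielding a CPDAG.

    For every non-adjacent pair (a, b) with common neighbor c, the triple is
    oriented a -> c <- b when c is not in sepset(a, b).  Conflicting
    orientation demands leave the edge undirected (logged).  Meek rules 1-4
    are then applied to a fixpoint.
    """
    und = {frozenset(e) for e in skel.undirected}
    dir_: set[tuple[str, str]] = set(skel.directed)
    nodes = skel.nodes
    conflicts: set[frozenset] = set()

    def adjacent(a, b):
        return frozenset((a, b)) in und or (a, b) in dir_ or (b, a) in dir_

    # --- v-structures
    demands: dict[tuple[str, str], int] = {}
    for c in nodes:
        nbrs = [x for x in nodes if x != c and frozenset((x, c)) in und]
        for a, b in combinations(sorted(nbrs), 2):
            if adjacent(a, b):
                continue
            sep = skel.sepsets.get(frozenset((a, b)), ())
            if c not in sep:
                demands[(a, c)] = 1
                demands[(b, c)] = 1
    for (a, c) in list(demands):
        if (c, a) in demands:
            conflicts.add(frozenset((a, c)))
    for (a, c) in demands:
        e = frozenset((a, c))
        if e in conflicts:
            continue
        if e in und:
            und.discard(e)
            dir_.add((a, c))
    if conflicts:
        logger.info("%d conflicting v-structure orientations left undirected", len(conflicts))

    # --- Meek rules to closure
    def orient(a, b) -> bool:
        e = frozenset((a, b))
        if e in und and (b, a) not in dir_:
            und.discard(e)
            dir_.add((a, b))
            return True
        return False

    changed = True
    while changed:
        changed = False
        for e in list(und):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, x - y, z and y non-adjacent  =>  x -> y
                if any((z, x) in dir_ and not adjacent(z, y) for z in nodes if z not in (x, y)):
                    changed |= orient(x, y)
                    break
                # R2: x -> z -> y and x - y  =>  x -> y
                if any((x, z) in dir_ and (z, y) in dir_ for z in nodes if z not in (x, y)):
                    changed |= orient(x, y)
                    break
                # R3: x - z1 -> y, x - z2 -> y, z1,z2 non-adjacent, x - y => x -> y
                zs = [
                    z
                    for z in nodes
                    if z not in (x, y)
                    and frozenset((x, z)) in und
                    and (z, y) in dir_
                ]
                if any(not adjacent(z1, z2) for z1, z2 in combinations(zs, 2)):
                    changed |= orient(x, y)
                    break
                # R4: x - z, z -> w, w -> y, x - y, z and y non-adjacent => x -> y
                hit = False
                for z in nodes:
                    if z in (x, y) or frozenset((x, z)) not in und:
                        continue
                    for w in nodes:
                        if w in (x, y, z):
                            continue
                        if (z, w) in dir_ and (w, y) in dir_ and not adjacent(z, y):
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    changed |= orient(x, y)
                    break
    return PredictivePathway(
        nodes=list(nodes),
        undirected=und,
        directed=dir_,
        alpha=skel.alpha,
        sepsets=dict(skel.sepsets),
        max_order=skel.max_order,
        conflicts=sorted(conflicts, key=sorted),
    )


def gene_importance(
    models: Sequence[GcnModelResult],
    *,
    top_k: int = 12,
    exclude: Sequence[str] = ("node",),
) -> pd.DataFrame:
    """Rank genes by their share of the Wald chi-square within each model.

    Within a model, importance_g = chi2_g / sum(chi2 over the model's
    genes); clinical covariates in ``exclude`` are left out of the
    normalization.  Returns a DataFrame indexed by gene, sorted by the
    summed importance across models (mean as tie-breaker), trimmed to
    ``top_k`` rows.
    """
    per_model: dict[str, dict[int, float]] = {}
    for res in models:
        fit = res.cox_fit
        chi = fit.wald_chi2
        genes = [
            (name, chi[k])
            for k, name in enumerate(fit.covariate_names)
            if name not in exclude
        ]
        total = sum(c for _, c in genes)
        if total == 0:
            continue
        for name, c in genes:
            per_model.setdefault(name, {})[res.model_id] = c / total
    if not per_model:
        return pd.DataFrame(columns=["sum_importance", "mean_importance", "n_models"])
    rows = {
        g: {
            "sum_importance": sum(d.values()),
            "mean_importance": sum(d.values()) / len(d),
            "n_models": len(d),
        }
        for g, d in per_model.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.sort_values(
        by=["sum_importance", "mean_importance"], ascending=False, kind="stable"
    )
    df.index.name = "gene"
    return df.head(top_k)
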