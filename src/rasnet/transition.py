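"""Transition-probability adjustments of RAS-weighted graphs.

Parallel biosynthetic series (e.g. the 0-, a-, b- and c-series of
ganglioside metabolism) are catalyzed step-wise by the same enzymes, so
their raw RAS values are identical and the series cannot be told apart.
Three transition-probability (TP) schemes disambiguate them:

* ``plain``: row-normalize each sample's weighted adjacency W, so t[i, j]
  is the probability a one-step random walker at metabolite i takes the
  reaction to j.
* ``recursive``: every TP equal to 1 (sole outgoing edge) inherits the
  largest plain TP among the incoming edges of its source node,
  recursing upstream until a value != 1 is found; a node without
  incoming edges keeps TP 1.  This propagates the branch decision down
  an unbranched chain.
* ``path``: enumerate all simple paths from a chosen source metabolite
  (lactosylceramide, C01290, in the glycosphingolipid graph — the point
  where the series diverge); each path's probability is the product of
  plain TPs along it, and an edge's new TP aggregates the probabilities
  of all simple paths that end with it (sum by default — on a DAG this
  is the probability that a walker from the source traverses the edge).
  Edges unreachable from the source get TP 0.

The adjusted matrices W1 = W * T, W2 = W * T^a and W3 = W * T^b
(element-wise) lower the RAS values proportionally to the flow the
network topology admits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import MetabolicGraph
from .ras import sample_adjacency

__all__ = [
    "TransitionMatrix",
    "AdjustedRASMatrix",
    "transition_matrix",
    "recursive_tp",
    "path_tp",
    "adjust_ras",
    "scale_reactions",
    "PathExplosionError",
]

_ONE_TOL = 1e-12


class PathExplosionError(RuntimeError):
    """Raised when simple-path enumeration exceeds the configured cap."""


@dataclass
class TransitionMatrix:
    """n x n edge-probability matrix aligned to a graph's node order."""

    values: np.ndarray
    variant: str  # plain | recursive | path
    node_order: tuple[str, ...]
    source_node: str | None = None

    def __post_init__(self) -> None:
        n = len(self.node_order)
        if self.values.shape != (n, n):
            raise ValueError("transition matrix shape does not match node order")
        if self.variant not in ("plain", "recursive", "path"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class AdjustedRASMatrix:
    """Reaction-by-sample matrix after one of the adjustment schemes."""

    values: pd.DataFrame
    scheme: str  # W1 | W2 | W3
    source_node: str | None = None


def transition_matrix(
    W: np.ndarray,
    node_order: tuple[str, ...] | None = None,
) -> TransitionMatrix:
    """Plain TP matrix: divide each element of W by its row sum.

    A row whose outgoing RAS values are all 0 stays all 0: zero
    expression implies zero activity, so no flow is invented there.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("adjacency weights must be non-negative")
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency must be square")
    if node_order is None:
        node_order = tuple(str(i) for i in range(W.shape[0]))
    row_sums = W.sum(axis=1)
    T = np.divide(W, row_sums[:, None], out=np.zeros_like(W),
                  where=row_sums[:, None] > 0)
    return TransitionMatrix(T, "plain", tuple(node_order))


def recursive_tp(T: TransitionMatrix, graph: MetabolicGraph) -> TransitionMatrix:
    """Recursive variant T^a: TP-1 edges inherit the upstream branch TP.

    Every entry with plain TP 1 is replaced by the largest plain TP among
    the incoming edges of its source node; while that value is itself 1,
    the lookup recurses from the corresponding upstream node (always over
    the original plain T, so the result is order-independent).  Ties take
    the lexicographically smallest source node; a node without incoming
    edges — and a cycle of all-1 TPs — keeps TP 1.
    """
    if T.variant != "plain":
        raise ValueError(f"recursive_tp expects the plain variant, got {T.variant}")
    if T.node_order != graph.node_order:
        raise ValueError("transition matrix is not aligned to this graph")
    plain = T.values
    idx = graph.node_index
    g = graph.graph

    def upstream_tp(node: str, visited: frozenset[str]) -> float:
        preds = sorted(g.predecessors(node))
        if not preds:
            return 1.0
        tps = [plain[idx[p], idx[node]] for p in preds]
        best = max(tps)
        src = preds[int(np.argmax(np.isclose(tps, best)))]  # smallest id wins
        if abs(best - 1.0) > _ONE_TOL:
            return best
        if src in visited:
            return 1.0
        return upstream_tp(src, visited | {src})

    out = plain.copy()
    for u, v in g.edges:
        i, j = idx[u], idx[v]
        if abs(plain[i, j] - 1.0) <= _ONE_TOL:
            out[i, j] = upstream_tp(u, frozenset({u}))
    return TransitionMatrix(out, "recursive", T.node_order)


def path_tp(
    T: TransitionMatrix,
    graph: MetabolicGraph,
    x: str,
    combine: str = "sum",
    max_paths: int = 1_000_000,
) -> TransitionMatrix:
    """Path variant T^b: simple-path products from source metabolite ``x``.

    For each simple path P from ``x``, the path probability is the
    product of plain TPs along its edges; the new TP of an edge combines
    the probabilities of all simple paths whose last edge it is
    (``combine="sum"``, default, or ``"max"``).  Edges on no simple path
    from ``x`` get 0.  Enumeration follows only edges with positive
    plain TP and aborts with :class:`PathExplosionError` past
    ``max_paths`` paths.
    """
    if T.variant != "plain":
        raise ValueError(f"path_tp expects the plain variant, got {T.variant}")
    if T.node_order != graph.node_order:
        raise ValueError("transition matrix is not aligned to this graph")
    if x not in graph.node_index:
        raise KeyError(f"source node {x!r} not in graph")
    if combine not in ("sum", "max"):
        raise ValueError(f"unknown combine mode {combine!r}")
    plain = T.values
    idx = graph.node_index
    g = graph.graph
    acc = np.zeros_like(plain)
    n_paths = 0

    def dfs(u: str, prod: float, visited: set[str]) -> None:
        nonlocal n_paths
        for v in sorted(g.successors(u)):
            if v in visited:
                continue
            t = plain[idx[u], idx[v]]
            if t <= 0.0:
                continue
            p = prod * t
            n_paths += 1
            if n_paths > max_paths:
                raise PathExplosionError(
                    f"more than {max_paths} simple paths from {x!r}")
            i, j = idx[u], idx[v]
            if combine == "sum":
                acc[i, j] += p
            else:
                acc[i, j] = max(acc[i, j], p)
            visited.add(v)
            dfs(v, p, visited)
            visited.remove(v)

    dfs(x, 1.0, {x})
    if (acc > 1.0 + 1e-9).any():
        warnings.warn(
            "path TP entries exceed 1 (cyclic graph); values reported as-is",
            stacklevel=2)
    return TransitionMatrix(acc, "path", T.node_order, source_node=x)


def _scheme_tp(
    scheme: str,
    W: np.ndarray,
    graph: MetabolicGraph,
    x: str | None,
    combine: str,
    max_paths: int,
) -> TransitionMatrix:
    T = transition_matrix(W, graph.node_order)
    if scheme == "W1":
        return T
    if scheme == "W2":
        return recursive_tp(T, graph)
    if scheme == "W3":
        if x is None:
            raise ValueError("scheme W3 requires a source metabolite x")
        return path_tp(T, graph, x, combine=combine, max_paths=max_paths)
    raise ValueError(f"unknown scheme {scheme!r} (expected W1, W2 or W3)")


def adjust_ras(
    ras: pd.DataFrame,
    graph: MetabolicGraph,
    scheme: str,
    x: str | None = None,
    combine: str = "sum",
    max_paths: int = 1_000_000,
) -> AdjustedRASMatrix:
    """Apply one adjustment scheme to every sample of a RAS matrix.

    Per sample: build the weighted adjacency W, compute the scheme's TP
    matrix from it, multiply element-wise, and collect the edge weights
    back into the reaction-by-sample layout.
    """
    if set(ras.index) != set(graph.reaction_ids):
        raise ValueError("RAS matrix rows do not match the graph's reactions")
    idx = graph.node_index
    edges = graph.edges()
    out = pd.DataFrame(0.0, index=list(graph.reaction_ids), columns=ras.columns)
    for sample in ras.columns:
        W = sample_adjacency(graph, ras, sample)
        T = _scheme_tp(scheme, W, graph, x, combine, max_paths)
        A = W * T.values
        for e in edges:
            out.loc[e.reaction_id, sample] = A[idx[e.source], idx[e.target]]
    return AdjustedRASMatrix(out, scheme, source_node=x if scheme == "W3" else None)


def scale_reactions(adj: AdjustedRASMatrix | pd.DataFrame) -> pd.DataFrame:
    """Standardize reactions for embedding: drop dead rows, z-score the rest.

    Reactions outside every possible path (all-zero rows) are removed;
    remaining rows are centered to mean 0 and scaled to unit variance
    across samples (sample standard deviation), making the scores
    homoscedastic.  Constant non-zero rows carry no signal and are
    dropped with a warning.
    """
    values = adj.values if isinstance(adj, AdjustedRASMatrix) else adj
    if values.shape[1] < 2:
        raise ValueError("scaling requires at least 2 samples")
    nonzero = values.loc[(values != 0).any(axis=1)]
    sd = nonzero.std(axis=1, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(
            f"{len(constant)} constant reaction row(s) dropped before "
            f"scaling: {list(constant[:5])}", stacklevel=2)
    kept = nonzero.drop(index=constant)
    return kept.sub(kept.mean(axis=1), axis=0).div(sd.drop(constant), axis=0)
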