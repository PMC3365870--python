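"""Directed-graph machinery for the network escape problem.

Networks of identical bistable nodes are described by directed,
unweighted, *unlabelled* graphs: nodes are interchangeable, so topologies
are compared up to isomorphism.  This module provides exhaustive
enumeration of the isomorphism classes of small digraphs, connectivity
classification, the *first transitive component* (FTC) -- the union of
source components of the strongly-connected-component condensation,
which governs escape at strong coupling -- the per-node out-minus-in
degree balance vector u that drives the centre-of-mass coupling term,
and the combinatorial escape-time score exp((N - |u|)/Ne) exponent.

Adjacency convention throughout: ``M[i, j] = 1`` means an edge i -> j
(node i influences node j).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "DirectedGraph",
    "FTCResult",
    "BalanceSummary",
    "canonical_form",
    "enumerate_digraphs",
    "connectivity_class",
    "first_transitive_component",
    "balance_summary",
    "com_coupling_term",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
    "write_graph_summary",
]

_CANONICAL_SIZE_CAP = 8


@dataclass(frozen=True)
class DirectedGraph:
    """An unweighted digraph without self-loops.

    Stores the binary adjacency matrix; ``adjacency[i, j] = 1`` iff there
    is an edge i -> j.  Node labels are 0-based integers.
    """

    n_nodes: int
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=int)
        if adj.shape != (self.n_nodes, self.n_nodes):
            raise ValueError(
                f"adjacency shape {adj.shape} inconsistent with n_nodes={self.n_nodes}"
            )
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.trace(adj) != 0:
            raise ValueError("self-loops are not allowed")
        if self.n_nodes < 1:
            raise ValueError("graph must have at least one node")
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)

    @classmethod
    def from_edges(cls, n_nodes: int, edges: "list[tuple[int, int]] | set") -> "DirectedGraph":
        adj = np.zeros((n_nodes, n_nodes), dtype=int)
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-loop {i}->{j} not allowed")
            adj[i, j] = 1
        return cls(n_nodes, adj)

    @classmethod
    def complete(cls, n_nodes: int) -> "DirectedGraph":
        adj = np.ones((n_nodes, n_nodes), dtype=int) - np.eye(n_nodes, dtype=int)
        return cls(n_nodes, adj)

    @classmethod
    def empty(cls, n_nodes: int) -> "DirectedGraph":
        return cls(n_nodes, np.zeros((n_nodes, n_nodes), dtype=int))

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in zip(*np.nonzero(self.adjacency))}

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def out_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def in_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def subgraph(self, nodes: "frozenset[int] | set[int]") -> "DirectedGraph":
        """Induced subgraph on ``nodes``, relabelled 0..len-1 in sorted order."""
        idx = sorted(nodes)
        return DirectedGraph(len(idx), self.adjacency[np.ix_(idx, idx)])


@dataclass(frozen=True)
class FTCResult:
    """First transitive component of a digraph.

    The FTC is the set of minimal nodes of the reachability partial order
    (A << B iff there is a directed path A -> B): equivalently the union
    of source components of the SCC condensation.  It is strongly
    connected (a single source SCC) or disconnected (several mutually
    unreachable source SCCs) -- never merely weakly connected.
    """

    member_nodes: frozenset[int]
    is_strongly_connected_ftc: bool
    is_disconnected_ftc: bool


@dataclass(frozen=True)
class BalanceSummary:
    """Degree balance and the combinatorial escape-time score.

    ``u[i]`` is out-degree minus in-degree of node i; a *balanced* graph
    (u = 0: unions of disjoint cycles, including all bidirectional
    graphs) maximises escape time among same-size networks.
    ``eq_score = (N - |u|) / Ne`` is the exponent of the empirical
    strong-coupling scaling law E[tau] ~ exp((N - |u|)/Ne), computed by
    default over the FTC subgraph (N = FTC node count, u and Ne within
    the FTC); ``nan`` when the scoped subgraph has no edges.
    """

    u: np.ndarray
    u_norm: float
    is_balanced: bool
    n_ftc: int
    n_edges: int
    scaling_score: float


def canonical_form(g: DirectedGraph) -> tuple[int, ...]:
    """Canonical key identifying the isomorphism class of ``g``.

    Brute force over all node permutations (correct by construction at
    this scale): the key is the lexicographically minimal row-major
    adjacency bit-string.  Identical keys iff the unlabelled digraphs
    are isomorphic.
    """
    n = g.n_nodes
    if n > _CANONICAL_SIZE_CAP:
        raise ValueError(f"canonical_form is brute-force; n_nodes={n} exceeds cap {_CANONICAL_SIZE_CAP}")
    adj = g.adjacency
    best: tuple[int, ...] | None = None
    for perm in itertools.permutations(range(n)):
        p = np.asarray(perm)
        key = tuple(adj[np.ix_(p, p)].ravel())
        if best is None or key < best:
            best = key
    assert best is not None
    return best


def connectivity_class(g: DirectedGraph) -> str:
    """One of ``strong``, ``weak`` (connected only when directions are
    ignored) or ``disconnected``.  A single node is strongly connected."""
    ng = g.to_networkx()
    if nx.is_strongly_connected(ng):
        return "strong"
    if nx.is_weakly_connected(ng):
        return "weak"
    return "disconnected"


def enumerate_digraphs(n: int, connectivity: str = "all") -> list[DirectedGraph]:
    """One representative per isomorphism class of n-node digraphs.

    ``connectivity`` filters classes: ``all`` (no filter), ``weak``
    (at least weakly connected, i.e. weak or strong) or ``strong``.
    Exhaustive over the 2^(n(n-1)) labelled graphs; deterministic output
    order by canonical key.
    """
    if n > 4:
        raise ValueError(f"exhaustive enumeration capped at n=4, got {n}")
    if connectivity not in ("all", "weak", "strong"):
        raise ValueError(f"unknown connectivity filter {connectivity!r}")
    slots = [(i, j) for i in range(n) for j in range(n) if i != j]
    seen: dict[tuple[int, ...], DirectedGraph] = {}
    for mask in range(2 ** len(slots)):
        adj = np.zeros((n, n), dtype=int)
        for b, (i, j) in enumerate(slots):
            if mask >> b & 1:
                adj[i, j] = 1
        g = DirectedGraph(n, adj)
        key = canonical_form(g)
        if key in seen:
            continue
        cls = connectivity_class(g)
        if connectivity == "strong" and cls != "strong":
            continue
        if connectivity == "weak" and cls == "disconnected":
            continue
        seen[key] = g
    return [seen[k] for k in sorted(seen)]


def first_transitive_component(g: DirectedGraph) -> FTCResult:
    """First transitive component: union of source SCCs of the condensation.

    For a strongly connected graph this is the whole node set.  The FTC
    subgraph is strongly connected iff there is exactly one source SCC;
    with several source SCCs it is disconnected (they cannot reach each
    other, or they would share an SCC).
    """
    ng = g.to_networkx()
    sccs = list(nx.strongly_connected_components(ng))
    cond = nx.condensation(ng, scc=sccs)
    source_comps = [c for c in cond.nodes if cond.in_degree(c) == 0]
    members: set[int] = set()
    for c in source_comps:
        members |= cond.nodes[c]["members"]
    single = len(source_comps) == 1
    return FTCResult(
        member_nodes=frozenset(members),
        is_strongly_connected_ftc=single,
        is_disconnected_ftc=not single,
    )


def _u_vector(g: DirectedGraph) -> np.ndarray:
    return (g.out_degrees() - g.in_degrees()).astype(int)


def balance_summary(g: DirectedGraph, norm: str = "L2", scope: str = "ftc") -> BalanceSummary:
    """Balance vector, its norm, and the strong-coupling escape score.

    ``norm`` selects |u| as the Euclidean (``L2``, default: u enters the
    centre-of-mass dynamics through a dot product) or ``L1`` norm.
    ``scope`` selects whether N, u and Ne in the score refer to the FTC
    subgraph (default: escape at strong coupling depends only on the
    FTC) or the whole graph.
    """
    if norm not in ("L1", "L2"):
        raise ValueError(f"norm must be 'L1' or 'L2', got {norm!r}")
    if scope not in ("ftc", "whole"):
        raise ValueError(f"scope must be 'ftc' or 'whole', got {scope!r}")
    u = _u_vector(g)
    ftc = first_transitive_component(g)
    if scope == "ftc":
        sub = g.subgraph(ftc.member_nodes)
        u_scoped = _u_vector(sub)
        n_scoped, ne_scoped = sub.n_nodes, sub.n_edges
    else:
        u_scoped, n_scoped, ne_scoped = u, g.n_nodes, g.n_edges
    ord_ = 1 if norm == "L1" else 2
    u_norm = float(np.linalg.norm(u_scoped, ord=ord_))
    score = (n_scoped - u_norm) / ne_scoped if ne_scoped else float("nan")
    return BalanceSummary(
        u=u,
        u_norm=u_norm,
        is_balanced=bool(np.all(u == 0)),
        n_ftc=len(ftc.member_nodes),
        n_edges=ne_scoped,
        scaling_score=score,
    )


def com_coupling_term(g: DirectedGraph, states: np.ndarray, beta: float) -> complex:
    """Coupling contribution (beta/N) u . z to the centre-of-mass velocity.

    The diffusive coupling moves the network mean state only through the
    projection of the states onto the balance vector u; for balanced
    graphs (u = 0) and for synchronised states the term vanishes.
    """
    states = np.asarray(states)
    if states.shape != (g.n_nodes,):
        raise ValueError(f"states shape {states.shape} != ({g.n_nodes},)")
    u = _u_vector(g)
    return complex(beta / g.n_nodes * np.dot(u, states))


# ---------------------------------------------------------------------------
# Graph I/O: whitespace-delimited edge list with a "# nodes N" header,
# square 0/1 adjacency matrices, and a JSON summary sidecar.

def write_edge_list(g: DirectedGraph, path: str | Path) -> None:
    lines = [f"# nodes {g.n_nodes}"]
    lines += [f"{i} {j}" for i, j in sorted(g.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> DirectedGraph:
    n = None
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] == "nodes":
                n = int(parts[1])
            continue
        i, j = line.split()
        edges.append((int(i), int(j)))
    if n is None:
        raise ValueError(f"{path}: missing '# nodes N' header")
    return DirectedGraph.from_edges(n, edges)


def write_adjacency(g: DirectedGraph, path: str | Path) -> None:
    np.savetxt(path, g.adjacency, fmt="%d")


def read_adjacency(path: str | Path) -> DirectedGraph:
    adj = np.loadtxt(path, dtype=int, ndmin=2)
    return DirectedGraph(adj.shape[0], adj)


def write_graph_summary(g: DirectedGraph, path: str | Path, norm: str = "L2") -> None:
    """JSON sidecar with FTC membership, balance vector and escape score."""
    ftc = first_transitive_component(g)
    bal = balance_summary(g, norm=norm)
    payload = {
        "n_nodes": g.n_nodes,
        "n_edges": g.n_edges,
        "connectivity": connectivity_class(g),
        "ftc_members": sorted(ftc.member_nodes),
        "ftc_strongly_connected": ftc.is_strongly_connected_ftc,
        "u": bal.u.tolist(),
        "u_norm": bal.u_norm,
        "is_balanced": bal.is_balanced,
        "scaling_score": None if np.isnan(bal.scaling_score) else bal.scaling_score,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
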