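"""Interaction-graph construction, centrality reporting and optimization.

Three families of topologies are supported: the fully connected graph, the
star (one hub connected to ``n`` leaves — "size n" throughout means n leaves
plus the hub, n+1 nodes), and connected 3-regular graphs optimized for a
centrality objective by a connectivity-preserving double-edge-swap annealer.

The star comes with a role-bias policy: in ``star-speaker`` mode a hub of
degree d takes the speaker role with probability (d-1)/d whenever it plays
(information flows hub → periphery); ``star-hearer`` is the mirror image;
``balanced`` assigns roles by a fair coin.

All per-node measures follow the usual conventions: betweenness is
normalized by (n-1)(n-2)/2 per node, closeness is (n-1) divided by the sum
of distances, clustering is the triangle density of the neighborhood, and
constraint is Burt's structural-holes measure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

__all__ = [
    "Topology",
    "CentralityReport",
    "build_complete",
    "build_star",
    "betweenness",
    "closeness",
    "clustering",
    "burt_constraint",
    "radius_diameter",
    "mean_betweenness",
    "mean_closeness",
    "centrality_report",
    "optimize_regular_topology",
    "enumerate_cubic_graphs",
    "assign_roles",
    "save_edgelist",
    "load_edgelist",
    "save_graphml",
    "load_graphml",
]

ROLE_MODES = ("balanced", "star-speaker", "star-hearer")

OBJECTIVES = (
    "avg-betweenness",
    "max-betweenness",
    "max-closeness",
    "avg-clustering",
    "var-constraint",
)


@dataclass(frozen=True)
class Topology:
    """An undirected simple connected interaction graph plus a role policy."""

    graph: nx.Graph
    kind: str = "generic"
    role_mode: str = "balanced"
    hub: int | None = None

    def __post_init__(self) -> None:
        g = self.graph
        if g.number_of_nodes() < 2:
            raise ValueError("topology needs at least 2 nodes")
        if any(g.has_edge(v, v) for v in g):
            raise ValueError("self-loops are not allowed")
        if not nx.is_connected(g):
            raise ValueError("topology must be connected")
        if self.role_mode not in ROLE_MODES:
            raise ValueError(f"unknown role mode: {self.role_mode!r}")
        if self.role_mode != "balanced" and self.hub is None:
            raise ValueError("role-biased star policies require a hub")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [tuple(sorted(e)) for e in self.graph.edges()]

    def with_role_mode(self, mode: str) -> "Topology":
        return replace(self, role_mode=mode)


@dataclass(frozen=True)
class CentralityReport:
    """Structural summary of a topology (per-node values plus aggregates)."""

    radius: int
    diameter: int
    closeness: dict[int, float]
    betweenness: dict[int, float]
    clustering: dict[int, float]
    constraint: dict[int, float]

    @property
    def mean_closeness(self) -> float:
        return float(np.mean(list(self.closeness.values())))

    @property
    def mean_betweenness(self) -> float:
        return float(np.mean(list(self.betweenness.values())))

    @property
    def mean_clustering(self) -> float:
        return float(np.mean(list(self.clustering.values())))

    @property
    def var_constraint(self) -> float:
        return float(np.var(list(self.constraint.values())))

    def summary(self) -> dict[str, float]:
        """One row mirroring the usual structural-properties table."""
        return {
            "radius": self.radius,
            "diameter": self.diameter,
            "closeness": round(self.mean_closeness, 2),
            "betweenness": round(self.mean_betweenness, 2),
            "clustering": round(self.mean_clustering, 2),
        }


def build_complete(n: int) -> Topology:
    """Fully connected graph on ``n`` nodes (the unrestricted baseline)."""
    if n < 2:
        raise ValueError("complete graph needs n >= 2")
    return Topology(graph=nx.complete_graph(n), kind="complete")


def build_star(n_leaves: int, mode: str = "balanced") -> Topology:
    """Star with ``n_leaves`` leaves around hub node 0 (n_leaves+1 nodes)."""
    if n_leaves < 2:
        raise ValueError("star needs at least 2 leaves")
    return Topology(graph=nx.star_graph(n_leaves), kind="star",
                    role_mode=mode, hub=0)


def _graph_of(t: Topology | nx.Graph) -> nx.Graph:
    return t.graph if isinstance(t, Topology) else t


def _require_connected(g: nx.Graph) -> None:
    if not nx.is_connected(g):
        raise ValueError("graph must be connected")


def betweenness(t: Topology | nx.Graph) -> dict[int, float]:
    """Normalized shortest-path betweenness, divisor (n-1)(n-2)/2 per node."""
    g = _graph_of(t)
    _require_connected(g)
    return nx.betweenness_centrality(g, normalized=True)


def closeness(t: Topology | nx.Graph) -> dict[int, float]:
    g = _graph_of(t)
    _require_connected(g)
    return nx.closeness_centrality(g)


def clustering(t: Topology | nx.Graph) -> dict[int, float]:
    return nx.clustering(_graph_of(t))


def burt_constraint(t: Topology | nx.Graph) -> dict[int, float]:
    g = _graph_of(t)
    if any(d == 0 for _, d in g.degree()):
        raise ValueError("constraint undefined for isolated nodes")
    return {v: float(c) for v, c in nx.constraint(g).items()}


def radius_diameter(t: Topology | nx.Graph) -> tuple[int, int]:
    g = _graph_of(t)
    _require_connected(g)
    ecc = nx.eccentricity(g)
    return min(ecc.values()), max(ecc.values())


def mean_betweenness(t: Topology | nx.Graph) -> float:
    return float(np.mean(list(betweenness(t).values())))


def mean_closeness(t: Topology | nx.Graph) -> float:
    return float(np.mean(list(closeness(t).values())))


def centrality_report(t: Topology | nx.Graph) -> CentralityReport:
    r, d = radius_diameter(t)
    return CentralityReport(
        radius=r,
        diameter=d,
        closeness=closeness(t),
        betweenness=betweenness(t),
        clustering=clustering(t),
        constraint=burt_constraint(t),
    )


# ---------------------------------------------------------------------------
# Optimized degree-regular topologies


def _objective_value(g: nx.Graph, objective: str) -> float:
    if objective == "avg-betweenness":
        return float(np.mean(list(
            nx.betweenness_centrality(g, normalized=True).values())))
    if objective == "max-betweenness":
        return float(max(
            nx.betweenness_centrality(g, normalized=True).values()))
    if objective == "max-closeness":
        return float(max(nx.closeness_centrality(g).values()))
    if objective == "avg-clustering":
        return float(np.mean(list(nx.clustering(g).values())))
    if objective == "var-constraint":
        return float(np.var(list(nx.constraint(g).values())))
    raise ValueError(f"unknown objective: {objective!r}")


def optimize_regular_topology(
    n: int,
    degree: int = 3,
    objective: str = "avg-betweenness",
    direction: str = "minimize",
    seed: int = 0,
    n_steps: int = 20_000,
    t_initial: float = 0.02,
    cooling: float = 0.9995,
) -> Topology:
    """Search connected ``degree``-regular graphs for a centrality optimum.

    Simulated annealing over double-edge swaps: a proposed move replaces
    edges (a,b),(c,d) by (a,c),(b,d), which preserves every node degree;
    moves that break simplicity or connectivity are rejected.  Geometric
    cooling; the best graph seen is returned.  Deterministic for fixed seed.
    """
    if n * degree % 2 != 0:
        raise ValueError("n * degree must be even")
    if n <= degree:
        raise ValueError("need n > degree")
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective: {objective!r}")
    if direction not in ("minimize", "maximize"):
        raise ValueError("direction must be 'minimize' or 'maximize'")
    sign = 1.0 if direction == "minimize" else -1.0
    rng = np.random.default_rng(seed)

    g = nx.random_regular_graph(degree, n, seed=int(rng.integers(2**31)))
    while not nx.is_connected(g):
        g = nx.random_regular_graph(degree, n, seed=int(rng.integers(2**31)))

    current = sign * _objective_value(g, objective)
    best_g, best_val = g.copy(), current
    temp = t_initial
    for _ in range(n_steps):
        temp *= cooling
        edges = list(g.edges())
        i, j = rng.choice(len(edges), size=2, replace=False)
        (a, b), (c, d) = edges[i], edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # simplicity: no self-loops or duplicate edges after the swap
        if len({a, b, c, d}) < 4 or g.has_edge(a, c) or g.has_edge(b, d):
            continue
        g.remove_edges_from([(a, b), (c, d)])
        g.add_edges_from([(a, c), (b, d)])
        if not nx.is_connected(g):
            g.remove_edges_from([(a, c), (b, d)])
            g.add_edges_from([(a, b), (c, d)])
            continue
        candidate = sign * _objective_value(g, objective)
        delta = candidate - current
        if delta <= 0 or rng.random() < math.exp(-delta / max(temp, 1e-12)):
            current = candidate
            if current < best_val:
                best_val = current
                best_g = g.copy()
        else:
            g.remove_edges_from([(a, c), (b, d)])
            g.add_edges_from([(a, b), (c, d)])
    return Topology(graph=best_g, kind="regular-optimized")


def enumerate_cubic_graphs(n: int) -> list[Topology]:
    """All connected 3-regular simple graphs on ``n`` labeled nodes, one
    representative per isomorphism class, ordered by canonical edge list.

    Exhaustive backtracking; refused for n > 10 (combinatorial blow-up).
    """
    if n > 10:
        raise ValueError("enumeration refused for n > 10")
    if n < 4 or (3 * n) % 2 != 0:
        raise ValueError("need even n with 4 <= n <= 10")

    # Symmetry pruning: every cubic graph can be relabeled so that node 0 is
    # adjacent to exactly {1, 2, 3}, so enumerating under that constraint
    # still visits every isomorphism class (possibly several times).
    degree = [0] * n
    adj = [set() for _ in range(n)]
    for u in (1, 2, 3):
        adj[0].add(u)
        adj[u].add(0)
        degree[u] += 1
    degree[0] = 3

    buckets: dict[tuple, list[nx.Graph]] = {}

    def record() -> None:
        # connectivity by BFS on the adjacency sets (cheap hot path)
        seen = {0}
        frontier = [0]
        while frontier:
            v = frontier.pop()
            for u in adj[v]:
                if u not in seen:
                    seen.add(u)
                    frontier.append(u)
        if len(seen) != n:
            return
        a = np.zeros((n, n))
        for i in range(n):
            for j in adj[i]:
                a[i, j] = 1.0
        # spectral invariant as bucket key; exact isomorphism check within
        key = tuple(np.round(np.linalg.eigvalsh(a), 6))
        reps = buckets.setdefault(key, [])
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((i, j) for i in range(n) for j in adj[i] if i < j)
        if any(nx.is_isomorphic(g, h) for h in reps):
            return
        reps.append(g)

    def backtrack() -> None:
        try:
            v = next(i for i in range(n) if degree[i] < 3)
        except StopIteration:
            record()
            return
        need = 3 - degree[v]
        candidates = [u for u in range(v + 1, n)
                      if degree[u] < 3 and u not in adj[v]]
        for combo in itertools.combinations(candidates, need):
            for u in combo:
                adj[v].add(u)
                adj[u].add(v)
                degree[v] += 1
                degree[u] += 1
            backtrack()
            for u in combo:
                adj[v].remove(u)
                adj[u].remove(v)
                degree[v] -= 1
                degree[u] -= 1

    backtrack()

    reps = [g for group in buckets.values() for g in group]
    reps.sort(key=lambda g: sorted(tuple(sorted(e)) for e in g.edges()))
    return [Topology(graph=g, kind="regular-optimized") for g in reps]


def assign_roles(
    t: Topology,
    edge: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Assign (speaker, hearer) roles to the two endpoints of ``edge``.

    Balanced mode flips a fair coin.  In star-speaker (star-hearer) mode a
    hub of degree d takes the speaker (hearer) role with probability
    (d-1)/d; if the hub is not on the edge a fair coin is used.
    """
    u, v = edge
    if not t.graph.has_edge(u, v):
        raise ValueError(f"edge {edge} not in topology")
    if t.role_mode != "balanced" and t.hub in (u, v):
        hub = t.hub
        other = v if u == hub else u
        d = t.graph.degree(hub)
        hub_takes_biased_role = rng.random() < (d - 1) / d
        if t.role_mode == "star-speaker":
            return (hub, other) if hub_takes_biased_role else (other, hub)
        return (other, hub) if hub_takes_biased_role else (hub, other)
    return (u, v) if rng.random() < 0.5 else (v, u)


def save_edgelist(t: Topology, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(t.edges):
            fh.write(f"{u} {v}\n")


def load_edgelist(path, kind: str = "generic",
                  role_mode: str = "balanced",
                  hub: int | None = None) -> Topology:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            if line.strip():
                u, v = line.split()
                g.add_edge(int(u), int(v))
    return Topology(graph=g, kind=kind, role_mode=role_mode, hub=hub)


def save_graphml(t: Topology, path) -> None:
    nx.write_graphml(t.graph, path)


def load_graphml(path, kind: str = "generic",
                 role_mode: str = "balanced",
                 hub: int | None = None) -> Topology:
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, {v: int(v) for v in g.nodes()})
    return Topology(graph=g, kind=kind, role_mode=role_mode, hub=hub)
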