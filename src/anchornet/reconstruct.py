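"""Anchored subnetwork reconstruction and near-optimal solution ensembles.

Given a weighted interaction network, an anchor set A and a terminal set T,
the task is to find a connected subnetwork H linking every terminal to the
anchor set while simultaneously minimizing two criteria: the *local* one
(the shortest-path length from the anchor set to each terminal inside H)
and the *global* one (the total edge length of H).  Edge lengths are
−ln(confidence), so path length is the negative log-reliability of the
path.  The trade-off is governed by alpha in [0, 0.5]:

    f_alpha(H) = (1 − 2·alpha) · Σ_t d_H(A, t)  +  2·alpha · Σ_e len(e)

alpha = 0 is the pure local criterion (shortest-path union), alpha = 0.5 the
pure global one (a Steiner tree over A ∪ T), alpha = 0.25 weighs both
equally.  Multiple anchors are handled through a virtual root joined to all
anchors by zero-length edges; solutions are trees over the rooted graph and
the root is stripped from every output.

Exact solutions are computed with a Dreyfus–Wagner style dynamic program
over terminal subsets, generalized to the cost-distance objective: a tree
edge shared by the root paths of k terminals costs (2·alpha + (1−2·alpha)·k)
times its length, so the subset-growing step is a Dijkstra relaxation with
a mask-dependent edge multiplier.  An independent brute-force enumerator
over all rooted subtrees serves as the oracle on small instances.

Near-optimal ensembles collect distinct solutions whose objective is within
a multiplicative margin of the optimum (margin 1.2 = 20% deviation); the
fraction of ensemble members containing a node is that node's confidence.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import QueryError
from .network_io import InteractionNetwork

#: Sentinel node connecting all anchors with zero-length edges.
VIRTUAL_ROOT = "__ANCHORNET_ROOT__"

#: Relative slack when admitting a solution at the margin threshold.
_MARGIN_RTOL = 1e-9

#: Instances at or below this node count support exhaustive enumeration.
EXACT_THRESHOLD = 12

#: The subset DP stays exact (and affordable) up to this many terminals.
EXACT_TERMINAL_LIMIT = 6


def _pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True, eq=False)
class QueryInstance:
    """One anchored reconstruction problem."""

    network: InteractionNetwork
    anchors: frozenset[str]
    terminals: frozenset[str]
    alpha: float
    margin: float = 1.0

    def __init__(self, network, anchors, terminals, alpha, margin=1.0):
        object.__setattr__(self, "network", network)
        object.__setattr__(self, "anchors", frozenset(anchors))
        object.__setattr__(self, "terminals", frozenset(terminals))
        object.__setattr__(self, "alpha", float(alpha))
        object.__setattr__(self, "margin", float(margin))
        self._validate()

    def _validate(self) -> None:
        if not self.anchors or not self.terminals:
            raise QueryError("anchors and terminals must both be non-empty")
        if not (0.0 <= self.alpha <= 0.5):
            raise QueryError(f"alpha {self.alpha} outside [0, 0.5]")
        if self.margin < 1.0:
            raise QueryError(f"margin {self.margin} must be >= 1")
        missing = (self.anchors | self.terminals) - self.network.nodes
        if missing:
            raise QueryError(f"nodes not in network: {sorted(missing)}")
        overlap = self.anchors & self.terminals
        if overlap:
            raise QueryError(f"anchors and terminals overlap: {sorted(overlap)}")
        unreachable = sorted(self.terminals - self._reachable_from_anchors())
        if unreachable:
            raise QueryError(f"terminals unreachable from anchors: {unreachable}")

    def _reachable_from_anchors(self) -> set[str]:
        seen = set(self.anchors)
        stack = list(self.anchors)
        while stack:
            u = stack.pop()
            for v in self.network.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    def base_lengths(self) -> dict[tuple[str, str], float]:
        """−ln(confidence) per network edge plus zero-length root edges.

        Cached on the instance; treat the returned mapping as read-only.
        """
        cached = self.__dict__.get("_base_lengths")
        if cached is None:
            cached = {it.pair: it.length
                      for it in self.network.interactions()}
            for a in sorted(self.anchors):
                cached[_pair(VIRTUAL_ROOT, a)] = 0.0
            object.__setattr__(self, "_base_lengths", cached)
        return cached


@dataclass(frozen=True)
class Subnetwork:
    """A solution: tree-structured after re-adding the virtual root."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    objective: float
    terminal_distances: dict[str, float] = field(compare=False, hash=False,
                                                 default_factory=dict)

    def sort_key(self) -> tuple:
        return (self.objective, len(self.edges), sorted(self.edges))


@dataclass(frozen=True, eq=False)
class SolutionEnsemble:
    """Margin-bounded set of near-optimal solutions with node confidences."""

    instance: QueryInstance
    optimum: Subnetwork
    members: tuple[Subnetwork, ...]
    node_confidence: dict[str, float]


# ---------------------------------------------------------------------------
# Deterministic shortest-path machinery (tolerates zero-length edges)
# ---------------------------------------------------------------------------

def _dijkstra_tree(g: nx.Graph, source: str):
    """Distances and parent pointers of a deterministic shortest-path tree.

    A node's parent is fixed at the moment the node is finalized, so the
    parent map is acyclic even in the presence of zero-length ties.
    """
    dist: dict[str, float] = {}
    parent: dict[str, str | None] = {}
    best: dict[str, float] = {source: 0.0}
    heap: list[tuple[float, str, str | None]] = [(0.0, source, None)]
    while heap:
        d, v, p = heapq.heappop(heap)
        if v in dist:
            continue
        dist[v] = d
        parent[v] = p
        for u in sorted(g[v]):
            if u in dist:
                continue
            nd = d + g.edges[v, u]["length"]
            if nd < best.get(u, math.inf):
                best[u] = nd
                heapq.heappush(heap, (nd, u, v))
    return dist, parent


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def objective(H: Subnetwork, q: QueryInstance) -> float:
    """Recompute f_alpha of a subnetwork from its edge set."""
    lengths = q.base_lengths()
    g = nx.Graph()
    g.add_nodes_from(H.nodes)
    for e in sorted(H.edges):
        g.add_edge(*e, length=lengths[_pair(*e)])
    for a in sorted(q.anchors & set(g.nodes)):
        g.add_edge(VIRTUAL_ROOT, a, length=0.0)
    if VIRTUAL_ROOT not in g:
        raise QueryError("subnetwork contains no anchor")
    dist, _ = _dijkstra_tree(g, VIRTUAL_ROOT)
    missing = sorted(t for t in q.terminals if t not in dist)
    if missing:
        raise QueryError(f"terminals disconnected in subnetwork: {missing}")
    term_dist = {t: dist[t] for t in sorted(q.terminals)}
    return _score(frozenset(_pair(*e) for e in H.edges), term_dist, q)


# ---------------------------------------------------------------------------
# Tree assembly helpers
# ---------------------------------------------------------------------------

def _score(edges: frozenset, term_dist: dict, q: QueryInstance) -> float:
    """f_alpha from a stripped edge set; summation order is canonical so
    identical trees score bit-identically regardless of discovery path."""
    base = q.base_lengths()
    total = math.fsum(base[e] for e in sorted(edges))
    local = math.fsum(term_dist[t] for t in sorted(term_dist))
    return (1.0 - 2.0 * q.alpha) * local + 2.0 * q.alpha * total


def _finalize(tree: nx.Graph, dist, q: QueryInstance) -> Subnetwork:
    """Prune dangling non-terminal branches, strip the root, score f_alpha."""
    keep = q.terminals | {VIRTUAL_ROOT}
    while True:
        leaves = [v for v in tree.nodes
                  if tree.degree(v) <= 1 and v not in keep]
        if not leaves:
            break
        tree.remove_nodes_from(leaves)
    term_dist = {t: dist[t] for t in sorted(q.terminals)}
    nodes = frozenset(tree.nodes) - {VIRTUAL_ROOT}
    edges = frozenset(_pair(u, v) for u, v in tree.edges
                      if VIRTUAL_ROOT not in (u, v))
    return Subnetwork(nodes, edges, _score(edges, term_dist, q), term_dist)


def _subnetwork_from_rooted_edges(edges, q: QueryInstance) -> Subnetwork:
    """Build a minimal solution tree from a rooted edge set.

    The edge set (which may be a non-tree union, e.g. a DP backtrack) is
    reduced to a deterministic shortest-path tree from the virtual root,
    then pruned; the objective is recomputed from scratch on the final tree
    under the base (unjittered) lengths.
    """
    base = q.base_lengths()
    g = nx.Graph()
    for e in sorted(edges):
        g.add_edge(*e, length=base[_pair(*e)])
    if VIRTUAL_ROOT not in g:
        raise QueryError("rooted edge set does not touch the virtual root")
    dist, parent = _dijkstra_tree(g, VIRTUAL_ROOT)
    missing = sorted(t for t in q.terminals if t not in dist)
    if missing:
        raise QueryError(f"terminals disconnected: {missing}")
    tree = nx.Graph()
    tree.add_node(VIRTUAL_ROOT)
    for v, p in parent.items():
        if p is not None:
            tree.add_edge(v, p, length=g.edges[v, p]["length"])
    return _finalize(tree, dist, q)


# ---------------------------------------------------------------------------
# Exact dynamic program (Dreyfus–Wagner over the cost-distance objective)
# ---------------------------------------------------------------------------

def _exact_reconstruct(q: QueryInstance, lengths) -> Subnetwork:
    nodes = sorted(q.network.nodes) + [VIRTUAL_ROOT]
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for (u, v), L in sorted(lengths.items()):
        iu, iv = idx[u], idx[v]
        adj[iu].append((iv, L))
        adj[iv].append((iu, L))
    terms = sorted(q.terminals)
    k = len(terms)
    full = (1 << k) - 1
    alpha = q.alpha
    INF = math.inf

    cost: dict[int, list[float]] = {}
    back: dict[int, list] = {}
    for mask in range(1, full + 1):
        cost[mask] = [INF] * n
        back[mask] = [None] * n
    for i, t in enumerate(terms):
        cost[1 << i][idx[t]] = 0.0

    for mask in range(1, full + 1):
        arr, bp = cost[mask], back[mask]
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if sub <= other:  # each unordered split once
                ca, cb = cost[sub], cost[other]
                for v in range(n):
                    cand = ca[v] + cb[v]
                    if cand < arr[v]:
                        arr[v] = cand
                        bp[v] = ("M", sub)
            sub = (sub - 1) & mask
        mult = 2.0 * alpha + (1.0 - 2.0 * alpha) * bin(mask).count("1")
        heap = [(arr[v], v) for v in range(n) if arr[v] < INF]
        heapq.heapify(heap)
        while heap:
            d, v = heapq.heappop(heap)
            if d > arr[v]:
                continue
            for u, L in adj[v]:
                nd = d + mult * L
                if nd < arr[u]:
                    arr[u] = nd
                    bp[u] = ("E", v)
                    heapq.heappush(heap, (nd, u))

    root = idx[VIRTUAL_ROOT]
    if not math.isfinite(cost[full][root]):
        raise QueryError(
            f"terminals unreachable from anchors: {sorted(q.terminals)}"
        )
    edges: set[tuple[str, str]] = set()
    stack = [(full, root)]
    while stack:
        mask, v = stack.pop()
        step = back[mask][v]
        if step is None:
            continue
        if step[0] == "E":
            u = step[1]
            edges.add(_pair(nodes[u], nodes[v]))
            stack.append((mask, u))
        else:
            sub = step[1]
            stack.append((sub, v))
            stack.append((mask ^ sub, v))
    return _subnetwork_from_rooted_edges(edges, q)


# ---------------------------------------------------------------------------
# Heuristic for large instances
# ---------------------------------------------------------------------------

def _rooted_graph(q: QueryInstance, lengths) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(q.network.nodes))
    for (u, v), L in sorted(lengths.items()):
        g.add_edge(u, v, length=L)
    return g


def _shortest_path_union(g: nx.Graph, q: QueryInstance) -> set:
    dist, parent = _dijkstra_tree(g, VIRTUAL_ROOT)
    missing = sorted(t for t in q.terminals if t not in dist)
    if missing:
        raise QueryError(f"terminals unreachable from anchors: {missing}")
    edges: set[tuple[str, str]] = set()
    for t in sorted(q.terminals):
        v = t
        while v != VIRTUAL_ROOT:
            p = parent[v]
            edges.add(_pair(v, p))
            v = p
    return edges


def _heuristic_reconstruct(q: QueryInstance, lengths,
                           max_rounds: int = 20) -> Subnetwork:
    """Shortest-path-tree seed plus local edge-swap improvement.

    Exactness is not guaranteed here; the exact route is used whenever the
    instance is small enough (see :func:`reconstruct`).
    """
    g = _rooted_graph(q, lengths)
    current = _subnetwork_from_rooted_edges(_shortest_path_union(g, q), q)
    for _ in range(max_rounds):
        improved = False
        tree_edges = set(current.edges)
        tree_nodes = current.nodes
        tg = nx.Graph()
        tg.add_edges_from(tree_edges)
        tg.add_nodes_from(tree_nodes)
        root_edges = {_pair(VIRTUAL_ROOT, a) for a in sorted(q.anchors)
                      if a in tree_nodes}
        for e in root_edges:
            tg.add_edge(*e)
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            if VIRTUAL_ROOT in (u, v) or _pair(u, v) in tree_edges:
                continue
            if u not in tree_nodes or v not in tree_nodes:
                continue
            cycle = nx.shortest_path(tg, u, v)
            for a, b in zip(cycle, cycle[1:]):
                if VIRTUAL_ROOT in (a, b):
                    continue
                cand = (tree_edges - {_pair(a, b)}) | {_pair(u, v)}
                try:
                    sub = _subnetwork_from_rooted_edges(cand | root_edges, q)
                except QueryError:
                    continue
                if sub.objective < current.objective - 1e-12:
                    current = sub
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return current


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def reconstruct(q: QueryInstance, *, lengths=None,
                exact_threshold: int = EXACT_THRESHOLD,
                exact_terminal_limit: int = EXACT_TERMINAL_LIMIT) -> Subnetwork:
    """Minimum-objective anchored solution tree for one query.

    Exact (subset dynamic program) whenever the network has at most
    `exact_threshold` nodes or at most `exact_terminal_limit` terminals;
    the swap-improvement heuristic is used otherwise.  `lengths` overrides
    the edge lengths used during the *search* (the returned objective is
    always recomputed under the base −ln(confidence) lengths).
    """
    if lengths is None:
        lengths = q.base_lengths()
    if (q.network.number_of_nodes() <= exact_threshold
            or len(q.terminals) <= exact_terminal_limit):
        return _exact_reconstruct(q, lengths)
    return _heuristic_reconstruct(q, lengths)


def iter_candidate_trees(q: QueryInstance):
    """Exhaustively yield every minimal rooted solution tree (oracle path).

    Recursively grows trees from the virtual root, branching on every
    frontier edge with an exclusion set so each rooted tree is generated
    exactly once.  Trees are yielded when they contain every terminal and
    have no dangling non-terminal leaf (such a branch contributes nothing
    and would only duplicate solutions).  Distances from the root are
    maintained incrementally (tree paths are unique).
    """
    lengths = q.base_lengths()
    adj: dict[str, list[tuple[str, float]]] = {n: [] for n in q.network.nodes}
    adj[VIRTUAL_ROOT] = []
    for (u, v), L in lengths.items():
        adj[u].append((v, L))
        adj[v].append((u, L))
    for u in adj:
        adj[u].sort()
    terms = q.terminals

    nodes: set[str] = {VIRTUAL_ROOT}
    edges: list[tuple[str, str]] = []
    dist: dict[str, float] = {VIRTUAL_ROOT: 0.0}
    deg: dict[str, int] = {VIRTUAL_ROOT: 0}

    def rec(excluded: frozenset):
        if terms <= nodes and all(
                deg[x] > 1 or x in terms or x == VIRTUAL_ROOT for x in nodes):
            stripped = frozenset(e for e in edges if VIRTUAL_ROOT not in e)
            term_dist = {t: dist[t] for t in sorted(terms)}
            yield Subnetwork(frozenset(nodes) - {VIRTUAL_ROOT}, stripped,
                             _score(stripped, term_dist, q), term_dist)
        cands = sorted(
            (u, v, L)
            for u in nodes for v, L in adj[u]
            if v not in nodes and _pair(u, v) not in excluded
        )
        banned = set(excluded)
        for u, v, L in cands:
            nodes.add(v)
            edges.append(_pair(u, v))
            dist[v] = dist[u] + L
            deg[u] += 1
            deg[v] = 1
            yield from rec(frozenset(banned))
            nodes.remove(v)
            edges.pop()
            del dist[v]
            deg[u] -= 1
            del deg[v]
            banned.add(_pair(u, v))

    yield from rec(frozenset())


def brute_force_optimum(q: QueryInstance,
                        max_nodes: int = EXACT_THRESHOLD) -> Subnetwork:
    """Exhaustive-enumeration optimum; refuses instances above `max_nodes`.

    Ties are broken by fewer edges, then by lexicographic edge list.
    """
    if q.network.number_of_nodes() > max_nodes:
        raise QueryError(
            f"brute force refuses instances with more than {max_nodes} nodes"
        )
    best: Subnetwork | None = None
    for sub in iter_candidate_trees(q):
        if best is None or sub.sort_key() < best.sort_key():
            best = sub
    if best is None:
        raise QueryError("no feasible solution tree exists")
    return best


def enumerate_ensemble(q: QueryInstance, n_samples: int = 30,
                       seed: int = 0) -> SolutionEnsemble:
    """Margin-bounded ensemble of distinct near-optimal solutions.

    Exact enumeration on small instances; otherwise `n_samples` randomized
    restarts with multiplicative edge-length jitter exp(U(−0.1, 0.1)),
    filtered by the margin threshold and deduplicated by edge set.  Node
    confidence is the fraction of ensemble members containing the node.
    Deterministic for a fixed seed.
    """
    if n_samples < 1:
        raise QueryError(f"n_samples must be >= 1, got {n_samples}")
    lengths = q.base_lengths()
    found: dict[frozenset, Subnetwork] = {}
    if q.network.number_of_nodes() <= EXACT_THRESHOLD:
        candidates = list(iter_candidate_trees(q))
        optimum = min(candidates, key=Subnetwork.sort_key)
        threshold = q.margin * optimum.objective
        admit = threshold * (1.0 + _MARGIN_RTOL) + 1e-12
        for sub in candidates:
            if sub.objective <= admit and sub.edges not in found:
                found[sub.edges] = sub
    else:
        optimum = reconstruct(q, lengths=lengths)
        threshold = q.margin * optimum.objective
        admit = threshold * (1.0 + _MARGIN_RTOL) + 1e-12
        found[optimum.edges] = optimum
        rng = np.random.default_rng(seed)
        for _ in range(n_samples):
            jitter = {e: L * math.exp(rng.uniform(-0.1, 0.1))
                      for e, L in lengths.items()}
            sub = reconstruct(q, lengths=jitter)
            # sub is already re-scored under the base lengths
            if sub.objective <= admit and sub.edges not in found:
                found[sub.edges] = sub
    members = tuple(sorted(found.values(), key=Subnetwork.sort_key))
    counts: dict[str, int] = {}
    for sub in members:
        for v in sub.nodes:
            counts[v] = counts.get(v, 0) + 1
    confidence = {v: c / len(members) for v, c in sorted(counts.items())}
    return SolutionEnsemble(q, optimum, members, confidence)
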