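"""Network propagation: diffusion-based proximity scores to a seed set.

Seed mass 1/|seeds| is injected at each seed node and diffused over the
confidence-weighted graph using insulated diffusion with a symmetric
normalization:

    F_{k+1} = beta * W' F_k + (1 - beta) * F_0,
    W' = D^{-1/2} W D^{-1/2}

where W is the weighted adjacency and D its diagonal (weighted) degree.
Rows of isolated nodes are zero.  For beta < 1 the iteration contracts to
the unique fixed point (I - beta W')^{-1} (1 - beta) F_0.  Two propagations,
seeded from the anchors and from the terminals of a query, yield the two
proximity features used by the refinement classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .errors import QueryError
from .network_io import InteractionNetwork


@dataclass(frozen=True)
class PropagationConfig:
    """Diffusion parameters.

    beta is the retention weight (fraction of mass that keeps diffusing);
    the iteration stops when the max-norm change drops below tol.
    """

    beta: float = 0.8
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.beta < 1.0):
            raise QueryError(f"beta {self.beta} outside (0, 1)")
        if self.tol <= 0 or self.max_iter < 1:
            raise QueryError("tol must be > 0 and max_iter >= 1")


@dataclass(frozen=True, eq=False)
class PropagationResult:
    scores: dict[str, float]
    seeds: frozenset[str]
    iterations_used: int


def _normalized_adjacency(net: InteractionNetwork,
                          nodes: list[str]) -> sp.csr_matrix:
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for it in net.interactions():
        i, j = idx[it.u], idx[it.v]
        rows += [i, j]
        cols += [j, i]
        vals += [it.confidence, it.confidence]
    w = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    deg = np.asarray(w.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)),
                            0.0)
    d = sp.diags(inv_sqrt)
    return d @ w @ d


def _seed_vector(nodes: list[str], seeds: frozenset[str],
                 normalize_seed_mass: bool) -> np.ndarray:
    f0 = np.zeros(len(nodes))
    mass = 1.0 / len(seeds) if normalize_seed_mass else 1.0
    for i, n in enumerate(nodes):
        if n in seeds:
            f0[i] = mass
    return f0


def propagate(net: InteractionNetwork, seeds, cfg: PropagationConfig
              = PropagationConfig(), *,
              normalize_seed_mass: bool = True) -> PropagationResult:
    """Iterate the diffusion to its fixed point.

    Seeds start at 1/|seeds| (or 1 each with `normalize_seed_mass=False`),
    all other nodes at 0.  Nodes in components containing no seed score
    exactly 0.  Raises on an empty seed set or a seed missing from the
    network.
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise QueryError("seed set must be non-empty")
    missing = sorted(seeds - net.nodes)
    if missing:
        raise QueryError(f"seed nodes not in network: {missing}")
    nodes = sorted(net.nodes)
    wn = _normalized_adjacency(net, nodes)
    f0 = _seed_vector(nodes, seeds, normalize_seed_mass)
    f = f0.copy()
    used = 0
    for used in range(1, cfg.max_iter + 1):
        nxt = cfg.beta * (wn @ f) + (1.0 - cfg.beta) * f0
        delta = np.max(np.abs(nxt - f))
        f = nxt
        if delta < cfg.tol:
            break
    scores = {n: float(max(f[i], 0.0)) for i, n in enumerate(nodes)}
    return PropagationResult(scores, seeds, used)


def propagate_direct(net: InteractionNetwork, seeds, cfg: PropagationConfig
                     = PropagationConfig(), *,
                     normalize_seed_mass: bool = True) -> dict[str, float]:
    """Closed-form fixed point via a direct sparse linear solve.

    Solves (I - beta W') F = (1 - beta) F_0; used as a cross-check of the
    iterative solver.
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise QueryError("seed set must be non-empty")
    missing = sorted(seeds - net.nodes)
    if missing:
        raise QueryError(f"seed nodes not in network: {missing}")
    nodes = sorted(net.nodes)
    wn = _normalized_adjacency(net, nodes)
    f0 = _seed_vector(nodes, seeds, normalize_seed_mass)
    n = len(nodes)
    lhs = sp.identity(n, format="csc") - cfg.beta * wn.tocsc()
    f = spsolve(lhs, (1.0 - cfg.beta) * f0)
    f = np.atleast_1d(f)
    return {node: float(f[i]) for i, node in enumerate(nodes)}


def proximity_features(net: InteractionNetwork, anchors, terminals,
                       cfg: PropagationConfig = PropagationConfig()
                       ) -> dict[str, tuple[float, float]]:
    """(anchor-propagation, terminal-propagation) score pair per node."""
    from_anchors = propagate(net, anchors, cfg).scores
    from_terminals = propagate(net, terminals, cfg).scores
    return {n: (from_anchors[n], from_terminals[n]) for n in sorted(net.nodes)}
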