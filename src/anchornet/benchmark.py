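"""Synthetic benchmark: background networks with planted signaling pathways.

Real training corpora for the refinement layer come from curated pathway
databases; this module generates a fully self-contained surrogate so the
whole pipeline can be exercised and validated without downloads.  The
background is an Erdős–Rényi graph with mid-range edge confidences; each
planted pathway is a layered DAG (sources in layer 0, sinks in the last
layer) whose undirected edges are inserted with high confidence, which
makes the degree-based anchor/terminal rule meaningful and gives the
reconstruction a recoverable signal.  Decoy high-confidence edges are added
to keep recovery nontrivial.  Everything is deterministic per seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AnchorNetError
from .network_io import Interaction, InteractionNetwork, write_network, write_node_list


@dataclass(frozen=True)
class BenchmarkConfig:
    """Corpus shape and noise knobs (all distributions seed-deterministic)."""

    n_background_nodes: int = 200
    background_edge_prob: float = 0.02
    n_pathways: int = 10
    pathway_size_range: tuple[int, int] = (8, 14)
    n_anchors_range: tuple[int, int] = (1, 2)
    n_terminals_range: tuple[int, int] = (2, 3)
    confidence_noise: float = 0.0
    decoy_edge_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.pathway_size_range, self.n_anchors_range,
                       self.n_terminals_range):
            if not (1 <= lo <= hi):
                raise AnchorNetError(f"invalid range ({lo}, {hi})")
        if not (0.0 < self.background_edge_prob < 1.0):
            raise AnchorNetError("background_edge_prob must be in (0, 1)")
        if self.n_background_nodes < self.pathway_size_range[1]:
            raise AnchorNetError("pathway larger than background")
        min_size = self.n_anchors_range[0] + self.n_terminals_range[0] + 1
        if self.pathway_size_range[0] < min_size:
            raise AnchorNetError(
                f"pathway_size_range minimum must be >= {min_size} "
                "(anchors + terminals + one intermediate)"
            )


@dataclass(frozen=True, eq=False)
class PlantedPathway:
    """Ground truth for one planted pathway."""

    name: str
    truth_nodes: frozenset[str]
    truth_edges: frozenset[tuple[str, str]]
    anchors: frozenset[str]
    terminals: frozenset[str]
    directed_edges: frozenset[tuple[str, str]] = frozenset()


def _plant_layers(members: list[str], n_anchors: int, n_terminals: int,
                  rng: np.random.Generator) -> list[list[str]]:
    anchors = members[:n_anchors]
    terminals = members[n_anchors:n_anchors + n_terminals]
    middle = members[n_anchors + n_terminals:]
    n_mid_layers = max(1, math.ceil(len(middle) / 3))
    mid_layers = [list(middle[i::n_mid_layers]) for i in range(n_mid_layers)]
    mid_layers = [layer for layer in mid_layers if layer]
    return [anchors] + mid_layers + [terminals]


def _layer_dag(layers: list[list[str]], rng: np.random.Generator,
               extra_edge_prob: float = 0.3) -> set[tuple[str, str]]:
    edges: set[tuple[str, str]] = set()
    for upper, lower in zip(layers, layers[1:]):
        for v in lower:  # every non-source node gets a parent
            u = upper[rng.integers(len(upper))]
            edges.add((u, v))
        for u in upper:  # every non-sink node gets a child
            if not any(e[0] == u for e in edges):
                v = lower[rng.integers(len(lower))]
                edges.add((u, v))
        for u in upper:
            for v in lower:
                if rng.random() < extra_edge_prob:
                    edges.add((u, v))
    return edges


def generate_corpus(cfg: BenchmarkConfig
                    ) -> tuple[InteractionNetwork, list[PlantedPathway]]:
    """Background network plus planted ground-truth pathways.

    Background confidences are Uniform(0.3, 0.95); planted and decoy edges
    get Uniform(0.8, 0.99).  Optional multiplicative log-normal confidence
    noise (sigma = `confidence_noise`) is applied to every edge at the end.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_background_nodes
    nodes = [f"n{i:04d}" for i in range(n)]
    net = InteractionNetwork(nodes=nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < cfg.background_edge_prob:
                net.add_interaction(Interaction(
                    nodes[i], nodes[j],
                    float(rng.uniform(0.3, 0.95)), source="background",
                ))

    pathways: list[PlantedPathway] = []
    planted_pairs: set[tuple[str, str]] = set()
    for k in range(cfg.n_pathways):
        size = int(rng.integers(cfg.pathway_size_range[0],
                                cfg.pathway_size_range[1] + 1))
        n_anchors = int(rng.integers(cfg.n_anchors_range[0],
                                     cfg.n_anchors_range[1] + 1))
        n_terminals = int(rng.integers(cfg.n_terminals_range[0],
                                       cfg.n_terminals_range[1] + 1))
        members = [nodes[i] for i in
                   rng.choice(n, size=size, replace=False)]
        layers = _plant_layers(members, n_anchors, n_terminals, rng)
        dag = _layer_dag(layers, rng)
        truth_edges = frozenset(tuple(sorted(e)) for e in dag)
        for u, v in sorted(truth_edges):
            net.add_interaction(Interaction(
                u, v, float(rng.uniform(0.8, 0.99)), source="planted",
            ))
            planted_pairs.add((u, v))
        pathways.append(PlantedPathway(
            name=f"pw{k:02d}",
            truth_nodes=frozenset(members),
            truth_edges=truth_edges,
            anchors=frozenset(layers[0]),
            terminals=frozenset(layers[-1]),
            directed_edges=frozenset(dag),
        ))

    n_decoys = int(round(cfg.decoy_edge_factor * len(planted_pairs)))
    added = 0
    while added < n_decoys:
        i, j = rng.integers(n), rng.integers(n)
        if i == j:
            continue
        pair = tuple(sorted((nodes[i], nodes[j])))
        if pair in planted_pairs:
            continue
        net.add_interaction(Interaction(
            pair[0], pair[1], float(rng.uniform(0.8, 0.99)), source="decoy",
        ))
        added += 1

    if cfg.confidence_noise > 0:
        noisy = InteractionNetwork(nodes=net.nodes)
        for it in net.interactions():
            c = it.confidence * math.exp(
                rng.normal(0.0, cfg.confidence_noise))
            noisy.add_interaction(Interaction(
                it.u, it.v, float(min(max(c, 0.05), 1.0)),
                it.source, it.method_term,
            ))
        net = noisy
    return net, pathways


def score_recovery(predicted, truth: PlantedPathway,
                   threshold: float = 0.5) -> tuple[float, float, float]:
    """Node-level precision/recall/F1 of a scored prediction vs the truth.

    Anchors and terminals are excluded from both sides (they are inputs,
    not predictions).  Returns NaNs when the truth set is empty after the
    exclusion.
    """
    given = truth.anchors | truth.terminals
    if hasattr(predicted, "items"):
        pred = {n for n, s in predicted.items() if s >= threshold}
    else:
        pred = set(predicted)
    pred -= given
    gold = truth.truth_nodes - given
    if not gold:
        return (float("nan"),) * 3
    tp = len(pred & gold)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(gold)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def write_corpus(net: InteractionNetwork, pathways: list[PlantedPathway],
                 out_dir: str | Path) -> None:
    """Persist a corpus in the package's own formats (tsv, node lists,
    truth JSON per pathway)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_network(net, out / "network.tsv")
    for pw in pathways:
        write_node_list(pw.anchors, out / f"{pw.name}.anchors.txt")
        write_node_list(pw.terminals, out / f"{pw.name}.terminals.txt")
        truth = {
            "name": pw.name,
            "truth_nodes": sorted(pw.truth_nodes),
            "truth_edges": sorted(list(e) for e in pw.truth_edges),
            "anchors": sorted(pw.anchors),
            "terminals": sorted(pw.terminals),
            "directed_edges": sorted(list(e) for e in pw.directed_edges),
        }
        (out / f"{pw.name}.truth.json").write_text(
            json.dumps(truth, indent=1) + "\n")


def read_corpus(in_dir: str | Path
                ) -> tuple[InteractionNetwork, list[PlantedPathway]]:
    """Re-read a corpus written by :func:`write_corpus`."""
    from .network_io import read_edge_list

    src = Path(in_dir)
    net = read_edge_list(src / "network.tsv")
    pathways = []
    for truth_file in sorted(src.glob("*.truth.json")):
        data = json.loads(truth_file.read_text())
        pathways.append(PlantedPathway(
            name=data["name"],
            truth_nodes=frozenset(data["truth_nodes"]),
            truth_edges=frozenset(tuple(e) for e in data["truth_edges"]),
            anchors=frozenset(data["anchors"]),
            terminals=frozenset(data["terminals"]),
            directed_edges=frozenset(
                tuple(e) for e in data.get("directed_edges", [])),
        ))
    return net, pathways
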