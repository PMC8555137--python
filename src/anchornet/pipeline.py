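"""Orchestration: run configuration, job planning, MST finalization, and
the end-to-end anchored query entry point."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Mapping

import yaml

from . import __version__
from .errors import AnchorNetError, QueryError
from .ml import (ALPHA_GRID, MARGIN_GRID, TrainedModel, load_model, refine)
from .network_io import (InteractionNetwork, read_edge_list, read_node_list,
                         write_network)
from .propagation import PropagationConfig
from .reconstruct import QueryInstance, enumerate_ensemble

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration; every CLI flag maps onto one key here."""

    alpha_grid: tuple[float, ...] = ALPHA_GRID
    margin_grid: tuple[float, ...] = MARGIN_GRID
    alpha: float = 0.25
    margin: float = 1.0
    n_samples: int = 20
    seed: int = 0
    beta: float = 0.8
    tol: float = 1e-6
    max_iter: int = 1000
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.alpha_grid or not self.margin_grid:
            raise AnchorNetError("alpha and margin grids must be non-empty")
        if any(not 0.0 <= a <= 0.5 for a in self.alpha_grid):
            raise AnchorNetError("alphas must lie in [0, 0.5]")
        if any(m < 1.0 for m in self.margin_grid):
            raise AnchorNetError("margins must be >= 1")

    @property
    def propagation(self) -> PropagationConfig:
        return PropagationConfig(beta=self.beta, tol=self.tol,
                                 max_iter=self.max_iter)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise AnchorNetError(f"config {path} must be a flat mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("alpha_grid", "margin_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Job planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Job:
    kind: str  # "reconstruction" | "propagation"
    pathway: str
    alpha: float | None = None
    margin: float | None = None
    seed_set: str | None = None  # "anchors" | "terminals"

    def key(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()


@dataclass(frozen=True, eq=False)
class JobPlan:
    jobs: tuple[Job, ...]

    @property
    def n_reconstruction_jobs(self) -> int:
        return sum(j.kind == "reconstruction" for j in self.jobs)

    @property
    def n_propagation_jobs(self) -> int:
        return sum(j.kind == "propagation" for j in self.jobs)

    def plan_hash(self) -> str:
        return hashlib.sha1(
            "".join(j.key() for j in self.jobs).encode()).hexdigest()

    def execute(self, runner: Callable[[Job], dict],
                cache_dir: str | Path | None = None) -> dict[str, dict]:
        """Run every job, skipping those already completed in `cache_dir`
        (keyed by the job's content hash); returns results by job key."""
        cache = Path(cache_dir) if cache_dir is not None else None
        if cache is not None:
            cache.mkdir(parents=True, exist_ok=True)
        results: dict[str, dict] = {}
        for job in self.jobs:
            key = job.key()
            if cache is not None:
                hit = cache / f"{key}.json"
                if hit.exists():
                    results[key] = json.loads(hit.read_text())
                    continue
            out = runner(job)
            results[key] = out
            if cache is not None:
                (cache / f"{key}.json").write_text(json.dumps(out))
        return results


def schedule_training(pathways, cfg: RunConfig) -> JobPlan:
    """Plan |pathways| x |alphas| x |margins| reconstructions plus two
    propagations (anchor- and terminal-seeded) per pathway."""
    pathways = list(pathways)
    if not pathways:
        raise AnchorNetError("cannot schedule training on an empty corpus")
    jobs: list[Job] = []
    for pw in pathways:
        name = getattr(pw, "name", str(pw))
        for margin in cfg.margin_grid:
            for alpha in cfg.alpha_grid:
                jobs.append(Job("reconstruction", name, alpha=alpha,
                                margin=margin))
        for seed_set in ("anchors", "terminals"):
            jobs.append(Job("propagation", name, seed_set=seed_set))
    return JobPlan(tuple(jobs))


# ---------------------------------------------------------------------------
# MST finalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class RefinedNetwork:
    """Final output: scored nodes connected as a minimum spanning forest."""

    nodes: dict[str, float]
    edges: tuple[tuple[str, str], ...]
    components: int


class _UnionFind:
    def __init__(self, items):
        self._p = {x: x for x in items}

    def find(self, x):
        while self._p[x] != x:
            self._p[x] = self._p[self._p[x]]
            x = self._p[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self._p[ra] = rb
        return True


def finalize_mst(nodes: Mapping[str, float],
                 net: InteractionNetwork) -> RefinedNetwork:
    """Minimum spanning forest of the induced subgraph on scored nodes.

    Kruskal under −ln(confidence) edge lengths with lexicographic
    tie-breaking; a disconnected induced subgraph yields a forest with
    more than one component (warned once per extra component).
    """
    if not nodes:
        raise QueryError("cannot build an MST over an empty node set")
    missing = sorted(set(nodes) - net.nodes)
    if missing:
        raise QueryError(f"scored nodes not in network: {missing}")
    keep = set(nodes)
    candidates = sorted(
        ((it.length, it.u, it.v) for it in net.interactions()
         if it.u in keep and it.v in keep),
    )
    uf = _UnionFind(keep)
    edges = []
    for _, u, v in candidates:
        if uf.union(u, v):
            edges.append((u, v))
    components = len(keep) - len(edges)
    if components > 1:
        logger.warning("refined node set induces %d components", components)
    return RefinedNetwork(nodes=dict(sorted(nodes.items())),
                          edges=tuple(sorted(edges)), components=components)


# ---------------------------------------------------------------------------
# End-to-end anchored query
# ---------------------------------------------------------------------------

def run_anchored(network_path: str | Path, anchors_path: str | Path,
                 terminals_path: str | Path, out_dir: str | Path,
                 cfg: RunConfig = RunConfig(), *,
                 model_path: str | Path | None = None,
                 ml_based: bool = False) -> RefinedNetwork:
    """Run one anchored query and write all outputs to `out_dir`.

    Without a model: plain reconstruction with margin-ensemble node
    confidences.  With ``ml_based`` and a model: classifier refinement
    followed by minimum-spanning-tree finalization.  Outputs: subnetwork
    SIF (+ confidence sidecar), a node tsv (node, score, is_anchor,
    is_terminal), a JSON summary, and a log of the resolved configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = read_edge_list(network_path)
    anchors = frozenset(read_node_list(anchors_path))
    terminals = frozenset(read_node_list(terminals_path))

    model: TrainedModel | None = None
    if ml_based:
        if model_path is None:
            raise AnchorNetError("--ml-based requires a trained model")
        model = load_model(model_path)

    summary: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "ml_based": ml_based,
        "n_anchors": len(anchors),
        "n_terminals": len(terminals),
    }
    if model is None:
        q = QueryInstance(net, anchors, terminals, alpha=cfg.alpha,
                          margin=cfg.margin)
        ens = enumerate_ensemble(q, n_samples=cfg.n_samples, seed=cfg.seed)
        scored = dict(ens.node_confidence)
        result = finalize_mst(scored, net)
        summary.update({
            "optimum_objective": ens.optimum.objective,
            "margin": q.margin,
            "member_count": len(ens.members),
        })
    else:
        q = QueryInstance(net, anchors, terminals, alpha=cfg.alpha,
                          margin=model.margin)
        scored = refine(q, model, cfg.threshold, seed=cfg.seed,
                        n_samples=cfg.n_samples, prop_cfg=cfg.propagation)
        result = finalize_mst(scored, net)
        summary.update({
            "model_margin": model.margin,
            "model_feature_set": model.feature_set,
            "threshold": cfg.threshold,
        })
    summary.update({
        "n_nodes": len(result.nodes),
        "n_edges": len(result.edges),
        "components": result.components,
    })

    write_network(_edge_network(result, net), out / "subnetwork.sif",
                  format="sif")
    with (out / "nodes.tsv").open("w") as fh:
        fh.write("node\tscore\tis_anchor\tis_terminal\n")
        for node, score in result.nodes.items():
            fh.write(f"{node}\t{score!r}\t{int(node in anchors)}"
                     f"\t{int(node in terminals)}\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True) + "\n")
    plan_hash = hashlib.sha1(
        json.dumps(summary["config"], sort_keys=True).encode()).hexdigest()
    (out / "run.log").write_text(
        f"anchornet {__version__}\nconfig hash {plan_hash}\n"
        + json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return result


def _edge_network(result: RefinedNetwork,
                  net: InteractionNetwork) -> InteractionNetwork:
    out = InteractionNetwork(nodes=result.nodes)
    for u, v in result.edges:
        out.add_interaction(net.interaction(u, v))
    return out
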