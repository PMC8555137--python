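"""Weighted interaction networks: data model, readers/writers, merging.

The background search universe is an undirected graph whose edges are
protein-protein interactions carrying a confidence in (0, 1].  This module
also handles the two auxiliary inputs needed to assemble such a network from
curated sources: a detection-method ontology (PSI-MI style OBO file) used to
reconcile discordant annotations when two databases report the same
interaction, and directed pathway graphs (KGML XML) that are converted into
undirected edges plus anchor/terminal sets for training.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import obonet

from .errors import NetworkFormatError, OntologyError, PathwayError

logger = logging.getLogger(__name__)

#: Confidence assigned to every pathway-derived (non-experimental) edge.
KEGG_CONFIDENCE = 0.6

EDGE_LIST_COLUMNS = ("u", "v", "confidence", "source", "method_term")


def _check_node_id(node: str) -> str:
    if not isinstance(node, str) or not node or any(c.isspace() for c in node):
        raise NetworkFormatError(
            f"invalid node identifier {node!r}: must be a non-empty token "
            "without whitespace"
        )
    return node


@dataclass(frozen=True)
class Interaction:
    """One undirected interaction; endpoints are stored in sorted order."""

    u: str
    v: str
    confidence: float
    source: str = "input"
    method_term: str | None = None

    def __post_init__(self) -> None:
        _check_node_id(self.u)
        _check_node_id(self.v)
        if self.u == self.v:
            raise NetworkFormatError(f"self-loop on node {self.u!r} rejected")
        if not (0.0 < self.confidence <= 1.0):
            raise NetworkFormatError(
                f"confidence {self.confidence} for edge ({self.u}, {self.v}) "
                "outside (0, 1]"
            )
        if self.u > self.v:  # canonical unordered-pair order
            u, v = self.v, self.u
            object.__setattr__(self, "u", u)
            object.__setattr__(self, "v", v)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.u, self.v)

    @property
    def length(self) -> float:
        """Edge length −ln(confidence); 0 for a fully reliable edge."""
        return -math.log(self.confidence)


class InteractionNetwork:
    """Undirected weighted interaction graph (at most one edge per pair)."""

    def __init__(self, interactions: Iterable[Interaction] = (),
                 nodes: Iterable[str] = ()):
        self._g = nx.Graph()
        for n in nodes:
            self.add_node(n)
        for it in interactions:
            self.add_interaction(it)

    # -- construction -----------------------------------------------------
    def add_node(self, node: str) -> None:
        self._g.add_node(_check_node_id(node))

    def add_interaction(self, it: Interaction, on_duplicate: str = "max") -> None:
        """Insert an edge; duplicates resolved by `on_duplicate`
        ("max" keeps the higher confidence, "error" raises, "replace")."""
        if self._g.has_edge(it.u, it.v):
            old: Interaction = self._g.edges[it.u, it.v]["interaction"]
            if on_duplicate == "error":
                raise NetworkFormatError(f"duplicate edge ({it.u}, {it.v})")
            if on_duplicate == "max" and old.confidence >= it.confidence:
                return
        self._g.add_edge(it.u, it.v, interaction=it)

    # -- queries ----------------------------------------------------------
    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def interaction(self, u: str, v: str) -> Interaction:
        try:
            return self._g.edges[u, v]["interaction"]
        except KeyError:
            raise NetworkFormatError(f"no edge ({u}, {v}) in network") from None

    def interactions(self) -> Iterator[Interaction]:
        for u, v in sorted(tuple(sorted(e)) for e in self._g.edges):
            yield self._g.edges[u, v]["interaction"]

    def confidence(self, u: str, v: str) -> float:
        return self.interaction(u, v).confidence

    def neighbors(self, u: str) -> Iterator[str]:
        return iter(self._g[u])

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self.interactions(), self.nodes)

    def subgraph(self, nodes: Iterable[str]) -> "InteractionNetwork":
        keep = set(nodes)
        edges = [it for it in self.interactions() if it.u in keep and it.v in keep]
        return InteractionNetwork(edges, keep)

    def to_length_graph(self) -> nx.Graph:
        """networkx view with a `length` = −ln(confidence) edge attribute."""
        g = nx.Graph()
        g.add_nodes_from(self._g.nodes)
        for it in self.interactions():
            g.add_edge(it.u, it.v, length=it.length, confidence=it.confidence)
        return g

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and list(self.interactions()) == list(
            other.interactions()
        )

    def __repr__(self) -> str:
        return (f"InteractionNetwork({self.number_of_nodes()} nodes, "
                f"{self.number_of_edges()} edges)")


# ---------------------------------------------------------------------------
# Edge-list IO
# ---------------------------------------------------------------------------

def _looks_like_header(fields: Sequence[str]) -> bool:
    if len(fields) < 3:
        return False
    try:
        float(fields[2])
    except ValueError:
        return True
    return False


def read_edge_list(path: str | Path,
                   columns: Sequence[str] = EDGE_LIST_COLUMNS,
                   default_source: str = "input") -> InteractionNetwork:
    """Read a tab-separated edge list (u, v, confidence[, source[, method]]).

    A header line is detected by a non-numeric third field.  Duplicate
    unordered pairs within the file keep the maximum confidence (warned).
    Malformed lines (bad column count, confidence outside (0,1], self-loop)
    reject the whole file with the offending line number.
    """
    idx = {name: i for i, name in enumerate(columns)}
    for required in ("u", "v", "confidence"):
        if required not in idx:
            raise ValueError(f"column spec {columns!r} lacks {required!r}")
    net = InteractionNetwork()
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            u, v = fields[idx["u"]].strip(), fields[idx["v"]].strip()
            try:
                conf = float(fields[idx["confidence"]])
            except ValueError:
                raise NetworkFormatError(
                    f"{path}:{lineno}: confidence {fields[idx['confidence']]!r}"
                    " is not a number"
                ) from None
            source = default_source
            if "source" in idx and len(fields) > idx["source"] and fields[idx["source"]]:
                source = fields[idx["source"]]
            method = None
            if ("method_term" in idx and len(fields) > idx["method_term"]
                    and fields[idx["method_term"]]):
                method = fields[idx["method_term"]]
            try:
                it = Interaction(u, v, conf, source, method)
            except NetworkFormatError as exc:
                raise NetworkFormatError(f"{path}:{lineno}: {exc}") from None
            if net.has_edge(it.u, it.v):
                logger.warning(
                    "%s:%d: duplicate pair (%s, %s); keeping max confidence",
                    path, lineno, it.u, it.v,
                )
            net.add_interaction(it, on_duplicate="max")
    return net


def write_network(net: InteractionNetwork, path: str | Path,
                  format: str = "tsv") -> None:
    """Write a network as a tsv edge list or a SIF file.

    tsv round-trips exactly through :func:`read_edge_list` (confidences are
    written with full float precision).  SIF uses the interaction type "pp"
    and stores confidences in a sidecar ``<path>.attrs`` tsv.
    """
    path = Path(path)
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("\t".join(EDGE_LIST_COLUMNS) + "\n")
            for it in net.interactions():
                fh.write(
                    f"{it.u}\t{it.v}\t{it.confidence!r}\t{it.source}"
                    f"\t{it.method_term or ''}\n"
                )
    elif format == "sif":
        with path.open("w") as fh:
            for it in net.interactions():
                fh.write(f"{it.u}\tpp\t{it.v}\n")
        with Path(str(path) + ".attrs").open("w") as fh:
            fh.write("u\tv\tconfidence\n")
            for it in net.interactions():
                fh.write(f"{it.u}\t{it.v}\t{it.confidence!r}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_node_list(path: str | Path) -> list[str]:
    """One node identifier per line; blank lines and '#' comments skipped."""
    out: list[str] = []
    for raw in Path(path).read_text().splitlines():
        tok = raw.strip()
        if tok and not tok.startswith("#"):
            out.append(_check_node_id(tok))
    return out


def write_node_list(nodes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{n}\n" for n in sorted(nodes)))


# ---------------------------------------------------------------------------
# Detection-method ontology
# ---------------------------------------------------------------------------

class MethodOntology:
    """Acyclic is_a hierarchy of interaction-detection-method terms."""

    def __init__(self, is_a: Mapping[str, Iterable[str]]):
        self._parents: dict[str, frozenset[str]] = {
            t: frozenset(ps) for t, ps in is_a.items()
        }
        # make sure every referenced parent is a known term
        for t, ps in list(self._parents.items()):
            for p in ps:
                self._parents.setdefault(p, frozenset())
        roots = [t for t, ps in self._parents.items() if not ps]
        if len(roots) != 1:
            raise OntologyError(
                f"ontology must have exactly one root, found {sorted(roots)}"
            )
        self.root = roots[0]
        self._check_dag()

    def _check_dag(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._parents)
        for t, ps in self._parents.items():
            g.add_edges_from((t, p) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise OntologyError("is_a relation contains a cycle")
        for t in self._parents:
            if t != self.root and not nx.has_path(g, t, self.root):
                raise OntologyError(f"term {t} does not reach the root")

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._parents)

    def parents(self, term: str) -> frozenset[str]:
        if term not in self._parents:
            raise OntologyError(f"unknown ontology term {term!r}")
        return self._parents[term]

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive-transitive is_a closure of `term`."""
        seen: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(self.parents(t))
        return frozenset(seen)

    @lru_cache(maxsize=None)
    def depth(self, term: str) -> int:
        """Length of the longest is_a chain from the root to `term`."""
        ps = self.parents(term)
        if not ps:
            return 0
        return 1 + max(self.depth(p) for p in ps)

    @classmethod
    def from_obo(cls, path: str | Path) -> "MethodOntology":
        graph = obonet.read_obo(str(path))
        is_a: dict[str, set[str]] = {t: set() for t in graph.nodes}
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                is_a[child].add(parent)
        return cls(is_a)


def lowest_common_method(a: str, b: str, ont: MethodOntology) -> str:
    """Deepest common ancestor of two detection-method terms.

    Depth is measured from the root; ties are broken by the
    lexicographically smallest term id.  ``lowest_common_method(a, a) == a``.
    """
    common = ont.ancestors(a) & ont.ancestors(b)
    # ancestors() raises OntologyError for unknown terms
    return min(common, key=lambda t: (-ont.depth(t), t))


def merge_networks(primary: InteractionNetwork,
                   secondary: InteractionNetwork,
                   ont: MethodOntology | None = None) -> InteractionNetwork:
    """Union of two interaction sources.

    Pairs present in both keep the maximum confidence, get source tag
    "both", and — when their detection-method annotations are discordant —
    carry the lowest common ancestral method from `ont`.
    """
    merged = primary.copy()
    for node in secondary.nodes:
        merged.add_node(node)
    for it in secondary.interactions():
        if not merged.has_edge(it.u, it.v):
            merged.add_interaction(it)
            continue
        old = merged.interaction(it.u, it.v)
        if old.method_term == it.method_term:
            method = old.method_term
        elif old.method_term is None or it.method_term is None:
            method = old.method_term or it.method_term
        else:
            if ont is None:
                raise OntologyError(
                    f"edge ({it.u}, {it.v}) has discordant method terms "
                    f"{old.method_term!r} vs {it.method_term!r} but no "
                    "ontology was provided"
                )
            method = lowest_common_method(old.method_term, it.method_term, ont)
        merged.add_interaction(
            Interaction(it.u, it.v, max(old.confidence, it.confidence),
                        source="both", method_term=method),
            on_duplicate="replace",
        )
    return merged


# ---------------------------------------------------------------------------
# Pathway graphs (KGML)
# ---------------------------------------------------------------------------

NODE_KINDS = ("protein", "group", "compound")


@dataclass
class PathwayGraph:
    """Directed pathway graph with protein, group and compound nodes."""

    name: str
    nodes: list[tuple[str, str]]  # (node id, kind)
    group_members: dict[str, list[str]] = field(default_factory=dict)
    directed_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        kinds = dict(self.nodes)
        for nid, kind in self.nodes:
            if kind not in NODE_KINDS:
                raise PathwayError(f"node {nid!r} has unknown kind {kind!r}")
        for gid, kind in self.nodes:
            if kind == "group" and not self.group_members.get(gid):
                raise PathwayError(f"group node {gid!r} has no members")
        for u, v in self.directed_edges:
            if u not in kinds or v not in kinds:
                raise PathwayError(
                    f"directed edge ({u}, {v}) references undeclared nodes"
                )

    def kind(self, node: str) -> str:
        return dict(self.nodes)[node]


def read_kgml(path: str | Path) -> PathwayGraph:
    """Parse a KGML pathway XML file (entry / relation / component subset).

    Gene entries become protein nodes named by the first token of their
    `name` attribute; compound entries become compound nodes; group entries
    become group nodes whose members are their component entries.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise NetworkFormatError(f"{path}: XML parse failure: {exc}") from None
    root = tree.getroot()
    name = root.get("name") or root.get("title") or path.stem

    entry_id_to_node: dict[str, str] = {}
    nodes: list[tuple[str, str]] = []
    raw_groups: dict[str, list[str]] = {}  # group node -> component entry ids
    seen: set[str] = set()

    def register(node_id: str, kind: str) -> None:
        if node_id not in seen:
            seen.add(node_id)
            nodes.append((node_id, kind))

    for entry in root.iter("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if eid is None or etype is None:
            raise NetworkFormatError(f"{path}: entry without id/type")
        if etype == "gene":
            node_id = (entry.get("name") or f"gene_{eid}").split()[0]
            register(node_id, "protein")
        elif etype == "compound":
            node_id = (entry.get("name") or f"compound_{eid}").split()[0]
            register(node_id, "compound")
        elif etype == "group":
            node_id = f"group_{eid}"
            register(node_id, "group")
            raw_groups[node_id] = [
                comp.get("id") for comp in entry.iter("component")
            ]
        else:
            continue  # map/ortholog/... entries are ignored
        entry_id_to_node[eid] = node_id

    group_members: dict[str, list[str]] = {}
    for gid, comp_ids in raw_groups.items():
        members = []
        for cid in comp_ids:
            if cid not in entry_id_to_node:
                raise NetworkFormatError(
                    f"{path}: group {gid} references unknown entry {cid!r}"
                )
            members.append(entry_id_to_node[cid])
        group_members[gid] = members

    directed_edges: list[tuple[str, str]] = []
    for rel in root.iter("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        for eid in (e1, e2):
            if eid not in entry_id_to_node:
                raise NetworkFormatError(
                    f"{path}: relation references unknown entry {eid!r}"
                )
        directed_edges.append((entry_id_to_node[e1], entry_id_to_node[e2]))

    return PathwayGraph(name=name, nodes=nodes, group_members=group_members,
                        directed_edges=directed_edges)


def _expanded_protein_graph(pw: PathwayGraph) -> nx.DiGraph:
    """Directed protein-level view: compounds dropped (with their incident
    edges, no transitive bridging), groups replaced by their members with
    every group-incident edge re-attached to every member."""
    kinds = dict(pw.nodes)

    def expand(node: str) -> list[str]:
        kind = kinds[node]
        if kind == "protein":
            return [node]
        if kind == "group":
            return list(pw.group_members[node])
        logger.info("pathway %s: dropping compound node %s", pw.name, node)
        return []

    g = nx.DiGraph()
    for nid, kind in pw.nodes:
        for p in ([nid] if kind == "protein" else
                  pw.group_members[nid] if kind == "group" else []):
            g.add_node(p)
    for u, v in pw.directed_edges:
        for pu in expand(u):
            for pv in expand(v):
                if pu != pv:
                    g.add_edge(pu, pv)
    return g


def pathway_to_network(pw: PathwayGraph,
                       kegg_confidence: float = KEGG_CONFIDENCE) -> InteractionNetwork:
    """Convert a directed pathway graph into undirected network edges.

    Compound nodes and their incident edges are dropped; each group node is
    decomposed into a fully connected subnetwork over its members, with
    group-incident edges re-attached to every member.  All output edges are
    undirected with confidence `kegg_confidence` and source "kegg".
    """
    g = _expanded_protein_graph(pw)
    pairs: set[tuple[str, str]] = set()
    for u, v in g.edges:
        pairs.add(tuple(sorted((u, v))))
    for gid, kind in pw.nodes:
        if kind != "group":
            continue
        members = pw.group_members[gid]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if a != b:
                    pairs.add(tuple(sorted((a, b))))
    net = InteractionNetwork(nodes=g.nodes)
    for u, v in sorted(pairs):
        net.add_interaction(
            Interaction(u, v, kegg_confidence, source="kegg")
        )
    return net


def extract_anchors_terminals(pw: PathwayGraph) -> tuple[set[str], set[str]]:
    """Anchor/terminal sets by the degree rule on the protein-level graph.

    Anchors are proteins with no inward directed edges (and at least one
    outward); terminals have no outward edges (and at least one inward).
    Isolated proteins belong to neither set and are logged.
    """
    g = _expanded_protein_graph(pw)
    anchors: set[str] = set()
    terminals: set[str] = set()
    for n in g.nodes:
        indeg, outdeg = g.in_degree(n), g.out_degree(n)
        if indeg == 0 and outdeg == 0:
            logger.warning(
                "pathway %s: isolated node %s excluded from anchors/terminals",
                pw.name, n,
            )
        elif indeg == 0:
            anchors.add(n)
        elif outdeg == 0:
            terminals.add(n)
    if not anchors or not terminals:
        raise PathwayError(
            f"pathway {pw.name!r} unusable for training: "
            f"{len(anchors)} anchors, {len(terminals)} terminals"
        )
    return anchors, terminals
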