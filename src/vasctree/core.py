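"""Vascular tree data model, exchange-format I/O, and skeleton-graph correction.

Vascular systems are represented as strictly bifurcative rooted geometric
trees: nodes carry 3-D positions (mm), edges carry radii (mm) and are
oriented in flow direction (initial -> terminal).  Each edge has exactly
zero or two daughter edges, and exactly one edge is incident to the root
node.  Raw skeletonized graphs extracted from image data usually violate
these invariants (isolated nodes, monofurcations, multifurcations, parallel
parent edges, multiple roots); :func:`correct_graph` repairs them.

Zero-length *trivial* edges are pure bookkeeping devices introduced when
splitting multifurcations; they carry a radius but no geometry.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "Node",
    "Edge",
    "RawVascularGraph",
    "VascularTree",
    "CorrectionLog",
    "GraphFormatError",
    "GraphStructureError",
    "read_graph",
    "write_graph",
    "correct_graph",
]


class GraphFormatError(ValueError):
    """Malformed exchange file (names the offending record)."""


class GraphStructureError(ValueError):
    """Graph violates a structural precondition (e.g. proper loop)."""


@dataclass
class Node:
    id: str
    position: np.ndarray  # shape (3,), mm

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise GraphFormatError(f"node {self.id!r}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise GraphFormatError(f"node {self.id!r}: non-finite position")


@dataclass
class Edge:
    id: str
    initial: str
    terminal: str
    radius: float
    trivial: bool = False

    def __post_init__(self) -> None:
        self.radius = float(self.radius)
        if not np.isfinite(self.radius) or self.radius < 0:
            raise GraphFormatError(f"edge {self.id!r}: radius must be finite and >= 0")


@dataclass
class RawVascularGraph:
    """Possibly defective skeleton graph before correction."""

    nodes: dict[str, Node]
    edges: dict[str, Edge]
    declared_roots: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate_referential()

    def validate_referential(self) -> None:
        for e in self.edges.values():
            for nid in (e.initial, e.terminal):
                if nid not in self.nodes:
                    raise GraphFormatError(
                        f"edge {e.id!r} references unknown node {nid!r}"
                    )

    def copy(self) -> "RawVascularGraph":
        return RawVascularGraph(
            nodes={k: Node(v.id, v.position.copy()) for k, v in self.nodes.items()},
            edges={
                k: Edge(v.id, v.initial, v.terminal, v.radius, v.trivial)
                for k, v in self.edges.items()
            },
            declared_roots=list(self.declared_roots),
        )


class VascularTree:
    """Strictly bifurcative rooted geometric tree.

    Construction validates all invariants: one edge incident to the root
    node, every edge has 0 or 2 daughters, acyclic, all nodes reachable
    from the root.
    """

    def __init__(
        self,
        nodes: Mapping[str, Node],
        edges: Mapping[str, Edge],
        root_node: str,
        validate: bool = True,
    ) -> None:
        self.nodes: dict[str, Node] = dict(nodes)
        self.edges: dict[str, Edge] = dict(edges)
        self.root_node = root_node
        self._index()
        if validate:
            self.validate()

    # -- indexing ---------------------------------------------------------
    def _index(self) -> None:
        self._out: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        self._in: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for e in self.edges.values():
            self._out[e.initial].append(e.id)
            self._in[e.terminal].append(e.id)
        for lst in self._out.values():
            lst.sort()
        for lst in self._in.values():
            lst.sort()

    def validate(self) -> None:
        if self.root_node not in self.nodes:
            raise GraphStructureError(f"root node {self.root_node!r} not in graph")
        if len(self._out[self.root_node]) != 1 or self._in[self.root_node]:
            raise GraphStructureError(
                "root node must have exactly one incident (daughter) edge"
            )
        for e in self.edges.values():
            nd = len(self._out[e.terminal])
            if nd not in (0, 2):
                raise GraphStructureError(
                    f"edge {e.id!r} has {nd} daughters (must be 0 or 2)"
                )
        for nid in self.nodes:
            if nid != self.root_node and len(self._in[nid]) != 1:
                raise GraphStructureError(
                    f"node {nid!r} has {len(self._in[nid])} parent edges"
                )
        # reachability + acyclicity: iterative DFS over edges
        seen_nodes = {self.root_node}
        seen_edges: set[str] = set()
        stack = [self.root_edge]
        while stack:
            eid = stack.pop()
            if eid in seen_edges:
                raise GraphStructureError("cycle detected")
            seen_edges.add(eid)
            t = self.edges[eid].terminal
            seen_nodes.add(t)
            stack.extend(self._out[t])
        if seen_edges != set(self.edges) or seen_nodes != set(self.nodes):
            raise GraphStructureError("not all nodes/edges reachable from root")

    # -- accessors --------------------------------------------------------
    @property
    def root_edge(self) -> str:
        return self._out[self.root_node][0]

    def daughters(self, edge_id: str) -> list[str]:
        """Daughter edge ids of an edge (0 or 2), sorted by id."""
        return self._out[self.edges[edge_id].terminal]

    def parent(self, edge_id: str) -> str | None:
        inc = self._in[self.edges[edge_id].initial]
        return inc[0] if inc else None

    def length(self, edge_id: str) -> float:
        e = self.edges[edge_id]
        return float(
            np.linalg.norm(self.nodes[e.terminal].position - self.nodes[e.initial].position)
        )

    def direction(self, edge_id: str) -> np.ndarray:
        """Unnormalized flow direction vector (terminal - initial)."""
        e = self.edges[edge_id]
        return self.nodes[e.terminal].position - self.nodes[e.initial].position

    def leaf_edges(self) -> list[str]:
        return sorted(e.id for e in self.edges.values() if not self._out[e.terminal])

    def postorder_edges(self) -> list[str]:
        """Edges with every daughter listed before its parent."""
        order: list[str] = []
        stack: list[tuple[str, bool]] = [(self.root_edge, False)]
        while stack:
            eid, done = stack.pop()
            if done:
                order.append(eid)
            else:
                stack.append((eid, True))
                for d in self.daughters(eid):
                    stack.append((d, False))
        return order

    def n_leaves(self) -> int:
        return len(self.leaf_edges())

    def copy(self) -> "VascularTree":
        return VascularTree(
            {k: Node(v.id, v.position.copy()) for k, v in self.nodes.items()},
            {
                k: Edge(v.id, v.initial, v.terminal, v.radius, v.trivial)
                for k, v in self.edges.items()
            },
            self.root_node,
            validate=False,
        )

    def as_raw(self) -> RawVascularGraph:
        return RawVascularGraph(
            nodes={k: Node(v.id, v.position.copy()) for k, v in self.nodes.items()},
            edges={
                k: Edge(v.id, v.initial, v.terminal, v.radius, v.trivial)
                for k, v in self.edges.items()
            },
            declared_roots=[self.root_node],
        )


@dataclass
class CorrectionLog:
    """Record of repairs applied by :func:`correct_graph`."""

    entries: list[dict] = field(default_factory=list)

    def add(self, kind: str, **info) -> None:
        self.entries.append({"kind": kind, **info})

    def kinds(self) -> list[str]:
        return [e["kind"] for e in self.entries]


# ---------------------------------------------------------------------------
# Exchange format I/O
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


def read_graph(path: str | Path, format: str | None = None) -> RawVascularGraph:
    """Read a raw vascular graph from JSON or the two-file CSV dialect.

    ``format`` is ``"json"`` or ``"csv"``; inferred from the path when None
    (a directory or ``.csv`` suffix selects CSV).
    """
    path = Path(path)
    if format is None:
        format = "csv" if (path.is_dir() or path.suffix == ".csv") else "json"
    if format == "json":
        return _read_json(path)
    if format == "csv":
        return _read_csv(path if path.is_dir() else path.parent)
    raise ValueError(f"unknown format {format!r}")


def _read_json(path: Path) -> RawVascularGraph:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise GraphFormatError(f"{path}: invalid JSON: {exc}") from exc
    nodes: dict[str, Node] = {}
    for rec in doc.get("nodes", []):
        try:
            nid = str(rec["id"])
            node = Node(nid, [rec["x"], rec["y"], rec["z"]])
        except KeyError as exc:
            raise GraphFormatError(f"node record {rec!r} missing field {exc}") from exc
        if nid in nodes:
            raise GraphFormatError(f"duplicated node id {nid!r}")
        nodes[nid] = node
    edges: dict[str, Edge] = {}
    for rec in doc.get("edges", []):
        try:
            eid = str(rec["id"])
            edge = Edge(eid, str(rec["from"]), str(rec["to"]), rec["radius"])
        except KeyError as exc:
            raise GraphFormatError(f"edge record {rec!r} missing field {exc}") from exc
        if eid in edges:
            raise GraphFormatError(f"duplicated edge id {eid!r}")
        edges[eid] = edge
    roots = [str(r) for r in doc.get("roots", [])]
    graph = RawVascularGraph(nodes, edges, roots)
    _flag_trivial(graph)
    return graph


def _read_csv(directory: Path) -> RawVascularGraph:
    nodes: dict[str, Node] = {}
    roots: list[str] = []
    with open(directory / "nodes.csv", newline="") as fh:
        for rec in csv.DictReader(fh):
            nid = str(rec["id"])
            if nid in nodes:
                raise GraphFormatError(f"duplicated node id {nid!r}")
            nodes[nid] = Node(nid, [float(rec["x"]), float(rec["y"]), float(rec["z"])])
            if rec.get("root", "0") in ("1", "true", "True"):
                roots.append(nid)
    edges: dict[str, Edge] = {}
    with open(directory / "edges.csv", newline="") as fh:
        for rec in csv.DictReader(fh):
            eid = str(rec["id"])
            if eid in edges:
                raise GraphFormatError(f"duplicated edge id {eid!r}")
            edges[eid] = Edge(eid, str(rec["from"]), str(rec["to"]), float(rec["radius"]))
    graph = RawVascularGraph(nodes, edges, roots)
    _flag_trivial(graph)
    return graph


def _flag_trivial(graph: RawVascularGraph) -> None:
    for e in graph.edges.values():
        if e.initial == e.terminal:
            continue
        p0 = graph.nodes[e.initial].position
        p1 = graph.nodes[e.terminal].position
        e.trivial = bool(np.all(p0 == p1))


def write_graph(
    graph: RawVascularGraph | VascularTree, path: str | Path, format: str | None = None
) -> None:
    """Write a graph in canonical order (nodes then edges, sorted by id)."""
    if isinstance(graph, VascularTree):
        graph = graph.as_raw()
    graph.validate_referential()
    for n in graph.nodes.values():
        if not np.all(np.isfinite(n.position)):
            raise GraphFormatError(f"node {n.id!r}: non-finite position")
    path = Path(path)
    if format is None:
        format = "csv" if (path.is_dir() or path.suffix == ".csv") else "json"
    if format == "json":
        _write_json(graph, path)
    elif format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        _write_csv(graph, path)
    elif format == "vtk":
        _write_vtk(graph, path)
    elif format == "dot":
        _write_dot(graph, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_json(graph: RawVascularGraph, path: Path) -> None:
    doc = {
        "nodes": [
            {
                "id": n.id,
                "x": float(n.position[0]),
                "y": float(n.position[1]),
                "z": float(n.position[2]),
            }
            for n in sorted(graph.nodes.values(), key=lambda n: n.id)
        ],
        "edges": [
            {"id": e.id, "from": e.initial, "to": e.terminal, "radius": float(e.radius)}
            for e in sorted(graph.edges.values(), key=lambda e: e.id)
        ],
        "roots": sorted(graph.declared_roots),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def _write_csv(graph: RawVascularGraph, directory: Path) -> None:
    roots = set(graph.declared_roots)
    with open(directory / "nodes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "z", "root"])
        for n in sorted(graph.nodes.values(), key=lambda n: n.id):
            w.writerow([n.id, _fmt(n.position[0]), _fmt(n.position[1]), _fmt(n.position[2]),
                        1 if n.id in roots else 0])
    with open(directory / "edges.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "from", "to", "radius"])
        for e in sorted(graph.edges.values(), key=lambda e: e.id):
            w.writerow([e.id, e.initial, e.terminal, _fmt(e.radius)])


def _write_vtk(graph: RawVascularGraph, path: Path) -> None:
    """Legacy-VTK polyline export (non-normative, for visualization)."""
    nodes = sorted(graph.nodes.values(), key=lambda n: n.id)
    idx = {n.id: i for i, n in enumerate(nodes)}
    edges = sorted(graph.edges.values(), key=lambda e: e.id)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvascular tree\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(nodes)} float\n")
        for n in nodes:
            fh.write(f"{n.position[0]} {n.position[1]} {n.position[2]}\n")
        fh.write(f"LINES {len(edges)} {3 * len(edges)}\n")
        for e in edges:
            fh.write(f"2 {idx[e.initial]} {idx[e.terminal]}\n")
        fh.write(f"CELL_DATA {len(edges)}\nSCALARS radius float 1\nLOOKUP_TABLE default\n")
        for e in edges:
            fh.write(f"{e.radius}\n")


def _write_dot(graph: RawVascularGraph, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("digraph vasctree {\n")
        for e in sorted(graph.edges.values(), key=lambda e: e.id):
            fh.write(f'  "{e.initial}" -> "{e.terminal}" [label="{e.radius:.3g}"];\n')
        fh.write("}\n")


# ---------------------------------------------------------------------------
# Graph correction
# ---------------------------------------------------------------------------

def correct_graph(
    graph: RawVascularGraph, primary_root: str | None = None
) -> tuple[VascularTree, CorrectionLog]:
    """Repair a raw skeleton graph into a strictly bifurcative tree.

    Repairs, in order: (1) drop self-loop trivial edges; (2) merge parallel
    parent edges sharing one initial node, conserving total cross-section
    area (r = sqrt(sum r_i^2)); (3) among parent edges with distinct initial
    nodes keep the one of maximal radius; (4) remove monofurcations,
    averaging the two radii; (5) split multifurcations into bifurcations by
    inserting zero-length trivial edges; (6) drop isolated nodes; (7) give
    every root a single incident daughter edge (via a trivial root edge if
    needed) and return the component of the primary root.

    The primary root is ``primary_root`` if given, else the declared (or
    discovered) root whose subtree contains the most edges.  Raises
    :class:`GraphStructureError` on proper loops (directed cycles) or an
    empty graph.
    """
    g = graph.copy()
    log = CorrectionLog()
    if not g.edges:
        raise GraphStructureError("cannot correct an empty graph (no edges)")

    nodes, edges = g.nodes, g.edges

    # step 1: remove existing trivial (self-loop) edges
    for eid in sorted(edges):
        e = edges[eid]
        if e.initial == e.terminal:
            del edges[eid]
            log.add("remove_self_loop", edge=eid)

    _check_proper_loops(nodes, edges)

    def in_edges(nid: str) -> list[str]:
        return sorted(e.id for e in edges.values() if e.terminal == nid)

    def out_edges(nid: str) -> list[str]:
        return sorted(e.id for e in edges.values() if e.initial == nid)

    # step 2: merge parallel parent edges with the same initial node
    for nid in sorted(nodes):
        by_init: dict[str, list[str]] = {}
        for eid in in_edges(nid):
            by_init.setdefault(edges[eid].initial, []).append(eid)
        for init, group in sorted(by_init.items()):
            if len(group) > 1:
                radii = [edges[eid].radius for eid in group]
                merged = float(np.sqrt(np.sum(np.square(radii))))
                keep = min(group)
                edges[keep].radius = merged
                for eid in group:
                    if eid != keep:
                        del edges[eid]
                log.add("merge_parallel_parents", node=nid, kept=keep,
                        removed=[e for e in group if e != keep],
                        radii_before=radii, radius_after=merged)

    # step 3: multiple parent edges with distinct initial nodes: keep max radius
    for nid in sorted(nodes):
        inc = in_edges(nid)
        if len(inc) > 1:
            keep = max(inc, key=lambda eid: (edges[eid].radius, *_neg_id(eid)))
            for eid in inc:
                if eid != keep:
                    del edges[eid]
            log.add("resolve_improper_loop", node=nid, kept=keep,
                    removed=[e for e in inc if e != keep])

    # step 4: remove monofurcations (1 parent, 1 daughter), averaging radii
    changed = True
    while changed:
        changed = False
        for nid in sorted(nodes):
            inc, out = in_edges(nid), out_edges(nid)
            if len(inc) == 1 and len(out) == 1:
                e1, e2 = edges[inc[0]], edges[out[0]]
                r = 0.5 * (e1.radius + e2.radius)
                log.add("remove_monofurcation", node=nid, edges=[e1.id, e2.id],
                        radii_before=[e1.radius, e2.radius], radius_after=r)
                e1.terminal = e2.terminal
                e1.radius = r
                p0 = nodes[e1.initial].position
                p1 = nodes[e1.terminal].position
                e1.trivial = bool(np.all(p0 == p1)) and e1.initial != e1.terminal
                del edges[e2.id]
                changed = True

    counter = _IdCounter(nodes, edges)

    # step 5: split multifurcations with trivial edges
    for nid in sorted(nodes):
        out = out_edges(nid)
        if len(out) > 2 and in_edges(nid):
            _split_multifurcation(nodes, edges, nid, out, in_edges(nid)[0], counter, log)

    # step 6: remove isolated nodes
    incident: set[str] = set()
    for e in edges.values():
        incident.add(e.initial)
        incident.add(e.terminal)
    for nid in sorted(nodes):
        if nid not in incident:
            del nodes[nid]
            log.add("remove_isolated_node", node=nid)

    # step 7: fix roots (single incident daughter edge each)
    roots = [nid for nid in sorted(nodes) if not in_edges(nid) and out_edges(nid)]
    for rid in list(roots):
        out = out_edges(rid)
        if len(out) > 1:
            new_root = counter.node_id()
            nodes[new_root] = Node(new_root, nodes[rid].position.copy())
            radius = float(np.sqrt(sum(edges[eid].radius ** 2 for eid in out)))
            teid = counter.edge_id()
            edges[teid] = Edge(teid, new_root, rid, radius, trivial=True)
            log.add("insert_trivial_root_edge", old_root=rid, new_root=new_root,
                    edge=teid, radius=radius)
            if len(out) > 2:
                _split_multifurcation(nodes, edges, rid, out, teid, counter, log)
            roots[roots.index(rid)] = new_root

    if not roots:
        raise GraphStructureError("no root found after correction")

    # pick primary root and extract its component
    subtrees = {rid: _reachable(edges, rid) for rid in roots}
    if primary_root is None:
        declared = [r for r in g.declared_roots]
        # declared ids may have been superseded by inserted trivial roots
        cand = []
        for rid in roots:
            srcs = {rid} | {edges[eid].initial for eid in subtrees[rid][1]}
            if not declared or any(d in srcs or d == rid for d in declared):
                cand.append(rid)
        if not cand:
            cand = roots
        primary = max(cand, key=lambda rid: (len(subtrees[rid][1]), *_neg_id(rid)))
    else:
        matches = [rid for rid in roots
                   if primary_root == rid
                   or primary_root in subtrees[rid][0]]
        if not matches:
            raise GraphStructureError(f"primary root {primary_root!r} not found")
        primary = matches[0]

    keep_nodes, keep_edges = subtrees[primary]
    tree = VascularTree(
        {nid: nodes[nid] for nid in keep_nodes},
        {eid: edges[eid] for eid in keep_edges},
        primary,
    )
    log.add("extract_primary_component", root=primary,
            n_nodes=len(keep_nodes), n_edges=len(keep_edges),
            other_roots=[r for r in roots if r != primary])
    return tree, log


def _neg_id(s: str) -> tuple:
    # descending-lexicographic tiebreak key ("smallest id wins" inside max())
    return tuple(-ord(c) for c in s)


class _IdCounter:
    """Deterministic fresh-id source for inserted nodes/edges."""

    def __init__(self, nodes: Mapping[str, Node], edges: Mapping[str, Edge]) -> None:
        self._n = 0
        self._e = 0
        self._nodes = nodes
        self._edges = edges

    def node_id(self) -> str:
        while True:
            self._n += 1
            nid = f"cn{self._n}"
            if nid not in self._nodes:
                return nid

    def edge_id(self) -> str:
        while True:
            self._e += 1
            eid = f"ce{self._e}"
            if eid not in self._edges:
                return eid


def _split_multifurcation(nodes, edges, nid, out, parent_edge, counter, log) -> None:
    """Split a k-furcation (k>2) at node ``nid`` into k-1 bifurcations."""
    remaining = sorted(out)
    current = nid
    trivial_radius = edges[parent_edge].radius
    inserted = []
    while len(remaining) > 2:
        new_node = counter.node_id()
        nodes[new_node] = Node(new_node, nodes[current].position.copy())
        teid = counter.edge_id()
        edges[teid] = Edge(teid, current, new_node, trivial_radius, trivial=True)
        for eid in remaining[1:]:
            edges[eid].initial = new_node
        inserted.append((new_node, teid))
        current = new_node
        remaining = remaining[1:]
    log.add("split_multifurcation", node=nid, degree=len(out),
            inserted_nodes=[n for n, _ in inserted],
            inserted_edges=[e for _, e in inserted])


def _reachable(edges: Mapping[str, Edge], root: str) -> tuple[set[str], set[str]]:
    out: dict[str, list[str]] = {}
    for e in edges.values():
        out.setdefault(e.initial, []).append(e.id)
    seen_nodes = {root}
    seen_edges: set[str] = set()
    stack = [root]
    while stack:
        nid = stack.pop()
        for eid in out.get(nid, []):
            if eid not in seen_edges:
                seen_edges.add(eid)
                t = edges[eid].terminal
                seen_nodes.add(t)
                stack.append(t)
    return seen_nodes, seen_edges


def _check_proper_loops(nodes: Mapping[str, Node], edges: Mapping[str, Edge]) -> None:
    import networkx as nx

    dg = nx.DiGraph()
    dg.add_nodes_from(nodes)
    dg.add_edges_from((e.initial, e.terminal) for e in edges.values())
    if not nx.is_directed_acyclic_graph(dg):
        raise GraphStructureError("proper loop (directed cycle) detected")
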