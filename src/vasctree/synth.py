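"""Synthetic vascular trees and populations.

No public cohort of skeletonized hepatic vascular trees exists, so the
package ships a generator of synthetic populations that emulates the
relevant statistical structure of such data: random strictly bifurcative
topologies with a configurable leaf-count range, edge lengths and radii
that scale with the supplied subtree size (so feature distributions depend
on the Strahler* order), noisy branching angles with out-of-plane tilt, and
— via :func:`corrupt_graph` — the defects of real skeletonizations
(monofurcations, multifurcations, parallel parent edges, improper loops,
isolated nodes, multiple roots) that the graph correction must repair.

All randomness is driven by seeded Mersenne-Twister generators; identical
specs and seeds reproduce populations bit for bit, and two populations with
the same spec but different seeds are draws from the same tree distribution
(the i.i.d. null of the similarity analysis).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Edge, Node, RawVascularGraph, VascularTree

__all__ = [
    "SyntheticPopulationSpec",
    "make_perfect_tree",
    "make_tree",
    "make_population",
    "make_seed_edge",
    "corrupt_graph",
    "tree_checksum",
]


def make_perfect_tree(depth: int, edge_length: float = 10.0,
                      root_radius: float = 2.0) -> VascularTree:
    """Planar perfect binary tree of the given depth (depth 0 = one edge).

    Radii follow the gamma = 3 halving of flow: each level's radius is
    2^(-1/3) times its parent's.  Used as an exact fixture for ordering and
    feature oracles.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    nodes: dict[str, Node] = {}
    edges: dict[str, Edge] = {}
    counter = {"n": 0, "e": 0}

    def new_node(pos) -> str:
        nid = f"n{counter['n']:04d}"
        counter["n"] += 1
        nodes[nid] = Node(nid, np.asarray(pos, dtype=float))
        return nid

    root = new_node((0.0, 0.0, 0.0))

    def grow(parent_node: str, x: float, y: float, level: int) -> None:
        nid = new_node((x, y - edge_length, 0.0))
        eid = f"e{counter['e']:04d}"
        counter["e"] += 1
        edges[eid] = Edge(eid, parent_node, nid,
                          root_radius * 2.0 ** (-level / 3.0))
        if level < depth:
            spread = edge_length * 2.0 ** (depth - 1 - level)
            grow(nid, x - spread / 2.0, y - edge_length, level + 1)
            grow(nid, x + spread / 2.0, y - edge_length, level + 1)

    grow(root, 0.0, 0.0, 0)
    return VascularTree(nodes, edges, root)


def make_seed_edge(start=(0.0, 0.0, 0.0), end=(0.0, 0.0, -10.0),
                   radius: float = 1.5) -> VascularTree:
    """Single-root-edge tree, the minimal seed for the generator."""
    nodes = {"root": Node("root", np.asarray(start, dtype=float)),
             "n0": Node("n0", np.asarray(end, dtype=float))}
    edges = {"e0": Edge("e0", "root", "n0", radius)}
    return VascularTree(nodes, edges, "root")


@dataclass
class SyntheticPopulationSpec:
    """Parameters of the synthetic tree distribution.

    Lengths/radii scale with the subtree leaf count k as k^decay times
    lognormal noise, which produces order-dependent feature distributions;
    the daughter opening angle is normal around ``angle_mean_deg`` and
    split between the daughters inversely to their flow share; independent
    azimuthal jitter (``tilt_spread_deg``) makes bifurcations nonflat.
    """

    n_trees: int = 10
    leaf_range: tuple[int, int] = (150, 350)
    length_scale: float = 4.0  # mm, terminal-edge scale
    length_decay: float = 1.0 / 3.0
    radius_scale: float = 0.12  # mm, terminal-edge scale
    radius_decay: float = 1.0 / 3.0
    angle_mean_deg: float = 80.0
    angle_spread_deg: float = 12.0
    tilt_spread_deg: float = 8.0
    size_noise: float = 0.15  # lognormal sigma for lengths/radii
    split_alpha: float = 2.0  # Beta(a, a) split of leaf counts
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.length_scale, self.radius_scale) <= 0:
            raise ValueError("scales must be positive")
        if self.leaf_range[0] < 1 or self.leaf_range[1] < self.leaf_range[0]:
            raise ValueError("invalid leaf range")


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about the unit axis."""
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * float(axis @ v) * (1 - c)


def _perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        w = rng.normal(size=3)
        w -= (w @ u) * u
        n = np.linalg.norm(w)
        if n > 1e-8:
            return w / n


def make_tree(spec: SyntheticPopulationSpec, rng: np.random.Generator,
              leaf_count: int | None = None) -> VascularTree:
    """One synthetic tree drawn from the spec's distribution."""
    k0 = leaf_count if leaf_count is not None else int(
        rng.integers(spec.leaf_range[0], spec.leaf_range[1] + 1))
    nodes: dict[str, Node] = {}
    edges: dict[str, Edge] = {}
    counter = {"n": 0, "e": 0}

    def new_node(pos) -> str:
        nid = f"n{counter['n']:05d}"
        counter["n"] += 1
        nodes[nid] = Node(nid, np.asarray(pos, dtype=float))
        return nid

    def noise() -> float:
        return float(np.exp(rng.normal(0.0, spec.size_noise)))

    root = new_node((0.0, 0.0, 0.0))
    # stack entries: (attach node id, unit direction, leaf count)
    stack = [(root, np.array([0.0, 0.0, -1.0]), k0)]
    while stack:
        nid, u, k = stack.pop()
        length = spec.length_scale * k**spec.length_decay * noise()
        radius = spec.radius_scale * k**spec.radius_decay * noise()
        term = new_node(nodes[nid].position + length * u)
        eid = f"e{counter['e']:05d}"
        counter["e"] += 1
        edges[eid] = Edge(eid, nid, term, radius)
        if k > 1:
            frac = rng.beta(spec.split_alpha, spec.split_alpha)
            k1 = min(max(int(round(k * frac)), 1), k - 1)
            k2 = k - k1
            phi_a = math.radians(float(np.clip(
                rng.normal(spec.angle_mean_deg, spec.angle_spread_deg), 15.0, 165.0)))
            # flow-weighted split: the smaller branch deviates more
            th1 = phi_a * k2 / k
            th2 = phi_a * k1 / k
            n = _perpendicular(u, rng)
            d1 = _rotate(u, n, th1)
            d2 = _rotate(u, n, -th2)
            tilt = math.radians(spec.tilt_spread_deg)
            d1 = _rotate(d1, u, rng.normal(0.0, tilt))
            d2 = _rotate(d2, u, rng.normal(0.0, tilt))
            stack.append((term, d1 / np.linalg.norm(d1), k1))
            stack.append((term, d2 / np.linalg.norm(d2), k2))
    return VascularTree(nodes, edges, root)


def make_population(spec: SyntheticPopulationSpec) -> list[VascularTree]:
    """Seeded population of synthetic trees (deterministic given the spec)."""
    trees = []
    for i in range(spec.n_trees):
        ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(i,))
        rng = np.random.Generator(np.random.MT19937(ss))
        trees.append(make_tree(spec, rng))
    return trees


# ---------------------------------------------------------------------------
# Defect injection (fixture for the graph correction)
# ---------------------------------------------------------------------------

def corrupt_graph(tree: VascularTree, seed: int,
                  n_defects: int = 6) -> RawVascularGraph:
    """Inject skeletonization-style defects into a valid tree.

    Randomly applies, with repetition: monofurcation insertion (an edge split
    into a chain), multifurcation creation (reattaching a grandchild edge to
    its grandparent node), parallel parent duplication (same initial node),
    an extra parent edge from a non-descendant node (improper loop),
    self-loop trivial edges, isolated nodes, and an extra disconnected root
    component.  The result has referential integrity and no proper loops, so
    the correction step can always repair it.
    """
    rng = np.random.Generator(np.random.MT19937(seed))
    raw = tree.as_raw()
    counter = {"n": 0, "e": 0}

    def new_nid() -> str:
        counter["n"] += 1
        return f"x{seed}n{counter['n']}"

    def new_eid() -> str:
        counter["e"] += 1
        return f"x{seed}e{counter['e']}"

    def descendants(nid: str) -> set[str]:
        out: dict[str, list[str]] = {}
        for e in raw.edges.values():
            out.setdefault(e.initial, []).append(e.terminal)
        seen = {nid}
        stack = [nid]
        while stack:
            cur = stack.pop()
            for t in out.get(cur, []):
                if t not in seen:
                    seen.add(t)
                    stack.append(t)
        return seen

    for _ in range(n_defects):
        kind = rng.integers(0, 7)
        eids = sorted(raw.edges)
        nids = sorted(raw.nodes)
        if kind == 0:  # monofurcation: split an edge into a chain
            eid = eids[rng.integers(len(eids))]
            e = raw.edges[eid]
            if e.initial == e.terminal:  # splitting a self-loop makes a real cycle
                continue
            p0 = raw.nodes[e.initial].position
            p1 = raw.nodes[e.terminal].position
            mid = new_nid()
            raw.nodes[mid] = Node(mid, 0.5 * (p0 + p1))
            tail = new_eid()
            raw.edges[tail] = Edge(tail, mid, e.terminal,
                                   e.radius * float(rng.uniform(0.8, 1.2)))
            e.terminal = mid
        elif kind == 1:  # multifurcation: lift a grandchild edge up
            parents = [i for i in eids
                       if any(raw.edges[j].initial == raw.edges[i].terminal
                              for j in eids)]
            if parents:
                eid = parents[rng.integers(len(parents))]
                e = raw.edges[eid]
                kids = [j for j in eids if raw.edges[j].initial == e.terminal]
                gkids = [j for j in eids
                         if raw.edges[j].initial in
                         {raw.edges[kk].terminal for kk in kids}]
                if gkids:
                    g = raw.edges[gkids[rng.integers(len(gkids))]]
                    g.initial = e.terminal
        elif kind == 2:  # parallel parent edges, same initial node
            eid = eids[rng.integers(len(eids))]
            e = raw.edges[eid]
            dup = new_eid()
            raw.edges[dup] = Edge(dup, e.initial, e.terminal,
                                  e.radius * float(rng.uniform(0.3, 0.9)))
        elif kind == 3:  # improper loop: extra parent from a non-descendant
            eid = eids[rng.integers(len(eids))]
            e = raw.edges[eid]
            pool = sorted(set(nids) - descendants(e.terminal) - {e.initial})
            if pool:
                src = pool[rng.integers(len(pool))]
                ne = new_eid()
                raw.edges[ne] = Edge(ne, src, e.terminal,
                                     e.radius * float(rng.uniform(0.2, 0.8)))
        elif kind == 4:  # self-loop trivial edge
            nid = nids[rng.integers(len(nids))]
            ne = new_eid()
            raw.edges[ne] = Edge(ne, nid, nid, float(rng.uniform(0.1, 1.0)))
        elif kind == 5:  # isolated node
            nid = new_nid()
            raw.nodes[nid] = Node(nid, rng.normal(size=3) * 10.0)
        else:  # extra disconnected component with its own root
            a, b, c = new_nid(), new_nid(), new_nid()
            base = rng.normal(size=3) * 50.0
            raw.nodes[a] = Node(a, base)
            raw.nodes[b] = Node(b, base + rng.normal(size=3))
            raw.nodes[c] = Node(c, base + rng.normal(size=3))
            e1, e2 = new_eid(), new_eid()
            raw.edges[e1] = Edge(e1, a, b, 0.5)
            raw.edges[e2] = Edge(e2, a, c, 0.4)
            raw.declared_roots.append(a)
    if tree.root_node not in raw.declared_roots:
        raw.declared_roots.insert(0, tree.root_node)
    return raw


def tree_checksum(tree: VascularTree) -> str:
    """SHA-256 of the canonical serialization (stable across runs)."""
    doc = {
        "nodes": [[nid, tree.nodes[nid].position.tolist()]
                  for nid in sorted(tree.nodes)],
        "edges": [[eid, tree.edges[eid].initial, tree.edges[eid].terminal,
                   tree.edges[eid].radius] for eid in sorted(tree.edges)],
        "root": tree.root_node,
    }
    return hashlib.sha256(json.dumps(doc).encode()).hexdigest()
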