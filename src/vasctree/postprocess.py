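"""Tree surgery and angle postprocessing for generated vascular trees.

The optimality criterion behind CCO makes bifurcations flat (the parent lies
in the daughters' plane) and the angles between daughters too small compared
with measured hepatic trees.  Two postprocessing steps repair this:

* :func:`bisector_shift` moves every bifurcation point along the daughters'
  angle bisector (away from the parent) by a fixed fraction — 9% by default —
  of the mean daughter length, widening the daughter angle phi_a.
* :func:`nonflatness_adjust` lifts bifurcation points out of plane.  The
  *nonflatness* of a bifurcation is the distance of the bifurcation point
  from the triangle spanned by the parent's initial node and the daughters'
  terminal nodes, relative to the triangle's longest side; adjusted trees
  draw target nonflatness values from an empirical distribution (measured
  on a reference population) and move each bifurcation along the triangle
  normal until its nonflatness matches the draw.

Neither step rebalances radii afterwards — rebalancing after the geometric
edits decreases similarity to measured trees.

The module also hosts the pruning/contraction surgery used by the
calibration pipeline: short-edge contraction, pruning to coarse anatomy
(root-side edges that are outside the organ or thick relative to the
maximum radius), and removal of one leaf level.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import CorrectionLog, VascularTree, correct_graph
from .domain import OrganDomain

__all__ = [
    "NonflatnessDistribution",
    "contract_short_edges",
    "prune_to_coarse",
    "coarse_keep_set",
    "prune_leaf_level",
    "bisector_shift",
    "nonflatness",
    "tree_nonflatness_sample",
    "nonflatness_adjust",
]

DEFAULT_SHIFT_FRACTION = 0.09
DEFAULT_SHORT_EDGE_THRESHOLD = 0.1  # mm


@dataclass
class NonflatnessDistribution:
    """Empirical sample of nonflatness ratios (dimensionless, >= 0)."""

    values: np.ndarray
    source: str = "unspecified"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("empty nonflatness distribution")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("nonflatness ratios must be finite and >= 0")

    @classmethod
    def from_csv(cls, path: str | Path) -> "NonflatnessDistribution":
        """One-column CSV (no header, or a single 'nonflatness' header)."""
        vals = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row:
                    continue
                try:
                    vals.append(float(row[0]))
                except ValueError:
                    continue  # header line
        return cls(np.array(vals), source=str(path))

    @classmethod
    def synthetic_halfnormal(cls, scale: float = 0.05, size: int = 500,
                             seed: int = 0) -> "NonflatnessDistribution":
        """Synthetic stand-in distribution (half-normal); use a measured
        sample via :func:`tree_nonflatness_sample` whenever one exists."""
        rng = np.random.Generator(np.random.MT19937(seed))
        return cls(np.abs(rng.normal(0.0, scale, size)),
                   source=f"synthetic half-normal scale={scale}")

    @classmethod
    def from_population(cls, trees: Sequence[VascularTree]) -> "NonflatnessDistribution":
        vals = np.concatenate([tree_nonflatness_sample(t) for t in trees])
        if vals.size == 0:
            raise ValueError("no nondegenerate bifurcations in population")
        return cls(vals, source=f"measured on {len(trees)} trees")

    def sample(self, rng: np.random.Generator) -> float:
        """Seeded inverse-CDF draw from the empirical distribution."""
        return float(self.values[rng.integers(self.values.size)])


# ---------------------------------------------------------------------------
# Contraction and pruning
# ---------------------------------------------------------------------------

def contract_short_edges(tree: VascularTree, threshold: float = DEFAULT_SHORT_EDGE_THRESHOLD) -> VascularTree:
    """Contract every nontrivial edge shorter than ``threshold`` to length 0.

    The edge's terminal node (and with it all downstream initial points) is
    moved onto the parent-side node, making the edge trivial; repeated until
    stable.  Features involving contracted edges become undefined downstream.
    """
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for eid in sorted(out.edges):
            e = out.edges[eid]
            if e.trivial:
                continue
            length = out.length(eid)
            if 0 < length < threshold or (length == 0 and not e.trivial):
                out.nodes[e.terminal].position = out.nodes[e.initial].position.copy()
                e.trivial = True
                changed = True
    return out


def coarse_keep_set(tree: VascularTree, domain: OrganDomain,
                    radius_fraction: float = 0.25) -> set[str]:
    """Edge ids kept by the coarse-anatomy rule: starting from the root
    edge (always kept), an edge survives while its initial node is outside
    the organ or its radius exceeds ``radius_fraction`` times the tree's
    maximum radius; recursion stops at the first failing edge."""
    r_max = max(e.radius for e in tree.edges.values())
    keep: set[str] = set()
    stack = [tree.root_edge]
    keep.add(tree.root_edge)
    while stack:
        eid = stack.pop()
        for d in tree.daughters(eid):
            e = tree.edges[d]
            outside = not domain.contains(tree.nodes[e.initial].position)
            if outside or e.radius > radius_fraction * r_max:
                keep.add(d)
                stack.append(d)
    return keep


def prune_to_coarse(tree: VascularTree, domain: OrganDomain,
                    radius_fraction: float = 0.25) -> tuple[VascularTree, CorrectionLog]:
    """Prune to the coarse anatomy (see :func:`coarse_keep_set`) and
    re-correct the resulting monofurcations into a valid tree."""
    keep = coarse_keep_set(tree, domain, radius_fraction)
    raw = tree.as_raw()
    for eid in list(raw.edges):
        if eid not in keep:
            del raw.edges[eid]
    return correct_graph(raw, primary_root=tree.root_node)


def prune_leaf_level(tree: VascularTree,
                     prune_nodes: Sequence[str] | None = None) -> tuple[VascularTree, CorrectionLog]:
    """Remove one bifurcation level of leaves and re-correct.

    By default every current leaf edge is removed.  ``prune_nodes`` limits
    (and possibly extends, across cascades) removal to leaf edges whose
    terminal node is in the given set — used by the calibration pipeline to
    prune the generated leaves together with the coarse seed tree's leaves.
    Raises if the whole tree would vanish.
    """
    targets = None if prune_nodes is None else set(prune_nodes)
    raw = tree.as_raw()

    def leaf_edges() -> list[str]:
        initials = {e.initial for e in raw.edges.values()}
        return [eid for eid, e in raw.edges.items() if e.terminal not in initials]

    while True:
        removable = [eid for eid in leaf_edges()
                     if targets is None or raw.edges[eid].terminal in targets]
        if not removable:
            break
        if len(removable) >= len(raw.edges):
            raise ValueError("pruning would remove the entire tree")
        for eid in removable:
            del raw.edges[eid]
        if targets is None:  # exactly one bifurcation level
            break
    if not raw.edges:
        raise ValueError("pruning would remove the entire tree")
    return correct_graph(raw, primary_root=tree.root_node)


# ---------------------------------------------------------------------------
# Angle postprocessing
# ---------------------------------------------------------------------------

def bisector_shift(tree: VascularTree, fraction: float = DEFAULT_SHIFT_FRACTION,
                   log: list | None = None) -> VascularTree:
    """Shift every bifurcation point along the daughters' angle bisector.

    The displacement is ``fraction`` times the mean of the two daughter
    lengths, directed away from the parent side (which widens phi_a); all
    displacements are computed from the input geometry and applied
    simultaneously, daughter endpoints and radii stay fixed, and radii are
    *not* rebalanced afterwards.  Bifurcations with an undefined bisector
    (antiparallel daughters) are skipped.
    """
    out = tree.copy()
    shifts: dict[str, np.ndarray] = {}
    for eid in sorted(tree.edges):
        ds = tree.daughters(eid)
        if not ds:
            continue
        node = tree.edges[eid].terminal
        d1 = tree.direction(ds[0])
        d2 = tree.direction(ds[1])
        l1, l2 = np.linalg.norm(d1), np.linalg.norm(d2)
        if l1 == 0 or l2 == 0:
            if log is not None:
                log.append({"skip": node, "reason": "zero-length daughter"})
            continue
        bis = d1 / l1 + d2 / l2
        nb = np.linalg.norm(bis)
        if nb < 1e-12:
            if log is not None:
                log.append({"skip": node, "reason": "antiparallel daughters"})
            continue
        shifts[node] = (fraction * 0.5 * (l1 + l2)) * (bis / nb)
    for node, shift in shifts.items():
        out.nodes[node].position = out.nodes[node].position + shift
    for e in out.edges.values():  # refresh trivial flags after moving nodes
        e.trivial = bool(
            np.all(out.nodes[e.initial].position == out.nodes[e.terminal].position)
        )
    return out


def _point_triangle_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                             c: np.ndarray) -> tuple[float, np.ndarray]:
    """Distance from p to the solid triangle abc and the closest point."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = float(ab @ ap), float(ac @ ap)
    if d1 <= 0 and d2 <= 0:
        return float(np.linalg.norm(p - a)), a
    bp = p - b
    d3, d4 = float(ab @ bp), float(ac @ bp)
    if d3 >= 0 and d4 <= d3:
        return float(np.linalg.norm(p - b)), b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        q = a + v * ab
        return float(np.linalg.norm(p - q)), q
    cp = p - c
    d5, d6 = float(ab @ cp), float(ac @ cp)
    if d6 >= 0 and d5 <= d6:
        return float(np.linalg.norm(p - c)), c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        q = a + w * ac
        return float(np.linalg.norm(p - q)), q
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        q = b + w * (c - b)
        return float(np.linalg.norm(p - q)), q
    denom = va + vb + vc
    v = vb / denom
    w = vc / denom
    q = a + v * ab + w * ac
    return float(np.linalg.norm(p - q)), q


def _bifurcation_triangle(tree: VascularTree, parent_edge: str):
    """(bifurcation point, triangle vertices, longest side, unit normal) or
    None for degenerate/leaf cases."""
    ds = tree.daughters(parent_edge)
    if not ds:
        return None
    e = tree.edges[parent_edge]
    p = tree.nodes[e.terminal].position
    a = tree.nodes[e.initial].position
    b = tree.nodes[tree.edges[ds[0]].terminal].position
    c = tree.nodes[tree.edges[ds[1]].terminal].position
    cross = np.cross(b - a, c - a)
    ncl = float(np.linalg.norm(cross))
    longest = max(float(np.linalg.norm(b - a)), float(np.linalg.norm(c - a)),
                  float(np.linalg.norm(c - b)))
    if ncl < 1e-12 * max(longest, 1.0) ** 2 or longest == 0:
        return None  # collinear (degenerate) triangle
    return p, (a, b, c), longest, cross / ncl


def nonflatness(tree: VascularTree, parent_edge: str) -> float:
    """Distance of the bifurcation point at the end of ``parent_edge`` from
    the triangle (parent initial node, daughter terminal nodes), relative to
    the triangle's longest side; NaN for leaves or degenerate triangles."""
    tri = _bifurcation_triangle(tree, parent_edge)
    if tri is None:
        return math.nan
    p, (a, b, c), longest, _ = tri
    d, _q = _point_triangle_distance(p, a, b, c)
    return d / longest


def tree_nonflatness_sample(tree: VascularTree) -> np.ndarray:
    """All defined nonflatness ratios of a tree."""
    vals = [nonflatness(tree, eid) for eid in sorted(tree.edges)]
    arr = np.array(vals, dtype=float)
    return arr[np.isfinite(arr)]


def nonflatness_adjust(tree: VascularTree, distribution: NonflatnessDistribution,
                       seed: int = 0, log: list | None = None,
                       tol: float = 1e-10, max_passes: int = 500) -> VascularTree:
    """Move bifurcation points out of their triangle planes so that the
    tree's nonflatness ratios follow ``distribution``.

    For each nondegenerate bifurcation (in sorted parent-edge order) a target
    ratio is drawn once from the empirical distribution and a normal
    direction sign is drawn at random.  Placing a bifurcation at its closest
    triangle point offset by target * longest side along the triangle normal
    realizes its target exactly — but every bifurcation point is itself a
    vertex of its neighbours' triangles, so the placements are iterated to a
    fixed point until all ratios match their targets within ``tol``.
    Applied uniformly over all Strahler* orders; radii unchanged.
    """
    out = tree.copy()
    rng = np.random.Generator(np.random.MT19937(seed))
    draws: dict[str, tuple[float, float]] = {}
    for eid in sorted(tree.edges):
        if _bifurcation_triangle(tree, eid) is None:
            if tree.daughters(eid) and log is not None:
                log.append({"skip": eid, "reason": "degenerate triangle"})
            continue
        target = distribution.sample(rng)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        draws[eid] = (target, sign)
    for _pass in range(max_passes):
        worst = 0.0
        for eid, (target, sign) in draws.items():
            tri = _bifurcation_triangle(out, eid)
            if tri is None:
                continue
            p, (a, b, c), longest, n = tri
            _d, q = _point_triangle_distance(p, a, b, c)
            node = out.edges[eid].terminal
            out.nodes[node].position = q + sign * target * longest * n
        for eid, (target, _sign) in draws.items():
            v = nonflatness(out, eid)
            if math.isfinite(v):
                worst = max(worst, abs(v - target))
        if worst <= tol:
            return out
    if log is not None:
        log.append({"warning": "nonflatness fixed point not reached",
                    "residual": worst})
    return out
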