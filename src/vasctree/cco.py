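"""Constrained Constructive Optimization (CCO) for vascular tree generation.

CCO grows a strictly binary tree by adding one leaf at a time.  Each
insertion splits a nearby existing edge with a new bifurcation whose
position minimizes the target functional

    F(T) = sum_edges l(e) r(e)^lambda + C * sum_nodes dist^2(node, organ)

(lambda = 2 makes the first term proportional to intravascular volume; the
second term penalizes nodes outside a nonconvex organ, C = 42 mm^(lambda-1)
when lengths are in mm).  At every cost evaluation the radii of the whole
tree are rebalanced so that (i) each leaf receives equal flow, (ii) at every
bifurcation the daughter radii satisfy the branching-exponent law
r_1^gamma + r_2^gamma = r_p^gamma with gamma = 3 (Murray's law), and
(iii) Hagen-Poiseuille pressure drops from root to every leaf are equal.
Skipping the mid-optimization rebalancing changes results considerably, so
it is never skipped.

Blood viscosity is radius dependent below ~150 um (Fahraeus-Lindqvist
effect): mu(r) = mu_inf (1 + delta/r)^2 with mu_inf = 4.0 cP and
delta = 4.29 um, blended linearly into the constant regime over
[140, 160] um.

The bifurcation position is optimized by gradient descent with Armijo
backtracking; gradients are central finite differences because moving a
bifurcation changes radii globally through the rebalancing.  For each new
leaf the 40 edges with closest midpoints are tried: each candidate is
optimized with a rough tolerance (square root of the final tolerance), the
20 best are re-optimized fully, and the cheapest connection is committed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from .core import Edge, Node, VascularTree
from .domain import OrganDomain

__all__ = [
    "CCOConfig",
    "FlowState",
    "viscosity",
    "edge_resistance",
    "rebalance_radii",
    "tree_cost",
    "candidate_edges",
    "optimize_bifurcation",
    "add_leaf",
    "generate",
    "RebalanceError",
]

MU_INF_CP = 4.0  # asymptotic viscosity [cP]
DELTA_UM = 4.29  # Fahraeus-Lindqvist constant [um]
_BLEND_LO, _BLEND_HI = 140.0, 160.0  # linear transition range [um]
_R_CLAMP = 4.0  # formula clamped below this radius [um]


class RebalanceError(RuntimeError):
    pass


@dataclass
class CCOConfig:
    """Tunables of the generator; defaults follow the standard choices.

    ``final_tolerance`` is the gradient-descent stopping step norm in mm;
    candidate pre-screening uses its square root.  ``root_condition`` is
    either ``fixed_root_radius`` (absolute scale from the seed tree or
    ``root_radius``) or ``fixed_pressure_drop`` (scale from ``pressure_drop``
    in Pa with ``leaf_flow`` in m^3/s per leaf).
    """

    lambda_exponent: float = 2.0
    penalty_C: float = 42.0  # mm^(lambda-1)
    n_candidates: int = 40
    n_shortlist: int = 20
    final_tolerance: float = 1e-3  # mm
    gamma: float = 3.0
    viscosity_model: Literal["constant", "radius_dependent"] = "radius_dependent"
    mu_constant: float = MU_INF_CP  # cP, used by the constant model
    root_condition: Literal["fixed_root_radius", "fixed_pressure_drop"] = "fixed_root_radius"
    root_radius: float | None = None  # mm; default: seed tree root edge radius
    pressure_drop: float | None = None  # Pa (fixed_pressure_drop mode)
    leaf_flow: float = 1e-9  # m^3/s per leaf (only sets absolute pressures)
    seed: int = 0
    max_sweeps: int = 200
    sweep_tol: float = 1e-10
    max_gd_iterations: int = 200
    armijo_factor: float = 0.5
    armijo_slope: float = 1e-4

    @property
    def rough_tolerance(self) -> float:
        return math.sqrt(self.final_tolerance)

    def __post_init__(self) -> None:
        if self.lambda_exponent <= 0:
            raise ValueError("lambda_exponent must be > 0")
        if self.penalty_C < 0:
            raise ValueError("penalty_C must be >= 0")
        if self.n_shortlist > self.n_candidates:
            raise ValueError("n_shortlist must be <= n_candidates")


def viscosity(r_um: float | np.ndarray, model: str = "radius_dependent",
              mu_constant: float = MU_INF_CP) -> float | np.ndarray:
    """Apparent blood viscosity [cP] for tube radius ``r_um`` [um].

    mu(r) = mu_inf (1 + delta/r)^2 below 140 um (radius clamped at 4 um),
    linear transition to mu_inf across [140, 160] um, mu_inf above.
    Continuous everywhere; raises on r <= 0.
    """
    scalar = np.isscalar(r_um)
    r = np.atleast_1d(np.asarray(r_um, dtype=float))
    if np.any(r <= 0):
        raise ValueError("viscosity requires r > 0")
    if model == "constant":
        out = np.full_like(r, mu_constant)
        return float(out[0]) if scalar else out
    rc = np.clip(r, _R_CLAMP, None)
    fl = MU_INF_CP * (1.0 + DELTA_UM / rc) ** 2
    mu_lo = MU_INF_CP * (1.0 + DELTA_UM / _BLEND_LO) ** 2
    w = np.clip((rc - _BLEND_LO) / (_BLEND_HI - _BLEND_LO), 0.0, 1.0)
    out = np.where(rc <= _BLEND_LO, fl, (1.0 - w) * mu_lo + w * MU_INF_CP)
    return float(out[0]) if scalar else out


def edge_resistance(l_mm: float, r_mm: float,
                    viscosity_model: str | Callable[[float], float] = "radius_dependent",
                    mu_constant: float = MU_INF_CP) -> float:
    """Hagen-Poiseuille resistance R = 8 mu l / (pi r^4) in SI [Pa s m^-3].

    Zero-length (trivial) edges have R = 0.  ``viscosity_model`` is
    "constant", "radius_dependent", or a callable mapping r [um] to cP.
    """
    if l_mm == 0:
        return 0.0
    if r_mm <= 0:
        raise ValueError("edge_resistance requires r > 0 on nontrivial edges")
    if callable(viscosity_model):
        mu_cp = viscosity_model(r_mm * 1000.0)
    else:
        mu_cp = viscosity(r_mm * 1000.0, viscosity_model, mu_constant)
    return 8.0 * (mu_cp * 1e-3) * (l_mm * 1e-3) / (math.pi * (r_mm * 1e-3) ** 4)


# ---------------------------------------------------------------------------
# Internal array-based network (fast attach/rebalance/cost)
# ---------------------------------------------------------------------------

class _Net:
    """Compact array representation of a strictly bifurcative tree."""

    def __init__(self) -> None:
        self.pos: np.ndarray = np.empty((0, 3))
        self.einit: list[int] = []
        self.eterm: list[int] = []
        self.echild: list[tuple[int, int] | None] = []
        self.eparent: list[int] = []
        self.root_edge: int = 0
        self.node_ids: list[str] = []
        self.edge_ids: list[str] = []
        self.radii: np.ndarray | None = None  # mm, warm start for rebalance
        self._post: list[int] | None = None
        self._leafcnt: np.ndarray | None = None

    @classmethod
    def from_tree(cls, tree: VascularTree) -> "_Net":
        net = cls()
        net.node_ids = sorted(tree.nodes)
        nidx = {nid: i for i, nid in enumerate(net.node_ids)}
        net.pos = np.array([tree.nodes[nid].position for nid in net.node_ids])
        net.edge_ids = sorted(tree.edges)
        eidx = {eid: i for i, eid in enumerate(net.edge_ids)}
        radii = []
        for eid in net.edge_ids:
            e = tree.edges[eid]
            net.einit.append(nidx[e.initial])
            net.eterm.append(nidx[e.terminal])
            radii.append(e.radius)
        for eid in net.edge_ids:
            ds = tree.daughters(eid)
            net.echild.append((eidx[ds[0]], eidx[ds[1]]) if ds else None)
            p = tree.parent(eid)
            net.eparent.append(eidx[p] if p is not None else -1)
        net.root_edge = eidx[tree.root_edge]
        net.radii = np.array(radii, dtype=float)
        return net

    @property
    def n_edges(self) -> int:
        return len(self.einit)

    def postorder(self) -> list[int]:
        if self._post is None:
            order: list[int] = []
            stack: list[tuple[int, bool]] = [(self.root_edge, False)]
            while stack:
                e, done = stack.pop()
                if done:
                    order.append(e)
                else:
                    stack.append((e, True))
                    if self.echild[e] is not None:
                        stack.append((self.echild[e][0], False))
                        stack.append((self.echild[e][1], False))
            self._post = order
        return self._post

    def leaf_counts(self) -> np.ndarray:
        if self._leafcnt is None:
            cnt = np.zeros(self.n_edges)
            for e in self.postorder():
                ch = self.echild[e]
                cnt[e] = 1.0 if ch is None else cnt[ch[0]] + cnt[ch[1]]
            self._leafcnt = cnt
        return self._leafcnt

    def lengths(self) -> np.ndarray:
        ei = np.asarray(self.einit)
        et = np.asarray(self.eterm)
        return np.linalg.norm(self.pos[et] - self.pos[ei], axis=1)

    def clone(self) -> "_Net":
        net = _Net.__new__(_Net)
        net.pos = self.pos.copy()
        net.einit = list(self.einit)
        net.eterm = list(self.eterm)
        net.echild = list(self.echild)
        net.eparent = list(self.eparent)
        net.root_edge = self.root_edge
        net.node_ids = list(self.node_ids)
        net.edge_ids = list(self.edge_ids)
        net.radii = None if self.radii is None else self.radii.copy()
        net._post = None if self._post is None else list(self._post)
        net._leafcnt = None if self._leafcnt is None else self._leafcnt.copy()
        return net

    def attach(self, target_edge: int, leaf_pos: np.ndarray,
               bif_pos: np.ndarray, node_tag: str, edge_tag: str) -> tuple["_Net", int, int]:
        """Clone and split ``target_edge`` (u->v) with a new bifurcation at
        ``bif_pos`` connecting a new leaf at ``leaf_pos``.  Returns
        (net, bifurcation node index, leaf edge index)."""
        net = self.clone()
        nb = net.pos.shape[0]
        nl = nb + 1
        net.pos = np.vstack([net.pos, bif_pos[None, :], leaf_pos[None, :]])
        net.node_ids += [f"{node_tag}b", f"{node_tag}l"]
        t = target_edge
        v = net.eterm[t]
        f = net.n_edges  # continuation b->v
        g = f + 1  # new leaf edge b->x
        net.einit += [nb, nb]
        net.eterm += [v, nl]
        net.edge_ids += [f"{edge_tag}c", f"{edge_tag}l"]
        net.echild += [net.echild[t], None]
        net.eparent += [t, t]
        old_children = net.echild[t]
        if old_children is not None:
            net.eparent[old_children[0]] = f
            net.eparent[old_children[1]] = f
        net.echild[t] = (f, g)
        net.eterm[t] = nb
        if net.radii is not None:
            rt = net.radii[t]
            net.radii = np.concatenate([net.radii, [rt, rt * 0.7]])
        net._post = None
        net._leafcnt = None
        return net, nb, g


_MU140 = MU_INF_CP * (1.0 + DELTA_UM / _BLEND_LO) ** 2  # cP at 140 um


def _mu_pa_s(r_m: float, constant_mu: float | None) -> float:
    """Scalar viscosity [Pa s] for a radius in meters (fast inner-loop path)."""
    if constant_mu is not None:
        return constant_mu
    r = r_m * 1e6
    if r >= _BLEND_HI:
        return MU_INF_CP * 1e-3
    if r < _R_CLAMP:
        r = _R_CLAMP
    if r <= _BLEND_LO:
        return MU_INF_CP * (1.0 + DELTA_UM / r) ** 2 * 1e-3
    w = (r - _BLEND_LO) / (_BLEND_HI - _BLEND_LO)
    return ((1.0 - w) * _MU140 + w * MU_INF_CP) * 1e-3


def _rebalance_core(
    post: list[int],
    children: list[tuple[int, int] | None],
    root_edge: int,
    Q: list[float],
    L_m: list[float],
    r_m: list[float],
    cfg: CCOConfig,
    root_radius_m: float | None,
) -> list[float]:
    """Fixed-point radius rebalancing over plain Python lists (hot path).

    Each sweep freezes viscosities at the current radii, accumulates reduced
    resistances leaf-to-root while choosing daughter fractions beta so that
    the branching-exponent law holds and both daughter subtrees produce
    equal pressure drops, then propagates absolute radii root-to-leaf.
    Sweeps repeat until the maximum relative radius change falls below
    ``cfg.sweep_tol``; with constant viscosity the first sweep is exact.
    Returns radii in meters.
    """
    nE = len(post)
    g = cfg.gamma
    inv_g = -1.0 / g
    const_mu = cfg.mu_constant * 1e-3 if cfg.viscosity_model == "constant" else None
    fixed_dp = cfg.root_condition == "fixed_pressure_drop"
    if fixed_dp and cfg.pressure_drop is None:
        raise ValueError("fixed_pressure_drop mode needs cfg.pressure_drop")
    if not fixed_dp and root_radius_m is None:
        raise ValueError("fixed_root_radius mode needs a root radius")
    K = [0.0] * nE
    beta = [1.0] * nE
    coef = 8.0 / math.pi
    tiny = 1e-300
    for _sweep in range(cfg.max_sweeps):
        for e in post:
            kappa = coef * _mu_pa_s(r_m[e], const_mu) * L_m[e]
            ch = children[e]
            if ch is None:
                K[e] = kappa
            else:
                a, b = ch
                wa = Q[a] * K[a]
                wb = Q[b] * K[b]
                if wa <= tiny or wb <= tiny:
                    x = 1.0 if wa <= tiny and wb <= tiny else (tiny if wa <= tiny else 1e75)
                else:
                    x = (wa / wb) ** 0.25
                bb = (1.0 + x**g) ** inv_g
                ba = x * bb
                beta[a] = ba
                beta[b] = bb
                if ba > tiny:
                    K[e] = kappa + Q[a] * K[a] / (ba**4 * Q[e])
                else:
                    K[e] = kappa + Q[b] * K[b] / (bb**4 * Q[e])
        if fixed_dp:
            r_root = (Q[root_edge] * K[root_edge] / cfg.pressure_drop) ** 0.25
        else:
            r_root = root_radius_m
        delta = 0.0
        new_r = [0.0] * nE
        new_r[root_edge] = r_root
        for i in range(nE - 1, -1, -1):  # preorder: parents before children
            e = post[i]
            ch = children[e]
            if ch is not None:
                re = new_r[e]
                new_r[ch[0]] = beta[ch[0]] * re
                new_r[ch[1]] = beta[ch[1]] * re
        for e in range(nE):
            d = abs(new_r[e] - r_m[e]) / (new_r[e] if new_r[e] > tiny else tiny)
            if d > delta:
                delta = d
        r_m = new_r
        if delta < cfg.sweep_tol:
            return r_m
    raise RebalanceError(
        f"radius rebalancing did not converge in {cfg.max_sweeps} sweeps "
        f"(last relative change {delta:.3e})"
    )


def _rebalance_arrays(net: _Net, cfg: CCOConfig, root_radius_mm: float | None,
                      lengths_mm: np.ndarray | None = None) -> np.ndarray:
    """Rebalance a network's radii in place; returns radii in mm."""
    nE = net.n_edges
    if lengths_mm is None:
        lengths_mm = net.lengths()
    L = [l * 1e-3 for l in np.asarray(lengths_mm).tolist()]
    Q = [q * cfg.leaf_flow for q in net.leaf_counts().tolist()]
    if net.radii is not None and net.radii.shape[0] == nE:
        r0 = (net.radii * 1e-3).tolist()
    else:
        base = (root_radius_mm if root_radius_mm else 1.0) * 1e-3
        r0 = [base] * nE
    root_r_m = None if root_radius_mm is None else root_radius_mm * 1e-3
    r = _rebalance_core(net.postorder(), net.echild, net.root_edge,
                        Q, L, r0, cfg, root_r_m)
    net.radii = np.asarray(r) * 1e3
    return net.radii


@dataclass
class FlowState:
    """Converged hemodynamic state: per-edge flow (units of leaf_flow),
    SI resistance, radius (mm), and per-leaf root-to-leaf pressure drop."""

    flow: dict[str, float]
    resistance: dict[str, float]
    radius: dict[str, float]
    leaf_pressure_drop: dict[str, float]

    def max_pressure_spread(self) -> float:
        v = np.array(list(self.leaf_pressure_drop.values()))
        return float((v.max() - v.min()) / v.max()) if v.size else 0.0


def rebalance_radii(tree: VascularTree, config: CCOConfig | None = None) -> FlowState:
    """Rebalance radii of a tree and return the converged flow state.

    The absolute scale comes from the root condition (by default the tree's
    current root edge radius).  The input tree is not modified.
    """
    cfg = config or CCOConfig()
    net = _Net.from_tree(tree)
    net.radii = None  # cold start from the root condition
    root_r = cfg.root_radius
    if root_r is None and cfg.root_condition == "fixed_root_radius":
        root_r = tree.edges[tree.root_edge].radius
    radii_mm = _rebalance_arrays(net, cfg, root_r)
    lengths = net.lengths()
    Q = net.leaf_counts()
    res = np.array([
        edge_resistance(lengths[i], radii_mm[i], cfg.viscosity_model, cfg.mu_constant)
        if lengths[i] > 0 else 0.0
        for i in range(net.n_edges)
    ])
    # accumulate pressure drops root -> leaf (flow in SI via leaf_flow)
    drop = np.zeros(net.n_edges)
    leaf_drops: dict[str, float] = {}
    for e in reversed(net.postorder()):
        p = net.eparent[e]
        drop[e] = (drop[p] if p >= 0 else 0.0) + Q[e] * cfg.leaf_flow * res[e]
        if net.echild[e] is None:
            leaf_drops[net.edge_ids[e]] = float(drop[e])
    return FlowState(
        flow={net.edge_ids[i]: float(Q[i]) for i in range(net.n_edges)},
        resistance={net.edge_ids[i]: float(res[i]) for i in range(net.n_edges)},
        radius={net.edge_ids[i]: float(radii_mm[i]) for i in range(net.n_edges)},
        leaf_pressure_drop=leaf_drops,
    )


def apply_flow_state(tree: VascularTree, state: FlowState) -> VascularTree:
    """Copy of ``tree`` with radii replaced by the rebalanced ones."""
    out = tree.copy()
    for eid, r in state.radius.items():
        out.edges[eid].radius = r
    return out


# ---------------------------------------------------------------------------
# Cost and optimization
# ---------------------------------------------------------------------------

def _net_cost(net: _Net, radii_mm: np.ndarray, lengths_mm: np.ndarray,
              domain: OrganDomain | None, cfg: CCOConfig) -> float:
    vol = float(np.sum(lengths_mm * radii_mm**cfg.lambda_exponent))
    if domain is None or cfg.penalty_C == 0:
        return vol
    d = domain.distance(net.pos)
    return vol + cfg.penalty_C * float(np.sum(np.asarray(d) ** 2))


def tree_cost(tree: VascularTree, domain: OrganDomain | None = None,
              config: CCOConfig | None = None) -> float:
    """Target functional sum l r^lambda + C sum dist^2(node, organ).

    Uses the tree's stored radii (call :func:`rebalance_radii` first if they
    are stale).
    """
    cfg = config or CCOConfig()
    net = _Net.from_tree(tree)
    return _net_cost(net, np.asarray(net.radii), net.lengths(), domain, cfg)


def candidate_edges(tree: VascularTree, new_point, k: int = 40) -> list[str]:
    """The k edges with midpoints closest to ``new_point`` (ties by edge id)."""
    p = np.asarray(new_point, dtype=float)
    eids = sorted(tree.edges)
    mids = np.array([
        0.5 * (tree.nodes[tree.edges[e].initial].position
               + tree.nodes[tree.edges[e].terminal].position)
        for e in eids
    ])
    d = np.linalg.norm(mids - p, axis=1)
    order = sorted(range(len(eids)), key=lambda i: (d[i], eids[i]))
    return [eids[i] for i in order[:k]]


def _candidate_indices(net: _Net, point: np.ndarray, k: int) -> list[int]:
    ei = np.asarray(net.einit)
    et = np.asarray(net.eterm)
    mids = 0.5 * (net.pos[ei] + net.pos[et])
    d = np.linalg.norm(mids - point, axis=1)
    order = sorted(range(net.n_edges), key=lambda i: (d[i], net.edge_ids[i]))
    return order[:k]


def _descend(net: _Net, nb: int, moving_edges: list[int], domain, cfg: CCOConfig,
             root_radius: float, tolerance: float) -> tuple[np.ndarray, float]:
    """Gradient descent with Armijo backtracking on the bifurcation position.

    Every cost evaluation performs a full radius rebalancing (warm started
    from the previous evaluation's radii); gradients are central finite
    differences.
    """
    lengths = net.lengths().tolist()
    local = max(sum(lengths[e] for e in moving_edges) / len(moving_edges), 1e-3)
    h = max(1e-4 * local, 1e-6)
    lam = cfg.lambda_exponent
    C = cfg.penalty_C
    post = net.postorder()
    children = net.echild
    Q = [q * cfg.leaf_flow for q in net.leaf_counts().tolist()]
    root_r_m = root_radius * 1e-3
    if net.radii is not None and len(net.radii) == net.n_edges:
        r_m = (np.asarray(net.radii) * 1e-3).tolist()
    else:
        r_m = [root_r_m] * net.n_edges
    # static part of the penalty: every node except the moving bifurcation
    if domain is not None and C > 0:
        mask = np.ones(net.pos.shape[0], dtype=bool)
        mask[nb] = False
        dstat = np.asarray(domain.distance(net.pos[mask]))
        static_pen = C * float(np.sum(dstat**2))
    else:
        static_pen = 0.0
    mv = [(e, net.einit[e], net.eterm[e]) for e in moving_edges]
    pos = net.pos

    def cost_at(px: float, py: float, pz: float) -> float:
        nonlocal r_m
        pos[nb, 0] = px
        pos[nb, 1] = py
        pos[nb, 2] = pz
        for e, i, t in mv:
            dx = pos[t, 0] - pos[i, 0]
            dy = pos[t, 1] - pos[i, 1]
            dz = pos[t, 2] - pos[i, 2]
            lengths[e] = math.sqrt(dx * dx + dy * dy + dz * dz)
        L_m = [l * 1e-3 for l in lengths]
        r_m = _rebalance_core(post, children, net.root_edge, Q, L_m, r_m,
                              cfg, root_r_m)
        vol = 0.0
        for e in range(len(lengths)):
            vol += lengths[e] * (r_m[e] * 1e3) ** lam
        if static_pen or (domain is not None and C > 0):
            d = domain.distance1((px, py, pz))
            return vol + static_pen + C * d * d
        return vol

    p = net.pos[nb].copy()
    f0 = cost_at(*p)
    step = 0.25 * local
    fn = f0
    for _ in range(cfg.max_gd_iterations):
        grad = np.empty(3)
        for k in range(3):
            dp = p.copy()
            dp[k] += h
            fp = cost_at(*dp)
            dp[k] -= 2 * h
            fm = cost_at(*dp)
            grad[k] = (fp - fm) / (2 * h)
        gn = float(np.linalg.norm(grad))
        if gn == 0:
            break
        d = -grad / gn
        t = step
        accepted = False
        for _ in range(40):
            trial = p + t * d
            fn = cost_at(*trial)
            if fn <= f0 - cfg.armijo_slope * t * gn:
                accepted = True
                break
            t *= cfg.armijo_factor
        if not accepted:
            break
        p = p + t * d
        f0 = fn
        step = min(2.0 * t, 4.0 * local)
        if t < tolerance:
            break
    f0 = cost_at(*p)  # leave net consistent with the final position
    net.radii = np.asarray(r_m) * 1e3
    return p, f0


def _prepare_attach(net: _Net, target: int, point: np.ndarray, tag: str,
                    start: np.ndarray | None = None) -> tuple[_Net, int, list[int]]:
    u = net.pos[net.einit[target]]
    v = net.pos[net.eterm[target]]
    bif = 0.5 * (u + v) if start is None else start.copy()
    for anchor in (u, v, point):
        if np.linalg.norm(bif - anchor) < 1e-12:
            bif = bif + 1e-6  # perturb degenerate start
    trial, nb, leaf_edge = net.attach(target, point, bif, f"g{tag}", f"g{tag}")
    cont = trial.echild[target][0]
    moving = [target, cont, leaf_edge]
    return trial, nb, moving


def optimize_bifurcation(
    tree: VascularTree,
    target_edge: str,
    new_leaf,
    tolerance: float | None = None,
    config: CCOConfig | None = None,
    domain: OrganDomain | None = None,
) -> tuple[np.ndarray, float]:
    """Optimal bifurcation position (and its cost) for connecting a new leaf
    by splitting ``target_edge``.  Starts from the edge midpoint."""
    cfg = config or CCOConfig()
    tol = cfg.final_tolerance if tolerance is None else tolerance
    net = _Net.from_tree(tree)
    root_r = cfg.root_radius or tree.edges[tree.root_edge].radius
    tidx = net.edge_ids.index(target_edge)
    point = np.asarray(new_leaf, dtype=float)
    trial, nb, moving = _prepare_attach(net, tidx, point, "opt")
    return _descend(trial, nb, moving, domain, cfg, root_r, tol)


def _add_leaf_net(net: _Net, point: np.ndarray, cfg: CCOConfig, domain,
                  root_radius: float, tag: str) -> tuple[_Net, dict]:
    cands = _candidate_indices(net, point, cfg.n_candidates)
    rough: list[tuple[float, int, np.ndarray]] = []
    for target in cands:
        trial, nb, moving = _prepare_attach(net, target, point, tag)
        p, c = _descend(trial, nb, moving, domain, cfg, root_radius,
                        cfg.rough_tolerance)
        rough.append((c, target, p))
    rough.sort(key=lambda rc: (rc[0], rc[1]))
    shortlist = rough[: cfg.n_shortlist]
    final: list[tuple[float, int, _Net]] = []
    for c0, target, p0 in shortlist:
        trial, nb, moving = _prepare_attach(net, target, point, tag, start=p0)
        p, c = _descend(trial, nb, moving, domain, cfg, root_radius,
                        cfg.final_tolerance)
        final.append((c, target, trial))
    final.sort(key=lambda fc: (fc[0], fc[1]))
    best_cost, best_target, best_net = final[0]
    audit = {
        "target_point": [float(x) for x in point],
        "rough_costs": {net.edge_ids[t]: c for c, t, _ in rough},
        "final_costs": {net.edge_ids[t]: c for c, t, _ in final},
        "committed_edge": net.edge_ids[best_target],
        "committed_cost": best_cost,
    }
    return best_net, audit


def add_leaf(tree: VascularTree, new_point, config: CCOConfig | None = None,
             domain: OrganDomain | None = None) -> tuple[VascularTree, dict]:
    """Connect one new leaf to the tree via the best candidate bifurcation.

    Returns the grown tree (radii rebalanced) and an audit record of the
    candidate costs.
    """
    cfg = config or CCOConfig()
    net = _Net.from_tree(tree)
    root_r = cfg.root_radius or tree.edges[tree.root_edge].radius
    point = np.asarray(new_point, dtype=float)
    tag = f"a{len(tree.edges)}"
    best_net, audit = _add_leaf_net(net, point, cfg, domain, root_r, tag)
    return _net_to_tree(best_net), audit


def generate(
    seed_tree: VascularTree,
    domain: OrganDomain | None,
    leaf_targets,
    config: CCOConfig | None = None,
) -> tuple[VascularTree, list[dict]]:
    """Grow ``seed_tree`` by adding every leaf target in sampling order.

    Deterministic given the inputs; returns the grown tree (radii
    rebalanced, branching-exponent law and equal leaf pressure drops hold)
    and the per-insertion audit log.
    """
    cfg = config or CCOConfig()
    points = getattr(leaf_targets, "points", leaf_targets)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    net = _Net.from_tree(seed_tree)
    root_r = cfg.root_radius
    if root_r is None and cfg.root_condition == "fixed_root_radius":
        root_r = seed_tree.edges[seed_tree.root_edge].radius
    audits: list[dict] = []
    for i, p in enumerate(points):
        net, audit = _add_leaf_net(net, p, cfg, domain, root_r, str(i))
        audit["insertion"] = i
        audits.append(audit)
    if points.shape[0] == 0 and net.radii is not None:
        return seed_tree.copy(), audits
    _rebalance_arrays(net, cfg, root_r)
    return _net_to_tree(net), audits


def _net_to_tree(net: _Net) -> VascularTree:
    radii = net.radii if net.radii is not None else np.ones(net.n_edges)
    nodes = {
        nid: Node(nid, net.pos[i].copy()) for i, nid in enumerate(net.node_ids)
    }
    edges = {}
    for i, eid in enumerate(net.edge_ids):
        ini = net.node_ids[net.einit[i]]
        ter = net.node_ids[net.eterm[i]]
        trivial = bool(np.all(net.pos[net.einit[i]] == net.pos[net.eterm[i]]))
        edges[eid] = Edge(eid, ini, ter, float(radii[i]), trivial=trivial)
    root_node = net.node_ids[net.einit[net.root_edge]]
    return VascularTree(nodes, edges, root_node)
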