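"""Per-edge geometric features: radii, lengths, their ratios and asymmetries,
the bifurcation exponent, and bifurcation angles.

Features per edge (NaN marks "undefined"; undefined values are excluded from
all downstream statistics):

====== =======================================================================
r      edge radius [mm]
l      edge length [mm] (0 for trivial edges)
eta_r  parent radius / own radius (undefined at the root edge)
sigma_r max daughter radius / min daughter radius (>= 1; terminal: undefined)
eta_l  parent length / own length
sigma_l max daughter length / min daughter length (>= 1)
gamma  bifurcation exponent: root of r_p^g = r_1^g + r_2^g (parent property)
phi_a  angle between the two daughter edges
phi_b  inclination of the parent edge against the daughters' plane
phi_c  angle between the in-plane projection of the parent and the daughters'
       bisector
====== =======================================================================

Angles are radians internally; :func:`feature_table` can report degrees.
The bifurcation angle frame places the daughters in the xy-plane with their
bisector along +x; all three angles are invariant under rigid motions and
under swapping the daughter labels.  Edge directions follow the flow
(initial -> terminal), so a straight pass-through has phi_c = 0.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import VascularTree
from .topology import strahler_star_orders

__all__ = [
    "bifurcation_angles",
    "bifurcation_exponent",
    "feature_table",
    "FEATURES",
    "FEATURE_GROUPS",
]

FEATURES = ["r", "l", "eta_r", "sigma_r", "eta_l", "sigma_l",
            "gamma", "phi_a", "phi_b", "phi_c"]

FEATURE_GROUPS = {
    "radius": ["r", "eta_r", "sigma_r", "gamma"],
    "length": ["l", "eta_l", "sigma_l"],
    "angle": ["phi_a", "phi_b", "phi_c"],
}

_GAMMA_BRACKET = (1e-3, 50.0)


class BifurcationAngles(NamedTuple):
    phi_a: float
    phi_b: float
    phi_c: float


def bifurcation_angles(
    parent_dir: np.ndarray, d1_dir: np.ndarray, d2_dir: np.ndarray
) -> BifurcationAngles:
    """Angles (phi_a, phi_b, phi_c) of a bifurcation, in radians.

    ``parent_dir`` points along the flow *into* the bifurcation; the
    daughter directions point away from it.  NaN components mark angles that
    are undefined (zero-length edge, or antiparallel daughters for phi_c).
    """
    p = np.asarray(parent_dir, dtype=float)
    u1 = np.asarray(d1_dir, dtype=float)
    u2 = np.asarray(d2_dir, dtype=float)
    np_, n1, n2 = np.linalg.norm(p), np.linalg.norm(u1), np.linalg.norm(u2)
    if np_ == 0 or n1 == 0 or n2 == 0:
        return BifurcationAngles(math.nan, math.nan, math.nan)
    p, u1, u2 = p / np_, u1 / n1, u2 / n2

    cross = np.cross(u1, u2)
    phi_a = math.atan2(float(np.linalg.norm(cross)), float(np.dot(u1, u2)))

    ncl = float(np.linalg.norm(cross))
    if ncl < 1e-12:  # daughters (anti)parallel: no unique plane
        return BifurcationAngles(phi_a, math.nan, math.nan)
    n = cross / ncl
    sin_b = float(np.clip(np.dot(p, n), -1.0, 1.0))
    phi_b = abs(math.asin(sin_b))  # unsigned inclination in [0, pi/2]

    bis = u1 + u2
    nb = float(np.linalg.norm(bis))
    if nb < 1e-12:  # antiparallel daughters: bisector undefined
        return BifurcationAngles(phi_a, phi_b, math.nan)
    bis = bis / nb
    p_proj = p - np.dot(p, n) * n
    npp = float(np.linalg.norm(p_proj))
    if npp < 1e-12:  # parent perpendicular to the daughter plane
        return BifurcationAngles(phi_a, phi_b, math.nan)
    cos_c = float(np.clip(np.dot(p_proj / npp, bis), -1.0, 1.0))
    return BifurcationAngles(phi_a, phi_b, math.acos(cos_c))


def bifurcation_exponent(r_p: float, r_1: float, r_2: float) -> float:
    """Exponent gamma with r_p^gamma = r_1^gamma + r_2^gamma, or NaN.

    Solved by bracketed root finding to 1e-10 inside [1e-3, 50]; undefined
    (NaN) when no positive root exists (r_p <= max daughter radius), when a
    radius is nonpositive, or when the root falls outside the bracket.
    """
    if r_p <= 0 or r_1 <= 0 or r_2 <= 0:
        return math.nan
    if r_p <= max(r_1, r_2):
        return math.nan
    a, b = r_1 / r_p, r_2 / r_p

    def f(g: float) -> float:
        return a**g + b**g - 1.0

    lo, hi = _GAMMA_BRACKET
    if f(lo) < 0 or f(hi) > 0:
        return math.nan
    return float(brentq(f, lo, hi, xtol=1e-10))


def feature_table(tree: VascularTree, degrees: bool = False) -> pd.DataFrame:
    """Per-edge feature table (one row per edge; NaN = undefined).

    gamma and the angles are attached to the parent edge of the bifurcation.
    Ratio features are undefined wherever a zero length or radius would force
    a division by zero; all derived features of trivial edges are undefined.
    """
    ss = strahler_star_orders(tree)
    lengths = {eid: tree.length(eid) for eid in tree.edges}
    rows = []
    for eid in sorted(tree.edges):
        e = tree.edges[eid]
        parent = tree.parent(eid)
        ds = tree.daughters(eid)
        rec: dict[str, float | int | str | bool] = {
            "edge_id": eid,
            "s_star": ss[eid],
            "trivial": bool(e.trivial),
            "r": e.radius,
            "l": lengths[eid],
        }
        # ratios to the parent
        rec["eta_r"] = math.nan
        rec["eta_l"] = math.nan
        if parent is not None:
            if e.radius > 0:
                rec["eta_r"] = tree.edges[parent].radius / e.radius
            if lengths[eid] > 0:
                rec["eta_l"] = lengths[parent] / lengths[eid]
        # daughter asymmetries, exponent, angles
        rec["sigma_r"] = rec["sigma_l"] = rec["gamma"] = math.nan
        rec["phi_a"] = rec["phi_b"] = rec["phi_c"] = math.nan
        if ds:
            r1, r2 = tree.edges[ds[0]].radius, tree.edges[ds[1]].radius
            l1, l2 = lengths[ds[0]], lengths[ds[1]]
            if min(r1, r2) > 0:
                rec["sigma_r"] = max(r1, r2) / min(r1, r2)
            if min(l1, l2) > 0:
                rec["sigma_l"] = max(l1, l2) / min(l1, l2)
            rec["gamma"] = bifurcation_exponent(e.radius, r1, r2)
            if lengths[eid] > 0 and min(l1, l2) > 0:
                ang = bifurcation_angles(
                    tree.direction(eid), tree.direction(ds[0]), tree.direction(ds[1])
                )
                rec["phi_a"], rec["phi_b"], rec["phi_c"] = ang
        rows.append(rec)
    df = pd.DataFrame(rows).set_index("edge_id")
    if degrees:
        for c in ("phi_a", "phi_b", "phi_c"):
            df[c] = np.degrees(df[c])
    return df


def feature_samples(
    table: pd.DataFrame,
) -> dict[tuple[str, int], np.ndarray]:
    """Defined values of each feature per Strahler* order, from a feature table."""
    out: dict[tuple[str, int], np.ndarray] = {}
    for s, sub in table.groupby("s_star"):
        for f in FEATURES:
            vals = sub[f].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                out[(f, int(s))] = vals
    return out
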