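"""Strahler and Strahler* ordering and order-census summaries.

The Strahler order is nondecreasing from the leaves to the root: leaf edges
have order 1, a parent edge takes the larger of its daughters' orders, or
their common order plus one when they coincide.  Because trees extracted at
different imaging resolutions have different root orders, cross-tree
comparisons use the *Strahler\\** order s*(e) = s(root) - s(e), which is 0
at the root edge and grows toward the leaves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import VascularTree

__all__ = [
    "strahler_orders",
    "strahler_star_orders",
    "connectivity_histogram",
    "order_census",
    "ConnectivityHistogram",
]


def strahler_orders(tree: VascularTree) -> dict[str, int]:
    """Strahler order per edge id (leaves = 1; max of daughters, +1 on tie)."""
    orders: dict[str, int] = {}
    for eid in tree.postorder_edges():
        ds = tree.daughters(eid)
        if not ds:
            orders[eid] = 1
        else:
            a, b = orders[ds[0]], orders[ds[1]]
            orders[eid] = a + 1 if a == b else max(a, b)
    return orders


def strahler_star_orders(tree: VascularTree) -> dict[str, int]:
    """Strahler* order per edge id: root Strahler order minus edge order."""
    s = strahler_orders(tree)
    root = s[tree.root_edge]
    return {eid: root - v for eid, v in s.items()}


@dataclass
class ConnectivityHistogram:
    """Parent/daughter Strahler* order co-occurrence.

    ``counts``: DataFrame indexed by parent order s', columns daughter order
    s.  In population mode counts are per-tree averages.  ``percent`` is the
    percent-of-all-parent-daughter-pairs normalization (sums to 100).
    """

    counts: pd.DataFrame
    percent: pd.DataFrame
    n_pairs: int

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)


def connectivity_histogram(
    trees: VascularTree | Sequence[VascularTree],
) -> ConnectivityHistogram:
    """Histogram of parent->daughter Strahler* order pairs.

    For a population the per-cell counts are averaged over trees; the
    percentage normalization is over all pairs of all trees.
    """
    if isinstance(trees, VascularTree):
        trees = [trees]
    pairs: list[tuple[int, int]] = []
    per_tree: list[dict[tuple[int, int], int]] = []
    for tree in trees:
        ss = strahler_star_orders(tree)
        counts: dict[tuple[int, int], int] = {}
        for eid in tree.edges:
            for d in tree.daughters(eid):
                key = (ss[eid], ss[d])
                counts[key] = counts.get(key, 0) + 1
                pairs.append(key)
        per_tree.append(counts)
    keys = sorted({k for c in per_tree for k in c})
    if not keys:
        empty = pd.DataFrame(dtype=float)
        return ConnectivityHistogram(empty, empty, 0)
    rows = sorted({k[0] for k in keys})
    cols = sorted({k[1] for k in keys})
    counts = pd.DataFrame(0.0, index=rows, columns=cols)
    for c in per_tree:
        for (i, j), v in c.items():
            counts.loc[i, j] += v
    avg = counts / len(per_tree)
    percent = counts / counts.values.sum() * 100.0
    counts.index.name = avg.index.name = percent.index.name = "parent_s*"
    return ConnectivityHistogram(avg, percent, len(pairs))


def order_census(population: Sequence[VascularTree]) -> pd.DataFrame:
    """Per Strahler* order: number of trees with edges of that order and the
    mean edge count among those trees (Table-1-style census)."""
    if not population:
        raise ValueError("order_census requires a nonempty population")
    per_tree_counts: list[dict[int, int]] = []
    for tree in population:
        ss = strahler_star_orders(tree)
        c: dict[int, int] = {}
        for v in ss.values():
            c[v] = c.get(v, 0) + 1
        per_tree_counts.append(c)
    orders = sorted({o for c in per_tree_counts for o in c})
    rows = []
    for o in orders:
        present = [c[o] for c in per_tree_counts if o in c]
        rows.append({"s_star": o, "n_trees": len(present),
                     "mean_edges": float(np.mean(present))})
    return pd.DataFrame(rows).set_index("s_star")


def trees_with_order(population: Sequence[VascularTree]) -> dict[int, int]:
    """n_s: number of trees in the population having edges of each order."""
    census = order_census(population)
    return {int(o): int(v) for o, v in census["n_trees"].items()}
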