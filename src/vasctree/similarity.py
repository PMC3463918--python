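"""Similarity quantification between populations of vascular trees.

The pipeline has six steps: (1) Strahler* orders and per-edge geometric
features; (2) empirical CDFs of each feature per Strahler* order and tree;
(3) a two-sample Kolmogorov-Smirnov decision per tree pair, feature, and
order, giving a similarity ratio (fraction of non-rejected pairs); (4) a
weighted average of these ratios over Strahler* orders; (5) averages over
the radius, length, and angle feature groups; (6) a weighted total average.

Two modes exist.  In the *single-population* case ratios run over all
ordered pairs of distinct trees of one population and averages are
arithmetic.  In the *two-population* case ratios run over the full cross
product and feature averages are weighted by the single-population values
of the first (reference/measured) population, so invariant features count
more ("similarity where it is expected"); the two modes' totals are not
directly comparable.

The KS decision rescales the sup-distance D by sqrt(n0*n1/(n0+n1)) and
evaluates the limiting Kolmogorov distribution; for small samples the
asymptotic form is conservative, so an exact permutation p-value is used by
default when n0+n1 <= 25.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import VascularTree
from .morphometry import FEATURES, FEATURE_GROUPS, feature_samples, feature_table
from .topology import trees_with_order

__all__ = [
    "ks_limit_cdf",
    "ks_two_sample",
    "KSResult",
    "similarity_ratio_single",
    "similarity_ratio_two",
    "average_over_orders",
    "average_over_features",
    "similarity_report",
    "SimilarityReport",
]

DEFAULT_SIGNIFICANCE = 0.05
EXACT_THRESHOLD = 25  # exact permutation p-value when n0 + n1 <= this
EXHAUSTIVE_LIMIT = 200_000  # enumerate all C(n, n0) splits up to this count
MC_PERMUTATIONS = 100_000


def ks_limit_cdf(x: float | np.ndarray) -> float | np.ndarray:
    """Limiting Kolmogorov distribution P_K(x).

    Uses the alternating series 1 - 2 sum (-1)^(i-1) exp(-2 i^2 x^2) for
    x >= 1 and the theta-series form sqrt(2 pi)/x sum exp(-(2i-1)^2 pi^2 /
    (8 x^2)) for 0 < x < 1 (numerically stable near 0).  Terms below 1e-16
    are truncated.  P_K(0) = 0.
    """
    scalar = np.isscalar(x)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x < 0):
        raise ValueError("ks_limit_cdf requires x >= 0")
    out = np.zeros_like(x)
    small = (x > 0) & (x < 1.0)
    large = x >= 1.0
    if np.any(small):
        xs = x[small]
        acc = np.zeros_like(xs)
        for i in itertools.count(1):
            term = np.exp(-((2 * i - 1) ** 2) * math.pi**2 / (8.0 * xs**2))
            acc += term
            if np.all(term < 1e-16):
                break
        out[small] = math.sqrt(2.0 * math.pi) / xs * acc
    if np.any(large):
        xl = x[large]
        acc = np.zeros_like(xl)
        for i in itertools.count(1):
            term = np.exp(-2.0 * i**2 * xl**2)
            acc += ((-1) ** (i - 1)) * term
            if np.all(term < 1e-16):
                break
        out[large] = 1.0 - 2.0 * acc
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


@dataclass
class KSResult:
    D: float
    n0: int
    n1: int
    scaled: float
    p: float
    reject: bool
    significance: float
    method: str


def _sup_distance(x: np.ndarray, y: np.ndarray) -> float:
    """sup |ECDF_x - ECDF_y| on the merged support."""
    grid = np.concatenate([x, y])
    cx = np.searchsorted(np.sort(x), grid, side="right") / x.size
    cy = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.max(np.abs(cx - cy)))


def _permutation_distances(pooled_sorted: np.ndarray, labels: np.ndarray,
                           n0: int, n1: int) -> np.ndarray:
    """D for each row of boolean ``labels`` (True = first sample) over the
    sorted pooled values.  Ties are handled by evaluating only at the last
    index of each tie group (right-continuous ECDFs)."""
    cx = np.cumsum(labels, axis=1) / n0
    cy = np.cumsum(~labels, axis=1) / n1
    diff = np.abs(cx - cy)
    keep = np.ones(pooled_sorted.size, dtype=bool)
    keep[:-1] = pooled_sorted[1:] != pooled_sorted[:-1]
    return np.max(diff[:, keep], axis=1)


def ks_two_sample(
    x_samples: Sequence[float],
    y_samples: Sequence[float],
    method: Literal["auto", "asymptotic", "exact_small"] = "auto",
    significance: float = DEFAULT_SIGNIFICANCE,
    exact_threshold: int = EXACT_THRESHOLD,
    seed: int = 0,
) -> KSResult:
    """Two-sample two-sided KS test.

    ``method="asymptotic"`` evaluates the limiting distribution on the
    rescaled statistic.  ``"exact_small"`` computes the permutation p-value,
    exhaustively over all C(n0+n1, n0) label splits when that count is at
    most 200 000, otherwise by 100 000 seeded Monte-Carlo permutations.
    ``"auto"`` selects ``exact_small`` when n0 + n1 <= ``exact_threshold``.
    """
    x = np.asarray(x_samples, dtype=float)
    y = np.asarray(y_samples, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_two_sample requires nonempty samples")
    n0, n1 = x.size, y.size
    D = _sup_distance(x, y)
    scaled = D * math.sqrt(n0 * n1 / (n0 + n1))
    if method == "auto":
        method = "exact_small" if n0 + n1 <= exact_threshold else "asymptotic"
    if method == "asymptotic":
        p = 1.0 - float(ks_limit_cdf(scaled))
    elif method == "exact_small":
        p = _exact_permutation_p(x, y, D, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KSResult(D, n0, n1, scaled, p, bool(p < significance), significance, method)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, D_obs: float, seed: int) -> float:
    n0, n1 = x.size, y.size
    n = n0 + n1
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="stable")
    pooled_sorted = pooled[order]
    n_splits = math.comb(n, n0)
    tol = 1e-12
    if n_splits <= EXHAUSTIVE_LIMIT:
        labels = np.zeros((n_splits, n), dtype=bool)
        for row, comb in enumerate(itertools.combinations(range(n), n0)):
            labels[row, comb] = True
        dists = _permutation_distances(pooled_sorted, labels, n0, n1)
        return float(np.mean(dists >= D_obs - tol))
    rng = np.random.Generator(np.random.MT19937(seed))
    base = np.zeros(n, dtype=bool)
    base[:n0] = True
    labels = rng.permuted(np.tile(base, (MC_PERMUTATIONS, 1)), axis=1)
    dists = _permutation_distances(pooled_sorted, labels, n0, n1)
    return float(np.mean(dists >= D_obs - tol))


# ---------------------------------------------------------------------------
# Similarity ratios and hierarchical averaging
# ---------------------------------------------------------------------------

def _tree_samples(trees: Sequence[VascularTree]) -> list[dict]:
    return [feature_samples(feature_table(t)) for t in trees]


def _pair_decision(sa, sb, feature, order, significance, ks_kwargs) -> KSResult | None:
    a = sa.get((feature, order))
    b = sb.get((feature, order))
    if a is None or b is None:
        return None
    return ks_two_sample(a, b, significance=significance, **ks_kwargs)


def similarity_ratio_single(
    population: Sequence[VascularTree],
    feature: str,
    order: int,
    significance: float = DEFAULT_SIGNIFICANCE,
    _samples: list[dict] | None = None,
    audit: list | None = None,
    **ks_kwargs,
) -> float | None:
    """Fraction of tree pairs of one population not rejected by the KS test
    for ``feature`` at Strahler* ``order``.  Pairs where either tree has no
    defined values are excluded; None when no valid pair exists."""
    samples = _samples if _samples is not None else _tree_samples(population)
    n_similar = n_pairs = 0
    for i, j in itertools.combinations(range(len(samples)), 2):
        res = _pair_decision(samples[i], samples[j], feature, order,
                             significance, ks_kwargs)
        if res is None:
            continue
        n_pairs += 1
        n_similar += not res.reject
        if audit is not None:
            audit.append({"feature": feature, "s_star": order, "i": i, "j": j,
                          "n0": res.n0, "n1": res.n1, "D": res.D, "p": res.p,
                          "reject": res.reject})
    return n_similar / n_pairs if n_pairs else None


def similarity_ratio_two(
    pop_m: Sequence[VascularTree],
    pop_g: Sequence[VascularTree],
    feature: str,
    order: int,
    significance: float = DEFAULT_SIGNIFICANCE,
    _samples_m: list[dict] | None = None,
    _samples_g: list[dict] | None = None,
    audit: list | None = None,
    **ks_kwargs,
) -> float | None:
    """As :func:`similarity_ratio_single` over the full cross product
    pop_m x pop_g."""
    sm = _samples_m if _samples_m is not None else _tree_samples(pop_m)
    sg = _samples_g if _samples_g is not None else _tree_samples(pop_g)
    n_similar = n_pairs = 0
    for i in range(len(sm)):
        for j in range(len(sg)):
            res = _pair_decision(sm[i], sg[j], feature, order,
                                 significance, ks_kwargs)
            if res is None:
                continue
            n_pairs += 1
            n_similar += not res.reject
            if audit is not None:
                audit.append({"feature": feature, "s_star": order, "i": i, "j": j,
                              "n0": res.n0, "n1": res.n1, "D": res.D, "p": res.p,
                              "reject": res.reject})
    return n_similar / n_pairs if n_pairs else None


def order_cutoff(n_s: Mapping[int, int], n_trees: int) -> int:
    """Smallest order s with n_s < n_trees/2 (strict half rule, real
    division); averaging later runs over s < cutoff."""
    s = 0
    while n_s.get(s, 0) >= n_trees / 2.0:
        s += 1
    return s


def average_over_orders(
    ratios: Mapping[int, float | None],
    populations: Sequence[Sequence[VascularTree]],
    mode: Literal["single", "two"],
    _n_s: Sequence[Mapping[int, int]] | None = None,
) -> tuple[float | None, int, dict[int, float]]:
    """Weighted average of per-order ratios for one feature.

    Weights are n_s (number of trees with edges of order s) in single mode
    and sqrt(n_s^m * n_s^g) in two-population mode; the cutoff is the
    population's own (single) or the minimum of both (two).  Orders with an
    undefined ratio are skipped together with their weight.  Returns
    (average or None, cutoff, weights used).
    """
    if _n_s is None:
        _n_s = [trees_with_order(pop) for pop in populations]
    cutoffs = [order_cutoff(ns, len(pop)) for ns, pop in zip(_n_s, populations)]
    s_tilde = min(cutoffs)
    weights: dict[int, float] = {}
    num = den = 0.0
    for s in range(s_tilde):
        if mode == "single":
            w = float(_n_s[0].get(s, 0))
        else:
            w = math.sqrt(_n_s[0].get(s, 0) * _n_s[1].get(s, 0))
        weights[s] = w
        r = ratios.get(s)
        if r is None or w == 0:
            continue
        num += w * r
        den += w
    if den == 0:
        return None, s_tilde, weights
    return num / den, s_tilde, weights


def average_over_features(
    per_feature: Mapping[str, float | None],
    mode: Literal["single", "two"],
    weights_from: Mapping[str, float | None] | None = None,
    groups: Mapping[str, Sequence[str]] = FEATURE_GROUPS,
) -> tuple[dict[str, float], dict[str, float], float | None]:
    """Group averages, group weights, and the total average.

    Single mode: arithmetic mean per group.  Two-population mode: per-group
    mean weighted by ``weights_from`` (the reference population's
    single-population per-feature values).  Group weights are the summed
    reference values divided by the number of defined features in the
    group; the total is the weight-averaged group mean.  Undefined features
    are excluded throughout.
    """
    if mode == "two" and weights_from is None:
        raise ValueError("two-population averaging requires weights_from")
    ref = weights_from if weights_from is not None else per_feature
    group_avg: dict[str, float] = {}
    group_w: dict[str, float] = {}
    for gname, feats in groups.items():
        defined = [f for f in feats
                   if per_feature.get(f) is not None and ref.get(f) is not None]
        if not defined:
            continue
        if mode == "single":
            group_avg[gname] = float(np.mean([per_feature[f] for f in defined]))
        else:
            wsum = sum(ref[f] for f in defined)
            if wsum == 0:
                continue
            group_avg[gname] = sum(ref[f] * per_feature[f] for f in defined) / wsum
        group_w[gname] = sum(ref[f] for f in defined) / len(defined)
    wtot = sum(group_w.values())
    total = (
        sum(group_w[g] * group_avg[g] for g in group_avg) / wtot if wtot else None
    )
    return group_avg, group_w, total


@dataclass
class SimilarityReport:
    """Full six-step similarity result with an audit log of every pair test."""

    mode: str
    per_cell: pd.DataFrame  # feature, s_star, ratio, n_pairs
    per_feature: dict[str, float | None]
    group_averages: dict[str, float]
    group_weights: dict[str, float]
    total: float | None
    s_tilde: int
    significance: float
    order_weights: dict[int, float]
    reference_per_feature: dict[str, float | None] | None = None
    audit: list[dict] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"feature": f, "similarity": v} for f, v in self.per_feature.items()]
        for g, v in self.group_averages.items():
            rows.append({"feature": f"{g} average", "similarity": v})
        rows.append({"feature": "Total average", "similarity": self.total})
        return pd.DataFrame(rows)

    def to_json(self) -> dict:
        return {
            "mode": self.mode,
            "per_cell": self.per_cell.to_dict(orient="records"),
            "per_feature": self.per_feature,
            "group_averages": self.group_averages,
            "group_weights": self.group_weights,
            "total": self.total,
            "s_tilde": self.s_tilde,
            "significance": self.significance,
            "order_weights": {str(k): v for k, v in self.order_weights.items()},
            "audit": self.audit,
        }


def similarity_report(
    pop_a: Sequence[VascularTree],
    pop_b: Sequence[VascularTree] | None = None,
    significance: float = DEFAULT_SIGNIFICANCE,
    features: Sequence[str] = FEATURES,
    keep_audit: bool = True,
    **ks_kwargs,
) -> SimilarityReport:
    """Run the six-step similarity pipeline.

    With one population the single-population ratios/averages are computed;
    with two, ``pop_a`` is the reference (measured) population whose
    single-population per-feature values supply the feature weights.
    """
    mode = "single" if pop_b is None else "two"
    samples_a = _tree_samples(pop_a)
    n_s_a = trees_with_order(pop_a)
    audit: list[dict] | None = [] if keep_audit else None
    cells = []
    if mode == "single":
        pops = [pop_a]
        n_s_list = [n_s_a]
        max_order = max(n_s_a)
        per_feature: dict[str, float | None] = {}
        order_weights: dict[int, float] = {}
        s_tilde = order_cutoff(n_s_a, len(pop_a))
        for f in features:
            ratios: dict[int, float | None] = {}
            for s in range(max_order + 1):
                r = similarity_ratio_single(
                    pop_a, f, s, significance, _samples=samples_a,
                    audit=audit, **ks_kwargs)
                ratios[s] = r
                cells.append({"feature": f, "s_star": s, "ratio": r})
            avg, s_tilde, order_weights = average_over_orders(
                ratios, pops, "single", _n_s=n_s_list)
            per_feature[f] = avg
        group_avg, group_w, total = average_over_features(per_feature, "single")
        ref_pf = None
    else:
        samples_b = _tree_samples(pop_b)
        n_s_b = trees_with_order(pop_b)
        n_s_list = [n_s_a, n_s_b]
        pops = [pop_a, pop_b]
        max_order = max(max(n_s_a), max(n_s_b))
        # reference single-population values (feature weights)
        ref = similarity_report(pop_a, None, significance, features,
                                keep_audit=False, **ks_kwargs)
        ref_pf = ref.per_feature
        per_feature = {}
        order_weights = {}
        s_tilde = 0
        for f in features:
            ratios = {}
            for s in range(max_order + 1):
                r = similarity_ratio_two(
                    pop_a, pop_b, f, s, significance,
                    _samples_m=samples_a, _samples_g=samples_b,
                    audit=audit, **ks_kwargs)
                ratios[s] = r
                cells.append({"feature": f, "s_star": s, "ratio": r})
            avg, s_tilde, order_weights = average_over_orders(
                ratios, pops, "two", _n_s=n_s_list)
            per_feature[f] = avg
        group_avg, group_w, total = average_over_features(
            per_feature, "two", weights_from=ref_pf)
    return SimilarityReport(
        mode=mode,
        per_cell=pd.DataFrame(cells),
        per_feature=per_feature,
        group_averages=group_avg,
        group_weights=group_w,
        total=total,
        s_tilde=s_tilde,
        significance=significance,
        order_weights=order_weights,
        reference_per_feature=ref_pf,
        audit=audit or [],
    )
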