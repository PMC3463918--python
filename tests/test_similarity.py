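"""KS machinery and the six-step similarity algebra."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from vasctree.similarity import (
    average_over_features,
    average_over_orders,
    ks_limit_cdf,
    ks_two_sample,
    order_cutoff,
    similarity_ratio_single,
    similarity_ratio_two,
    similarity_report,
)
from vasctree.synth import SyntheticPopulationSpec, make_population


class TestKSLimitCDF:
    def test_boundary_values(self):
        assert ks_limit_cdf(0.0) == 0.0
        assert ks_limit_cdf(10.0) == pytest.approx(1.0, abs=1e-15)

    def test_against_direct_series(self):
        # five alternating terms suffice at x = 1.2247
        x = 1.2247
        direct = 1.0 - 2.0 * sum(
            (-1) ** (i - 1) * math.exp(-2 * i**2 * x**2) for i in range(1, 6)
        )
        assert ks_limit_cdf(x) == pytest.approx(direct, abs=1e-12)
        assert 1.0 - ks_limit_cdf(x) == pytest.approx(0.0996, abs=2e-4)

    def test_series_forms_agree_at_crossover(self):
        for x in (0.5, 0.8, 0.999, 1.0, 1.001, 1.5):
            assert ks_limit_cdf(x) == pytest.approx(
                scipy.stats.kstwobign.cdf(x), abs=1e-10)

    def test_negative_is_an_error(self):
        with pytest.raises(ValueError):
            ks_limit_cdf(-0.1)


class TestKSTwoSample:
    def test_identical_samples(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.D == 0.0 and r.p == 1.0 and not r.reject

    def test_disjoint_small_samples_exact(self):
        r = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert r.D == 1.0
        assert r.method == "exact_small"
        assert r.p == pytest.approx(2 / 20)
        ra = ks_two_sample([1, 2, 3], [4, 5, 6], method="asymptotic")
        assert ra.p == pytest.approx(0.0996, abs=2e-4)

    def test_symmetry(self):
        rng = np.random.Generator(np.random.MT19937(1))
        for _ in range(20):
            # sizes small enough for the exhaustive permutation path
            x = rng.random(rng.integers(3, 10))
            y = rng.random(rng.integers(3, 10))
            a, b = ks_two_sample(x, y), ks_two_sample(y, x)
            assert a.D == b.D and a.p == pytest.approx(b.p)
        for _ in range(10):
            x = rng.random(40)
            y = rng.random(25)
            a, b = ks_two_sample(x, y), ks_two_sample(y, x)
            assert a.D == b.D and a.p == pytest.approx(b.p)

    def test_exact_matches_scipy_exact(self):
        rng = np.random.Generator(np.random.MT19937(2))
        for _ in range(10):
            x = rng.random(6)
            y = rng.random(7)
            r = ks_two_sample(x, y, method="exact_small")
            ref = scipy.stats.ks_2samp(x, y, method="exact")
            assert r.D == pytest.approx(ref.statistic)
            assert r.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        x=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
        y=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
    )
    def test_sup_distance_matches_scipy(self, x, y):
        """The ECDF sup-distance (incl. ties) agrees with an independent
        implementation on arbitrary float samples."""
        ours = ks_two_sample(x, y, method="asymptotic").D
        ref = scipy.stats.ks_2samp(x, y, method="asymp").statistic
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_null_rejection_rate_is_conservative(self):
        """At n0 = n1 = 20 the attained size is P(D >= 0.45) ~ 0.034: below
        the nominal 0.05 (discreteness of D) but well above zero."""
        rng = np.random.Generator(np.random.MT19937(0))
        rej = sum(
            ks_two_sample(rng.random(20), rng.random(20)).reject
            for _ in range(800)
        )
        rate = rej / 800
        assert 0.02 <= rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 800)


class TestSimilarityRatios:
    def _identical_pop(self, n=4):
        pop = make_population(SyntheticPopulationSpec(
            n_trees=1, leaf_range=(20, 30), seed=5))
        return [pop[0].copy() for _ in range(n)]

    def test_identical_trees_score_one(self):
        pop = self._identical_pop()
        assert similarity_ratio_single(pop, "l", 1) == 1.0
        assert similarity_ratio_two(pop, pop, "l", 1) == 1.0

    def test_disjoint_ranges_score_zero(self):
        pop = self._identical_pop(2)
        # force disjoint radius samples via scaling one tree; test at the
        # best-populated order so D = 1 forces rejection
        for e in pop[1].edges.values():
            e.radius = e.radius * 1e6
        from collections import Counter

        from vasctree.topology import strahler_star_orders

        order, n = Counter(strahler_star_orders(pop[0]).values()).most_common(1)[0]
        assert n >= 8
        assert similarity_ratio_single(pop, "r", order) == 0.0

    def test_matches_brute_force_pair_enumeration(self, small_population):
        pop = small_population[:4]
        from vasctree.morphometry import feature_samples, feature_table

        samples = [feature_samples(feature_table(t)) for t in pop]
        for feature, order in [("l", 1), ("phi_a", 2), ("gamma", 1)]:
            expected_pairs = 0
            expected_similar = 0
            for i, j in itertools.combinations(range(4), 2):
                a = samples[i].get((feature, order))
                b = samples[j].get((feature, order))
                if a is None or b is None:
                    continue
                expected_pairs += 1
                expected_similar += not ks_two_sample(a, b).reject
            got = similarity_ratio_single(pop, feature, order)
            if expected_pairs == 0:
                assert got is None
            else:
                assert got == pytest.approx(expected_similar / expected_pairs)

    def test_two_population_cross_product(self, small_population):
        a, b = small_population[:3], small_population[3:5]
        audit = []
        got = similarity_ratio_two(a, b, "l", 1, audit=audit)
        assert len(audit) == 6  # full 3 x 2 cross product
        hand = sum(1 for rec in audit if not rec["reject"]) / 6
        assert got == pytest.approx(hand)


class TestAveraging:
    def test_order_cutoff_half_rule(self):
        # exactly half still qualifies (real division, no rounding)
        assert order_cutoff({0: 4, 1: 4, 2: 2}, 4) == 3
        assert order_cutoff({0: 4, 1: 4, 2: 1}, 4) == 2
        assert order_cutoff({0: 1}, 3) == 0

    def test_weighted_average_hand_computed(self):
        ratios = {0: 1.0, 1: 0.5, 2: 0.9}
        avg, s_tilde, w = average_over_orders(
            ratios, [[None] * 4], "single", _n_s=[{0: 4, 1: 4, 2: 1}])
        assert s_tilde == 2
        assert avg == pytest.approx((4 * 1.0 + 4 * 0.5) / 8)
        avg, s_tilde, _ = average_over_orders(
            ratios, [[None] * 4], "single", _n_s=[{0: 4, 1: 4, 2: 2}])
        assert s_tilde == 3
        assert avg == pytest.approx((4 * 1.0 + 4 * 0.5 + 2 * 0.9) / 10)

    def test_constant_ratios_average_to_constant(self):
        ratios = {s: 0.7 for s in range(4)}
        avg, _, _ = average_over_orders(
            ratios, [[None] * 6], "single", _n_s=[{0: 6, 1: 5, 2: 4, 3: 3}])
        assert avg == pytest.approx(0.7)

    def test_two_population_geometric_mean_weights(self):
        ratios = {0: 1.0}
        avg, s_tilde, w = average_over_orders(
            ratios, [[None] * 4, [None] * 9], "two",
            _n_s=[{0: 4, 1: 1}, {0: 9, 1: 1}])
        assert w[0] == pytest.approx(6.0)  # sqrt(4 * 9)
        assert s_tilde == 1

    def test_undefined_orders_skipped_with_weight(self):
        ratios = {0: 0.8, 1: None}
        avg, _, _ = average_over_orders(
            ratios, [[None] * 4], "single", _n_s=[{0: 4, 1: 4}])
        assert avg == pytest.approx(0.8)

    def test_feature_group_spreadsheet_oracle(self):
        per_feature = {"r": 0.2, "eta_r": 0.6, "sigma_r": 0.7, "gamma": 0.9,
                       "l": 0.8, "eta_l": 0.95, "sigma_l": 0.9,
                       "phi_a": 0.9, "phi_b": 0.95, "phi_c": 0.85}
        groups, weights, total = average_over_features(per_feature, "single")
        assert groups["radius"] == pytest.approx((0.2 + 0.6 + 0.7 + 0.9) / 4)
        assert groups["length"] == pytest.approx((0.8 + 0.95 + 0.9) / 3)
        assert groups["angle"] == pytest.approx((0.9 + 0.95 + 0.85) / 3)
        assert weights["radius"] == pytest.approx(2.4 / 4)
        assert weights["length"] == pytest.approx(2.65 / 3)
        assert weights["angle"] == pytest.approx(2.7 / 3)
        expect = sum(weights[g] * groups[g] for g in groups) / sum(weights.values())
        assert total == pytest.approx(expect)

    def test_two_population_weighting_oracle(self):
        ref = {"r": 0.4, "eta_r": 0.8, "sigma_r": 0.6, "gamma": 1.0,
               "l": 0.9, "eta_l": 0.8, "sigma_l": 0.7,
               "phi_a": 0.5, "phi_b": 0.5, "phi_c": 1.0}
        two = {f: 0.5 * v for f, v in ref.items()}
        groups, weights, total = average_over_features(two, "two", weights_from=ref)
        # weighted by the reference values
        num = 0.4 * 0.2 + 0.8 * 0.4 + 0.6 * 0.3 + 1.0 * 0.5
        assert groups["radius"] == pytest.approx(num / 2.8)
        assert weights["radius"] == pytest.approx(2.8 / 4)

    def test_uniform_weights_reduce_to_arithmetic_mean(self):
        per = {"phi_a": 0.6, "phi_b": 0.8, "phi_c": 0.7}
        ref = {"phi_a": 0.5, "phi_b": 0.5, "phi_c": 0.5}
        g1, _, _ = average_over_features(per, "single")
        g2, _, _ = average_over_features(per, "two", weights_from=ref)
        assert g1["angle"] == pytest.approx(g2["angle"])


class TestSimilarityReport:
    def test_identical_population_total_is_one(self):
        base = make_population(SyntheticPopulationSpec(
            n_trees=1, leaf_range=(25, 35), seed=6))[0]
        pop = [base.copy() for _ in range(4)]
        rep = similarity_report(pop, keep_audit=False)
        assert rep.total == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in rep.per_feature.values())
        rep2 = similarity_report(pop, pop, keep_audit=False)
        assert rep2.total == pytest.approx(1.0)

    def test_report_is_deterministic(self, small_population):
        a = similarity_report(small_population, keep_audit=False)
        b = similarity_report(small_population, keep_audit=False)
        assert a.per_feature == b.per_feature
        assert a.total == b.total

    def test_per_cell_ratios_match_audit_log(self, small_population):
        pop = small_population[:4]
        rep = similarity_report(pop)
        for (f, s), group in itertools.groupby(
                sorted(rep.audit, key=lambda r: (r["feature"], r["s_star"])),
                key=lambda r: (r["feature"], r["s_star"])):
            recs = list(group)
            ratio = sum(1 for r in recs if not r["reject"]) / len(recs)
            cell = rep.per_cell[(rep.per_cell.feature == f)
                                & (rep.per_cell.s_star == s)]
            assert cell.ratio.iloc[0] == pytest.approx(ratio)

    def test_relabeling_invariance(self, small_population):
        pop = small_population[:4]
        rep1 = similarity_report(pop, keep_audit=False)
        rep2 = similarity_report(pop[::-1], keep_audit=False)
        assert rep1.total == pytest.approx(rep2.total)

    def test_rigid_motion_invariance(self, small_population):
        from scipy.spatial.transform import Rotation

        pop = small_population[:3]
        rng = np.random.Generator(np.random.MT19937(3))
        moved = [t.copy() for t in pop]
        R = Rotation.random(rng=rng).as_matrix()
        for n in moved[1].nodes.values():
            n.position = R @ n.position + np.array([5.0, -3.0, 2.0])
        a = similarity_report(pop, keep_audit=False)
        b = similarity_report(moved, keep_audit=False)
        for f in a.per_feature:
            assert a.per_feature[f] == pytest.approx(b.per_feature[f], abs=1e-12)
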