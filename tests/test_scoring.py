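"""Score transformations, partition counts, optimization and discrimination."""

import math

import numpy as np
import pytest
import sympy

import foldbench as fb
from foldbench.scoring import (
    BenchmarkCounts,
    ComparisonRecord,
    PartitionCurve,
            curve_score,
    curve_value,
    discrimination_curve,
    gaussian_limit,
    normalized_sap_score,
    optimize_partition,
    partition_counts,
    rank_metric,
    ratio_scores,
    read_records_tsv,
    s_score,
    write_records_tsv,
)


def gaussian_limit_highprec(n, sigma=70, half_bell=True):
    n = sympy.Integer(n) if float(n).is_integer() else sympy.Float(n, 50)
    sigma = sympy.Integer(sigma)
    denom = 2 * sigma**2 if half_bell else sigma**2
    return float(sympy.sqrt(n) * (1 - sympy.exp(-(n**2) / denom)))


def curve_value_highprec(n, a, b, c, d, N):
    n, a, b, c, d, N = (sympy.Float(x, 50) for x in (n, a, b, c, d, N))
    return float(a * sympy.sqrt(n) / (1 + sympy.exp((b * N - n + c) / d)))


class TestGaussianLimit:
    def test_zero_at_zero(self):
        assert gaussian_limit(0) == 0.0

    def test_asymptote_sqrt_n(self):
        assert gaussian_limit(4900, sigma=70) == pytest.approx(70.0, abs=1e-12)

    def test_monotone_increasing(self):
        n = np.arange(0, 500)
        v = gaussian_limit(n)
        assert np.all(np.diff(v) > 0)

    def test_against_high_precision(self):
        for n in [1, 7, 42, 90, 126, 350, 1000]:
            assert gaussian_limit(n) == pytest.approx(
                gaussian_limit_highprec(n), abs=1e-9
            )

    def test_alternative_exponent_reading(self):
        v = gaussian_limit(90, sigma=70, half_bell=False)
        assert v == pytest.approx(gaussian_limit_highprec(90, half_bell=False), abs=1e-9)
        assert v > gaussian_limit(90, sigma=70, half_bell=True)

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            gaussian_limit(-1)
        with pytest.raises(ValueError):
            gaussian_limit(10, sigma=0)


class TestNormalizedScore:
    def test_point_on_curve_scores_one(self):
        r = gaussian_limit(100)
        assert normalized_sap_score(r, 100) == pytest.approx(1.0)

    def test_zero_rmsd(self):
        assert normalized_sap_score(0.0, 50) == 0.0

    def test_linear_in_r(self):
        assert normalized_sap_score(4.0, 80) == pytest.approx(
            2 * normalized_sap_score(2.0, 80)
        )

    def test_undefined_at_zero_length(self):
        with pytest.raises(ValueError):
            normalized_sap_score(1.0, 0)


class TestRatioScores:
    def test_arithmetic(self):
        assert ratio_scores(100, 5) == (20.0, 2000.0)

    def test_published_pair_values(self):
        n_over_r, n2_over_r = ratio_scores(113, 5.07)
        assert n_over_r == pytest.approx(22.29, abs=0.005)
        assert n2_over_r == pytest.approx(2518.5, abs=0.5)

    def test_quadratic_homogeneity(self):
        assert ratio_scores(60, 3)[1] * 4 == ratio_scores(120, 3)[1]

    def test_zero_rmsd_sentinel(self):
        assert ratio_scores(50, 0.0) == (math.inf, math.inf)


class TestCurve:
    SHAPE = PartitionCurve(a=2.5, b=0.7, c=5.0, d=4.0, N=120.0)

    def test_zero_at_origin(self):
        assert curve_value(0, self.SHAPE) == 0.0

    def test_switch_point_identity(self):
        n = self.SHAPE.switch_point
        assert curve_value(n, self.SHAPE) == pytest.approx(
            self.SHAPE.a * math.sqrt(n) / 2, abs=1e-12
        )

    def test_against_high_precision(self):
        for n in [1, 30, 89, 95, 120]:
            assert curve_value(n, self.SHAPE) == pytest.approx(
                curve_value_highprec(n, 2.5, 0.7, 5.0, 4.0, 120.0), abs=1e-12
            )

    def test_invalid_steepness(self):
        with pytest.raises(ValueError):
            PartitionCurve(a=1, b=0.5, c=0, d=0, N=100)

    def test_score_inverts_value(self):
        for a in [0.3, 2.5, 11.0]:
            curve = PartitionCurve(a=a, b=0.7, c=5.0, d=4.0, N=120.0)
            for n in [10, 60, 100]:
                r = curve_value(n, curve)
                assert curve_score(n, r, self.SHAPE) == pytest.approx(a, abs=1e-10)

    def test_score_matches_bisection_oracle(self):
        n, r = 85, 4.2
        a = curve_score(n, r, self.SHAPE)
        lo, hi = 0.0, 100.0
        for _ in range(60):
            mid = (lo + hi) / 2
            c = PartitionCurve(a=mid, b=0.7, c=5.0, d=4.0, N=120.0)
            if curve_value(n, c) < r:
                lo = mid
            else:
                hi = mid
        assert a == pytest.approx((lo + hi) / 2, abs=1e-10)

    def test_score_linear_in_r(self):
        assert curve_score(70, 8.0, self.SHAPE) == pytest.approx(
            2 * curve_score(70, 4.0, self.SHAPE)
        )

    def test_score_undefined_at_zero(self):
        with pytest.raises(ValueError):
            curve_score(0, 1.0, self.SHAPE)


class TestPartitionCounts:
    CURVE = PartitionCurve(a=1.0, b=0.5, c=0.0, d=5.0, N=100.0)

    def hand_records(self):
        # hand enumeration against the fixed curve: the boundary is about
        # sqrt(n) for n well beyond the switch at n = 50 and near zero below it
        pts = [
            ("p1", 90, 1.0, True),    # below sqrt(90) ~ 9.49 -> TP
            ("p2", 90, 12.0, True),   # above -> FN
            ("p3", 90, 1.0, False),   # below -> FP
            ("p4", 90, 12.0, False),  # above -> TN
            ("p5", 10, 0.1, True),    # boundary ~ 0.001 there -> FN
            ("p6", 95, float(curve_value(95, self.CURVE)), True),  # exactly on -> FN
        ]
        return [
            ComparisonRecord(idA=i, idB="x", n=n, r=r, same_fold=s)
            for i, n, r, s in pts
        ]

    def test_hand_enumerated_counts(self):
        counts = partition_counts(self.hand_records(), self.CURVE)
        assert (counts.TP, counts.FN, counts.FP, counts.TN) == (1, 3, 1, 1)

    def test_on_curve_is_negative(self):
        rec = ComparisonRecord(
            idA="a", idB="b", n=60, r=float(curve_value(60, self.CURVE)), same_fold=True
        )
        counts = partition_counts([rec] + self.hand_records(), self.CURVE)
        assert counts.FN == 4

    def test_unlabelled_rejected(self):
        rec = ComparisonRecord(idA="a", idB="b", n=50, r=1.0)
        with pytest.raises(ValueError):
            partition_counts([rec], self.CURVE)


class TestSScore:
    def test_perfect_partition(self):
        assert s_score(BenchmarkCounts(TP=10, FP=0, TN=5, FN=0), 0.5) == 100.0

    def test_worked_example(self):
        assert s_score(BenchmarkCounts(TP=8, FP=4, TN=0, FN=2), 0.5) == 60.0

    def test_fp_strictly_decreases_s(self):
        base = s_score(BenchmarkCounts(TP=8, FP=4, TN=0, FN=2), 0.5)
        worse = s_score(BenchmarkCounts(TP=8, FP=5, TN=0, FN=2), 0.5)
        assert worse < base

    def test_tn_invariance(self):
        a = s_score(BenchmarkCounts(TP=8, FP=4, TN=0, FN=2), 0.5)
        b = s_score(BenchmarkCounts(TP=8, FP=4, TN=1000, FN=2), 0.5)
        assert a == b

    def test_no_true_matches_error(self):
        with pytest.raises(ValueError, match="no true matches"):
            s_score(BenchmarkCounts(TP=0, FP=3, TN=2, FN=0), 0.5)


def separable_records(rng, n_true=40, n_false=80):
    recs = []
    for i in range(n_true):
        recs.append(
            ComparisonRecord(
                idA=f"t{i}", idB="x", n=int(rng.integers(60, 121)),
                r=float(rng.uniform(0.5, 3.0)), same_fold=True,
            )
        )
    for i in range(n_false):
        recs.append(
            ComparisonRecord(
                idA=f"f{i}", idB="x", n=int(rng.integers(20, 121)),
                r=float(rng.uniform(6.5, 15.0)), same_fold=False,
            )
        )
    return recs


class TestOptimizePartition:
    def test_separable_set_scores_100(self):
        res = optimize_partition(separable_records(np.random.default_rng(1)))
        assert res.s == 100.0
        assert res.counts.FN == 0 and res.counts.FP == 0

    def test_deterministic(self):
        recs = separable_records(np.random.default_rng(2))
        r1 = optimize_partition(recs)
        r2 = optimize_partition(recs)
        assert r1.curve == r2.curve and r1.s == r2.s

    def test_refinement_never_below_grid(self):
        rng = np.random.default_rng(3)
        recs = separable_records(rng, 30, 60)
        # overlap the classes so the optimum is not trivially 100
        recs += [
            ComparisonRecord(idA=f"o{i}", idB="x", n=int(rng.integers(60, 121)),
                             r=float(rng.uniform(2.0, 8.0)), same_fold=bool(i % 2))
            for i in range(30)
        ]
        grid = optimize_partition(recs, refine=False)
        refined = optimize_partition(recs, refine=True)
        assert refined.s >= grid.s

    def test_single_label_rejected(self):
        recs = [
            ComparisonRecord(idA=f"t{i}", idB="x", n=50, r=1.0, same_fold=True)
            for i in range(5)
        ]
        with pytest.raises(ValueError):
            optimize_partition(recs)

    def test_majority_of_true_pairs_enclosed_on_overlapping_data(self):
        """With w = 0.5 the fitted curve encloses most same-fold pairs."""
        rng = np.random.default_rng(4)
        recs = []
        for i in range(150):
            n = int(rng.integers(60, 127))
            recs.append(ComparisonRecord(
                idA=f"t{i}", idB="x", n=n,
                r=float(np.clip(rng.normal(3.0, 1.5), 0.2, None)), same_fold=True))
        for i in range(600):
            n = int(rng.integers(20, 127))
            recs.append(ComparisonRecord(
                idA=f"f{i}", idB="x", n=n,
                r=float(np.clip(rng.normal(9.0, 2.5), 0.5, None)), same_fold=False))
        res = optimize_partition(recs)
        assert res.tp_fraction >= 0.7


class TestRankMetric:
    def test_values(self):
        assert rank_metric(100, 0) == 0.5
        assert rank_metric(0, 0) == 0.0
        for k in [1, 10, 500]:
            assert rank_metric(k, k) == 0.0


class TestDiscrimination:
    def make_records(self, rng, n=60):
        recs = []
        for i in range(n):
            same = i % 3 == 0
            r = rng.uniform(1, 3) if same else rng.uniform(5, 12)
            recs.append(
                ComparisonRecord(idA=f"m{i:03d}", idB="x", n=100,
                                 r=float(r), tm=float(1 / (1 + r)), same_fold=same)
            )
        return recs

    def test_perfect_ranking_hugs_tp_axis(self):
        recs = self.make_records(np.random.default_rng(0))
        df = discrimination_curve(recs, key="tm")
        n_true = sum(r.same_fold for r in recs)
        assert df.TP.iloc[n_true - 1] == n_true and df.FP.iloc[n_true - 1] == 0

    def test_reversed_ranking_hugs_fp_axis(self):
        recs = self.make_records(np.random.default_rng(0))
        flipped = [
            ComparisonRecord(idA=r.idA, idB=r.idB, n=r.n, r=r.r,
                             tm=-r.tm, same_fold=r.same_fold)
            for r in recs
        ]
        df = discrimination_curve(flipped, key="tm")
        n_false = sum(not r.same_fold for r in recs)
        assert df.FP.iloc[n_false - 1] == n_false and df.TP.iloc[n_false - 1] == 0

    def test_random_ranking_tracks_diagonal(self):
        """Monte-Carlo: random scores put TP growth near the class fraction."""
        rng = np.random.default_rng(5)
        n = 400
        frac_true = 0.25
        tps = []
        for _ in range(100):
            recs = [
                ComparisonRecord(idA=f"m{i:03d}", idB="x", n=100, r=1.0,
                                 tm=float(rng.uniform()), same_fold=i < n * frac_true)
                for i in range(n)
            ]
            df = discrimination_curve(recs, key="tm")
            tps.append(df.TP.iloc[n // 2 - 1])
        mean_tp = np.mean(tps)
        expect = frac_true * n / 2
        sd = math.sqrt(n / 2 * frac_true * (1 - frac_true))
        assert abs(mean_tp - expect) < 4 * sd / math.sqrt(100)

    def test_curve_key_requires_curve(self):
        recs = self.make_records(np.random.default_rng(0))
        with pytest.raises(ValueError):
            discrimination_curve(recs, key="curve")


class TestTsvRoundTrip:
    def test_round_trip(self, tmp_path):
        recs = [
            ComparisonRecord(idA="a", idB="b", n=100, r=4.5, tm=0.6,
                             same_fold=True, edit_dist=0),
            ComparisonRecord(idA="a", idB="c", n=80, r=7.0, same_fold=False,
                             edit_dist=2),
        ]
        p = tmp_path / "records.tsv"
        write_records_tsv(p, recs)
        back = read_records_tsv(p)
        assert back == recs
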