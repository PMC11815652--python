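"""Method-comparison statistics: CCC, GEE proportion, Bland-Altman, MOVER."""

import math

import numpy as np
import pytest

from hemoval.agreement import (
    AgreementReport,
    agreement_report,
    ba_repeated,
    bootstrap_ccc_ci,
    lin_ccc,
    loa_mover_single,
    loa_with_mover,
    prop_within_gee,
    relative_difference,
)
from hemoval.io import PairedMeasurement

from conftest import make_pairs


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "ref, dev, expected",
        [
            (10.0, 8.0, 20.0),
            (10.0, 10.0, 0.0),
            (531.0, 657.0, 23.728813559322035),  # pooled SVR means
            (8.0, 10.0, 25.0),  # absolute value: sign of the error ignored
        ],
    )
    def test_arithmetic(self, ref, dev, expected):
        assert relative_difference(ref, dev) == pytest.approx(expected)

    def test_pair_overload_and_zero_reference(self):
        p = PairedMeasurement("A", 0.0, "CO", 10.0, 8.0)
        assert relative_difference(p) == 20.0
        with pytest.raises(ValueError):
            relative_difference(0.0, 8.0)


class TestLinCcc:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_location_shift_penalty(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        prev = 1.0
        for c in (0.5, 2.0, 10.0, 100.0):
            ccc = lin_ccc(x, x + c)
            assert ccc < prev
            prev = ccc
        assert prev < 1e-3  # -> 0 as the shift grows

    def test_hand_computed_value(self):
        # s_xy = 1, s_x^2 = 2/3, s_y^2 = 14/9, (mean gap)^2 = 1/9  ->  6/7
        assert lin_ccc([1, 2, 3], [1, 2, 4]) == pytest.approx(6.0 / 7.0)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(5, 2, 40), rng.normal(4, 3, 40)
        assert lin_ccc(x, y) == pytest.approx(lin_ccc(y, x))

    def test_equals_pearson_when_moments_match(self):
        # same mean and variance in both margins -> ccc == r
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        r = np.corrcoef(x, y)[0, 1]
        assert lin_ccc(x, y) == pytest.approx(r)

    def test_never_exceeds_pearson_magnitude(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), 30)
            y = 0.5 * x + rng.normal(0, 1, 30)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(lin_ccc(x, y)) <= abs(r) + 1e-12

    def test_undefined_when_degenerate(self):
        with pytest.raises(ValueError):
            lin_ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestBootstrapCcc:
    def test_identical_patients_perfect_agreement(self):
        pairs = []
        for pid in ("A", "B", "C"):
            pairs += make_pairs([(pid, 1.0, 1.0), (pid, 2.0, 2.0), (pid, 3.0, 3.0)])
        lo, hi = bootstrap_ccc_ci(pairs, n_boot=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_deterministic_given_seed(self, small_cohort):
        pairs = small_cohort.pairs_for("CO")
        ci1 = bootstrap_ccc_ci(pairs, n_boot=200, seed=5)
        ci2 = bootstrap_ccc_ci(pairs, n_boot=200, seed=5)
        assert ci1 == ci2

    def test_needs_two_patients(self):
        pairs = make_pairs([("A", 1.0, 1.1), ("A", 2.0, 2.2)])
        with pytest.raises(ValueError):
            bootstrap_ccc_ci(pairs, n_boot=100, seed=0)

    def test_small_n_boot_warns(self, small_cohort):
        with pytest.warns(UserWarning, match="n_boot"):
            bootstrap_ccc_ci(small_cohort.pairs_for("CO"), n_boot=50, seed=0)


class TestPropWithinGee:
    def test_all_within_tolerance_degenerate(self):
        pairs = make_pairs([("A", 10.0, 10.5), ("A", 10.0, 9.5), ("B", 8.0, 8.1)])
        res = prop_within_gee(pairs)
        assert res.proportion == 1.0 and res.se == 0.0 and res.ci == (1.0, 1.0)

    def test_one_indicator_per_patient_reduces_to_sample_mean(self):
        # patients A..F with one pair each; half within 20%, half outside
        data = [("A", 10, 9), ("B", 10, 5), ("C", 10, 9.5), ("D", 10, 4),
                ("E", 10, 10), ("F", 10, 3)]
        res = prop_within_gee(make_pairs(data))
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        assert res.proportion == pytest.approx(y.mean())
        # sandwich SE with one observation per cluster: sqrt(sum((y-p)^2))/n
        expected_se = math.sqrt(np.sum((y - y.mean()) ** 2)) / len(y)
        assert res.se == pytest.approx(expected_se, rel=1e-6)

    def test_matches_binomial_wald_when_independent(self):
        # many single-pair patients: GEE CI ~ Wald CI
        rng = np.random.default_rng(3)
        data = [(f"P{i}", 10.0, 9.0 if rng.random() < 0.6 else 5.0) for i in range(400)]
        res = prop_within_gee(make_pairs(data))
        p = res.proportion
        wald = math.sqrt(p * (1 - p) / 400)
        assert res.se == pytest.approx(wald, rel=0.05)

    def test_single_patient_falls_back_with_warning(self):
        pairs = make_pairs([("A", 10, 9), ("A", 10, 5), ("A", 10, 9.5)])
        with pytest.warns(UserWarning, match="fewer than 2 patients"):
            res = prop_within_gee(pairs)
        assert res.method == "binomial-wald"
        assert res.proportion == pytest.approx(2.0 / 3.0)

    def test_logit_link_close_to_identity(self, small_cohort):
        pairs = small_cohort.pairs_for("CO")
        ident = prop_within_gee(pairs, link="identity")
        logit = prop_within_gee(pairs, link="logit")
        assert logit.proportion == pytest.approx(ident.proportion, abs=0.05)


class TestBaRepeated:
    def test_constant_differences(self):
        pairs = make_pairs([("A", 10, 8), ("A", 9, 7), ("B", 12, 10), ("B", 6, 4)])
        ba = ba_repeated(pairs)
        assert ba.bias == pytest.approx(2.0) and ba.sd == pytest.approx(0.0)

    def test_balanced_zero_within_variance(self):
        # each patient: identical replicate differences -> sd = SD of means
        diffs = {"A": 1.0, "B": 3.0, "C": 5.0}
        data = [(pid, 10.0 + d, 10.0) for pid, d in diffs.items() for _ in range(3)]
        ba = ba_repeated(make_pairs(data))
        assert ba.bias == pytest.approx(3.0)
        assert ba.sd == pytest.approx(np.std([1.0, 3.0, 5.0], ddof=1))

    def test_bias_order_invariance(self):
        rng = np.random.default_rng(2)
        data = [(f"P{i % 5}", 10 + rng.normal(), 8 + rng.normal()) for i in range(40)]
        pairs = make_pairs(data)
        ba1 = ba_repeated(pairs)
        perm = list(rng.permutation(len(pairs)))
        ba2 = ba_repeated([pairs[i] for i in perm])
        assert ba1.bias == pytest.approx(ba2.bias)
        assert ba1.sd == pytest.approx(ba2.sd)

    def test_singleton_patients_contribute_to_between_only(self):
        data = [("A", 11, 10), ("B", 13, 10), ("B", 12, 10), ("C", 14, 10)]
        ba = ba_repeated(make_pairs(data))
        assert ba.bias == pytest.approx((1 + 2.5 + 4) / 3)
        assert ba.df_within == 1

    def test_all_singletons_falls_back(self):
        data = [("A", 11, 10), ("B", 13, 10), ("C", 14, 10)]
        with pytest.warns(UserWarning, match="single replicate"):
            ba = ba_repeated(make_pairs(data))
        assert ba.sd == pytest.approx(np.std([1.0, 3.0, 4.0], ddof=1))

    def test_simple_sd_method_is_pooled_sd(self):
        rng = np.random.default_rng(4)
        data = [(f"P{i % 4}", 10 + rng.normal(), 8 + rng.normal()) for i in range(24)]
        pairs = make_pairs(data)
        diffs = [p.difference for p in pairs]
        ba = ba_repeated(pairs, sd_method="simple")
        assert ba.sd == pytest.approx(np.std(diffs, ddof=1))


class TestMover:
    def test_degenerate_zero_sd(self):
        ba = ba_repeated(
            make_pairs([("A", 10, 8), ("A", 9, 7), ("B", 12, 10), ("B", 6, 4)])
        )
        loa = loa_with_mover(ba)
        assert loa.loa_lower == loa.loa_upper == 2.0
        assert loa.loa_lower_ci == loa.loa_upper_ci == (2.0, 2.0)

    def test_limit_arithmetic_and_ordering(self, small_cohort):
        ba = ba_repeated(small_cohort.pairs_for("SVR"))
        loa = loa_with_mover(ba)
        z = 1.959963984540054
        assert loa.loa_upper == pytest.approx(ba.bias + z * ba.sd)
        assert loa.loa_lower == pytest.approx(ba.bias - z * ba.sd)
        assert loa.loa_lower_ci[0] < loa.loa_lower < loa.loa_lower_ci[1]
        assert loa.loa_upper_ci[0] < loa.loa_upper < loa.loa_upper_ci[1]
        assert loa.loa_lower < ba.bias < loa.loa_upper

    def test_single_level_matches_hand_mover(self):
        # n independent differences: t CI for mean, exact chi-square for sd
        mean, sd, n = 0.5, 2.0, 30
        from scipy import stats

        loa = loa_mover_single(mean, sd, n)
        z = 1.959963984540054
        tq = stats.t.ppf(0.975, n - 1)
        l_s = z * sd * math.sqrt((n - 1) / stats.chi2.ppf(0.975, n - 1))
        u_s = z * sd * math.sqrt((n - 1) / stats.chi2.ppf(0.025, n - 1))
        se = sd / math.sqrt(n)
        upper = mean + z * sd
        expect_hi = upper + math.sqrt((tq * se) ** 2 + (u_s - z * sd) ** 2)
        expect_lo = upper - math.sqrt((tq * se) ** 2 + (z * sd - l_s) ** 2)
        assert loa.loa_upper_ci == pytest.approx((expect_lo, expect_hi))


class TestAgreementReport:
    def test_perfect_co_agreement(self):
        data = [(pid, v, v) for pid in "ABC" for v in (8.0, 10.0, 12.0)]
        rep = agreement_report(make_pairs(data), "CO", n_boot=100, seed=0)
        assert rep.agrees_point and rep.agrees_ci and rep.agrees
        assert rep.ccc == pytest.approx(1.0)

    def test_svr_like_disagreement(self, small_cohort):
        rep = agreement_report(small_cohort.pairs, "SVR", n_boot=200, seed=0)
        assert rep.bias < 0  # device reads higher than reference
        assert not rep.agrees  # limits far outside +/-200
        assert rep.loa_lower < -rep.cad

    def test_json_round_trip(self, small_cohort):
        rep = agreement_report(small_cohort.pairs, "CO", n_boot=100, seed=1)
        back = AgreementReport.from_dict(rep.to_dict())
        assert back.to_dict() == rep.to_dict()
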