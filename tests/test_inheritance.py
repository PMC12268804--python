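"""Dominance statistics, the DML curve, and the backcross monogenic test."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from resistkit import (classify_dominance, dml_curve, dominance_bourguet,
                       dominance_stone, expected_backcross_mortality,
                       functional_dominance, monogenic_test)
from resistkit.dose_response import ProbitFit
from resistkit.errors import ContractError, UndefinedStatisticError


def _equal_slope_fit(lc50, slope=1.5):
    return ProbitFit(strain="S", compound="bif",
                     intercept=-slope * np.log10(lc50), slope=slope,
                     slope_se=0.1, cov=np.zeros((2, 2)), n_groups=6, df=4,
                     pearson_chi2=2.0, gof_p=0.7, heterogeneity=0.5,
                     n_total=240, loglik=0.0)


class TestStone:
    def test_study_strain_lc50s_give_incomplete_dominance(self):
        # H2 cross: LC50s 77.38 (F1), 3080.95 (RR), 0.64 (SS)
        d = dominance_stone(77.38, 3080.95, 0.64)
        assert d.rounded() == 0.13
        assert d.classification == "incomplete dominant"

    def test_h1_cross_direct_evaluation(self):
        assert dominance_stone(58.98, 3080.95, 0.64).rounded() == 0.07

    def test_endpoints(self):
        assert dominance_stone(3080.95, 3080.95, 0.64).D == pytest.approx(1.0)
        assert dominance_stone(0.64, 3080.95, 0.64).D == pytest.approx(-1.0)

    def test_equal_parents_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            dominance_stone(1.0, 2.0, 2.0)

    def test_nonpositive_lc50_rejected(self):
        with pytest.raises(ContractError):
            dominance_stone(-1.0, 2.0, 1.0)


class TestBourguet:
    def test_endpoints_and_midpoint(self):
        assert dominance_bourguet(0.95, 0.05, 0.95).D == pytest.approx(0.0)
        assert dominance_bourguet(0.05, 0.05, 0.95).D == pytest.approx(1.0)
        assert dominance_bourguet(0.50, 0.05, 0.95).D == pytest.approx(0.50)

    def test_direct_formula_value(self):
        d = dominance_bourguet(0.25, 0.03, 0.99)
        assert d.D == pytest.approx((0.25 - 0.99) / (0.03 - 0.99))
        assert d.D == pytest.approx(0.770833, abs=1e-6)

    def test_out_of_range_flagged_not_clamped(self):
        d = dominance_bourguet(0.01, 0.10, 0.90)
        assert d.D > 1.0 and d.out_of_range

    def test_equal_parents_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            dominance_bourguet(0.5, 0.3, 0.3)

    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.999),
           st.floats(0.001, 0.999))
    @settings(max_examples=200, deadline=None)
    def test_survival_mortality_exchange_invariance(self, mrs, mrr, mss):
        # replacing every mortality m by survival 1-m leaves D unchanged
        if abs(mrr - mss) < 1e-6:
            return
        d1 = dominance_bourguet(mrs, mrr, mss).D
        d2 = ((1 - mrs) - (1 - mss)) / ((1 - mrr) - (1 - mss))
        assert d1 == pytest.approx(d2, rel=1e-9, abs=1e-9)


class TestDmlCurve:
    def test_closed_form_values_equal_slopes(self):
        fits = [_equal_slope_fit(lc) for lc in (0.64, 59.0, 3081.0)]
        curve = dml_curve(*fits, concentrations=[1.0, 100.0])
        assert curve["D"].iloc[0] == pytest.approx(0.993, abs=0.001)
        assert curve["D"].iloc[1] == pytest.approx(0.369, abs=0.001)

    def test_non_increasing_with_concentration(self):
        fits = [_equal_slope_fit(lc) for lc in (0.64, 59.0, 3081.0)]
        curve = dml_curve(*fits, concentrations=np.geomspace(0.5, 500, 50))
        assert (np.diff(curve["D"].to_numpy()) <= 1e-12).all()

    def test_heterozygote_equal_to_resistant_gives_unity(self):
        ss, rr = _equal_slope_fit(0.64), _equal_slope_fit(3081.0)
        curve = dml_curve(ss, rr, rr, concentrations=np.geomspace(1, 100, 5))
        assert np.allclose(curve["D"], 1.0)

    def test_degenerate_point_flagged_not_dropped(self):
        same = _equal_slope_fit(10.0)
        curve = dml_curve(same, same, same, concentrations=[1.0, 10.0])
        assert len(curve) == 2 and curve["undefined"].all()


class TestBackcrossExpectation:
    def test_arithmetic_mean(self):
        assert expected_backcross_mortality(0.9, 0.0).p == pytest.approx(0.45)
        assert expected_backcross_mortality(0.4, 0.4).p == pytest.approx(0.4)
        assert expected_backcross_mortality(0.878, 0.022).p == pytest.approx(
            0.45)

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            expected_backcross_mortality(1.2, 0.0)


class TestMonogenicTest:
    def test_exact_expectation_gives_zero_chi2(self):
        res = monogenic_test([{"concentration": 10, "n_dead": 18,
                               "n_total": 40, "expected_p": 0.45}])
        assert res.rows["chi2"].iloc[0] == pytest.approx(0.0)
        assert not res.rejected

    def test_strong_deviation_detected(self):
        res = monogenic_test([{"concentration": 3.2, "n_dead": 5,
                               "n_total": 40, "expected_p": 0.45}])
        assert res.rows["chi2"].iloc[0] == pytest.approx(17.0707, abs=1e-3)
        assert res.rows["significant"].iloc[0]
        assert res.verdict == "monogenic rejected"

    def test_degenerate_expectation_rejected(self):
        for p in (0.0, 1.0):
            with pytest.raises(UndefinedStatisticError):
                monogenic_test([{"concentration": 1, "n_dead": 0,
                                 "n_total": 40, "expected_p": p}])

    @given(st.integers(1, 200), st.integers(0, 200),
           st.floats(0.01, 0.99))
    @settings(max_examples=300, deadline=None)
    def test_chi2_is_square_of_proportion_z(self, ni, Ni, p):
        # oracle: one-sample proportion z statistic computed independently
        if Ni > ni:
            return
        res = monogenic_test([{"concentration": 1.0, "n_dead": Ni,
                               "n_total": ni, "expected_p": p}])
        z = (Ni / ni - p) / np.sqrt(p * (1 - p) / ni)
        assert res.rows["chi2"].iloc[0] == pytest.approx(z ** 2, rel=1e-9)

    def test_bonferroni_policy_more_conservative(self):
        rows = [{"concentration": c, "n_dead": d, "n_total": 40,
                 "expected_p": 0.5}
                for c, d in [(1, 13), (2, 27), (3, 20)]]
        anyrow = monogenic_test(rows, policy="any-row")
        bonf = monogenic_test(rows, policy="bonferroni")
        assert anyrow.rejected and not bonf.rejected


class TestFunctionalDominance:
    def test_bourguet_at_dose_from_counts(self):
        res = functional_dominance(
            {"SS": (48, 50), "RR": (2, 50), "H1": (25, 50)},
            dose=94.0, ss="SS", rr="RR")
        assert res.D_at_dose["H1"].D == pytest.approx(0.50)

    def test_identical_counts_share_one_letter(self):
        res = functional_dominance(
            {s: (20, 50) for s in ("SS", "RR", "H1", "H2")},
            dose=94.0, ss="SS", rr="RR", het=[])
        assert len(set(res.letters.values())) == 1

    def test_extreme_difference_gets_distinct_letters(self):
        res = functional_dominance({"SS": (50, 50), "RR": (0, 50)},
                                   dose=469.0, ss="SS", rr="RR", het=[])
        row = res.comparisons.iloc[0]
        assert row["p_adj"] < 0.001
        assert res.letters["SS"] != res.letters["RR"]

    def test_letters_consistent_with_adjusted_tests(self):
        res = functional_dominance(
            {"SS": (49, 50), "RR": (1, 50), "H1": (24, 50), "H2": (27, 50)},
            dose=94.0, ss="SS", rr="RR")
        for _, row in res.comparisons.iterrows():
            shared = set(res.letters[row["strain_1"]]) & set(
                res.letters[row["strain_2"]])
            assert bool(shared) == (not row["significant"])

    def test_zero_exposed_rejected(self):
        with pytest.raises(ContractError):
            functional_dominance({"SS": (0, 0), "RR": (1, 50)}, dose=94.0,
                                 ss="SS", rr="RR")


class TestClassify:
    @pytest.mark.parametrize("d,label", [
        (0.13, "incomplete dominant"),
        (1.0, "complete dominant"),
        (0.997, "complete dominant"),
        (-0.4, "incomplete recessive"),
        (-1.0, "complete recessive"),
        (0.0, "codominant/additive midpoint"),
    ])
    def test_boundary_convention(self, d, label):
        assert classify_dominance(d) == label
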