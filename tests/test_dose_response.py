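"""Probit fitting, lethal concentrations, ratios, and line comparisons."""
import numpy as np
import pytest
from scipy import stats

from resistkit import (compare_lines, diagnostic_dose, estimate_lc,
                       fit_probit, goodness_of_fit, resistance_ratio,
                       LcEstimate)
from resistkit.dose_response import ProbitFit, pearson_chi2
from resistkit.errors import (ContractError, SeparationError,
                              UndefinedStatisticError,
                              UnidentifiableSlopeError)
from conftest import (probit_grid_loglik, simulate_single_line,
                      table_from_counts)


def _fit_from_params(intercept, slope, slope_se=0.0, cov=None, het=1.0,
                     inflate=False):
    cov = np.zeros((2, 2)) if cov is None else np.asarray(cov)
    return ProbitFit(strain="S", compound="bif", intercept=intercept,
                     slope=slope, slope_se=slope_se, cov=cov, n_groups=6,
                     df=4, pearson_chi2=het * 4, gof_p=0.5,
                     heterogeneity=het, n_total=240, loglik=0.0,
                     inflate=inflate)


class TestFitProbit:
    def test_recovers_simulated_parameters(self):
        # beta = 2, LC50 = 10, 7 log-spaced concentrations 1-100, n = 50
        t = simulate_single_line(10.0, 2.0, np.geomspace(1, 100, 7), 50,
                                 seed=1)
        fit = fit_probit(t)
        lc = estimate_lc(fit, 0.5)
        assert lc.ci_low <= lc.dose <= lc.ci_high
        assert 8.0 <= lc.dose <= 12.5
        assert fit.loglik >= probit_grid_loglik(t) - 1e-3

    @pytest.mark.parametrize("seed", range(6))
    def test_loglik_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lc50 = 10 ** rng.uniform(-0.5, 2.0)
        slope = rng.uniform(1.0, 2.5)
        concs = lc50 * np.geomspace(0.08, 12.0, rng.integers(5, 9))
        t = simulate_single_line(lc50, slope, concs, 40, seed=seed + 100)
        fit = fit_probit(t)
        assert fit.loglik >= probit_grid_loglik(t) - 1e-3

    def test_duplicated_table_shrinks_se_by_sqrt2(self):
        import pandas as pd
        from resistkit import BioassayTable
        t = simulate_single_line(10.0, 2.0, np.geomspace(1, 100, 7), 50,
                                 seed=4)
        fit1 = fit_probit(t)
        doubled = BioassayTable(pd.concat([t.df, t.df], ignore_index=True))
        fit2 = fit_probit(doubled)
        assert fit2.slope == pytest.approx(fit1.slope, rel=1e-6)
        assert fit2.intercept == pytest.approx(fit1.intercept, rel=1e-6)
        assert fit2.slope_se == pytest.approx(fit1.slope_se / np.sqrt(2),
                                              rel=1e-4)

    def test_complete_separation_raises(self):
        t = table_from_counts([1.0, 3.2, 32.0, 100.0], 50, [0, 0, 50, 50])
        with pytest.raises(SeparationError):
            fit_probit(t)

    def test_all_equal_mortality_unidentifiable(self):
        t = table_from_counts([1.0, 3.2, 10.0], 40, [20, 20, 20])
        with pytest.raises(UnidentifiableSlopeError):
            fit_probit(t)

    def test_single_concentration_rejected(self):
        t = table_from_counts([1.0, 1.0], 40, [10, 12])
        with pytest.raises(ContractError):
            fit_probit(t)

    def test_controls_never_enter_likelihood(self):
        t1 = simulate_single_line(10.0, 2.0, np.geomspace(1, 100, 7), 50,
                                  seed=9)
        import pandas as pd
        from resistkit import BioassayTable
        ctrl = pd.DataFrame([{"strain": "S", "compound": "bifenthrin",
                              "concentration_ug_ml": 0.0, "n_total": 40,
                              "n_dead": 1}])
        t2 = BioassayTable(pd.concat([t1.df, ctrl], ignore_index=True))
        assert fit_probit(t2).loglik == pytest.approx(fit_probit(t1).loglik)


class TestEstimateLc:
    def test_lc50_closed_form(self):
        fit = _fit_from_params(-2.0, 2.0)
        assert estimate_lc(fit, 0.5).dose == pytest.approx(10.0)

    def test_lc99_closed_form_sus_parameters(self):
        # slope 1.88, LC50 0.64: LC99 = 0.64 * 10^(2.32635/1.88)
        fit = _fit_from_params(1.88 * np.log10(1 / 0.64), 1.88)
        assert estimate_lc(fit, 0.99).dose == pytest.approx(11.06, abs=0.01)

    def test_lc50_inverts_predicted_mortality(self):
        t = simulate_single_line(5.0, 1.5, np.geomspace(0.5, 50, 7), 50,
                                 seed=2)
        fit = fit_probit(t)
        dose = estimate_lc(fit, 0.5).dose
        assert float(fit.predict(dose)) == pytest.approx(0.5, abs=1e-12)

    def test_quantile_bounds_enforced(self):
        fit = _fit_from_params(-2.0, 2.0)
        for p in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ContractError):
                estimate_lc(fit, p)

    def test_heterogeneity_inflates_interval(self):
        cov = np.array([[0.04, -0.01], [-0.01, 0.02]])
        plain = _fit_from_params(-2.0, 2.0, cov=cov)
        hot = _fit_from_params(-2.0, 2.0, cov=cov, het=3.0, inflate=True)
        lc0, lc1 = estimate_lc(plain, 0.5), estimate_lc(hot, 0.5)
        assert lc1.se_log10 == pytest.approx(lc0.se_log10 * np.sqrt(3.0))


class TestGoodnessOfFit:
    def test_exact_fit_gives_zero_chi2(self):
        n = np.array([40.0, 40.0, 40.0])
        p = np.array([0.2, 0.5, 0.8])
        assert pearson_chi2(n * p, n, p) == pytest.approx(0.0)

    def test_six_groups_give_four_df(self):
        t = simulate_single_line(10.0, 1.5, np.geomspace(1, 100, 6), 40,
                                 seed=3)
        fit = fit_probit(t)
        gof = goodness_of_fit(fit, t)
        assert gof["df"] == 4
        assert gof["chi2"] == pytest.approx(fit.pearson_chi2)

    def test_two_groups_undefined(self):
        t = simulate_single_line(10.0, 2.0, [3.0, 30.0], 200, seed=5)
        fit = fit_probit(t)
        with pytest.raises(UndefinedStatisticError):
            goodness_of_fit(fit)


class TestResistanceRatio:
    def test_self_ratio_is_one_with_ci_containing_one(self):
        t = simulate_single_line(10.0, 2.0, np.geomspace(1, 100, 7), 50,
                                 seed=6)
        lc = estimate_lc(fit_probit(t), 0.5)
        rr = resistance_ratio(lc, lc)
        assert rr.ratio == pytest.approx(1.0)
        assert rr.ci_low <= 1.0 <= rr.ci_high

    def test_point_inputs_flagged_as_rounded(self):
        rr = resistance_ratio(LcEstimate.from_point(1431.76),
                              LcEstimate.from_point(0.70))
        assert rr.inputs_rounded
        assert round(rr.ratio, 2) == 2045.37

    def test_mismatched_quantiles_rejected(self):
        with pytest.raises(ContractError):
            resistance_ratio(LcEstimate.from_point(10.0, p=0.5),
                             LcEstimate.from_point(1.0, p=0.9))

    def test_mismatched_compounds_rejected(self):
        with pytest.raises(ContractError):
            resistance_ratio(
                LcEstimate.from_point(10.0, compound="bifenthrin"),
                LcEstimate.from_point(1.0, compound="acephate"))

    def test_antisymmetry(self):
        a = LcEstimate.from_point(74.62)
        b = LcEstimate.from_point(0.12)
        prod = resistance_ratio(a, b).ratio * resistance_ratio(b, a).ratio
        assert prod == pytest.approx(1.0, rel=1e-12)


class TestCompareLines:
    def _two_lines(self, lc1, lc2, slope1, slope2, seed):
        t1 = simulate_single_line(lc1, slope1, np.geomspace(1, 1000, 6), 40,
                                  seed=seed, strain="A")
        t2 = simulate_single_line(lc2, slope2, np.geomspace(1, 1000, 6), 40,
                                  seed=seed + 1, strain="B")
        return [t1, t2]

    def test_identical_data_gives_zero_chi2(self):
        t = simulate_single_line(10.0, 2.0, np.geomspace(1, 100, 7), 50,
                                 seed=8)
        for hyp in ("equality", "parallelism"):
            cmp = compare_lines([t, t], hyp)
            assert cmp.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_df_conventions_two_lines(self):
        tabs = self._two_lines(50.0, 80.0, 1.0, 1.0, seed=10)
        assert compare_lines(tabs, "equality").df == 2
        assert compare_lines(tabs, "parallelism").df == 1

    def test_chi2_invariant_to_unit_rescaling(self):
        import pandas as pd
        from resistkit import BioassayTable
        tabs = self._two_lines(50.0, 120.0, 1.2, 1.8, seed=12)
        ref = {h: compare_lines(tabs, h).chi2
               for h in ("equality", "parallelism")}
        scaled = []
        for t in tabs:
            df = t.df.copy()
            df["concentration_ug_ml"] *= 1000.0  # mg -> ug
            scaled.append(BioassayTable(df))
        for h in ("equality", "parallelism"):
            assert compare_lines(scaled, h).chi2 == pytest.approx(
                ref[h], abs=1e-5)

    def test_monte_carlo_rejection_rates(self):
        # common slope 1.5, intercepts offset by one log10 unit:
        # parallelism (true) rarely rejected, equality (false) almost always
        rng_seeds = range(200)
        par_rej = eq_rej = 0
        for s in rng_seeds:
            tabs = self._two_lines(30.0, 300.0, 1.5, 1.5, seed=3000 + 2 * s)
            par_rej += compare_lines(tabs, "parallelism").p_value < 0.05
            eq_rej += compare_lines(tabs, "equality").p_value < 0.05
        assert par_rej / len(rng_seeds) <= 0.09
        assert eq_rej / len(rng_seeds) >= 0.95

    def test_mixed_compounds_rejected(self):
        t1 = simulate_single_line(10.0, 2.0, np.geomspace(1, 100, 6), 40,
                                  seed=20)
        import pandas as pd
        from resistkit import BioassayTable
        df = t1.df.copy()
        df["compound"] = "acephate"
        with pytest.raises(ContractError):
            compare_lines([t1, BioassayTable(df)], "equality")


class TestDiagnosticDose:
    def test_zero_variance_equals_point_lc99(self):
        fit = _fit_from_params(1.88 * np.log10(1 / 0.64), 1.88)
        assert diagnostic_dose(fit) == pytest.approx(
            estimate_lc(fit, 0.99).dose)

    def test_exceeds_point_estimate_with_uncertainty(self):
        cov = np.array([[0.05, -0.015], [-0.015, 0.02]])
        fit = _fit_from_params(1.88 * np.log10(1 / 0.64), 1.88, cov=cov)
        assert diagnostic_dose(fit) > 11.06

    def test_monotone_in_parameter_variance(self):
        base = np.array([[0.05, -0.015], [-0.015, 0.02]])
        doses = [diagnostic_dose(_fit_from_params(
            1.88 * np.log10(1 / 0.64), 1.88, cov=s * base))
            for s in (1.0, 2.0, 4.0)]
        assert doses[0] < doses[1] < doses[2]
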