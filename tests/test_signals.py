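import math

import numpy as np
import pytest
from scipy import stats

from pvsignal.contingency import ContingencyTable, build_tables
from pvsignal.signals import (DUMOUCHEL_START, DisproportionalityModel,
                              GpsPrior, SignalCriteria, SignalResult,
                              classify, compute_signals, ebgm,
                              fit_gps_prior, fit_gps_prior_counts,
                              gps_marginal_loglik, ic_bate, prr_estimate,
                              ror_estimate)

from _oracles import ebgm05_quadrature_oracle, ic_mc_oracle


def T(a, b, c, d):
    return ContingencyTable("E", "PT", a, b, c, d)


class TestRor:
    def test_closed_form(self):
        r = ror_estimate(T(10, 20, 30, 240))
        assert r.ror == pytest.approx(4.0)
        assert not r.corrected

    def test_ci_matches_wald_formula(self):
        r = ror_estimate(T(10, 20, 30, 240))
        se = math.sqrt(1 / 10 + 1 / 20 + 1 / 30 + 1 / 240)
        assert r.lo == pytest.approx(4.0 * math.exp(-1.96 * se))
        assert r.hi == pytest.approx(4.0 * math.exp(1.96 * se))

    def test_null_table_symmetric_on_log_scale(self):
        r = ror_estimate(T(5, 5, 5, 5))
        assert r.ror == pytest.approx(1.0)
        assert r.lo * r.hi == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        r = ror_estimate(T(0, 10, 10, 100))
        assert r.corrected
        assert r.ror == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))


class TestPrr:
    def test_closed_form(self):
        p = prr_estimate(T(10, 20, 30, 240))
        assert p.prr == pytest.approx((10 / 30) / (30 / 270))
        assert p.prr == pytest.approx(3.0)

    def test_null_table_chi2_degenerates_to_zero(self):
        p = prr_estimate(T(5, 5, 5, 5))
        assert p.prr == pytest.approx(1.0)
        assert p.chi2 == 0.0

    @pytest.mark.parametrize("cells", [
        (20, 80, 10, 890), (10, 20, 30, 240), (3, 7, 11, 200), (1, 1, 1, 50)])
    def test_yates_chi2_matches_independent_computation(self, cells):
        """Brute-force expected-table oracle for the Yates statistic."""
        a, b, c, d = cells
        n = a + b + c + d
        obs = np.array([[a, b], [c, d]], dtype=float)
        exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
        oracle = float(
            ((np.maximum(np.abs(obs - exp) - 0.5, 0.0)) ** 2 / exp).sum())
        assert prr_estimate(T(*cells)).chi2 == pytest.approx(oracle)
        assert prr_estimate(T(*cells)).chi2 == pytest.approx(
            stats.chi2_contingency(obs, correction=True)[0])

    def test_zero_margin_flags_undefined(self):
        p = prr_estimate(T(0, 0, 10, 100))
        assert not p.defined and math.isnan(p.prr)


class TestIc:
    def test_independence_limit_is_near_zero(self):
        # a = (a+b)(a+c)/N exactly
        t = T(100, 900, 900, 8100)
        assert abs(ic_bate(t).ic) < 0.05

    def test_matches_monte_carlo_oracle(self):
        t = T(10, 20, 30, 240)
        est = ic_bate(t)
        mc, se = ic_mc_oracle(t, n_draws=10**6)
        assert abs(est.ic - mc) <= 3 * se

    def test_zero_count_is_finite(self):
        est = ic_bate(T(0, 50, 200, 5000))
        assert math.isfinite(est.ic) and math.isfinite(est.ic025)
        assert est.ic < 0

    def test_ic025_below_ic(self):
        est = ic_bate(T(10, 20, 30, 240))
        assert est.ic025 < est.ic
        assert est.ic025 == pytest.approx(est.ic - 2 * math.sqrt(est.var))


class TestGpsPriorFit:
    def test_fewer_than_10_tables_is_error(self):
        with pytest.raises(ValueError, match="10"):
            fit_gps_prior([T(1, 1, 1, 1)] * 9)

    def test_deterministic_under_fixed_data(self):
        rng = np.random.default_rng(0)
        tables = [
            T(int(a), 50, int(c), 5000)
            for a, c in zip(rng.integers(0, 30, 40), rng.integers(1, 100, 40))]
        p1, p2 = fit_gps_prior(tables), fit_gps_prior(tables)
        assert p1 == p2

    def test_known_prior_likelihood_recovered(self):
        """Counts simulated from the default prior: the fitted maximum must
        reach the truth's marginal log-likelihood (within optimizer slack)."""
        rng = np.random.default_rng(42)
        truth = GpsPrior()
        n = 5000
        e = rng.lognormal(1.0, 1.0, n)
        comp = rng.random(n) < truth.pi
        lam = np.where(
            comp,
            rng.gamma(truth.alpha1, 1 / truth.beta1, n),
            rng.gamma(truth.alpha2, 1 / truth.beta2, n))
        a = rng.poisson(lam * e)
        fitted = fit_gps_prior_counts(a, e)
        ll_truth = gps_marginal_loglik(truth, a.astype(float), e)
        assert fitted.converged
        assert fitted.log_likelihood >= ll_truth - 2.0

    def test_null_poisson_data_concentrates_prior_near_one(self):
        rng = np.random.default_rng(7)
        e = rng.lognormal(1.5, 1.0, 4000)
        a = rng.poisson(e)
        fitted = fit_gps_prior_counts(a, e)
        assert 0.5 <= fitted.prior_mean <= 2.0


class TestEbgm:
    def test_quantile_matches_quadrature_oracle(self):
        prior = GpsPrior(alpha1=0.7, beta1=0.6, alpha2=1.8, beta2=1.5, pi=0.4)
        for cells in [(10, 20, 30, 240), (3, 100, 40, 2000), (0, 30, 60, 900)]:
            t = T(*cells)
            mine = ebgm(t, prior).ebgm05
            oracle = ebgm05_quadrature_oracle(t, prior)
            assert mine == pytest.approx(oracle, rel=1e-4)

    def test_shrinkage_vanishes_for_large_counts(self):
        # a/E fixed at 5 with growing a
        vals = []
        for scale in (1, 10, 100, 1000):
            a = 5 * scale
            b = 95 * scale
            c = 95 * scale          # column total 100*scale, E = a_exp
            d = 9905 * scale
            t = T(a, b, c, d)
            vals.append(ebgm(t, DUMOUCHEL_START).ebgm / (t.a / t.expected))
        assert abs(vals[-1] - 1.0) < 0.02
        assert abs(vals[-1] - 1.0) < abs(vals[0] - 1.0)

    def test_zero_count_shrinks_below_one(self):
        assert ebgm(T(0, 100, 500, 10_000), DUMOUCHEL_START).ebgm < 1.0

    def test_zero_expected_flags_undefined(self):
        est = ebgm(T(0, 0, 0, 10), DUMOUCHEL_START)
        assert not est.defined


class TestClassify:
    def _result(self, **kw):
        base = dict(term="E", level="PT", a=10, ror=3, ror_lo=1.5, ror_hi=6,
                    ror_corrected=False, prr=3, chi2=10, ic=1, ic025=0.5,
                    ebgm=3, ebgm05=2.5)
        base.update(kw)
        return SignalResult(**base)

    def test_minimum_count_gates_ror(self):
        r = self._result(a=2, ror=100, ror_lo=50)
        assert not classify(r)["ROR"]

    def test_mhra_boundaries_inclusive(self):
        r = self._result(a=3, prr=2.0, chi2=4.0)
        assert classify(r)["PRR"]
        assert not classify(self._result(a=3, prr=1.999, chi2=4.0))["PRR"]

    def test_ic025_boundary_strict(self):
        assert not classify(self._result(ic025=0.0))["BCPNN"]
        assert classify(self._result(ic025=1e-9))["BCPNN"]

    def test_ebgm05_boundary_strict(self):
        assert not classify(self._result(ebgm05=2.0))["MGPS"]

    def test_composite_any_vs_all(self):
        r = self._result(ic025=-1.0)  # BCPNN negative, others positive
        assert classify(r, SignalCriteria(composite="any"))["composite"]
        assert not classify(r, SignalCriteria(composite="all"))["composite"]

    def test_invalid_composite_rejected(self):
        with pytest.raises(ValueError):
            SignalCriteria(composite="most")


class TestMonotonicityAndRanking:
    def test_all_estimators_increase_with_a(self):
        prior = DUMOUCHEL_START
        prev = None
        for a in (1, 5, 20, 80):
            t = T(a, 100, 300, 9000)
            cur = (ror_estimate(t).ror, prr_estimate(t).prr,
                   ic_bate(t).ic, ebgm(t, prior).ebgm)
            if prev is not None:
                assert all(c > p for c, p in zip(cur, prev))
            prev = cur

    def test_estimators_rank_like_relative_reporting_ratio(self, small_planted):
        corpus, target = small_planted["corpus"], small_planted["target"]
        tables = build_tables(corpus, target, "PT")
        res = DisproportionalityModel(tables).fit().frame
        rrr = np.array([t.a / t.expected for t in tables])
        for col in ("ror", "prr", "ic", "ebgm"):
            rho = stats.spearmanr(rrr, res[col]).statistic
            assert rho > 0.9, col


class TestModelFacade:
    def test_summary_and_report_layout(self, small_planted):
        corpus, target = small_planted["corpus"], small_planted["target"]
        res = DisproportionalityModel.from_corpus(corpus, target, "PT").fit()
        text = res.summary()
        assert "Disproportionality screen" in text
        frame = res.report_frame()
        assert list(frame.columns) == [
            "Preferred term (PT)", "Case reports", "ROR (95% CI)",
            "PRR (95% CI)", "IC (IC025)", "EBGM (EBGM05)"]

    def test_mixed_levels_rejected(self):
        with pytest.raises(ValueError):
            DisproportionalityModel([
                ContingencyTable("E", "PT", 1, 1, 1, 1),
                ContingencyTable("S", "SOC", 1, 1, 1, 1)])

    def test_interval_orderings(self, small_planted):
        corpus, target = small_planted["corpus"], small_planted["target"]
        frame = DisproportionalityModel.from_corpus(corpus, target, "PT").fit().frame
        full = frame[frame["a"] > 0]
        assert (full["ror_lo"] <= full["ror"]).all()
        assert (full["ror"] <= full["ror_hi"]).all()
        assert (full["ic025"] <= full["ic"]).all()
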