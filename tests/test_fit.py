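"""Likelihood construction, MLE, intervals and LRT for the PH mortality model."""

import dataclasses

import numpy as np
import pytest

from paleomort import (
    FitOptions,
    GompertzMakehamParams,
    Individual,
    PHParams,
    chisq_upper_tail,
    compare_strata,
    density,
    fit_mle,
    log_likelihood,
    lrt,
    profile_ci,
    wald_ci,
)


class TestLogLikelihood:
    def test_single_individual_value(self, gm_reference):
        ind = Individual(id="a", t=10.0, x=0)
        # ln h(10) - H(10) = ln(0.0235914...) - 0.1859141...; rho irrelevant at x=0
        expected = np.log(0.01 + 0.005 * np.e) - (0.1 + 0.05 * (np.e - 1))
        for rho in (0.0, 0.8, -3.0):
            got = log_likelihood([ind], PHParams(gm_reference, rho=rho))
            assert got == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-3.932787, abs=5e-7)

    def test_iid_sum_scales(self, gm_reference):
        ind = Individual(id="a", t=10.0, x=0)
        p = PHParams(gm_reference, rho=0.3)
        assert log_likelihood([ind, ind], p) == pytest.approx(
            2 * log_likelihood([ind], p), rel=1e-14)

    def test_zero_rho_matches_baseline_for_x1(self, gm_reference):
        i0 = Individual(id="a", t=7.0, x=0)
        i1 = Individual(id="b", t=7.0, x=1)
        p = PHParams(gm_reference, rho=0.0)
        assert log_likelihood([i1], p) == log_likelihood([i0], p)

    def test_matches_log_density_oracle(self, gm_reference, simulate):
        """Brute-force oracle: sum of ln f(t_i | x_i) from the density layer."""
        data = simulate(gm_reference, 0.4, 200, seed=1)
        p = PHParams(gm_reference, rho=0.4)
        oracle = sum(float(np.log(density(gm_reference, d.t, x=d.x, rho=0.4)))
                     for d in data)
        assert log_likelihood(data, p) == pytest.approx(oracle, abs=1e-10 * abs(oracle))

    def test_empty_data_rejected(self, gm_reference):
        with pytest.raises(ValueError, match="nonempty"):
            log_likelihood([], PHParams(gm_reference))


class TestFitMLE:
    def test_parameter_recovery_large_n(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.005, a2=0.02, beta=0.09)
        data = simulate(truth, 0.3, 5000, seed=2)
        fit = fit_mle(data, family="gm", covariate=True, options=fast_options)
        assert fit.converged
        # within ~3 Monte-Carlo standard errors of the generating values
        for name, true_val in [("a1", 0.005), ("a2", 0.02), ("beta", 0.09), ("rho", 0.3)]:
            se = fit.se[name]
            assert abs(fit.parameter_value(name) - true_val) < 3.5 * se, name

    def test_null_rho_unbiased(self, simulate):
        truth = GompertzMakehamParams(a1=0.005, a2=0.015, beta=0.08)
        opts = FitOptions(n_starts=2)
        rhos = []
        for rep in range(60):
            data = simulate(truth, 0.0, 400, seed=100 + rep)
            rhos.append(fit_mle(data, options=opts).params.rho)
        rhos = np.asarray(rhos)
        sem = rhos.std(ddof=1) / np.sqrt(len(rhos))
        assert abs(rhos.mean()) < 3 * sem

    def test_single_covariate_level_rejected(self, gm_reference, simulate):
        data = [Individual(id=str(i), t=float(i + 1), x=0) for i in range(30)]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_mle(data, covariate=True)

    def test_sample_floor(self, gm_reference):
        data = [Individual(id="a", t=5.0, x=0), Individual(id="b", t=9.0, x=1)]
        with pytest.raises(ValueError, match="at least"):
            fit_mle(data)

    def test_determinism(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.004, a2=0.018, beta=0.07)
        data = simulate(truth, 0.2, 400, seed=3)
        f1 = fit_mle(data, options=fast_options)
        f2 = fit_mle(data, options=fast_options)
        assert f1.loglik == f2.loglik
        assert f1.params == f2.params
        assert f1.se == f2.se

    def test_row_order_invariance(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.004, a2=0.018, beta=0.07)
        data = simulate(truth, 0.2, 400, seed=4)
        rng = np.random.default_rng(0)
        shuffled = [data[i] for i in rng.permutation(len(data))]
        f1 = fit_mle(data, options=fast_options)
        f2 = fit_mle(shuffled, options=fast_options)
        assert f1.data_digest == f2.data_digest
        assert f2.params.rho == pytest.approx(f1.params.rho, abs=1e-6)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-7)

    def test_covariate_label_flip_negates_rho(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.004, a2=0.018, beta=0.07)
        data = simulate(truth, 0.5, 800, seed=5)
        flipped = [dataclasses.replace(d, x=1 - d.x) for d in data]
        f1 = fit_mle(data, options=fast_options)
        f2 = fit_mle(flipped, options=fast_options)
        assert f2.params.rho == pytest.approx(-f1.params.rho, abs=1e-4)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)


class TestIntervals:
    def test_wald_standard_normal_quantile(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.005, a2=0.015, beta=0.08)
        data = simulate(truth, 0.0, 600, seed=6)
        fit = fit_mle(data, options=fast_options)
        lo, hi = wald_ci(fit, level=0.95, parameter="rho")
        rho, se = fit.params.rho, fit.se["rho"]
        assert lo == pytest.approx(rho - 1.959964 * se, abs=1e-6)
        assert hi == pytest.approx(rho + 1.959964 * se, abs=1e-6)

    def test_degenerate_level_and_containment(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.005, a2=0.015, beta=0.08)
        data = simulate(truth, 0.3, 600, seed=7)
        fit = fit_mle(data, options=fast_options)
        lo, hi = wald_ci(fit, level=0.0, parameter="rho")
        assert lo == hi == pytest.approx(fit.params.rho)
        for level in (0.5, 0.9, 0.99):
            lo, hi = wald_ci(fit, level=level, parameter="rho")
            assert lo <= fit.params.rho <= hi

    def test_profile_brackets_estimate_and_agrees_with_wald(self, simulate):
        truth = GompertzMakehamParams(a1=0.005, a2=0.015, beta=0.08)
        data = simulate(truth, 0.4, 3000, seed=8)
        opts = FitOptions(n_starts=3)
        fit = fit_mle(data, options=opts)
        plo, phi = profile_ci(data, fit, level=0.95, options=FitOptions(n_starts=1))
        assert plo < fit.params.rho < phi
        wlo, whi = wald_ci(fit, level=0.95, parameter="rho")
        width = whi - wlo
        # asymptotic equivalence at large n
        assert abs(plo - wlo) < 0.1 * width
        assert abs(phi - whi) < 0.1 * width


class TestLRT:
    def test_chisq_upper_tail_values(self):
        assert chisq_upper_tail(0.51, 1) == pytest.approx(0.475139, abs=1e-5)
        assert chisq_upper_tail(0.0, 1) == 1.0
        assert chisq_upper_tail(0.0, 3) == 1.0
        assert chisq_upper_tail(3.841459, 1) == pytest.approx(0.05, abs=1e-6)

    def test_chisq_domain_errors(self):
        with pytest.raises(ValueError):
            chisq_upper_tail(-0.1, 1)
        with pytest.raises(ValueError):
            chisq_upper_tail(1.0, 0)

    def test_lrt_stat_and_p(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.005, a2=0.015, beta=0.08)
        data = simulate(truth, 0.0, 500, seed=9)
        full = fit_mle(data, covariate=True, options=fast_options)
        red = fit_mle(data, covariate=False, options=fast_options)
        res = lrt(full, red)
        assert res.df == 1
        assert res.stat == pytest.approx(2 * (full.loglik - red.loglik), abs=1e-9)
        assert res.p == pytest.approx(chisq_upper_tail(res.stat, 1))
        # identical log-likelihoods -> zero statistic, p = 1
        res0 = lrt(full, dataclasses.replace(red, loglik=full.loglik))
        assert res0.stat == 0.0 and res0.p == 1.0

    def test_makeham_term_comparison_is_nested(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.01, a2=0.01, beta=0.09)
        data = simulate(truth, 0.0, 2000, seed=10)
        gm = fit_mle(data, family="gm", covariate=False, options=fast_options)
        gomp = fit_mle(data, family="gompertz", covariate=False, options=fast_options)
        res = lrt(gm, gomp)
        assert res.df == 1 and res.stat >= 0

    def test_mismatched_data_rejected(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.005, a2=0.015, beta=0.08)
        full = fit_mle(simulate(truth, 0.0, 300, seed=11), options=fast_options)
        red = fit_mle(simulate(truth, 0.0, 300, seed=12), covariate=False,
                      options=fast_options)
        with pytest.raises(ValueError, match="same data"):
            lrt(full, red)

    def test_non_nested_rejected(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.005, a2=0.015, beta=0.08)
        data = simulate(truth, 0.0, 300, seed=13)
        full = fit_mle(data, covariate=True, options=fast_options)
        with pytest.raises(ValueError, match="nested"):
            lrt(full, full)


class TestCompareStrata:
    def test_null_strata_overlap(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.005, a2=0.015, beta=0.08)
        data = (simulate(truth, 0.0, 400, seed=14, period="early")
                + simulate(truth, 0.0, 400, seed=15, period="late"))
        comp = compare_strata(data, options=fast_options)
        assert comp.overlap is True
        assert all(comp.spans_zero.values())
        assert "failing to indicate" in comp.conclusion

    def test_distinct_effects_detected_at_large_n(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.005, a2=0.015, beta=0.08)
        data = (simulate(truth, 0.0, 2000, seed=16, period="early")
                + simulate(truth, 1.5, 2000, seed=17, period="late"))
        comp = compare_strata(data, options=fast_options)
        assert comp.overlap is False
        assert comp.spans_zero["early"] and not comp.spans_zero["late"]

    def test_single_stratum_degenerate(self, simulate, fast_options):
        truth = GompertzMakehamParams(a1=0.005, a2=0.015, beta=0.08)
        data = simulate(truth, 0.0, 300, seed=18, period="early")
        comp = compare_strata(data, options=fast_options)
        assert comp.overlap is None
        assert "late" in comp.skipped
        assert "one stratum" in comp.conclusion.lower()
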