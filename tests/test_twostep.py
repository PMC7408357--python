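"""Levy time scaling, IVIVC fitting, reconvolution, prediction errors."""

import numpy as np
import pandas as pd
import pytest

from ivivckit import (
    AbsorptionProfile,
    DispositionParams,
    IvivcModel,
    LevyMap,
    NcaMetrics,
    WeibullParams,
    build_levy,
    eval_weibull,
    fit_ivivc,
    fit_levy_line,
    nca_metrics,
    predict_fa,
    prediction_errors,
    reconvolve,
    two_compartment_oral_conc,
)

MICRO = dict(kel=0.12, k12=0.35, k21=0.5)


class TestLevy:
    def test_identical_processes_give_diagonal(self):
        w = WeibullParams(100, 1.2, 0.8)
        t = np.linspace(0, 12, 200)
        fa = AbsorptionProfile(t, eval_weibull(w, t) / 100.0)
        pairs = build_levy(fa, w)
        np.testing.assert_allclose(pairs[:, 0], pairs[:, 1], rtol=1e-3)

    def test_three_fold_speedup_gives_slope_three(self):
        w = WeibullParams(100, 1.2, 0.8)
        t = np.linspace(0, 30, 400)
        fa = AbsorptionProfile(t, eval_weibull(w, t / 3.0) / 100.0)
        levy = fit_levy_line(build_levy(fa, w))
        assert levy.m == pytest.approx(3.0, rel=0.01)
        assert levy.n == pytest.approx(0.0, abs=0.05)

    def test_exact_line_through_pairs(self):
        levy = fit_levy_line(np.array([(1.0, 2.0), (2.0, 4.0), (3.0, 6.0)]))
        assert levy.m == pytest.approx(2.0)
        assert levy.n == pytest.approx(0.0, abs=1e-12)
        assert levy.r2 == pytest.approx(1.0)

    def test_noisy_slope_is_unbiased(self, rng):
        x = np.linspace(0.2, 3.0, 9)
        slopes = [
            fit_levy_line(np.column_stack([x, 3.0 * x + rng.normal(0, 0.05, x.size)])).m
            for _ in range(1000)
        ]
        assert np.mean(slopes) == pytest.approx(3.0, rel=0.02)

    def test_empty_grid_rejected(self):
        w = WeibullParams(100, 1.2, 0.8)
        fa = AbsorptionProfile([0, 1, 2], [0, 0.5, 1.0])
        with pytest.raises(ValueError, match="empty"):
            build_levy(fa, w, fraction_grid=[])

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_levy_line(np.array([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)]))


class TestIvivcFit:
    def test_identity_relationship(self):
        x = np.linspace(0.05, 0.95, 10)
        model = fit_ivivc(x, x, "linear")
        assert model.coeffs[0] == pytest.approx(1.0)
        assert model.coeffs[1] == pytest.approx(0.0, abs=1e-12)
        assert model.r2 == pytest.approx(1.0)

    def test_affine_coefficients_recovered(self):
        x = np.linspace(0.0, 1.0, 15)
        y = 0.9 * x + 0.05
        model = fit_ivivc(y, x, "linear")
        assert model.coeffs[0] == pytest.approx(0.9, abs=1e-6)
        assert model.coeffs[1] == pytest.approx(0.05, abs=1e-6)

    def test_quadratic_needs_degree_two(self):
        x = np.linspace(0.1, 1.0, 12)
        quad = fit_ivivc(x**2, x, "polynomial", degree=2)
        lin = fit_ivivc(x**2, x, "linear")
        assert quad.r2 == pytest.approx(1.0)
        assert lin.r2 < 1.0

    def test_excessive_degree_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            fit_ivivc([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], "polynomial", degree=3)


class TestPredictFa:
    def test_identity_model_reproduces_weibull(self):
        w = WeibullParams(100, 1.2, 0.8)
        model = IvivcModel("linear", 1, [0.01, 0.0], 1.0)  # % -> fraction
        levy = LevyMap(1.0, 0.0)
        t = np.linspace(0, 10, 50)
        fa = predict_fa(model, levy, w, t)
        np.testing.assert_allclose(fa.fa, eval_weibull(w, t) / 100.0, rtol=1e-9)

    def test_times_before_intercept_see_zero_dissolution(self):
        w = WeibullParams(100, 1.2, 0.8)
        model = IvivcModel("linear", 1, [0.01, 0.0], 1.0)
        levy = LevyMap(2.0, 1.0)
        fa = predict_fa(model, levy, w, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(fa.fa, 0.0, atol=1e-12)

    def test_output_is_nondecreasing(self):
        w = WeibullParams(100, 1.2, 0.8)
        model = IvivcModel("polynomial", 2, [-1.5, 2.0, -0.05], 0.9)
        fa = predict_fa(model, LevyMap(1.5, 0.2), w, np.linspace(0, 24, 60))
        assert (np.diff(fa.fa) >= 0).all()


class TestReconvolve:
    def test_zero_absorption_gives_zero_concentration(self):
        fa = AbsorptionProfile(np.linspace(0, 24, 25), np.zeros(25))
        cp = reconvolve(fa, DispositionParams(**MICRO), scale=0.3)
        np.testing.assert_allclose(cp.conc, 0.0, atol=1e-12)

    def test_first_order_input_matches_closed_form(self):
        ka = 1.0
        t = np.linspace(0, 48, 481)
        fa = AbsorptionProfile(t, 1.0 - np.exp(-ka * t))
        d = DispositionParams(**MICRO)
        cp = reconvolve(fa, d, scale=0.3)
        ref = two_compartment_oral_conc(t, ka, scale=0.3, **MICRO)
        assert np.max(np.abs(cp.conc - ref)) / ref.max() < 0.01

    def test_deconvolve_then_reconvolve_is_identity(self, be_dataset):
        from ivivckit import loo_riegelman
        from ivivckit.deconvolution import auc_infinity

        profile = be_dataset.study1["Reference"]
        d = be_dataset.disposition
        auc_inf = auc_infinity(profile, d)
        fa = loo_riegelman(profile, d, auc_inf=auc_inf)
        cp = reconvolve(fa, d, scale=d.kel * auc_inf, times=profile.times)
        rmse = np.sqrt(np.mean((cp.conc - profile.conc) ** 2)) / profile.conc.max()
        assert rmse < 0.02


class TestPredictionErrors:
    def test_reported_error_arithmetic(self):
        # printed experimental/predicted AUC pairs with their recomputed PE%
        cases = [
            (3.303, 3.468, 5.00),  # linear correlation, slowest product
            (3.303, 3.505, 6.12),  # polynomial correlation, same product
            (3.303, 3.138, 5.00),  # one-step time-scaled model
            (3.508, 3.226, 8.04),
        ]
        for exp, pred, pe in cases:
            rep = prediction_errors(
                {"X": NcaMetrics(1.0, 1.0, exp)}, {"X": NcaMetrics(1.0, 1.0, pred)}
            )
            auc_pe = rep.table.loc[rep.table.parameter == "AUC0-tlast", "pe_pct"].item()
            assert round(auc_pe, 2) == pe

    def test_perfect_prediction_is_valid(self):
        m = NcaMetrics(0.2, 2.0, 3.5)
        rep = prediction_errors({"X": m}, {"X": m})
        assert (rep.table.pe_pct == 0).all()
        assert rep.verdict

    def test_verdict_monotone_in_errors(self):
        exp = {"A": NcaMetrics(0.2, 2.0, 3.5), "B": NcaMetrics(0.21, 2.0, 3.6)}
        # one AUC off by 20% -> individual limit (15%) breached, verdict False
        bad = {"A": NcaMetrics(0.2, 2.0, 3.5), "B": NcaMetrics(0.21, 2.0, 3.6 * 1.2)}
        rep_bad = prediction_errors(exp, bad)
        assert not rep_bad.verdict
        # worsening a further prediction can never flip the verdict back to True
        worse = {"A": NcaMetrics(0.2, 2.0, 3.5 * 0.7), "B": NcaMetrics(0.21, 2.0, 3.6 * 1.2)}
        rep_worse = prediction_errors(exp, worse)
        assert (rep_worse.table.pe_pct >= rep_bad.table.pe_pct - 1e-12).all()
        assert not rep_worse.verdict

    def test_zero_experimental_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            prediction_errors(
                {"X": NcaMetrics(0.0, 1.0, 1.0)}, {"X": NcaMetrics(0.1, 1.0, 1.0)}
            )


class TestEndToEnd:
    def test_pipeline_recovers_construction(self, be_dataset, twostep_result):
        res = twostep_result
        m_true, n_true = be_dataset.levy
        assert abs(res.levy.m - m_true) / m_true < 0.02
        assert res.models["linear"].r2 > 0.99
        for rep in res.reports.values():
            assert (rep.table.pe_pct < 1.0).all()
            assert rep.verdict
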