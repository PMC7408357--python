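"""One-step ODE models: ESC coefficient, besc scaling, simulation, joint fit."""

import numpy as np
import pytest

from ivivckit import (
    DissolutionProfile,
    OneStepModel1Params,
    OneStepModel2Params,
    PlasmaProfile,
    WeibullParams,
    besc_transform,
    esc_eval,
    fit_onestep,
    simulate_model1,
    simulate_model2,
    two_compartment_oral_conc,
)
from ivivckit.synthetic import DISSOLUTION_SCHEDULE_MIN, PLASMA_SCHEDULE_48H

MICRO = dict(kel=0.12, k12=0.35, k21=0.5)


class TestEsc:
    def test_branch_arithmetic(self):
        segs = ((1.0, 0.2), (0, 0), (0, 0), (0, 0), (0, 0))
        assert esc_eval(segs, 0.3) == pytest.approx(0.5)

    def test_breakpoints_are_left_closed(self):
        segs = ((1.0, 0.0), (2.0, 0.0), (3.0, 0.0), (4.0, 0.0), (5.0, 0.0))
        assert esc_eval(segs, 0.5) == pytest.approx(0.5)  # branch 1 at t = 0.5
        assert esc_eval(segs, 0.5 + 1e-9) == pytest.approx(2 * (0.5 + 1e-9))
        assert esc_eval(segs, 2.0) == pytest.approx(4.0)  # branch 2 at t = 2
        assert esc_eval(segs, 4.5) == pytest.approx(13.5)  # branch 3 at t = 4.5
        assert esc_eval(segs, 10.0) == pytest.approx(40.0)  # branch 4 at t = 10
        assert esc_eval(segs, 10.0 + 1e-9) == pytest.approx(5 * 10.0, rel=1e-6)

    def test_constant_segments_reduce_to_first_order(self):
        segs = ((0.0, 0.7),) * 5
        t = np.linspace(0, 20, 50)
        np.testing.assert_allclose(esc_eval(segs, t), 0.7)


class TestBesc:
    def test_identity_map_leaves_b(self):
        assert besc_transform(1.3, 0.8, 1.0, 0.0) == pytest.approx(0.8)

    def test_closed_form_value(self):
        assert besc_transform(2.0, 4.0, 2.0, 1.0) == pytest.approx(25.0)

    def test_characteristic_time_maps_through_levy(self):
        # the 63.2% time under besc equals the Levy image of the one under b
        a, b, m, n = 1.4, 0.9, 1.6, 0.25
        besc = besc_transform(a, b, m, n)
        t63_vitro = b ** (1 / a)
        t63_vivo = besc ** (1 / a)
        assert t63_vivo == pytest.approx(m * t63_vitro + n)

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            besc_transform(1.0, 0.5, 1.0, -1.0)


class TestSimulateModel1:
    def test_zero_scale_decouples_plasma(self):
        p = OneStepModel1Params(WeibullParams(80, 1.2, 1.0), 1.6, 0.25, s_scale=0.0, **MICRO)
        t = np.linspace(0, 24, 49)
        fdiss, cp = simulate_model1(p, t)
        np.testing.assert_allclose(cp, 0.0, atol=1e-12)
        np.testing.assert_allclose(fdiss, 80 * (1 - np.exp(-(t**1.2) / 1.0)))

    def test_first_order_limit_matches_closed_form(self):
        # a = 1, m = 1, n = 0: Weibull-rate input is first order with ka = 1/b
        b = 1.0
        p = OneStepModel1Params(WeibullParams(80, 1.0, b), 1.0, 0.0, s_scale=0.3, **MICRO)
        t = np.linspace(0.01, 48, 300)
        _, cp = simulate_model1(p, t)
        ref = two_compartment_oral_conc(t, 1.0 / b, scale=0.3 * 0.8, **MICRO)
        assert np.max(np.abs(cp - ref)) / ref.max() < 0.005

    def test_mass_balance_without_elimination(self):
        # kel = 0: central + peripheral must equal the cumulative input
        from scipy.integrate import solve_ivp

        w = WeibullParams(80, 1.2, 1.0)
        m, n, s = 1.6, 0.25, 0.3

        def rhs(tt, y):
            c, q = y
            tesc = m * tt + n
            rate = (
                s * w.a * (w.fmax / 100.0) * tesc ** (w.a - 1) * np.exp(-(tesc**w.a) / w.b) / w.b
                if tesc > 0 else 0.0
            )
            return [rate - 0.35 * c + 0.5 * q, 0.35 * c - 0.5 * q]

        t = np.linspace(0, 24, 100)
        sol = solve_ivp(rhs, (0, 24), [0, 0], t_eval=t, rtol=1e-10, atol=1e-12, max_step=0.25)
        total = sol.y[0] + sol.y[1]
        tesc = m * t + n
        cum_input = (s / m) * (w.fmax / 100.0) * (
            np.exp(-(n**w.a) / w.b) - np.exp(-(tesc**w.a) / w.b)
        )
        np.testing.assert_allclose(total, cum_input, atol=1e-6)


class TestSimulateModel2:
    def test_zero_esc_gives_zero_plasma(self):
        p = OneStepModel2Params(
            WeibullParams(80, 1.2, 0.3), 0.8, ((0.0, 0.0),) * 5, s_scale=1.0, **MICRO
        )
        _, cp = simulate_model2(p, np.linspace(0, 24, 49))
        np.testing.assert_allclose(cp, 0.0, atol=1e-12)

    def test_constant_esc_steady_state_limit(self):
        # kel-only disposition, constant ESC c: late Cp -> c * plateau / kel
        c_esc, kel, s = 0.4, 0.1, 1.0
        p = OneStepModel2Params(
            WeibullParams(80, 1.2, 0.3), 0.3, ((0.0, c_esc),) * 5,
            kel=kel, k12=0.0, k21=0.3, s_scale=s,
        )
        t = np.linspace(0, 300, 400)
        _, cp = simulate_model2(p, t)
        assert cp[-1] == pytest.approx(c_esc * s * 0.8 / kel, rel=1e-3)

    def test_continuous_across_breakpoints(self):
        segs = ((0.5, 0.1), (-0.2, 0.9), (0.1, 0.0), (0.0, 0.5), (-0.01, 0.6))
        p = OneStepModel2Params(
            WeibullParams(80, 1.2, 0.3), 0.9, segs, s_scale=0.3, **MICRO
        )
        # a genuine jump would keep |C(bp+eps) - C(bp-eps)| bounded away from
        # zero as eps shrinks; a continuous solution scales linearly with eps
        for bp in (0.5, 2.0, 4.5, 10.0):
            gaps = []
            for eps in (1e-3, 1e-4):
                t = np.array([0.0, bp - eps, bp + eps])
                _, cp = simulate_model2(p, t)
                gaps.append(abs(cp[2] - cp[1]))
            assert gaps[1] < gaps[0] / 5.0


WEIBULLS = {"Reference": (1.2, 1.0, 80.0), "ProductA": (1.2, 1.45, 80.0)}
TRUE_SHARED = dict(m=1.6, n=0.25, s_scale=0.3, **MICRO)


def _model1_dataset():
    tv = np.asarray(DISSOLUTION_SCHEDULE_MIN, float)
    tp = np.asarray(PLASMA_SCHEDULE_48H, float)
    diss, plasma = {}, {}
    for prod, (a, b, fmax) in WEIBULLS.items():
        pars = OneStepModel1Params(WeibullParams(fmax, a, b), **TRUE_SHARED)
        fd, cp = simulate_model1(pars, tp, times_vitro=tv / 60.0)
        diss[prod] = DissolutionProfile(prod, "USP4", "sim", tv, fd)
        plasma[prod] = PlasmaProfile(prod, "sim", tp, cp)
    return diss, plasma


class TestFitOneStep:
    def test_self_consistent_recovery_model1(self):
        diss, plasma = _model1_dataset()
        init = {
            "kel": 0.12 * 1.3, "k12": 0.35 / 1.3, "k21": 0.5 * 1.2,
            "m": 1.6 * 0.8, "n": 0.25 * 1.5, "s_scale": 0.3 * 1.2,
            "weibull": {
                p: {"a": a * 1.1, "b": b * 0.8, "fmax": fmax * 1.05}
                for p, (a, b, fmax) in WEIBULLS.items()
            },
        }
        res = fit_onestep(1, diss, plasma, init)
        ref = res.params["Reference"]
        for got, want in [
            (ref.kel, 0.12), (ref.k12, 0.35), (ref.k21, 0.5),
            (ref.m, 1.6), (ref.n, 0.25), (ref.s_scale, 0.3),
            (ref.w.a, 1.2), (ref.w.b, 1.0), (ref.w.fmax, 80.0),
        ]:
            assert got == pytest.approx(want, rel=0.05)
        assert (res.report.table.pe_pct < 1.0).all()

    def test_perturbed_starts_converge(self, rng):
        diss, plasma = _model1_dataset()
        hits = 0
        for _ in range(5):
            factors = np.exp(rng.uniform(-np.log(2.0), np.log(2.0), size=6))
            init = {
                "kel": 0.12 * factors[0], "k12": 0.35 * factors[1],
                "k21": 0.5 * factors[2], "m": 1.6 * factors[3],
                "n": 0.25 * factors[4], "s_scale": 0.3 * factors[5],
                "weibull": {
                    p: {"a": a, "b": b, "fmax": fmax}
                    for p, (a, b, fmax) in WEIBULLS.items()
                },
            }
            try:
                res = fit_onestep(1, diss, plasma, init)
            except RuntimeError:
                continue
            if abs(res.params["Reference"].kel - 0.12) / 0.12 < 0.05:
                hits += 1
        assert hits >= 4

    def test_model2_zero_residual_at_truth(self):
        # self-consistency: initializing at the generating parameters keeps
        # the optimizer at (essentially) zero joint residual
        tv = np.asarray(DISSOLUTION_SCHEDULE_MIN, float)
        tp = np.asarray(PLASMA_SCHEDULE_48H, float)
        segs = ((0.0, 0.6), (0.1, 0.55), (0.0, 0.75), (-0.02, 0.84), (0.0, 0.64))
        besc = besc_transform(1.2, 1.0, 1.6, 0.25)
        diss, plasma = {}, {}
        for prod in ("Reference",):
            pars = OneStepModel2Params(
                WeibullParams(80, 1.2, 1.0), besc, segs, s_scale=0.3, **MICRO
            )
            fd, cp = simulate_model2(pars, tp, times_vitro=tv / 60.0)
            diss[prod] = DissolutionProfile(prod, "USP4", "sim", tv, fd)
            plasma[prod] = PlasmaProfile(prod, "sim", tp, cp)
        init = {"kel": 0.12, "k12": 0.35, "k21": 0.5, "m": 1.6, "n": 0.25,
                "s_scale": 0.3,
                "weibull": {"Reference": {"a": 1.2, "b": 1.0, "fmax": 80.0}}}
        res = fit_onestep(2, diss, plasma, init, esc_init=segs)
        assert res.residual < 1e-10
        assert (res.report.table.pe_pct < 0.1).all()

    def test_dissolution_block_alone_reproduces_weibull_fit(self):
        # withholding the plasma block: the dissolution residuals dominate and
        # the fitted Weibull matches the standalone nonlinear fit
        from ivivckit import fit_weibull

        diss, plasma = _model1_dataset()
        standalone = fit_weibull(diss["Reference"]).params
        assert standalone.a == pytest.approx(1.2, rel=1e-3)
        assert standalone.b == pytest.approx(1.0, rel=1e-3)
        assert standalone.fmax == pytest.approx(80.0, rel=1e-3)
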