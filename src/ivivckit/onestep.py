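"""One-step IVIVC: ODE models fitted simultaneously to dissolution and
plasma data.

Model 1 drives a two-compartment disposition system with the Weibull
dissolution rate evaluated at the Levy-scaled time t_esc = m*t + n (in vivo
dissolution is the in vitro process played on a stretched clock).  Model 2
instead time-scales the Weibull scale parameter itself
(b_esc = (n + m*b^(1/a))^a) and converts the cumulative dissolved amount to
an absorption rate through a piecewise-linear, time-varying coefficient
ESC(t) with fixed breakpoints at 0.5, 2, 4.5 and 10 h.  The equations are
written in amounts with no explicit volume; a lumped concentration scale
``s_scale`` (~ F*Dose/Vc) lets the models fit concentration data directly.
Note that Model 2's dissolved amount is cumulative and is not depleted by
absorption; a mass-conserving variant that depletes the dissolved pool is
available behind ``deplete=True`` for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy.integrate import solve_ivp

from .profiles import DissolutionProfile, PlasmaProfile, nca_metrics
from .twostep import PredictionErrorReport, prediction_errors
from .weibull import WeibullParams, fit_weibull

logger = logging.getLogger(__name__)

#: fixed breakpoints (h) of the piecewise-linear ESC coefficient
ESC_BREAKPOINTS = (0.5, 2.0, 4.5, 10.0)


@dataclass(frozen=True)
class OneStepModel1Params:
    """Weibull dissolution + Levy time map + two-compartment disposition."""

    w: WeibullParams
    m: float
    n: float
    kel: float
    k12: float
    k21: float
    s_scale: float  # concentration scale (~ F*Dose/Vc)

    def __post_init__(self):
        if min(self.kel, self.k21, self.m) <= 0 or self.k12 < 0:
            raise ValueError("rates must be positive (k12 >= 0) and m > 0")


@dataclass(frozen=True)
class OneStepModel2Params:
    """Weibull with in-vivo-scaled b_esc and piecewise-linear ESC coefficient.

    ``esc_segments`` holds five (u_i, v_i) pairs; segment i applies on the
    printed interval with left-closed membership at each breakpoint.
    """

    w: WeibullParams  # b here is the in vitro scale; besc is separate
    besc: float
    esc_segments: tuple  # ((u1, v1), ..., (u5, v5))
    kel: float
    k12: float
    k21: float
    s_scale: float

    def __post_init__(self):
        if self.besc <= 0:
            raise ValueError("besc must be positive")
        if len(self.esc_segments) != 5:
            raise ValueError("ESC needs exactly five (u, v) segments")


def esc_eval(segments, t):
    """Piecewise-linear ESC(t) (1/h) with breakpoints 0.5, 2, 4.5, 10 h.

    Branch membership is left-closed exactly as the piecewise definition
    reads: t <= 0.5 uses segment 1, 0.5 < t <= 2 segment 2, and so on.
    """
    t_arr = np.asarray(t, dtype=float)
    idx = np.searchsorted(ESC_BREAKPOINTS, t_arr, side="left")
    u = np.asarray([s[0] for s in segments], dtype=float)
    v = np.asarray([s[1] for s in segments], dtype=float)
    out = u[idx] * t_arr + v[idx]
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def besc_transform(a: float, b: float, m: float, n: float) -> float:
    """Scale the in vitro Weibull b into the in vivo frame:
    b_esc = (n + m * b^(1/a))^a."""
    base = n + m * b ** (1.0 / a)
    if base <= 0:
        raise ValueError("non-positive base: n + m * b^(1/a) must exceed 0")
    return float(base**a)


def _weibull_rate_at(a, b, fmax, t):
    """Release rate a*Fmax*t^(a-1)*exp(-t^a/b)/b, zero for t <= 0."""
    if t <= 0:
        return 0.0 if a >= 1 else 0.0
    return a * fmax * t ** (a - 1.0) * np.exp(-(t**a) / b) / b


def simulate_model1(p: OneStepModel1Params, times, *, times_vitro=None):
    """Simulate Model 1: (in vitro % dissolved, plasma concentrations).

    The dissolution curve is reported against in vitro time (``times_vitro``
    defaults to ``times``); the central/peripheral amounts are driven by the
    Weibull rate evaluated at t_esc = m*t + n, weighted by s_scale.
    """
    t = np.asarray(times, dtype=float)
    tv = t if times_vitro is None else np.asarray(times_vitro, dtype=float)
    w = p.w
    fdiss = w.fmax * (1.0 - np.exp(-(np.maximum(tv, 0.0) ** w.a) / w.b))

    def rhs(tt, y):
        c, q = y
        tesc = p.m * tt + p.n
        rate = p.s_scale * _weibull_rate_at(w.a, w.b, w.fmax / 100.0, tesc)
        return [rate - p.kel * c - p.k12 * c + p.k21 * q, p.k12 * c - p.k21 * q]

    sol = solve_ivp(rhs, (0.0, float(t[-1])), [0.0, 0.0], t_eval=t,
                    method="LSODA", rtol=1e-8, atol=1e-10, max_step=0.25)
    if not sol.success:
        raise RuntimeError(f"Model 1 integration failed ({sol.message}); params={p}")
    return fdiss, np.maximum(sol.y[0], 0.0)


def simulate_model2(p: OneStepModel2Params, times, *, times_vitro=None, deplete=False):
    """Simulate Model 2: (in vitro % dissolved, plasma concentrations).

    The in vivo dissolved amount follows the Weibull curve with scale
    ``besc``; the absorption input into the central compartment is
    ESC(t) * Q_dissESC(t).  By default the dissolved amount is cumulative
    (not reduced by absorption), as the model is defined; ``deplete=True``
    subtracts the absorbed amount for a mass-conserving variant.
    """
    t = np.asarray(times, dtype=float)
    tv = t if times_vitro is None else np.asarray(times_vitro, dtype=float)
    w = p.w
    fdiss = w.fmax * (1.0 - np.exp(-(np.maximum(tv, 0.0) ** w.a) / w.b))
    seg = p.esc_segments

    def rhs(tt, y):
        qdiss, c, q = y
        dqdiss = p.s_scale * _weibull_rate_at(w.a, p.besc, w.fmax / 100.0, tt)
        inp = esc_eval(seg, tt) * qdiss
        ddiss = dqdiss - inp if deplete else dqdiss
        return [ddiss, inp - p.kel * c - p.k12 * c + p.k21 * q, p.k12 * c - p.k21 * q]

    sol = solve_ivp(rhs, (0.0, float(t[-1])), [0.0, 0.0, 0.0], t_eval=t,
                    method="LSODA", rtol=1e-8, atol=1e-10, max_step=0.25)
    if not sol.success:
        raise RuntimeError(f"Model 2 integration failed ({sol.message}); params={p}")
    return fdiss, np.maximum(sol.y[1], 0.0)


class OneStepFitError(RuntimeError):
    """Raised when the joint fit fails; carries ``best_params`` and
    ``residual_trace`` for post-mortem inspection."""


@dataclass
class OneStepFitResult:
    params: dict  # per-product OneStepModel1Params / OneStepModel2Params
    report: PredictionErrorReport
    residual: float
    lmfit_result: object = field(repr=False, default=None)


def _pack_model1(shared: dict, per: dict, product: str) -> OneStepModel1Params:
    return OneStepModel1Params(
        WeibullParams(per[f"fmax_{product}"], per[f"a_{product}"], per[f"b_{product}"]),
        shared["m"], shared["n"], shared["kel"], shared["k12"], shared["k21"],
        shared["s_scale"],
    )


def fit_onestep(
    model: int,
    dissolution: dict[str, DissolutionProfile],
    plasma: dict[str, PlasmaProfile],
    init,
    *,
    esc_init=None,
    max_nfev: int = 2000,
) -> OneStepFitResult:
    """Joint weighted least squares on the dissolution and plasma blocks.

    Per-product Weibull parameters, shared disposition (kel, k12, k21),
    shared time-scale parameters — (m, n) for Model 1; (besc-generating
    m, n plus the five ESC segments) for Model 2 — and one shared
    concentration scale.  Each data block is normalized by its observed
    maximum so dissolution % and plasma concentrations weigh comparably.

    ``init`` supplies starting values from the two-step stage as a dict with
    keys ``kel, k12, k21, m, n, s_scale`` plus per-product
    ``(a, b, fmax)`` under ``weibull[product]``.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    products = sorted(plasma)
    if sorted(dissolution) != products:
        raise ValueError("dissolution and plasma product sets differ")

    pars = lmfit.Parameters()
    for key, lo in (("kel", 1e-4), ("k12", 0.0), ("k21", 1e-4),
                    ("m", 1e-3), ("s_scale", 1e-9)):
        pars.add(key, value=float(init[key]), min=lo)
    pars.add("n", value=float(init["n"]))
    for prod in products:
        a, b, fmax = (init["weibull"][prod][k] for k in ("a", "b", "fmax"))
        pars.add(f"a_{prod}", value=float(a), min=0.05, max=10.0)
        pars.add(f"b_{prod}", value=float(b), min=1e-9)
        pars.add(f"fmax_{prod}", value=float(fmax), min=1e-6, max=120.0)
    if model == 2:
        segs = esc_init if esc_init is not None else ((0.0, 1.0),) * 5
        for i, (u, v) in enumerate(segs, start=1):
            pars.add(f"u{i}", value=float(u))
            pars.add(f"v{i}", value=float(v))

    diss_norm = {p: float(dissolution[p].fdiss.max()) for p in products}
    plasma_norm = {p: float(plasma[p].conc.max()) for p in products}
    trace: list[float] = []

    def residual(parameters):
        v = parameters.valuesdict()
        out = []
        for prod in products:
            w = WeibullParams(v[f"fmax_{prod}"], v[f"a_{prod}"], v[f"b_{prod}"])
            t_vitro = dissolution[prod].times_h
            t_vivo = plasma[prod].times
            if model == 1:
                params = OneStepModel1Params(w, v["m"], v["n"], v["kel"], v["k12"],
                                             v["k21"], v["s_scale"])
                fdiss, cp = simulate_model1(params, t_vivo, times_vitro=t_vitro)
            else:
                besc = besc_transform(w.a, w.b, v["m"], v["n"])
                segs = tuple((v[f"u{i}"], v[f"v{i}"]) for i in range(1, 6))
                params = OneStepModel2Params(w, besc, segs, v["kel"], v["k12"],
                                             v["k21"], v["s_scale"])
                fdiss, cp = simulate_model2(params, t_vivo, times_vitro=t_vitro)
            out.append((fdiss - dissolution[prod].fdiss) / diss_norm[prod])
            out.append((cp - plasma[prod].conc) / plasma_norm[prod])
        r = np.concatenate(out)
        trace.append(float(r @ r))
        return r

    result = lmfit.minimize(residual, pars, method="least_squares", max_nfev=max_nfev)
    if not result.success:
        err = OneStepFitError(
            f"one-step fit did not converge (best residual {result.chisqr:.4g})"
        )
        err.best_params = result.params.valuesdict()
        err.residual_trace = trace
        raise err
    v = result.params.valuesdict()
    fitted, pred_metrics, exp_metrics = {}, {}, {}
    for prod in products:
        w = WeibullParams(v[f"fmax_{prod}"], v[f"a_{prod}"], v[f"b_{prod}"])
        if model == 1:
            params = OneStepModel1Params(w, v["m"], v["n"], v["kel"], v["k12"],
                                         v["k21"], v["s_scale"])
            _, cp = simulate_model1(params, plasma[prod].times)
        else:
            besc = besc_transform(w.a, w.b, v["m"], v["n"])
            segs = tuple((v[f"u{i}"], v[f"v{i}"]) for i in range(1, 6))
            params = OneStepModel2Params(w, besc, segs, v["kel"], v["k12"],
                                         v["k21"], v["s_scale"])
            _, cp = simulate_model2(params, plasma[prod].times)
        fitted[prod] = params
        pred = PlasmaProfile(prod, "onestep-pred", plasma[prod].times, cp)
        pred_metrics[prod] = nca_metrics(pred)
        exp_metrics[prod] = nca_metrics(plasma[prod])
    report = prediction_errors(exp_metrics, pred_metrics)
    logger.info("one-step fit: residual trace length %d, final %.4g", len(trace),
                trace[-1] if trace else float("nan"))
    return OneStepFitResult(fitted, report, float(result.chisqr), result)


def init_from_twostep(twostep_result, s_scale: float | None = None) -> dict:
    """Build a one-step starting-value dict from a two-step pipeline result."""
    dispo = twostep_result.dispositions
    kel = float(np.mean([d.kel for d in dispo.values()]))
    k12 = float(np.mean([d.k12 for d in dispo.values()]))
    k21 = float(np.mean([d.k21 for d in dispo.values()]))
    if s_scale is None:
        metrics = {p: nca_metrics(prof, kel=dispo[p].kel)
                   for p, prof in twostep_result.plasma.items()}
        s_scale = float(np.mean([dispo[p].kel * m.auc_inf for p, m in metrics.items()]))
    return {
        "kel": kel, "k12": k12, "k21": k21,
        "m": twostep_result.levy.m, "n": twostep_result.levy.n,
        "s_scale": s_scale,
        "weibull": {
            p: {"a": w.a, "b": w.b, "fmax": w.fmax}
            for p, w in twostep_result.weibull.items()
        },
    }
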