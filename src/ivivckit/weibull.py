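"""Weibull modelling of dissolution profiles.

Cumulative release follows F(t) = Fmax * (1 - exp(-t^a / b)) with shape a
and scale b; a = 1 reduces to first-order release.  The fitted model,
inverted analytically (the inverse release function, IRF), gives the time at
which any fraction is dissolved — the ingredient needed for Levy-plot time
scaling.  All fitting happens in hours (the in vivo frame); dissolution
minutes are converted on ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import lmfit
import numpy as np

from .profiles import DissolutionProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeibullParams:
    """Weibull release parameters: plateau % ``fmax``, shape ``a``, scale ``b``.

    ``b`` carries units of h^a.
    """

    fmax: float
    a: float
    b: float

    def __post_init__(self):
        if not (self.fmax > 0 and self.a > 0 and self.b > 0):
            raise ValueError("fmax, a and b must all be positive")


@dataclass(frozen=True)
class WeibullFit:
    params: WeibullParams
    r2: float
    residual: float  # sum of squared residuals


def eval_weibull(w: WeibullParams, t) -> np.ndarray | float:
    """Cumulative % dissolved at time t (h): Fmax * (1 - exp(-t^a/b))."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = w.fmax * (1.0 - np.exp(-(t_arr**w.a) / w.b))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def weibull_rate(w: WeibullParams, t) -> np.ndarray | float:
    """Instantaneous release rate dF/dt = a * Fmax * t^(a-1) * exp(-t^a/b) / b."""
    t_arr = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(
            t_arr > 0,
            w.a * w.fmax * t_arr ** (w.a - 1.0) * np.exp(-(t_arr**w.a) / w.b) / w.b,
            w.a * w.fmax / w.b if w.a == 1 else (np.inf if w.a < 1 else 0.0),
        )
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def invert_weibull(w: WeibullParams, f) -> np.ndarray | float:
    """Inverse release function: time (h) at which F(t) = f (%).

    t = (-b * ln(1 - f/Fmax))^(1/a), defined for 0 <= f < Fmax.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0) or np.any(f_arr >= w.fmax):
        raise ValueError(f"fraction unreachable: need 0 <= f < Fmax ({w.fmax:g})")
    out = (-w.b * np.log1p(-f_arr / w.fmax)) ** (1.0 / w.a)
    return float(out) if np.isscalar(f) or f_arr.ndim == 0 else out


def plateau_estimate(p: DissolutionProfile, method: str = "weibull", n_last: int = 2) -> float:
    """Final-plateau estimate for one dissolution profile.

    ``method='weibull'`` (default) uses the fitted Weibull asymptote Fmax,
    which stays unbiased when the profile is still rising at the last
    sampling time; ``method='last_points'`` uses the mean of the last
    ``n_last`` observed mean values.
    """
    if method == "weibull":
        return fit_weibull_xy(p.times_h, p.fdiss).params.fmax
    if method == "last_points":
        return float(np.mean(p.fdiss[-n_last:]))
    raise ValueError("method must be 'weibull' or 'last_points'")


def scale_to_reference_max(profiles, method: str = "weibull", n_last: int = 2):
    """Magnitude-scale dissolution profiles so the highest plateau reads 100%.

    The largest plateau across products is assumed to represent complete
    release; every profile is multiplied by 100/M where M is that plateau.
    Returns ``(scaled_profiles, factor)``; rank order is preserved.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    m = max(plateau_estimate(p, method, n_last) for p in profiles)
    if m <= 0:
        raise ValueError("largest plateau is non-positive; cannot scale")
    factor = 100.0 / m
    logger.info("magnitude scaling: max plateau %.3f%% -> factor %.4f", m, factor)
    return [p.scaled(factor) for p in profiles], factor


def fit_weibull_xy(times_h, fdiss) -> WeibullFit:
    """Nonlinear least squares of F(t) = Fmax(1 - exp(-t^a/b)) on (t, %) data.

    Multistart over shape a in {0.5, 1, 2}; for each, b is seeded from the
    observed time to half-plateau (t50^a / ln 2) and Fmax from the largest
    observation.  Bounds: a in (0.05, 10), b > 0, Fmax in (0, 120].
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(fdiss, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points to fit a Weibull model")
    if not np.any(y > 0):
        raise ValueError("no release signal: profile is identically zero")
    fmax0 = float(y.max())
    pos = t[y >= fmax0 / 2.0]
    t50 = float(pos[0]) if pos.size else float(t[t > 0][0])
    t50 = max(t50, 1e-3)

    def model(pars):
        v = pars.valuesdict()
        return v["fmax"] * (1.0 - np.exp(-(t ** v["a"]) / v["b"]))

    best = None
    for a0 in (0.5, 1.0, 2.0):
        pars = lmfit.Parameters()
        pars.add("fmax", value=fmax0, min=1e-6, max=120.0)
        pars.add("a", value=a0, min=0.05, max=10.0)
        pars.add("b", value=max(t50**a0 / np.log(2.0), 1e-6), min=1e-9)
        try:
            res = lmfit.minimize(lambda p: model(p) - y, pars, method="leastsq")
        except Exception:  # singular start; try the next one
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None or not np.isfinite(best.chisqr):
        raise RuntimeError("Weibull fit failed to converge from all starts")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best.chisqr / ss_tot if ss_tot > 0 else 1.0
    v = best.params.valuesdict()
    return WeibullFit(WeibullParams(v["fmax"], v["a"], v["b"]), float(r2), float(best.chisqr))


def fit_weibull(p: DissolutionProfile) -> WeibullFit:
    """Fit the Weibull release model to a dissolution profile's mean curve.

    Times are converted from minutes to hours first, so the fitted scale b
    is in h^a.
    """
    return fit_weibull_xy(p.times_h, p.fdiss)
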