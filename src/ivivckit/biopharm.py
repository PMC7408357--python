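"""Biopharmaceutic classification support: dose number, f2 similarity factor
and the closed-loop intestinal perfusion (Doluisio) calculations.

The dose number Do = dose / (250 mL x solubility) flags low-solubility
behavior (Do > 1) over the physiological pH range.  The Doluisio technique
estimates an apparent first-order absorption rate constant from the decline
of luminal concentrations in an in-situ perfused intestinal segment, and
converts it to an apparent permeability through the segment's
surface-to-volume ratio.  The f2 factor compares two dissolution profiles:
f2 >= 50 declares similarity (average difference below ~10%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .profiles import DissolutionProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DoseNumberResult:
    do: float
    low_solubility: bool  # Do > 1 at this pH


@dataclass(frozen=True)
class DoluisioResult:
    c0: float  # extrapolated luminal concentration at t=0 (ug/mL)
    kapp: float  # apparent first-order absorption rate constant (1/min)
    r2: float
    papp: float | None = None  # cm/s, set once a radius is supplied
    radius: float | None = None  # cm


@dataclass(frozen=True)
class F2Result:
    f2: float
    n_points: int
    variant: str
    similar: bool  # f2 >= 50


def dose_number(dose: float, solubility: float, volume: float = 250.0) -> DoseNumberResult:
    """Dose number Do = dose / (volume x solubility), dimensionless.

    Parameters are mg, mg/mL and mL (default glass-of-water volume 250 mL).
    """
    if dose <= 0 or volume <= 0:
        raise ValueError("dose and volume must be positive")
    if solubility <= 0:
        raise ValueError("solubility must be positive")
    do = dose / (volume * solubility)
    return DoseNumberResult(do, do > 1.0)


def doluisio_fit(times, conc_corrected) -> DoluisioResult:
    """Log-linear fit of luminal concentrations: C = C0 * exp(-kapp * t).

    ``conc_corrected`` must already be corrected for water reabsorption
    (see :func:`reabsorption_correction`).  Returns kapp = -slope (1/min),
    C0 = exp(intercept) and the r^2 of the regression in log space.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc_corrected, dtype=float)
    if t.size != c.size or t.size < 3:
        raise ValueError("need at least 3 matching (time, concentration) points")
    if np.any(c <= 0):
        raise ValueError("all concentrations must be positive for the log transform")
    res = stats.linregress(t, np.log(c))
    kapp = -res.slope
    if kapp < 0:
        logger.warning("doluisio_fit: concentrations rise with time (kapp=%g < 0)", kapp)
    return DoluisioResult(float(np.exp(res.intercept)), float(kapp), float(res.rvalue**2))


def reabsorption_correction(conc, volumes=None, *, v0=None, v_end=None, t_end=None, times=None):
    """Correct measured luminal concentrations for water reabsorption.

    Either supply the measured volume time-course ``volumes`` (same length as
    ``conc``; the first entry is V0), or the start/end volumes ``v0``/``v_end``
    with the experiment duration ``t_end`` and sampling ``times``, from which
    an exponential volume model V(t) = V0 * exp(-k0 t) is built.
    Corrected concentration: C_corr = C_meas * V(t) / V0.
    """
    c = np.asarray(conc, dtype=float)
    if volumes is not None:
        v = np.asarray(volumes, dtype=float)
        if v.size != c.size:
            raise ValueError("volumes must match concentrations")
        return c * v / v[0]
    if None in (v0, v_end, t_end) or times is None:
        raise ValueError("supply volumes, or (v0, v_end, t_end, times)")
    k0 = np.log(v0 / v_end) / t_end
    t = np.asarray(times, dtype=float)
    return c * np.exp(-k0 * t)


def apparent_permeability(
    kapp: float, radius: float, *, literal_r_squared: bool = False
) -> float:
    """Apparent permeability (cm/s) from kapp (1/min) and segment radius (cm).

    For a cylindrical lumen the area-to-volume ratio is 2/R, so
    Papp = kapp * R / 2 with kapp converted to 1/s.  ``literal_r_squared``
    switches to kapp * R^2 instead.
    """
    if kapp < 0:
        raise ValueError("kapp must be non-negative")
    if radius <= 0:
        raise ValueError("radius must be positive")
    k_s = kapp / 60.0
    return k_s * radius**2 if literal_r_squared else k_s * radius / 2.0


def _truncate_after_85(ref: np.ndarray, test: np.ndarray, variant: str) -> int:
    """Index one past the last point retained by the 85%-dissolved rule."""
    if variant == "EMA":
        over = np.flatnonzero((ref > 85.0) & (test > 85.0))
    elif variant == "FDA":
        over = np.flatnonzero(ref > 85.0)
    else:
        raise ValueError("variant must be 'EMA' or 'FDA'")
    return int(over[0]) + 1 if over.size else ref.size


def f2_similarity(
    ref: DissolutionProfile,
    test: DissolutionProfile,
    variant: str = "EMA",
    *,
    scale_to_max: bool = False,
) -> F2Result:
    """f2 similarity factor between two mean dissolution profiles.

    f2 = 50 log10(100 / sqrt(1 + mean((R_t - T_t)^2))) over the usable
    points.  Point selection follows the chosen regulatory reading: the EMA
    variant keeps points up to (and including) the first time both products
    exceed 85% dissolved; the FDA variant truncates at the first time the
    reference exceeds 85%.  The t=0 point, if present, is excluded.  With
    ``scale_to_max`` both profiles are first rescaled so the larger final
    plateau reads 100% (magnitude scaling for products that never release
    the full dose).
    """
    if not np.array_equal(ref.times, test.times):
        raise ValueError("profiles must share sampling times")
    r = ref.fdiss.copy()
    t = test.fdiss.copy()
    if scale_to_max:
        from .weibull import scale_to_reference_max

        (ref_s, test_s), factor = scale_to_reference_max([ref, test])
        r, t = ref_s.fdiss, test_s.fdiss
        logger.info("f2: magnitude scaling factor %.4f applied", factor)
    start = 1 if ref.times[0] == 0 else 0
    stop = _truncate_after_85(r, t, variant)
    r, t = r[start:stop], t[start:stop]
    if r.size < 3:
        raise ValueError("fewer than 3 usable points for f2")
    for prof in (ref, test):
        if prof.n_replicates:
            cv = np.where(
                prof.fdiss > 0,
                prof.replicates.std(axis=0, ddof=1) / np.maximum(prof.fdiss, 1e-12) * 100,
                0.0,
            )
            if cv[start:stop].size and np.nanmax(cv[start:stop]) > 20:
                logger.warning(
                    "f2: %s replicate CV exceeds 20%% at some usable times", prof.product_id
                )
    msd = float(np.mean((r - t) ** 2))
    f2 = 50.0 * np.log10(100.0 / np.sqrt(1.0 + msd))
    return F2Result(float(f2), int(r.size), variant, bool(f2 >= 50.0))
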