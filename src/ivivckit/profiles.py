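"""Plasma and dissolution profile containers, I/O, NCA metrics and
cross-study normalization.

Plasma concentration-time profiles are mean profiles from bioequivalence
studies (time in hours); dissolution profiles are % of labeled dose dissolved
versus time (minutes) for one product under one apparatus/media program,
usually with six replicate vessels.  Concentration units are carried as an
opaque label and never converted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: times are matched across studies after rounding to this many decimals (h)
_TIME_DECIMALS = 6


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def _check_times(times: np.ndarray) -> None:
    if times.size and times[0] < 0:
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise ValueError(
            f"times must be strictly increasing; violation at row {bad} "
            f"(t={times[bad]:g} after t={times[bad - 1]:g})"
        )


@dataclass(frozen=True)
class PlasmaProfile:
    """Mean plasma concentration-time profile for one product in one study."""

    product_id: str
    study_id: str
    times: np.ndarray  # h
    conc: np.ndarray  # concentration units (label in ``conc_unit``)
    conc_unit: str = "conc"

    def __post_init__(self):
        object.__setattr__(self, "times", _as_1d(self.times, "times"))
        object.__setattr__(self, "conc", _as_1d(self.conc, "conc"))
        if self.times.size != self.conc.size:
            raise ValueError("times and conc must have equal length")
        _check_times(self.times)
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")

    def with_conc(self, conc, **labels) -> "PlasmaProfile":
        kw = dict(
            product_id=self.product_id,
            study_id=self.study_id,
            times=self.times,
            conc=np.asarray(conc, dtype=float),
            conc_unit=self.conc_unit,
        )
        kw.update(labels)
        return PlasmaProfile(**kw)

    def restrict_to(self, times) -> "PlasmaProfile":
        """Return the profile restricted to the given sampling times.

        Matching is exact after rounding to 1e-6 h; no interpolation.
        """
        wanted = np.round(np.asarray(times, dtype=float), _TIME_DECIMALS)
        have = np.round(self.times, _TIME_DECIMALS)
        mask = np.isin(have, wanted)
        return self.with_conc(self.conc[mask]) if mask.all() else PlasmaProfile(
            self.product_id, self.study_id, self.times[mask], self.conc[mask],
            self.conc_unit,
        )


@dataclass(frozen=True)
class DissolutionProfile:
    """% of labeled dose dissolved vs time for one product/apparatus/program.

    ``replicates`` holds one row per vessel (shape ``(n_rep, n_times)``);
    ``fdiss`` is the replicate mean.  Either may be given; the mean is
    computed when replicates are supplied.
    """

    product_id: str
    apparatus: str  # "USP2" | "USP4"
    program_id: str
    times: np.ndarray  # min
    fdiss: np.ndarray = None  # mean % dissolved
    replicates: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", _as_1d(self.times, "times"))
        _check_times(self.times)
        if self.apparatus not in ("USP2", "USP4"):
            raise ValueError("apparatus must be 'USP2' or 'USP4'")
        if self.replicates is not None:
            reps = np.atleast_2d(np.asarray(self.replicates, dtype=float))
            if reps.shape[1] != self.times.size:
                raise ValueError("replicate columns must match times")
            object.__setattr__(self, "replicates", reps)
            if self.fdiss is None:
                object.__setattr__(self, "fdiss", reps.mean(axis=0))
        if self.fdiss is None:
            raise ValueError("either fdiss or replicates is required")
        object.__setattr__(self, "fdiss", _as_1d(self.fdiss, "fdiss"))
        if self.fdiss.size != self.times.size:
            raise ValueError("fdiss and times must have equal length")
        vals = [self.fdiss] + ([self.replicates] if self.replicates is not None else [])
        for v in vals:
            if np.any(v < 0) or np.any(v > 110):
                raise ValueError("fdiss values must lie in [0, 110] %")

    @property
    def n_replicates(self) -> int:
        return 0 if self.replicates is None else self.replicates.shape[0]

    @property
    def times_h(self) -> np.ndarray:
        """Sampling times converted to hours (the in vivo frame)."""
        return self.times / 60.0

    def scaled(self, factor: float) -> "DissolutionProfile":
        reps = None if self.replicates is None else self.replicates * factor
        return DissolutionProfile(
            self.product_id, self.apparatus, self.program_id, self.times,
            self.fdiss * factor, reps,
        )


@dataclass(frozen=True)
class NcaMetrics:
    """Noncompartmental metrics of a plasma profile."""

    cmax: float
    tmax: float
    auc_tlast: float
    auc_inf: float | None = None


@dataclass(frozen=True)
class NormalizationMap:
    """Per-time ratio of study-1 to study-2 reference concentrations."""

    common_times: np.ndarray
    factors: np.ndarray


def read_profiles(
    path,
    kind: str,
    *,
    study_id: str = "study",
    product_id: str = "product",
    apparatus: str = "USP4",
    program_id: str = "program",
    conc_unit: str = "conc",
    sep: str = ",",
):
    """Read profiles from a delimited text file.

    The first column (or one whose name starts with ``time``) is the sampling
    time; every other column is a product (``kind='plasma'``) or a replicate
    vessel (``kind='dissolution'``).  Plasma times are hours, dissolution
    times minutes.

    Returns a list of :class:`PlasmaProfile` (one per column) or a single
    :class:`DissolutionProfile` whose mean is the arithmetic replicate mean.
    """
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("expected a time column plus at least one data column")
    time_cols = [c for c in df.columns if str(c).lower().startswith("time")]
    tcol = time_cols[0] if time_cols else df.columns[0]
    times = df[tcol].to_numpy(dtype=float)
    _check_times(times)
    data_cols = [c for c in df.columns if c != tcol]
    if (df[data_cols].to_numpy(dtype=float) < 0).any():
        raise ValueError("negative values are not allowed in profile data")
    if kind == "plasma":
        return [
            PlasmaProfile(str(c), study_id, times, df[c].to_numpy(dtype=float), conc_unit)
            for c in data_cols
        ]
    if kind == "dissolution":
        reps = df[data_cols].to_numpy(dtype=float).T
        return DissolutionProfile(product_id, apparatus, program_id, times, replicates=reps)
    raise ValueError("kind must be 'plasma' or 'dissolution'")


def auc_trapezoid(times, conc, *, log: bool = False) -> float:
    """Cumulative AUC by the trapezoidal rule (linear by default).

    With ``log=True`` the log-trapezoid is used on intervals where the
    concentration declines (both endpoints positive); linear otherwise.
    """
    t = _as_1d(times, "times")
    c = _as_1d(conc, "conc")
    if not log:
        return float(np.trapezoid(c, t))
    total = 0.0
    for i in range(1, t.size):
        dt = t[i] - t[i - 1]
        c0, c1 = c[i - 1], c[i]
        if c1 < c0 and c1 > 0 and c0 > 0:
            total += dt * (c0 - c1) / np.log(c0 / c1)
        else:
            total += dt * (c0 + c1) / 2.0
    return float(total)


def nca_metrics(p: PlasmaProfile, kel: float | None = None, *, log: bool = False) -> NcaMetrics:
    """Cmax/Tmax from the observed maximum; AUC by trapezoid.

    ``auc_inf = auc_tlast + C(tlast)/kel`` when an elimination rate constant
    (1/h) is supplied, else ``None``.
    """
    if p.times.size < 3:
        raise ValueError("need at least 3 sampling points for NCA")
    if not np.any(p.conc > 0):
        raise ValueError("no absorption signal: profile is identically zero")
    imax = int(np.argmax(p.conc))
    auc_t = auc_trapezoid(p.times, p.conc, log=log)
    auc_inf = None
    if kel is not None:
        if kel <= 0:
            raise ValueError("kel must be positive for AUC extrapolation")
        auc_inf = auc_t + float(p.conc[-1]) / kel
    return NcaMetrics(float(p.conc[imax]), float(p.times[imax]), auc_t, auc_inf)


def common_times(*profiles: PlasmaProfile) -> np.ndarray:
    """Sampling times shared by all profiles (exact match after rounding)."""
    sets = [set(np.round(p.times, _TIME_DECIMALS)) for p in profiles]
    return np.array(sorted(set.intersection(*sets)))


def normalization_map(ref1: PlasmaProfile, ref2: PlasmaProfile) -> NormalizationMap:
    """Per-time factors ref1(t)/ref2(t) at the common sampling times.

    t = 0 with both concentrations zero gets factor 1.  Times where both
    references are zero (t > 0) are dropped with a log message; a zero in
    ref2 against a positive ref1 is an undefined factor and raises.
    """
    ct = common_times(ref1, ref2)
    if ct.size == 0:
        raise ValueError("reference profiles share no sampling times")
    r1 = ref1.restrict_to(ct).conc
    r2 = ref2.restrict_to(ct).conc
    keep, factors = [], []
    for i, t in enumerate(ct):
        if r2[i] == 0:
            if r1[i] == 0:
                if t == 0:
                    keep.append(i)
                    factors.append(1.0)
                else:
                    logger.info("normalization: dropped t=%g h (both references zero)", t)
                continue
            raise ValueError(
                f"normalization factor undefined at t={t:g} h: "
                "study-2 reference is zero while study-1 reference is positive"
            )
        keep.append(i)
        factors.append(r1[i] / r2[i])
    return NormalizationMap(ct[keep], np.asarray(factors))


def cross_study_normalize(
    ref1: PlasmaProfile,
    ref2: PlasmaProfile,
    test2: PlasmaProfile,
    *,
    pooled: bool = False,
) -> PlasmaProfile:
    """Rescale a study-2 test profile into the study-1 concentration frame.

    Each concentration of ``test2`` at a common sampling time is multiplied
    by the reference ratio ref1(t)/ref2(t) at that time.  With
    ``pooled=True`` a single geometric-mean factor over the common times is
    used instead (sensitivity analysis).
    """
    nm = normalization_map(ref1, ref2)
    t2 = test2.restrict_to(nm.common_times)
    if t2.times.size != nm.common_times.size:
        raise ValueError("test profile lacks some common reference sampling times")
    factors = nm.factors
    if pooled:
        pos = factors[nm.common_times > 0]
        factors = np.full_like(factors, float(np.exp(np.mean(np.log(pos)))))
    logger.info(
        "cross_study_normalize: %s/%s rescaled at %d common times",
        test2.product_id, test2.study_id, nm.common_times.size,
    )
    return t2.with_conc(t2.conc * factors, study_id=ref1.study_id)
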