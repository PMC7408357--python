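"""Ground-truth generators for the IVIVC pipeline.

The raw bioequivalence profiles behind a typical immediate-release IVIVC
exercise are never public, so every pipeline stage is exercised on synthetic
data with the statistical structure the analysis assumes: mean plasma
profiles following two-compartment disposition with first-order or
Weibull-rate oral input on bioequivalence-study-like schedules (up to
48-60 h), and replicate dissolution profiles following Weibull kinetics with
an incomplete plateau (Fmax < 100%).  Plasma noise is multiplicative
log-normal (concentrations stay positive); dissolution noise is additive
truncated Gaussian on the percentage scale.  All generators are pure
functions of their truth object and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .deconvolution import DispositionParams
from .profiles import DissolutionProfile, PlasmaProfile
from .weibull import WeibullParams

#: default bioequivalence-study sampling schedules (h); study 2 runs to 60 h
PLASMA_SCHEDULE_48H = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0)
PLASMA_SCHEDULE_60H = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 60.0)
#: default dissolution sampling times (min), flow-through-cell style
DISSOLUTION_SCHEDULE_MIN = (5, 10, 15, 20, 30, 45, 60, 90, 120, 150, 180, 210, 240)


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to generate one product's in vivo / in vitro data.

    ``input_kind`` selects the oral input: ``first_order`` with rate
    constant ``ka`` (1/h), or ``weibull_rate`` driven by the in vitro
    Weibull parameters time-scaled into the in vivo frame by the Levy map
    t_esc = m * t_vitro + n (fractions absorbed reach 1; the in vitro
    plateau ``weibull.fmax`` applies to the dissolution curve only).
    ``conc_scale`` is kel * AUCinf, i.e. F*Dose/Vc in concentration units.
    """

    disposition: DispositionParams = field(
        default_factory=lambda: DispositionParams(kel=0.12, k12=0.35, k21=0.5)
    )
    input_kind: str = "weibull_rate"
    ka: float = 1.0  # 1/h, used when input_kind == "first_order"
    weibull: WeibullParams = field(default_factory=lambda: WeibullParams(80.0, 1.2, 1.0))
    levy: tuple[float, float] = (1.6, 0.25)  # (m, n): t_vivo = m * t_vitro + n
    conc_scale: float = 0.3
    plasma_cv: float = 0.10  # proportional CV of plasma noise
    diss_sd: float = 2.0  # additive SD (%) of dissolution noise
    seed: int = 0
    plasma_schedule: tuple = PLASMA_SCHEDULE_48H
    diss_schedule_min: tuple = DISSOLUTION_SCHEDULE_MIN


def two_compartment_oral_conc(t, ka, kel, k12, k21, scale=1.0):
    """Closed-form plasma concentration after first-order oral input.

    Solution of dC/dt = scale*ka*e^(-ka t) - (kel + k12) C + k21 P,
    dP/dt = k12 C - k21 P from (0, 0); ``scale`` = F*Dose/Vc.
    """
    t = np.asarray(t, dtype=float)
    s = kel + k12 + k21
    disc = np.sqrt(s * s - 4.0 * kel * k21)
    lam1, lam2 = (s + disc) / 2.0, (s - disc) / 2.0
    for lam in (lam1, lam2):
        if abs(ka - lam) < 1e-12:
            raise ValueError("ka coincides with a disposition exponent")
    c = scale * ka * (
        (k21 - lam1) / ((ka - lam1) * (lam2 - lam1)) * np.exp(-lam1 * t)
        + (k21 - lam2) / ((ka - lam2) * (lam1 - lam2)) * np.exp(-lam2 * t)
        + (k21 - ka) / ((lam1 - ka) * (lam2 - ka)) * np.exp(-ka * t)
    )
    return c


def _fa_analytic(truth: SyntheticTruth):
    """The exact cumulative fraction-absorbed curve implied by the truth."""
    if truth.input_kind == "first_order":
        ka = truth.ka

        def fa(t):
            return 1.0 - np.exp(-ka * np.asarray(t, dtype=float))

        return fa
    if truth.input_kind == "weibull_rate":
        a, b = truth.weibull.a, truth.weibull.b
        m, n = truth.levy

        def fa(t):
            tau = np.maximum((np.asarray(t, dtype=float) - n) / m, 0.0)
            return 1.0 - np.exp(-(tau**a) / b)

        return fa
    raise ValueError("input_kind must be 'first_order' or 'weibull_rate'")


def _fa_rate(truth: SyntheticTruth):
    if truth.input_kind == "first_order":
        ka = truth.ka
        return lambda t: ka * np.exp(-ka * max(t, 0.0))
    a, b = truth.weibull.a, truth.weibull.b
    m, n = truth.levy

    def rate(t):
        tau = (t - n) / m
        if tau <= 0:
            return 0.0
        return (a / (m * b)) * tau ** (a - 1.0) * np.exp(-(tau**a) / b)

    return rate


def _mean_plasma_curve(truth: SyntheticTruth, times: np.ndarray) -> np.ndarray:
    d = truth.disposition
    if truth.input_kind == "first_order":
        return two_compartment_oral_conc(times, truth.ka, d.kel, d.k12, d.k21, truth.conc_scale)
    rate = _fa_rate(truth)

    def rhs(t, y):
        c, p = y
        return [
            truth.conc_scale * rate(t) - (d.kel + d.k12) * c + d.k21 * p,
            d.k12 * c - d.k21 * p,
        ]

    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), [0.0, 0.0], t_eval=times,
        method="LSODA", rtol=1e-9, atol=1e-12, max_step=0.25,
    )
    if not sol.success:
        raise RuntimeError(f"plasma simulation failed: {sol.message}")
    return np.maximum(sol.y[0], 0.0)


def gen_two_compartment_oral(
    truth: SyntheticTruth, *, product_id: str = "product", study_id: str = "study"
):
    """Generate a mean plasma profile plus its exact fraction-absorbed curve.

    Returns ``(PlasmaProfile, fa)`` where ``fa`` is a callable giving the
    noiseless cumulative fraction absorbed at any time (the oracle for
    deconvolution tests).  Noise is multiplicative log-normal at the stated
    CV, mean-unbiased.
    """
    times = np.asarray(truth.plasma_schedule, dtype=float)
    mean = _mean_plasma_curve(truth, times)
    conc = mean.copy()
    if truth.plasma_cv > 0:
        rng = np.random.default_rng(truth.seed)
        sigma = np.sqrt(np.log1p(truth.plasma_cv**2))
        conc = mean * np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=mean.shape))
        conc[mean == 0] = 0.0
    return PlasmaProfile(product_id, study_id, times, conc), _fa_analytic(truth)


def gen_dissolution_weibull(
    truth: SyntheticTruth,
    n_replicates: int = 6,
    *,
    product_id: str = "product",
    apparatus: str = "USP4",
    program_id: str = "synthetic",
) -> DissolutionProfile:
    """Replicate dissolution curves: Weibull mean plus truncated Gaussian noise.

    Each replicate is the in vitro Weibull curve (in minutes; the truth's
    scale b is in h^a) plus additive N(0, diss_sd) noise clipped at 0%.
    """
    t_min = np.asarray(truth.diss_schedule_min, dtype=float)
    t_h = t_min / 60.0
    w = truth.weibull
    mean = w.fmax * (1.0 - np.exp(-(t_h**w.a) / w.b))
    rng = np.random.default_rng(truth.seed)
    reps = mean[None, :] + rng.normal(0.0, truth.diss_sd, size=(n_replicates, mean.size))
    reps = np.clip(reps, 0.0, 110.0)
    if truth.diss_sd == 0:
        reps = np.tile(mean, (n_replicates, 1))
    return DissolutionProfile(product_id, apparatus, program_id, t_min, replicates=reps)


@dataclass(frozen=True)
class BeDataset:
    """Two-study bioequivalence bundle with matched dissolution profiles.

    Study 1 contains Reference and Product A; study 2 contains Reference and
    Product B with every concentration multiplied by ``study2_scale``
    (between-study level shift that cross-study normalization must undo).
    In vivo absorption of each product equals its in vitro dissolution curve
    (rescaled to fraction 1) under the shared Levy map, making this the
    end-to-end recovery fixture.
    """

    study1: dict
    study2: dict
    dissolution: dict
    truths: dict
    fa_true: dict
    study2_scale: float
    levy: tuple[float, float]
    disposition: DispositionParams


#: per-product in vitro Weibull truths: equal plateaus, distinct rates
#: (Reference dissolves fastest, Product A slowest — the in vivo rank order)
DEFAULT_PRODUCT_WEIBULLS = {
    "Reference": WeibullParams(80.0, 1.2, 1.0),
    "ProductA": WeibullParams(80.0, 1.2, 1.45),
    "ProductB": WeibullParams(80.0, 1.2, 1.25),
}


def gen_be_dataset(
    seed: int = 0,
    *,
    product_weibulls: dict | None = None,
    disposition: DispositionParams | None = None,
    levy: tuple[float, float] = (1.6, 0.25),
    conc_scale: float = 0.3,
    study2_scale: float = 0.8,
    plasma_cv: float = 0.0,
    diss_sd: float = 0.0,
    n_replicates: int = 6,
) -> BeDataset:
    """Generate the full two-study, three-product IVIVC fixture.

    Schedules overlap partially (study 1 to 48 h, study 2 to 60 h);
    noiseless by default so recovery tests have exact ground truth.
    """
    weibulls = dict(product_weibulls or DEFAULT_PRODUCT_WEIBULLS)
    dispo = disposition or DispositionParams(kel=0.12, k12=0.35, k21=0.5)
    rng = np.random.default_rng(seed)
    truths, fa_true, dissolution = {}, {}, {}
    base = SyntheticTruth(
        disposition=dispo, input_kind="weibull_rate", levy=levy,
        conc_scale=conc_scale, plasma_cv=plasma_cv, diss_sd=diss_sd,
    )
    for product, w in weibulls.items():
        truths[product] = replace(base, weibull=w, seed=int(rng.integers(2**31)))
    study1, study2 = {}, {}
    for product in ("Reference", "ProductA"):
        tr = replace(truths[product], plasma_schedule=PLASMA_SCHEDULE_48H,
                     seed=int(rng.integers(2**31)))
        study1[product], fa_true[product] = gen_two_compartment_oral(
            tr, product_id=product, study_id="study1"
        )
    for product in ("Reference", "ProductB"):
        tr = replace(truths[product], plasma_schedule=PLASMA_SCHEDULE_60H,
                     seed=int(rng.integers(2**31)))
        profile, fa = gen_two_compartment_oral(tr, product_id=product, study_id="study2")
        study2[product] = profile.with_conc(profile.conc * study2_scale)
        fa_true.setdefault(product, fa)
    for product in weibulls:
        tr = replace(truths[product], seed=int(rng.integers(2**31)))
        dissolution[product] = gen_dissolution_weibull(
            tr, n_replicates, product_id=product
        )
    return BeDataset(study1, study2, dissolution, truths, fa_true,
                     study2_scale, levy, dispo)
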