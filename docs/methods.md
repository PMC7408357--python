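# Methods

This note documents the models implemented in `ivivckit`, the numerical
choices behind them, what the synthetic data generator does and does not
emulate, and the package's known limitations.

## Data model and units

Plasma profiles are mean concentration–time series (time in hours;
concentration units carried as an opaque label, never converted). Dissolution
profiles are % of labeled dose dissolved versus time in minutes, with
replicate vessels (n = 6 typically) and their arithmetic mean. Internally all
modelling is done in hours — the in vivo frame — because the Levy map mixes
the two time frames; dissolution minutes are converted on ingestion, so the
Weibull scale parameter b carries units of hᵃ. Times are matched across
studies by exact equality after rounding to 10⁻⁶ h; no interpolation across
studies is attempted.

## Cross-study normalization

Mean profiles from two BE studies sharing a reference product are combined by
rescaling study-2 profiles with the per-time reference ratio
ref₁(t)/ref₂(t) at the common sampling times. Factors are per-time-point; a
pooled geometric-mean factor is available (`pooled=True`) for sensitivity
analysis. At t = 0 with both references zero the factor is defined as 1;
other times where both references are zero are dropped and logged; a zero
study-2 reference against a positive study-1 reference is an error (the
factor is undefined). Note the combined dataset is limited to the common
sampling window — with a 48 h and a 60 h schedule, the test product of study
2 effectively ends at 24 h if that is the last shared time.

## NCA

Cmax/Tmax are read from the observed maximum; AUC₀₋tlast uses the linear
trapezoid by default with a linear-up/log-down option (`log=True`);
AUC∞ = AUC₀₋tlast + C(tlast)/kel when a rate constant is supplied.

## Disposition estimation without intravenous data

The classical approach fits C = B₁e^(−λ₁t) + B₂e^(−λ₂t) to the post-Cmax
concentrations (initialized by curve stripping, relative residuals so the
orders-of-magnitude concentration range is weighted sensibly) and converts to
micro-constants by k21 = (B₁λ₂ + B₂λ₁)/(B₁ + B₂), kel = λ₁λ₂/k21,
k12 = λ₁ + λ₂ − k21 − kel. This is exposed as
`fit_biexponential_postcmax` / `method="postcmax"`. Its well-known weakness
is bias whenever absorption continues past Cmax — exactly the situation for a
dissolution-limited drug with Tmax ≈ 3–4 h — because the early post-Cmax
curve then reflects input as well as disposition.

The default estimator (`fit_disposition_oral`) therefore refines those
stripping estimates by fitting the full oral curve with a two-compartment
model driven by a lagged Weibull-rate input (seven parameters; relative
least squares). The input family is flexible enough to absorb the absorption
phase, leaving the disposition constants identified by the whole curve rather
than a contaminated tail window.

In the pipeline one **shared** disposition set, fitted on the study-1
reference profile, is applied to all products (`disposition_sharing`
option). Disposition is a property of the drug, not of the formulation, and
the study-2 test product only retains the short common-time window after
normalization — too short to identify micro-constants on its own
(per-product estimation is available and its effect is visible by comparing
the two settings on synthetic data).

## Loo-Riegelman deconvolution

Absorbed amount per unit central volume: A(t)/Vc = C(t) + kel·AUC(0→t) +
P(t)/Vc, normalized by kel·AUC∞, so no volume estimate is ever needed. The
peripheral amount uses the exact recursion for a plasma curve interpolated
linearly over each sampling interval,

    P_n = P_{n−1}e^(−x) + (k12/k21)[C_{n−1}(1 − e^(−x)) + ΔC(1 − (1 − e^(−x))/x)],  x = k21Δt,

whose small-x expansion is the familiar trapezoidal correction k12·ΔC·Δt/2.
The exact form matters on BE schedules: the tail intervals (12→24→48 h) have
k21·Δt ≈ 6–18, where the trapezoid correction term grows linearly in Δt and
destroys the mass balance, while the exact form settles into the correct
pseudo-equilibrium P ≈ (k12/k21)·C. For the same reason the cumulative AUC
inside deconvolution uses linear-up/log-down trapezoids, and AUC∞ is
extrapolated with the terminal exponent λ₂ implied by the disposition
(extrapolating with kel underestimates the biexponential tail and makes fa
plateau above 1). Flags restore the plain-linear and kel variants.
Wagner-Nelson (the k12 = 0 limit) shares the same AUC rules and matches the
Loo-Riegelman recursion exactly in that limit.

## Dissolution modelling and magnitude scaling

Weibull fits use nonlinear least squares with multistart over the shape
a ∈ {0.5, 1, 2}; b is seeded from the observed time to half-plateau
(t₅₀ᵃ/ln 2) and Fmax from the largest observation; bounds a ∈ (0.05, 10),
b > 0, Fmax ∈ (0, 120]. Products that never release 100 % are magnitude-scaled
before correlation: the largest plateau across products is defined as 100 %.
The plateau of each profile is estimated by its fitted Weibull asymptote
(default) rather than the mean of the last two observations: when a profile
is still rising at the final sampling time the last-points estimate is biased
low, which after scaling pushes the fitted Fmax above 100 and distorts the
IRF at high fractions. The last-points estimator remains available. Profiles
are scaled first and the Weibull for the correlation is fitted to the scaled
data.

## Levy plot and correlation

For each fraction in the grid (default 0.1…0.9), the in vivo time is obtained
by inverting the deconvolved fa curve with a shape-preserving (PCHIP)
monotone interpolant of its increasing envelope — linear inversion of the
steep, sparsely sampled early limb is the single largest error source
otherwise — and the in vitro time from the Weibull IRF. One pooled line
t_vivo = m·t_vitro + n is fitted across products by ordinary least squares
(one time-scale map; per-product pairs can be inspected via `build_levy`).
Fractions unreachable by either curve are dropped with a warning.

The correlation itself is a polynomial (degree 1 or 2 by default) least
squares of fa on f_diss evaluated at Levy-equivalent times, pooled across
products. Predictions are clipped to [0, 1] and forced nondecreasing by a
running maximum.

## Reconvolution and validation

Predicted absorption curves are pushed through
dC/dt = s·(dfa/dt) − (kel + k12)·C + k21·P, dP/dt = k12·C − k21·P with
dfa/dt from a PCHIP interpolant, s = kel·AUC∞ taken from each product's own
experimental profile (internal validation). PE% = |exp − pred|/exp·100 is
computed with an absolute value; validity requires each PE% < 15 and each
parameter's mean < 10.

## One-step models

Both models are linear disposition systems with analytic forcing, integrated
with LSODA at rtol 10⁻⁸ / atol 10⁻¹⁰ and a 0.25 h step cap (delayed inputs
are invisible to the starting-step heuristic otherwise). Model 1's input rate
is the Weibull rate evaluated at t_esc = m·t + n, exactly as the model is
written — without the dt_esc/dt Jacobian factor m, whose constant effect is
absorbed by the lumped concentration scale s_scale (≈ F·D/Vc; the equations
are in amounts and no central volume is ever reported, so the scale lets the
model fit concentration data directly). Model 2 integrates the cumulative
dissolved amount with the in-vivo-scaled b_esc and feeds ESC(t)·Q_diss into
the central compartment; the dissolved pool is *not* depleted by absorption,
as the model is defined — mass is not conserved between dissolution and
absorption — and a conservative depleting variant is available
(`deplete=True`) for comparison. ESC breakpoint membership is left-closed
(t = 0.5 belongs to the first branch); the breakpoints are fixed constants,
not fitted, and ESC continuity across them is not enforced.

The joint fit is weighted least squares on concatenated residual blocks —
dissolution % and plasma concentration, each normalized by its observed
maximum so the blocks weigh comparably — with per-product Weibull parameters
and shared disposition, time-scale and concentration-scale parameters,
started from the two-step results (`init_from_twostep`). Non-convergence
raises an error carrying the best parameters and the residual trace.

## Synthetic data generator

The generator emulates the study design the pipeline assumes: two crossover
BE studies sharing a reference (study 2 scaled by a between-study factor,
default 0.8), three products, plasma schedules 0–48 h and 0–60 h, six
replicate dissolution vessels sampled 5–240 min. Disposition defaults
kel = 0.12, k12 = 0.35, k21 = 0.5 h⁻¹ give a terminal half-life ≈ 10 h,
matching candesartan's reported ~9 h. The Levy map defaults to m = 1.6,
n = 0.25 h (dissolution faster than absorption, with a short pre-absorption
lag), consistent with the reported in vivo↔in vitro time correspondences
(0.5 ↔ 0.15 h, 2 ↔ 1.1 h). Product Weibull scales (b = 1.0, 1.25, 1.45 hᵃ
for Reference, B, A; a = 1.2; Fmax = 80 %) put the reference Tmax near 3 h —
the reported Tmax window — and preserve the in vivo rank order
Reference > B > A. Plasma noise is multiplicative log-normal (mean-unbiased,
default CV 10 %); dissolution noise is additive Gaussian clipped at 0
(default SD 2 %). All generators are pure functions of (truth, seed).

What the generator does **not** emulate: individual-subject variability and
crossover structure (only mean profiles), enterohepatic recirculation double
peaks, below-quantitation censoring, non-Weibull release, and any
disposition nonlinearity. Passing recovery tests therefore demonstrate the
pipeline's correctness and numerical accuracy under its own model
assumptions, not robustness to real-data violations of them.

## Numerical conventions and degenerate inputs

Strictly increasing times and non-negative values are enforced at
construction; all-zero profiles are rejected ("no absorption signal" / "no
release signal"). f2 excludes the t = 0 point, requires ≥ 3 usable points,
truncates at 85 % dissolved per the selected regulatory variant (EMA: first
point where both products exceed 85 %, kept; FDA: first point where the
reference does), and logs — but does not enforce — replicate-CV warnings.
The Doluisio fit refuses non-positive concentrations before the log
transform; the water-reabsorption correction accepts either a measured
volume time-course or an exponential volume model built from start/end
volumes. Permeability uses Papp = kapp·R/2 (cylindrical lumen,
area/volume = 2/R); the literal kapp·R² reading is available behind a flag.

## Known limitations

- Disposition from oral data is an approximation in any variant; the
  full-profile refinement assumes a parametric input family.
- The combined two-study dataset is restricted to common sampling times.
- Model 2's non-depleting dissolved pool means its parameters are effective,
  not mass-balanced, quantities.
- The piecewise ESC makes Model 2 flexible enough to overfit sparse plasma
  schedules; its use is only sensible with the two-step results as anchors.
- Correlations are valid strictly within the dissolution-rate design space
  of the products used to build them; external validation against
  non-bioequivalent products is out of scope.
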