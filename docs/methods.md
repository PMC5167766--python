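# Methods

## Scope and data flow

`phytoalloc` turns five raw data streams from a turbidostat photophysiology
experiment into per-culture estimates and study-level fits:

1. FRR flashlet fluorescence (dark-adapted and actinic-state inductions, a
   post-train relaxation record, and a second induction after a 2-s dark
   gap) → F₀, F_M, σ_PSII, connectivity p, τ₁, τ₂, F_S, F′_M, σ′_PSII, F′₀,
   q_P, electron transport.
2. Turbidostat OD₆₈₀ logs → specific growth rate µ.
3. Immunoblot band signals with standard ladders → RbcL and PsbA per cell.
4. Absorbance triplets (A₆₆₄, A₆₃₀, A₇₅₀) → chlorophyll *a* per cell.
5. Elemental analysis (C per cell, mass C:N) → N per cell.

An allocation layer converts contents into molar N fractions and the
apparent RUBISCO turnover; a pipeline layer orchestrates whole studies and
fits growth–irradiance and growth–allocation relationships. A synthetic
generator emulates all five instruments from explicit ground truth, so
every stage is validated by round-trip parameter recovery.

## Single-turnover FRR model

The closed-PSII fraction is integrated continuously over each flashlet's
photon dose, dC/dE = σ(1−C)(1−p)/(1−pC), using the monotone potential
g(C) = pC − (1−p)ln(1−C): g(Cₙ) = (1−p)σE_cum,ₙ + g(C₀), solved by a
vectorized, monotone Newton iteration started from the p = 0 closed form
C = 1 − exp(−σE) (which the model reproduces exactly at p = 0). Fluorescence
at flashlet n reflects the closure after that flashlet's full dose.
Assumptions: a true single-turnover regime (no reopening within the 128 µs
train), uniform flashlet spacing and dose, and no spectral correction of
σ_PSII for the excitation LED.

Fitting minimizes residuals on **log** fluorescence — flashlet noise is
multiplicative, so the log scale is homoscedastic and prevents the F_M
plateau from dominating; at zero noise the optimum is unchanged. Bounds:
F₀, F_M > 0; σ_PSII ∈ [10, 3000] ×10⁻²⁰ m²; p ∈ [0, 0.6]; initial closure
C₀ ∈ [0, 0.95]. Starts: F₀ from the first flashlet, F_M from the maximum,
σ from the early-rise slope of −ln(1 − normalized F); two fallback starts
(σ×3 with p=0, σ×0.3 with p=0.3) run only if the first lands badly
(rms log-residual > 20 % or solver failure). Dark fits fix C₀ = 0; the
actinic-state fit frees C₀ (its baseline is F_S) and fixes p at the
dark-fit value; the post-2-s fit fixes C₀ = 0 again. A fit whose optimum
has F_M ≤ F₀ is flagged failed, never silently defaulted. p is freely
fixable (e.g. to 0) through `fix_p`.

Relaxation is fitted as F(t) = F₀ + (F_pk − F₀)[α₁e^(−t/τ₁) + (1−α₁)e^(−t/τ₂)]
with baseline and peak free. Freeing the baseline matters: anchoring it to
the (noisy) induction F₀ estimate propagated that error into τ₁ (+8 % mean
bias at 2 % noise in Monte-Carlo), whereas the free-baseline fit shows +2 %
bias with the default 24-sample schedule. Lifetimes are ordered τ₁ < τ₂
after fitting; optima with a vanishing amplitude (< 0.02) or τ₂/τ₁ < 1.2
collapse to a single exponential with α₂ = 0 and a `single_exponential`
flag.

Derived quantities follow the standard definitions given in the README;
q_P values outside [0, 1] (possible under noise) are reported raw with a
flag rather than clipped, and electron transport uses the raw value.
A >5 % change between F′_M and F′_M2s raises a quality flag in addition to
the proportional F′₀ correction.

## Turbidostat growth

Dilution events are detected on log OD: a median filter whose window is
sized from a robust noise estimate (MAD of first differences) so that the
difference of two disjoint window medians has sd ≤ threshold/5 (a ~5σ
criterion; noise-free logs collapse to window 1 and sample-exact
boundaries), then thresholded at a relative drop of 0.05 — half the 0.0909
drop that a 10 % volumetric dilution produces — across a window-length gap,
with runs merged and each event localized at the largest raw single-sample
drop. Segments are trimmed by half the detection window at both ends
(boundary positions are only certain to that resolution and a stray
pre/post-dilution sample is a large-leverage outlier), the first and last
partial cycles are excluded, and each remaining cycle with ≥ 4 points is
fitted log-linearly (slope of ln OD vs days = µ; exact at zero noise and
gain-invariant). The per-run estimate is the mean ± SD over the final ten
cycles; shorter series are used in full with a `short_series` flag.

## Growth–irradiance and gated linear fits

Eilers–Peeters fits use bounded least squares (a ∈ [0, 1], c > 0, b free)
from a small deterministic grid of photoinhibition starts (a₀ = 10⁻⁵…10⁻¹,
c₀ = I₁/µ₁, b₀ = 1/µ_top − 2√(a₀c₀)), keeping the best optimum. 95 % CIs
come from the linearized covariance (JᵀJ)⁻¹·RSS/dof with Student-t
quantiles; exactly-identified fits (3 distinct lights, no replicates) are
flagged `exact_fit_no_ci`. µ_max and I_opt use the closed forms; every fit
is cross-checked in the tests against brute-force maximization. Linear
responses are OLS with a two-sided t-test of zero slope; the fit is
*reported* (model = "linear") only at p < 0.05, and the gate's type-I error
is verified against its nominal 5 % on null simulations. Model selection
prefers Eilers–Peeters only when the photoinhibition coefficient is
significantly positive (95 % CI of a excludes 0); otherwise the gated
linear fit stands. Pooled replicates (not replicate means) are fitted.

## Quantitation

Blot standard curves are free-intercept linear fits over unsaturated
standard lanes (≥ 3 required; slope ≤ 0 is a calibration error; r² < 0.95
flags a warning). Sample lanes are inverse-regressed and must fall within
the closed ladder range — out-of-range or saturated lanes raise named
errors, never extrapolate. Per-cell content (amol cell⁻¹) =
(fmol/µg loaded) × (pg protein cell⁻¹) × 10⁻³, with loads of 0.5 µg (RbcL)
and 1 µg (PsbA). Chlorophyll uses the trichromatic-style equation on the
acetone phase and back-calculates through the 10× dilution (50 µL extract
into 450 µL acetone), the 450 µL extract volume, the filtered volume and
the cell density. N per cell is C/(C:N).

## Allocation

Complex-level N stoichiometries are **extrapolation constants**, not
measurements: 4 N per Chl *a*; 4000 N per PSII monomer per PsbA (a whole
PSII–antenna complex of roughly 1 MDa protein at ~16 % N); 800 N per RbcL
(L8S8 holoenzyme ≈ 560 kDa at ~16 % N over 8 RbcL). They are provisional
defaults in `StoichiometryConfig` and every fraction is exactly linear in
them, so alternative factors rescale results without refitting. A RUBISCO
fraction above 1 raises; fractions summing above 1 are emitted with a
warning flag. Turnover applies (e^µ − 1) — the fractional daily biomass
gain of exponential growth — to molar C per cell over molar RbcL per cell,
and divides by 86 400 because µ is per day while the quantity is reported
per second.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design: small (*T. pseudonana*-like) and
large (*T. punctigera*-like) centric diatoms, ~550 vs ~55 µmol L⁻¹ NO₃⁻
media, growth lights 30/180/380 and 30/90/180 µmol photons m⁻² s⁻¹, 3–4
replicates, cell densities 3.6×10⁵ and 650 mL⁻¹, 50 mL filtered volumes and
the blot/pigment protocol constants above. Treatment-mean compositions are
fixed at published per-cell contents for these species and conditions;
growth-light responses are Eilers–Peeters truths constructed to µ_max =
1.5 d⁻¹ (I_opt 180) and 0.39 d⁻¹ (I_opt 90) under HN with saturating
low-N responses; dark photophysiology truths hold F_V/F_M = 0.58 (small
species) and 0.44→0.32 with light under HN (large species), with p = 0.3,
τ₁ = 0.35–0.6 ms and τ₂ = 5 ms.

Generator-side choices the instruments leave open: uniform 2.05 µs flashlet
spacing (only train totals are specified); 24 log-spaced relaxation samples
from 50 µs to 50 ms; instantaneous dilutions at the setpoint crossing; OD
sampling at ~2000 samples per dilution cycle (period clamped to 1–300 s),
sized so the standard error of the final-ten-cycle µ at 2 % OD noise stays
near 0.008 d⁻¹ even at µ = 1.5 d⁻¹; runs last ~14.5 cycles. The
light-acclimated state uses F′_M = 0.9 F_M, σ′ = 0.95 σ, F′₀ = 0.95 F₀, a
2-s recovery factor of 1.05, and steady-state closure C_ss = σ′Iτ_ss/(1 +
σ′Iτ_ss) with an effective turnover time τ_ss = 1 ms (slower than τ₁,
reflecting plastoquinone-pool limitation; gives q_P ≈ 0.55–0.95 across the
design). Noise: multiplicative log-normal for fluorescence (CV 1 %), OD
(2 %) and blot signals (5 %); additive Gaussian for absorbance (sd 0.005);
log-normal replicate spreads for contents (10 %), cell density (30 %, the
accepted across-treatment variation) and delivered light (3 %).

What it does **not** emulate — and hence what passing tests do not show
about real data: nitrogen draw-down dynamics, photoacclimation kinetics,
non-photochemical quenching beyond a static F_M quench, spectral effects on
σ_PSII, detector nonlinearity or saturation, pump transients, gel/transfer
artifacts beyond a saturation flag, or any correlation structure between
channels. Real-data behaviour of the estimators (e.g. σ–p trade-off under
structured noise) may differ.

A realism note: the small species' LN/30 treatment implies ~1490 fmol RbcL
in a 0.5 µg lane, just under the 1500 fmol top standard, so noisy
replicates of that one treatment sometimes fall out of ladder range and are
censored with flags — intentional behaviour of the in-range rule, matching
what a strict analyst would do at the bench.

## Numerical choices and problem sizes

Nonlinear fits use SciPy trust-region-reflective least squares with
ftol = xtol = gtol = 10⁻¹³; zero-noise round trips recover parameters to
≤ 10⁻⁶ relative throughout. Determinism: all randomness descends from one
`numpy.random.SeedSequence`, identical seeds give byte-identical bundles
and result tables. Degenerate inputs have defined behaviour (flat traces
flagged, µ = 0 logs event-free and flagged, zero-gain blots fail
calibration loudly, blank absorbances give 0). Monte-Carlo validation sizes
are the package's own verification scale: the 27-point σ/p/F₀:F_M grid ×
100 seeds, 100-seed relaxation and 500-seed standard-curve benchmarks,
1000-dataset regression-gate calibration, 200-seed µ_max recovery, and
full 36-replicate studies (noise-free and noisy) end to end.

## Known limitations

- Connectivity p and σ_PSII are partially confounded in 40-flashlet
  inductions; single-replicate σ estimates carry ~10–13 % spread at 1 %
  noise even though the median error is < 5 %.
- The actinic-state baseline closure C₀ is weakly identified when q_P ≈ 1
  (low light); its error mostly cancels in q_P but not in F_S.
- Inverse regression reports no Working–Hotelling-style calibration
  uncertainty; curve covariance is available but not propagated per lane.
- The complex-level N extrapolation factors are provisional defaults; all
  allocation fractions (and any half-saturation derived from them) shift
  linearly with that configuration and should be re-examined before
  cross-study comparison.
- Treatment aggregation is mean ± SD only; between-treatment inference is
  deliberately left to external statistical tools.
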