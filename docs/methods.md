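# Methods

## The spectroscopic model

A skin Raman trace in the protein spectral zone is modelled as

    y(x) = Σ_b A_b · PV(x; x0_b, w_b, η_b) + B(x) + ε(x)

where each sub-band `b` is a height-normalised pseudo-Voigt,

    PV(x; x0, w, η) = η · L(x; x0, w) + (1 − η) · G(x; x0, w),

with `G` and `L` Gaussian and Lorentzian profiles of common full width at
half maximum `w` and unit peak height (`G(x0) = L(x0) = 1`), `B` a smooth
fluorescence background, and `ε` zero-mean noise.  Because the profiles are
height-normalised, `A_b` *is* the band's peak intensity, and the
protein-folding ratio is simply

    R_PF = A_random_coil / A_alpha_helix     (height mode, the default)

or the ratio of integrated band areas (area mode; for a shared shape the
two differ only by the ratio of fitted widths).

The default band library places the α-helix marker at 1652 cm⁻¹ and the
random-coil marker at 1681 cm⁻¹; a third β-sheet band defaults to
1667 cm⁻¹.  The β-sheet position and all widths are assumptions — the
decomposition of the Amide I envelope varies across tissues and
instruments — and are configurable.  Defaults: FWHM 18 cm⁻¹, Lorentzian
fraction 0.5, relative heights α:β = 1:0.5, analysis window
1570–1730 cm⁻¹ (both markers plus flanks for baseline anchoring).

## Band fitting and identifiability

`fit_bands` minimises the sum of squared residuals with
`scipy.optimize.least_squares` (trf) under box constraints: amplitudes
≥ 0, centers within ±5 cm⁻¹ of their library positions, FWHM in
[8, 40] cm⁻¹, η in [0, 1].  Initialisation is deterministic: library
centers, midpoint FWHM, amplitude from the spectrum value at each center
floored at 0.  Convergence is a relative cost change below 1e-10 (or the
evaluation cap, 500 per parameter); non-convergence sets a flag rather
than raising.  Fits whose bands collapse to within 4 cm⁻¹ of each other
are flagged degenerate.

Two numerical choices matter and were validated on synthetic spectra with
known truth:

- **Shape parameter.**  With three heavily overlapping bands, a free η per
  band is not identifiable: at realistic noise (see below) the bands trade
  amplitude against shape and R_PF errors reach 0.02–0.05.  The default
  fits a *single η shared by all bands*, which recovers both the shape and
  the heights (max R_PF error ≈ 0.01 across true η from 0 to 1).  Per-band
  η and frozen η remain available via `FitOptions.eta`.
- **Residual background.**  A quadratic polynomial is co-fitted inside the
  window (`FitOptions.baseline_degree = 2`).  After any global baseline
  subtraction a curved residual of a few intensity units remains, and
  without the co-fit the band amplitudes absorb it.

## Baseline correction

The default estimator is an iterative peak-clipping polynomial fit
(modpoly-style, degree 3, 20 iterations): fit, clip the working signal to
the fitted curve, repeat.  It reproduces polynomial backgrounds up to its
degree essentially exactly and does not sag into the ~70 cm⁻¹ wide Amide I
envelope.  Asymmetric least squares (Whittaker smoother, asymmetry
p = 0.01, 10 reweighting iterations) is available as an alternative; its
stiffness λ (default 1e7 at 1 cm⁻¹ sampling) trades following genuine
background curvature against sinking into broad envelopes, and no single λ
does both perfectly — which is why it is not the default.  Correction is
applied to the full recorded range before cropping, so the flanks anchor
the estimate.  Corrected intensities are deliberately not clipped at zero.

## Calibration

Four candidate OLS models relate age (years) to R_PF, with sex coded
M=1/F=0:

    1: age ~ 1 + R          3: age ~ 1 + R + R² + sex
    2: age ~ 1 + R + R²     4: age ~ 1 + R + sex + R·sex

`fit_model` returns coefficients, residual scale s = √(SSE/df), df, and
the design cross-product matrix X'X.  Model choice uses repeated k-fold
cross-validation (default k = 10, 100 repeats): per repeat, a seeded
uniform shuffle is cut into k contiguous folds (sizes differ by ≤ 1), each
fold predicted from a fit on the rest, held-out squared errors pooled into
RMSE and R² = 1 − SSE/SST (SST about the full-sample mean); reported
metrics are means over repeats.  The model with the lowest mean RMSE wins;
ties within 1e-6 go to higher R², then lower model id.  Age clamping never
enters fitting or CV error computation — only reported predictions and
interval bounds are floored at age 0, and rounding to 0.1 year happens
only in the reporting layer.

Prediction intervals are the classical t form, point ±
t_{(1+γ)/2, df} · s · √(1 + h), with new-point leverage
h = x'(X'X)⁻¹x.  A **reproduction mode** (`reference_model()`,
`leverage_mode="none"`) evaluates intervals from the reference
calibration's printed coefficients with s = 11.3 years and df = 129 and
h = 0, because the original design matrix is not available; this
reproduces the reference interval table to within ±0.1 year.  Whether the
11.3-year figure was the study's CV RMSE, its residual s, or both is not
recorded; reproduction mode uses it as s, which is the assumption that
reproduces the published bounds.

The sex comparison is a two-sided Wald test of the sex coefficient in
model 3 at the 5% level — a specific choice among several reasonable
tests of "no difference between male and female samples".

## The synthetic cohort generator

`CohortSpec` defaults encode the reference study's structure: n = 132
donors, male fraction 92/132, R_PF drawn from Normal(0.41, 0.16) truncated
to [0.16, 0.90] by rejection sampling (exact truncation), age equal to the
reference quadratic evaluated at true R_PF plus Gaussian noise with SD
11.15 years, unclamped (clamping is opt-in; the calibration layer tolerates
the occasional negative synthetic age).  The noise SD is chosen so that a
quadratic fit on a synthetic cohort has a residual scale matching the
reference calibration's 11.3 years.  Per donor, 100 replicate spectra
emulate the depth-resolved scans that are averaged in practice: the
three-band forward model on a gentle quadratic fluorescence background
(evaluated in a centred coordinate so coefficients stay well-scaled),
α-helix height 100, random-coil height exactly R_PF × 100, additive
Gaussian noise of SD 1.0 (1% of the α-helix height).  Heights and weights
are drawn independently of R_PF, reflecting the absence of a BMI
association, and exist only to exercise BMI bookkeeping.  All randomness
in a call flows from one integer seed; equal seeds give bit-identical
output.

What the generator does *not* emulate — and therefore what passing tests
cannot certify about real tissue: non-Amide-I protein bands and the lipid
zone, depth-dependent composition gradients, instrument response and
wavenumber miscalibration, cosmic-ray artifacts (a simple median-filter
despiker exists but spikes are not simulated by default), and any
age-dependence of band positions or widths.  Tests against the generator
validate the *pipeline's* correctness and the calibration's statistical
behaviour, not the biology.

## Problem sizes in the shipped checks

The repeated-CV RMSE of a 132-donor cohort varies cohort-to-cohort with an
SD of ≈ 0.7 years, so the shipped checks average it over 40–60 independent
cohorts (and |Pearson r|, SD ≈ 0.019, over 40); spectral-stage recovery is
checked on 25-replicate averages over a grid of true R_PF values, and
interval coverage on 10,000 fresh simulated donors against models fitted
on 5 independent training cohorts.

## Known limitations

- The reference R² of 0.743 and the full descriptive table of the original
  cohort are properties of the unavailable raw data; no simple generator
  reproduces them jointly with the other statistics, and they are treated
  as context, not as reproduction targets.
- The β-sheet band position and all band widths are assumptions, exposed
  as configuration.
- JCAMP-DX and vendor binary formats are not read; spectra are two-column
  text/CSV.
- Inverse regression (inferring R_PF from age), Bayesian calibration and
  bootstrap intervals are out of scope.
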