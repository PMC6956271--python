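# Methods

This note documents the models behind each stage, the defaults and why,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was open.

## Dynamic-dialysis binding

The donor compartment of a dialysis cell, held under sink conditions, loses
free drug at a rate proportional to the membrane constant `K_m` (h⁻¹).
Drug reversibly bound to dissolved polymer or adsorbed on nanoparticles is
not membrane-permeable, so only the free fraction `F_f` contributes:

    ln(100 · C_d / C_d0) = ln(100) − K_m F_f t.

The control run (plain drug, `F_f = 1`) calibrates `K_m`; the ratio of a
formulation's fitted slope magnitude to `K_m` is its `F_f`, and
`100(1 − F_f)` is the bound percentage ("Interaction %").

Choices:

- **Free intercept.** The model fixes the intercept at `ln(100) = 4.605`,
  but the measured `C_d0` carries noise; pinning makes the fit brittle.
  We fit the intercept freely and warn when it deviates from 4.605 by more
  than 0.5 (a sink-condition / `C_d0` diagnostic).
- **Per-replicate fits** are the default (slopes averaged, SD across
  replicates reported, formulation-vs-control compared by two-sided
  Student's t at α = 0.05); pooled fitting over concatenated replicates is
  available via `pooled=True`. On noiseless data the two coincide.
- **Clamping.** Noise can push `F_f` marginally above 1; since the bound
  percentage lives on [0, 100], such ratios are clamped to 1 with a
  recorded warning rather than raised.
- Times are in hours, slopes in h⁻¹ throughout.

## Interrupted-dialysis mass balance

Only the dispersion medium (after centrifugation) and the receiving phase
are assayed; the nanoparticle-matrix percentage is obtained by closure,
`%NPM = 100 − %DM − %RP`, so the three percentages sum to 100 by
construction. Assayed masses exceeding the load by up to 2% (relative) are
treated as assay error and renormalized; larger excess raises a
mass-balance error. "Virtually constant" retention is operationalized as a
range threshold on `%NPM` within a time window, default 5 percentage
points — the qualitative claim in the source domain is a 15–18% band held
over 15 h, which this rule reproduces. A decreasing cumulative `%RP`
triggers a data-quality warning (transport is cumulative), not an error.

## Higuchi release kinetics

Cumulative release from the gel is fit as `Q = k√t + b` by OLS. The sqrt
axis defaults to **minutes**: a slope of 3.34 %/√min extrapolated to
300 min gives ≈59.5% cumulative release at 5 h, matching the measured
five-hour value, whereas per-√hour units would predict ≈7.5%. The unit is
configurable and recorded on every fit. The fit window is capped at 300 min
(the release-study duration); intercepts outside the empirically observed
−0.99%…2.88% band are flagged as burst/lag indicators but not rejected.
Predictions are clamped to [0, 100]. Replicate slopes are compared with an
equal-variance t-test by default (n = 3 per group, balanced); Welch is
available.

## DLS passive microrheology

Chain: Siegert relation `g₂ = 1 + β g₁²` → Gaussian-displacement inversion
`MSD(τ) = −(6/q²) ln g₁` with `q = (4πn/λ) sin(θ/2)` → Mason's local
power-law generalized Stokes–Einstein relation at `ω = 1/τ`:

    α(ω) = d ln MSD / d ln τ,   |G*| = k_B T / (π a MSD(1/ω) Γ(1+α)),
    G′ = |G*| cos(πα/2),        G″ = |G*| sin(πα/2),   η* = |G*|/ω.

This is the established single-particle chain for backscatter DLS
instruments and is exact in the two limits used for validation: a
Newtonian fluid (α = 1, η* = η, G′ = 0) and an elastic plateau (α = 0,
G′ = k_B T/(π a δ²)). For a Maxwell element the α = 1/2 point falls at
τ = λ, so the G′/G″ crossover lands at ω = 1/λ up to grid resolution.

Numerical choices:

- α by centered finite differences on log-log MSD (`numpy.gradient`,
  one-sided at the ends) smoothed with a centered 5-point moving average
  (shrinking at the edges), then clamped to [0, 1] — which guarantees
  G′, G″ ≥ 0.
- Lag retention: `g₂ − 1 > max(3 × tail-noise SD, 10⁻⁹)`, the tail noise
  estimated from the last 10% of lags; the absolute floor guards against
  float cancellation in `g₂ − 1`.
- If `(g₂ − 1)/β > 1` anywhere (coherence factor set too low), `g₁` is
  clipped to 1 with a warning; the MSD is biased toward zero at those lags.
- Instrument defaults: λ = 633 nm, n = 1.33, θ = 173° (backscatter),
  T = 298.15 K, tracer radius 250 nm (500-nm polystyrene latex). All
  overridable per correlogram.

Mucoadhesion is scored on the η* thickening a nanoparticle dispersion
causes in a mucin solution: spectra are log-log interpolated onto the
overlap of their frequency ranges and the mixture is called mucoadhesive
when the median η* ratio exceeds 1.10 (a 10% thickening threshold; the
source data show ordering, not absolute moduli, so the threshold is a
package choice). G′ ratios are reported alongside, since an elastic
contribution indicates an interconnected NP–mucin microstructure.

## Confocal FWHM sizing

An equatorial intensity profile through a particle is fit with
`A exp(−(x−µ)²/2σ²) + B` by Levenberg–Marquardt (scipy `curve_fit`;
moment-based initialization, amplitude and width bounded positive), and the
diameter is `FWHM = 2√(2 ln 2) σ`. Because the optics blur the object with
the point-spread function, this measures the *apparent* diameter; modes
with mean below 0.3 µm (1.5× the ~0.2 µm diffraction limit) are flagged
`diffraction-limited` rather than suppressed. Profiles with no peak above
3× the first-difference noise, non-convergent fits, or fitted σ at or below
the sampling spacing raise an unresolved-particle error.

Population structure: diameters are split by an exhaustive two-means scan
over the sorted values, accepting the split when the between-group sum of
squares over the within-group mean square exceeds 4 (or when a bimodal
split is requested). Each mode reports mean ± SE (SD/√n). Image handling
averages the profile over 3 adjacent lines through the blob centroid along
the axis of maximal extent; multi-bead images are processed by local-maximum
detection with per-bead windows.

## Sparse-sampling pharmacokinetics

Each animal gives one aqueous-humor sample, so profiles are per-time-point
(mean, SD, n) summaries. Exposure is the linear trapezoidal `AUC` over
0–10 h; a zero concentration is prepended at t = 0 when absent (topical
instillation, no baseline drug). The AUC variance follows Bailer's
propagation with trapezoidal weights (endpoints: half the adjacent
interval; interior: half the span of the flanking intervals). Two
formulations are compared with `z = ΔAUC/√(V_a + V_b)` against the standard
normal; a t reference with Satterthwaite degrees of freedom pooled over the
per-time-point variance components is available via `use_t=True`. With the
study design emulated here (7 time points, n = 6), the normal reference's
simulated type-I error is ≈0.06 and the t reference's ≈0.05; the normal is
kept as the default, the t option documented for smaller designs. Relative
AUC is reported rounded to one decimal, matching the convention of the
source tables. Window endpoints falling between samples are linearly
interpolated (exact for the AUC; approximate for the variance, since
interpolated SDs are not independent — noted limitation).

## Synthetic data: what it emulates, and what it does not

Generator defaults reproduce the study conditions: dialysis sampled every
0.5 h over 0.5–5 h with 2% multiplicative assay noise; release sampled
every 30 min to 300 min with ~1 percentage-point additive noise and
[0, 100] clamping; PK sampled at 0.5–10 h with n = 6 animals per time and
15% relative assay SD; DLS correlograms on a 200-point log-spaced lag grid
(10⁻⁶–1 s) with coherence factor 0.8; bead images at 0.03 µm/pixel
(0.08 µm for beads ≥ 1 µm) with Poisson counting noise at a stated peak
SNR.

The PK shape is zero-order input (gel-erosion-controlled absorption) with
one-compartment first-order elimination (default k_el = 3 h⁻¹, reaching
95% of steady state within 1 h) — the simplest mechanism producing the
observed 1–10 h concentration plateau. The source study fits no
compartmental model; this generator is a testing stand-in, not an estimate
of ocular disposition. Likewise the generators assume independent Gaussian
assay errors, ideal Siegert statistics, and isotropic Gaussian bead images;
passing round-trip tests therefore demonstrates correctness of the
inference chain under the stated noise models, not robustness to real
instrument artefacts (baseline drift, number fluctuations, detector
afterpulsing, PSF asymmetry, non-sink dialysis).

Problem sizes used by the validation suites — 200 seeds per free-fraction
recovery condition, 1000 null simulations for test calibration, five-bead
averages per sizing condition — were chosen to bound the Monte-Carlo error
of each check well below its acceptance margin.

## Known limitations

- `K_m` absorbs all membrane/geometry physics; no receiving-phase
  accumulation model, so validity rests on the sink condition.
- The Higuchi fit is empirical; no erosion/diffusion PDE of the gel.
- One-point microrheology only; no inertial or compressibility
  corrections, and absolute moduli depend on the mixing proportions of
  tracer, mucin and NP, which only affect comparisons if they differ
  between arms.
- The two-means bimodality rule resolves mode ratios ≥ 2 reliably; closely
  spaced populations merge.
- The nanoparticle-batch characteristics table ships as measured fixture
  data (sizes, ζ, EE); the package never recomputes instrument readings.
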