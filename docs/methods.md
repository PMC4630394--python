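# Methods

This note records the models, defaults and design choices behind
`woodftir`, in the order data flows through the package.

## Synthetic spectra

The generator emulates a small hardwood calibration study: `n_samples`
(default 37) samples on a descending wavenumber grid from 4000 to 650 cm⁻¹.
The grid step is 2 cm⁻¹ (1676 points) — a typical ATR export interval for
instruments acquiring at 4 cm⁻¹ spectral resolution; it is configurable.

Each spectrum is

```
A(v) = b0 + b1·(v − 650)
     + Σ_c (pct_c/100) · Σ_{bands of c} a · exp(−(v − μ)²/(2σ²))
     + ε(v)
```

* **Band table.** Centers μ come from the shipped literature assignment
  table (31 rows over the four constituents). Overlapping assignments are
  kept — e.g. the 1510 cm⁻¹ aromatic band is claimed by both extractives
  and lignin, as it genuinely is in wood spectra — and assignments quoted
  as a range in the literature (1047–1004 cm⁻¹ for the cellulose C-O
  stretch) are stored as two separate rows rather than a guessed midpoint.
* **Band shape.** Gaussian with default σ = 12 cm⁻¹ and amplitude a = 1
  per unit mass fraction. Real mid-IR bands are Lorentzian/Voigt-ish and
  asymmetric; Gaussians were chosen because their closed-form derivatives
  make exact oracles possible in tests. Per-band width/amplitude overrides
  are supported.
* **Compositions.** Uniform per-constituent draws from plausible hardwood
  ranges (extractives 1–8, lignin 18–30, cellulose 38–52, hemicellulose
  18–32 % w/w — generator defaults, not literature claims); rows whose sum
  exceeds 100 % are rejected and redrawn (the remainder is ash/unresolved
  mass). Rejection is bounded and errors out for infeasible ranges.
* **Baseline and noise.** Per-sample linear baseline with intercept
  ~U(0, 0.05) absorbance and slope ~U(−2e−5, +2e−5) absorbance/cm⁻¹ —
  enough drift for the first derivative to demonstrably help — and iid
  Gaussian noise with default SD 0.005 absorbance.
* **Seeding.** One master seed feeds named substreams (compositions,
  baseline, noise; the calibration split uses a fixed distinct stage tag),
  so adding a stage never perturbs earlier draws and all outputs are
  bit-reproducible.

What the generator deliberately does **not** model: ATR penetration-depth
effects, band asymmetry, scattering, nonlinear detector response, or real
biological covariance between constituents. Passing tests therefore show
that the algorithms are implemented correctly and recover known structure,
not that real hardwood spectra behave this way.

## Pretreatment

Per-constituent modelling windows default to extractives 1750–1250,
lignin 1800–800, cellulose 1500–1000, hemicellulose 1750–800 cm⁻¹, applied
as closed intervals. The first derivative is Savitzky–Golay (default
window 9 points, polyorder 2) with respect to increasing wavenumber;
descending storage is handled internally and edges use the polynomial-fit
continuation, so the interior is exact for polynomials up to the fit
order. The derivative's peak-shift behaviour is window-dependent, which is
why both SG parameters are exposed. The window is cut before the
derivative by default (configurable; the difference is confined to the
window edges). No normalisation (SNV/MSC) is applied — only mean
centering, performed inside the fit functions and recorded on the model.

## Calibration

* **PCR** — SVD of the centered calibration spectra; y is regressed on
  the first k score columns; the coefficient vector is V_k·γ. Requesting
  k beyond the numerical rank is an error that reports the rank.
* **PLS1** — NIPALS with deflation of both X and y: per component
  w ∝ Xᵀy, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt; regression vector
  b = W(PᵀW)⁻¹q. For a single response each component converges in one
  step; an iteration cap exists only as a safety guard. PLS1 (not PLS2)
  because each constituent is modelled separately.
* **Component selection** — cross-validation on all samples
  (leave-one-out by default), choosing the smallest k whose RMSECV is
  within 5 % of the global minimum.
* **Split** — seeded random 31/6 split, redrawn (bounded) until the
  validation mean of every constituent is within 0.75 pooled SDs of the
  calibration mean; the tolerance is configurable and ∞ accepts the first
  draw.
* **Diagnostics** — r² is reported in percent as the squared Pearson
  correlation of fitted vs. reference values on the calibration set
  (a calibration-based, not cross-validated, r²; labelled as such).
  RMSEC and RMSEP use a 1/n denominator with no degrees-of-freedom
  correction. RPD = SD(y_val, n−1)/RMSEP; when RMSEP is exactly zero RPD
  is reported as undefined rather than infinite.
* **Interpretation profile** — for PLS1 the full regression-coefficient
  vector; for PCR the loading of a single "related" PC. Which PC relates
  to a constituent is not well defined a priori; the default picks the PC
  whose score column has maximal absolute correlation with y, with an
  explicit `pc_index` override.

## Integrity analysis

Peaks of |profile| (both signed lobes count, since coefficient plots have
negative excursions) are extracted with prominence ≥ 10 % of max |profile|
and minimum separation 16 cm⁻¹ — defaults tuned so a single-Gaussian
profile yields exactly one peak — and refined by 3-point parabolic
interpolation, since band centers rarely fall on grid points. Window-edge
peaks inherit scipy's convention that boundary samples cannot be local
maxima, so bands within ~2σ of a window edge are not reliably recoverable.

Matching to the constituent's literature assignments is greedy by
ascending |W − BA_L| with ties broken toward the higher-wavenumber
assignment; each peak and each assignment is used at most once, and pairs
farther than 50 cm⁻¹ apart are discarded. The tolerance exceeds the
largest first-derivative peak shift expected (≈35 cm⁻¹) while preventing
cross-band capture in the crowded 1300–1000 cm⁻¹ region.

Residuals are pooled across all constituent models (and pretreatment
modes) per algorithm before summary, giving one column per model family:
mean, sample variance (n−1), SD, and a 95 % CI using the t distribution
with n−1 df. The F-test reports both orientations (var_PLS/var_PCR with
the upper-tail p and its reciprocal with the lower-tail p — the layout
summary tables usually print) together with the α = 0.05 critical values;
the t-test supports pooled and Welch variants. The residual histogram
uses half-open bins (left, right] with edges at integer multiples of the
bin width. Peak positions are kept at sub-grid precision throughout and
rounded only for display.

## Replicated direction study

`direction_study` repeats the integrity stage over many (default 50)
seeded datasets: models fitted on all samples at the CV-selected k
(5-fold CV, k_max 8 inside replicates — chosen to keep a 50-replicate
study around a minute on one core), then the fraction of replicates with
var(R_PLS) > var(R_PCR) and an F-test on the pooled residuals. In this
idealised linear-mixture world the PLS coefficient profiles are usually
*more* precise than single-PC PCR loadings (the fraction is well below
0.5): with noiseless linear structure, the PLS vector concentrates on the
constituent's own bands, whereas a single principal component mixes
whatever covariance the random compositions happen to produce. Real
spectra — with correlated constituents, nonlinearity and instrument
artefacts — can push the comparison the other way, which is exactly why
the direction is an empirical question the machinery is built to answer,
not an assumption.

## Numerical choices and limitations

* Rank is determined from singular values with threshold
  max(n, p)·eps·s₁; NIPALS convergence tolerance 1e−12, cap 500
  iterations per component.
* Sample variance uses n−1 throughout; RMSE quantities use 1/n.
* All report JSON is written with sorted keys and full float precision,
  so identical configs give byte-identical files.
* The JCAMP-DX reader covers only single-spectrum AFFN `(X++(Y..Y))`
  data; compressed (SQZ/DIF/DUP) forms are rejected explicitly.
* Degenerate inputs: zero-variance y is an error for PLS1 and for the
  F-test; a constant coefficient profile yields an empty peak set; an
  all-zero composition renders the baseline-plus-noise spectrum.
* The matched-peak count per model is configuration-dependent (prominence,
  separation, tolerance); pooled n is therefore reported, never assumed.
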