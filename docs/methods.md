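# Methods

## Scope and data model

`ovofresh` analyses visible/NIR diffuse-transmittance spectra of intact
eggs against destructive freshness references. A `SpectraSet` holds an
absorbance matrix (rows = eggs) on a shared `WavelengthGrid` with
per-sample metadata (storage day, temperature group, replicate). Two
grid-construction conventions are supported because instrument software
disagrees about whether the nominal start point is emitted:
`count_floor_steps` (⌊(stop−start)/step⌋ points starting at
start + step; 550–985 nm at 0.21 nm → 2071 variables) and
`inclusive_points` (one more point, starting at start; 4000–10000 cm⁻¹
at 3.856 cm⁻¹ → 1557 variables). Both are kept explicit rather than
guessing a single convention.

Calibration/prediction splitting follows the every-third-sample rule:
after a stable sort by (storage day, replicate), samples at 1-based
positions 3, 6, 9, … form the prediction set. The sort key is fixed so
that a 15-egg day subgroup always contributes 10 calibration and 5
prediction eggs, giving 70/35 for the full 105-egg design.

## Freshness indices

Weight loss `WR% = 100·(W_org − W_tst)/W_org`, yolk index
`YI = h/d`, Haugh unit `HU = 100·log₁₀(h + 7.57 − 1.7·m^0.37)` with the
logarithm base 10 (the standard Haugh definition) and *m* the current
egg mass. Grading is AA for HU ≥ 72, A below; the boundary is taken
inclusive because only the boundary value itself is standardised.
Per-day summary tables report mean ± sd per (day, group) cell plus, per
group and index, the squared Pearson correlation of the per-day means
against storage day; this trend statistic is undefined (reported
missing) for a flat trend. Averaging the three albumen-height readings
happens at data collection; a `mean_albumen_height` helper is provided
but the formulas take the final height.

## Preprocessing

All pretreatments are per spectrum, or use a reference computed from
calibration rows only, so the prediction set never leaks into the
model:

- **SNV**: centre and scale each spectrum to unit sd (n−1 denominator —
  stated explicitly because both conventions circulate). Removes any
  positive affine scatter distortion: snv(a·x + b) = snv(x).
- **MSC**: ordinary least squares of each spectrum on a reference
  (default: calibration-mean spectrum), then inversion of the fitted
  slope and offset. Idempotent against a fixed reference.
- **Derivatives**: Savitzky–Golay with window 15 points and polynomial
  order 2 by default; plain differencing would amplify detector noise,
  so derivatives are always taken through the local polynomial fit.
  Output is scaled by the grid step (units per nm) and edges are
  evaluated from the edge polynomials so the output length equals the
  input length and interval bookkeeping downstream is unaffected.

The discrimination pipeline defaults to SNV, the calibration pipeline
to the first derivative. The split default is deliberate: derivative
filtering amplifies the noisy detector channels at the ends of the
wavelength range, which contaminates a whole-spectrum PCA, while the
interval search simply discards those regions, where the derivative's
band-sharpening then helps regression.

## Chemometric core

**PCA** is computed by SVD of the column-centred matrix; component
signs are fixed by making each component's largest-magnitude loading
positive so score plots reproduce across runs. Explained ratios are
per-component variances over total centred variance.

**PLS** is single-response NIPALS (PLS1). With one response the NIPALS
inner loop converges in a single pass, so each component is the
closed-form step w = X'y/‖X'y‖, t = Xw, p = X't/t't, q = y't/t't
followed by deflation; extraction stops early if the residual
covariance vanishes. Predictors and response are centred but not
autoscaled — derivative/SNV pretreatment already equalises scales and
no variance scaling is part of the reference procedure — though
`pls_fit(..., autoscale=True)` exposes it. The sequential model is
collapsed into one regression vector b = W(PᵀW)⁻¹q.

**Cross-validation** is leave-one-out ("full" CV) with re-centring and
refitting inside every fold. All n folds are advanced through the
NIPALS recursion together as one batched computation (an [n × n−1 × p]
tensor), which is algebraically identical to a per-fold loop — the test
suite checks exact agreement with a naive per-fold refit — and roughly
an order of magnitude faster, which is what makes the exhaustive
interval search tractable. The latent-variable count is chosen as the
argmin of RMSECV with ties broken toward fewer components.

**Si-PLS** partitions the variable axis into k equidistant intervals
(remainder-first: with r = p mod k the first r intervals get one extra
variable — any balanced rule is admissible, one is fixed for
reproducibility), enumerates all 2- and 3-interval combinations in
lexicographic order (C(25,2)+C(25,3) = 2600 at the default k = 25),
scores each by LOO RMSECV over 1..max_lv (capped by the combination's
column count), and keeps the global minimiser; ties break toward fewer
latent variables, then the lexicographically smallest combination.
Preprocessing is applied to the full spectrum before column subsetting
so derivative windows never straddle artificial interval edges. The
winning combination is reported as wavelength regions with adjacent
intervals merged. The default latent-variable cap is 15.

**LDA** uses class means with a pooled within-class covariance,
ridge-regularised by 1e-6·trace(Σ)/d by default — 13 score dimensions
estimated from 70 samples across 7 classes is near-singular territory —
and equal priors (the design is balanced; empirical priors are an
option). Prediction is the shared-covariance Gaussian discriminant with
ties broken toward the earlier class label. Percentages are reported to
one decimal, rounding half away from zero; reference count tables mix
truncation and rounding, so comparisons allow ±0.1.

## Synthetic storage trial

The generator emulates a two-regime cross-sectional trial: 15 eggs per
storage day (1, 3, …, 13) at 25 °C (regime A) and 4 °C (regime B),
105 eggs per regime. Per-day HU/YI/WR distributions are normal with the
published trajectory means and sds (weight loss truncated at zero);
destructive measurements are back-solved from the drawn indices (free
anatomical draws for original mass and yolk diameter, then stored mass,
albumen height and yolk height solved exactly) so the index formulas
recover the drawn values to machine precision without modelling egg
anatomy.

Spectra are a smooth baseline plus Gaussian absorption bands at 665,
760 and 930 nm — inside the wavelength regions where C–H/O–H/N–H
overtones respond to albumen protein and water changes — with
amplitudes linear in the egg state. The state has two parts:

1. the three drawn indices, via per-band coupling coefficients
   (absorbance per index unit), and
2. a **latent degradation state** (0 = fresh → 1 = fully aged over the
   13-day trial at 25 °C; only 0.04 at 4 °C), with its own band
   couplings of alternating sign.

The latent state is the package's model of the physicochemical aging —
albumen liquefaction, water migration — that spectra sense directly and
the destructive indices track only noisily. It is what makes the
regime contrast reproducible: at 25 °C the state advances ~0.17 per
2-day step against a per-egg sd of 0.025, so days separate; at 4 °C
refrigeration arrests it, and the small index-coupled signals that
remain sit below the noise floor. Without it, the within-day index
scatter alone caps day discrimination near 80% and leaves the
refrigerated group discriminable through its monotone weight-loss
trend, contradicting the qualitative pattern the pipeline is supposed
to recover.

Degradation is generated per egg as the day mean plus N(0, 0.025)
noise and couples to the bands with coefficients (0.15, −0.12, 0.18);
index couplings are an order of magnitude smaller in amplitude terms.
These magnitudes, like all generator noise scales, were fixed once
while designing the generator and are documented in `SimConfig`.

Nuisance structure comprises exactly the artifact families the analysis
stages exist to handle:

- per-sample multiplicative scatter (log-normal, log-sd 0.08) and
  additive offset (sd 0.04) — removed by SNV/MSC;
- a smooth per-egg structure term (five broad fixed Gaussians with
  random amplitudes, sd 0.003) — shell-to-shell variability that
  survives scatter correction;
- freshness-blind interferent bands at 585 nm (shell-pigment-like,
  amplitude sd 0.04) and 850 nm (sd 0.03) — regions interval selection
  must learn to avoid;
- white detector noise (sd 0.002 per variable) rising up to 20× at the
  grid edges below ~610 nm and above ~955 nm, emulating the detector
  sensitivity fall-off that keeps informative regions away from the
  range ends.

All randomness flows through a single `numpy` Generator seeded from
`SimConfig.seed`; a given configuration is bit-reproducible.

What passing recovery tests do show: the pipeline finds planted
informative regions, beats full-spectrum PLS when irrelevant regions
are genuinely disruptive, and reproduces the qualitative
room-temperature/refrigerated contrast. What they do not show: that
these conclusions transfer to real instrument data — the generator's
bands are idealised Gaussians, its index-to-spectrum map is exactly
linear (the model class PLS assumes), scatter is exactly the affine
family SNV/MSC invert, and absolute absorbance levels are free
parameters never calibrated to an instrument.

## Problem sizes and numerical choices

Recovery sweeps run at a scaled-down but structurally faithful size:
the full 105-egg design with the 550–985 nm axis thinned to 1.05 nm
(414 variables), 10 intervals, LOO CV and a 10-LV cap; these sizes are
the package's default validation conditions and keep a 20-seed sweep in
the low minutes. Zero-variance spectra, constant responses, degenerate
MSC slopes (|a| < 1e-12), non-positive Haugh log arguments and singular
pooled covariances all raise a `ValidationError` naming the offending
quantity. NIPALS extraction stops when the residual covariance norm
falls below 1e-13 of its initial scale; LOO folds that stop early
simply carry their last prediction forward to higher LV counts.

## Known limitations

- PLS1 only; multi-response PLS2, kernel PLS and venetian-blind CV are
  out of scope, as are moving-window or genetic-algorithm interval
  selection.
- The discrimination and calibration analyses assume the balanced
  cross-sectional design; unbalanced classes work (empirical priors)
  but are untested against reference counts.
- The generator draws the three indices independently within a day;
  real within-day correlations (e.g. HU–WR) are not emulated.
- Diffuse-reflectance mode appears only as a grid definition; no
  reflectance spectra are simulated.
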