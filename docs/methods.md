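# Methods

This note documents the models behind `qclspec`, the parameters that matter,
the numerical decisions taken where the design was genuinely open, and what
the synthetic study can and cannot say about real measurements.

## 1. Prism ray optics (`qclspec.optics`)

The ATR element is a trapezoidal ZnS prism, modelled in its 2-D cross
section: the geometry is translationally invariant along the prism width, so
the bounce pattern of a meridional ray is planar. The central ray enters at
the midpoint of the 45° entry facet at normal incidence (so it propagates
undeviated at the facet angle) and is traced by exact specular reflection
between the top and bottom facets until it leaves through the exit facet.
Total internal reflection is checked at every top/bottom incidence against
the critical angle asin(n₂/n₁) ≈ 36.2° for n₁ = 2.2 (ZnS), n₂ = 1.3 (water
in the mid-IR); both indices are dispersionless defaults and configurable.

For the default prism (top facet 24 mm, height h = 2.4 mm) the trace gives
9 reflections (5 on the sample facet) and a path of 21.6·√2 ≈ 30.55 mm. The
midpoint-entry geometry has a closed form: reflections occur every h of
horizontal travel starting h/2 from the entry point, so N = L_top/h − 1 and
the path is N·h·√2. Halving the height to 1.2 mm therefore gives N = 19 —
the sample-facet count exactly doubles (5 → 10) while the path grows only
5.6% (22.8·√2 mm): more sampling interactions at nearly unchanged material
absorption. Entry-offset sensitivity: moving the entry point off the facet
midpoint changes where the final partial segments fall and can change N by
±1; the 9/5 pattern is specific to midpoint entry.

With a nonzero fiber numerical aperture the tracer adds eight marginal rays
(beam-edge offsets × the internal divergence half-angle asin(NA/n₁) ≈ 7.8°
for NA = 0.30) and reports the worst-case path difference against the
central ray. For the default prism this is ≈3.7 mm — dominated by the
1/cos(α) path stretching of the tilted rays over the full 30 mm trace. A
focused 3-D treatment that weights rays by the fiber's intensity profile
would report a much smaller effective spread; we state our 2-D worst case
and do not pin it further.

**Evanescent sampling.** At each sample-facet reflection the field probes
the solution to the Harrick penetration depth
d_p = λ/(2π·n₁·√(sin²θ − (n₂/n₁)²)). At these indices and θ = 45°,
d_p ≈ 1.55–2.0 μm over 1200–925 cm⁻¹. The absorbance-equivalent *sampling
depth* is taken as `effective_depth_factor` × d_p with a default factor of
2.6, calibrated so the sampling depth spans 4.0–5.2 μm across the band —
the conventional "effective depth ≈ 3·d_p" scale for bulk absorbers. The
factor is a calibration, not a derivation; it is exposed in the
configuration. The ATR interaction length is the sampling depth times the
sample-facet reflection count: ≈20–26 μm, i.e. ≈1/7 of the 165 μm
transmission gap at mid-band, which fixes the ≈7× absorbance contrast
between the two setups.

## 2. Experiment design (`qclspec.design`)

The 25-sample calibration set covers four analytes (glucose 0–800, albumin
0–6000, urea 0–200, lactate 0–90 mg/dL). Each concentration is scaled by its
range to a pseudo-component; a fifth closing component (water/buffer
diluent) brings every sample onto the unit simplex, as Scheffé mixture
models require. The model is the quadratic Scheffé polynomial — q linear
terms plus q(q−1)/2 cross terms, no intercept, no pure quadratics (both are
confounded with the listed terms on the simplex): 15 coefficients for q = 5.

A-optimality minimises trace((XᵀX)⁻¹), the average coefficient variance.
The optimiser is a plain Fedorov exchange over a degree-4 simplex-lattice
candidate set (70 points): from a random full-rank start, the single
point/candidate swap with the largest criterion reduction is applied until
no swap improves, with 10 random restarts (seeded, deterministic). Design
rows are kept unique. The exchange descends monotonically by construction;
on the default problem it beats the best of 1000 random full-rank designs
by a wide margin (criterion ≈179 vs ≈290) and matches exhaustive search on
saturated toy problems. The real study's candidate set and algorithm are
unpublished, so our 25 compositions are *a* quadratic-Scheffé A-optimal
design, not *the* original one.

## 3. Instrument simulator (`qclspec.instrument`)

The simulator emulates the laser/detector chain at pulse resolution: one
intensity per pulse (the digitiser's intra-pulse waveform is out of scope),
100,000 pulses per 1 s scan over 1200 → 925 cm⁻¹.

**Deterministic structure.** The clean signal is
emission envelope × 10^(−A_total) with
A_total(ν̃) = [Σₐ εₐ(ν̃)·cₐ + a_w(ν̃)]·L(ν̃). The envelope is a wide Gaussian
(centre 1080 cm⁻¹, width parameter 350 cm⁻¹, relative intensity 0.82–1.0
across the scan) — a smooth plateau-like gain curve typical of an EC-QCL
operated in the middle of its tuning range. The water term
a_w(ν̃) = 0.004 + 0.008/(1 + exp((ν̃−970)/12)) AU/μm produces ≈0.7 AU of
background absorbance at mid-band and ≈1.9 AU at 925 cm⁻¹ for the 165 μm
gap, which is what amplifies noise at the red end of transmission spectra;
the ≈25 μm ATR interaction length keeps the same term below 0.3 AU, so the
amplification is much weaker there.

**Band library.** Gaussian bands (FWHM 35–100 cm⁻¹): lactate at 1040 and
1124 cm⁻¹ and urea at 1160 cm⁻¹ at their known solution-phase positions;
glucose at 1036/1080/1110/1152 cm⁻¹ and a broad two-band albumin profile
(1075/1160 cm⁻¹) from standard mid-IR literature positions. Peak
absorptivities are calibrated so a full-range sample at 165 μm gives peak
absorbances of ≈0.10 AU (glucose), ≈0.11 (albumin), ≈0.024 (lactate),
≈0.026 (urea). The library is a synthetic stand-in with realistic overlap
structure, not a fit to measured spectra — real band shapes, ATR band
distortions and anomalous-dispersion effects are deliberately out of scope.

**Noise terms and defaults.**

| term | default | meaning |
|---|---|---|
| `per_pulse_rsd` | 3.54% | multiplicative pulse-to-pulse noise; back-derived so 255×10 averaging lands at the characterised 0.07% RSD |
| `scan_offset_sd` | 0.1% | multiplicative intensity offset drawn once per scan |
| `scan_shift_sd` | 1 bin | integer spectral-bin jitter of the axis per scan (tuning-start jitter) |
| `detector_noise_sd` | 5·10⁻⁴ | additive, in units of the envelope peak |
| `series_shift_sd` | 0 | sub-bin axis offset per series (calibration drift) |
| `series_pathlength_sd` | 0 | fractional pathlength scale per series (gap/contact re-assembly) |
| `series_baseline_sd` | 0 | smooth per-series absorbance baseline on sample measurements (AU) |

The three series-level terms default to zero: the baseline study conditions
are pulse noise, scan offsets and axis jitter. They exist to model
between-series drift. A relevant finding from their analysis: axis shifts
and pathlength scales act (to first order) multiplicatively on the analyte
signal, so they degrade leave-one-out and leave-one-series-out validation
*equally* — a single global linear model cannot adapt per series whether or
not the series was seen in training. Only the additive baseline term opens
a genuine generalisation gap: when a series is present in the training set,
PLS orthogonalises its coefficient vector against that series' baseline
shape; an unseen series contributes an unseen direction, and its projection
onto the regression vector becomes a systematic error. With a 0.002 AU
baseline the LDOCV/LOOCV RMSECV ratio is ≈1.5.

## 4. Signal processing (`qclspec.processing`)

The chain is: 255-pulse binning → chi-squared scan alignment → 10-scan
averaging → sample/background ratio.

* **Binning.** 100,000 pulses yield 392 complete 255-pulse bins; the last
  two bins at the 925 cm⁻¹ end are dropped to reach the configured 390
  points (≈0.70 cm⁻¹ spacing). Axes are stored ascending; the scan
  direction lives in metadata.
* **Scan-to-scan alignment.** Each scan is aligned to the first scan of its
  measurement by grid search over integer bin shifts with a closed-form
  additive intensity offset (the mean difference over the overlap); ties
  break toward the smaller |shift|. Bins uncovered by the shift are filled
  from the reference scan — for repeat scans of identical content the
  reference bin is an unbiased draw of the missing one, whereas replicating
  the nearest edge value was found to imprint the steep water-edge
  intensity slope into the average (edge artifacts up to 0.007 AU, as large
  as the entire ATR glucose signal).
* **Sample-to-background alignment.** Here the two spectra differ by
  genuine analyte absorption, which changes the estimator twice over.
  First, no additive offset is fitted: it would absorb part of the
  absorption signal (and break the exact noiseless limit). Second, the
  shift is *not* chosen by the intensity chi-squared: that estimator can
  lower its residual by sliding absorption dips onto low-intensity regions
  of the background, which misaligns the sharp water edge and imprints
  ≈0.02 AU of its derivative onto the absorbance (reproducibly, even
  without noise). Instead, a misalignment by s bins adds approximately
  s·d(log₁₀I₀)/dbin to the absorbance, so candidate shifts are scored by
  the squared absorbance weighted by that derivative squared — a matched
  filter concentrated at the water edge and envelope roll-off, where the
  analytes are silent. The few edge bins uncovered by the winning shift are
  replaced by the nearest valid absorbance (absorbance is flat at the
  edges, because the steep water/envelope slopes cancel in the ratio).
* **Absorbance.** A = −log₁₀(I/I₀), base 10; non-positive intensities raise
  an error naming the offending wavenumber.

Two limits of the chain are worth stating. (i) The first scan's own axis
jitter has no in-pipeline reference, so jitter recovery is exact only up to
one global integer-bin shift of the whole spectrum — a real instrument
resolves this with an external wavelength calibrant. (ii) The binned
forward model is not exactly linear in concentration: averaging
transmittance across a 0.7 cm⁻¹ bin adds a ≈5·10⁻⁷ AU quadratic term, so
the "noiseless" pipeline recovers concentrations to ≈10⁻⁴ mg/dL, not to
machine precision.

## 5. Chemometrics (`qclspec.chemometrics`)

Preprocessing is Savitzky–Golay smoothing (width 9, polynomial order 2 —
the order is our choice; the width is the study's) followed by per-feature
centring and scaling to unit variance, with the statistics always taken
from the training fold only. Feature scales are floored at 10⁻³ of the
dominant standard deviation: channels whose variance is < 10⁻⁶ of the
largest carry no usable signal, and scaling them up would amplify
numerical/discretisation residue into unit-size noise features.

PLS uses the NIPALS recursion, deterministic throughout (the multi-response
variant starts from the largest-variance response column and iterates to
1e-10 relative tolerance). One model per analyte (PLS1) is the default;
PLS2 is available. Rank exhaustion stops extraction with a warning and
records the achieved component count. One fit per training fold stores the
coefficient path for all component counts, so cross-validation scores
latent-variable counts 1–8 from a single model per fold and flags the
minimum-RMSECV choice.

Fold schemes: LOOCV (one measurement per fold); L5OCV (blocks of five
consecutive sample ids within each series — the grouping is our choice, a
seeded random grouping is available); LDOCV (one fold per measurement
series, requiring at least two series). RMSECV is the root-mean-square
error over all pooled held-out predictions; R² is computed on the same
pooled predictions about the reference mean.

## 6. The default synthetic study (`qclspec.pipeline`)

The default experiment is the full study layout: one 25-sample design,
four measurement series (two per day on two days), both setups, ten scans
per measurement, one fresh water background per sample measurement — 200
sample and 200 background measurements in total, ≈4·10⁸ simulated pulses,
about a minute on one CPU. All randomness derives from one root seed via
spawned generator streams; rerunning with the same seed reproduces the
results byte for byte.

Typical results at the calibrated defaults (seed 7): glucose L5OCV RMSECV
≈4 mg/dL (R² ≈ 1.000) in transmission and ≈18 mg/dL (R² ≈ 0.992) in ATR,
with predicted-vs-reference slopes within 1% of unity; albumin behaves
analogously at its 7.5× wider range. The ≈4× transmission/ATR error ratio
follows directly from the ≈7× signal contrast at a shared ≈0.0003 AU noise
floor, partially recovered by the multivariate fit. In transmission, five
latent variables reach R² > 0.99; the ATR setup needs six at this band
overlap — with a 7× weaker signal PLS needs the extra component to finish
separating four overlapping analytes from the offset/drift directions.

**What passing tests do and do not show.** The simulator reproduces the
statistical structure the processing chain assumes — Beer–Lambert
linearity, 1/√N pulse-noise averaging, water-background noise
amplification, axis jitter, scan offsets, series drift — so the tests
validate the *pipeline*: optics arithmetic, noise bookkeeping, alignment,
design optimality and regression machinery. They do not validate the
spectroscopy of real solutions: real band shapes and intensities, ATR band
distortions, temperature and pH effects, detector nonlinearity and
fiber-coupling drift are all absent, and the real study's cross-validation
errors (roughly 8–18 mg/dL for glucose depending on setup and scheme) serve
only as a plausibility scale for the synthetic ones, not as targets.

## 7. Known limitations

* 2-D ray optics; no polarisation-resolved Fresnel coefficients, no
  focusing model for the divergent-beam path spread.
* Dispersionless refractive indices; the effective-depth factor is a
  calibration constant, not derived from the field distribution.
* Gaussian bands and a synthetic water model; no ATR band-distortion
  physics.
* One intensity per pulse; the 80 MS/s intra-pulse waveform and digitiser
  are out of scope.
* Wavelength calibration is only relative (global-shift ambiguity above).
* The mixture design differs from the unpublished original; only its
  optimality class matches.
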