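# qclspec

Simulation and chemometric analysis of fiber-coupled, pulsed quantum-cascade-laser
(QCL) mid-infrared spectroscopy for multianalyte quantification in aqueous
solutions — glucose and albumin with lactate and urea as interferents, measured
both by attenuated total reflection (ATR) on a ZnS prism and by direct
transmission through a 165 μm fiber gap.

## Who this is for

Researchers developing MIR biosensors who want a tested, end-to-end software
model of such a spectrometer: the prism optics that set the ATR sensitivity,
the pulse/scan noise structure of a swept EC-QCL, the signal-processing chain
that turns raw pulse trains into absorbance spectra, and the partial
least-squares (PLS) calibration that turns spectra into concentrations. All
measurements are synthetic — the package contains a first-class instrument
simulator — so every stage can be validated against known ground truth.

## The model in brief

**ATR optics.** The beam enters a trapezoidal ZnS prism (top facet 24 × 6 mm,
height 2.4 mm, 45° facets, n₁ ≈ 2.2) normal to the entry facet and bounces
between the parallel facets by total internal reflection: 9 reflections, 5 on
the sample-carrying top facet, ≈30.5 mm internal path. At each sample-facet
reflection the evanescent field probes the solution to the Harrick penetration
depth

  d_p = λ / (2π n₁ √(sin²θ − (n₂/n₁)²)),

giving an effective sampling depth of ≈4–5.4 μm over 1200–925 cm⁻¹ and a
5-reflection interaction length of ≈20–27 μm — about 1/7 of the 165 μm
transmission gap, which is why ATR absorbances are ≈7× weaker.

**Instrument.** A pulsed EC-QCL (500 ns, 100 kHz, 5% duty cycle) sweeps
1200 → 925 cm⁻¹ at 275 cm⁻¹/s: 100,000 pulses per 1 s scan. Samples follow
Beer–Lambert absorption, A(ν̃) = Σₐ εₐ(ν̃)·cₐ·L(ν̃), on a water background that
absorbs steeply below 970 cm⁻¹. Noise terms: multiplicative pulse-to-pulse
intensity noise (3.54% RSD), a per-scan intensity offset, integer-bin tuning
jitter of the wavenumber axis, additive detector noise, and optional
series-level drift terms.

**Processing.** Spectra are formed by averaging 255 pulses per spectral bin
(390 points, ≈0.7 cm⁻¹ spacing) and 10 scans per measurement, aligning scans
by chi-squared minimisation over integer bin shifts, and ratioing against a
water background: A = −log₁₀(I/I₀). The 255 × 10 = 2550-fold averaging takes
the 3.54% per-pulse RSD to ≈0.07%, i.e. ≈0.0003 absorbance units.

**Chemometrics.** Savitzky–Golay smoothing (width 9) and per-feature
standardisation, then NIPALS PLS regression (one model per analyte), scored by
RMSECV and R² under leave-one-out (LOOCV), leave-5-out (L5OCV) and
leave-one-series-out (LDOCV) cross-validation. The 25-sample calibration set
is a quadratic Scheffé mixture design made A-optimal by Fedorov exchange.

## Worked example

```python
from qclspec import PrismGeometry, trace_prism, penetration_depth
from qclspec.pipeline import StudyConfig, run_study

prism = PrismGeometry()  # 24 x 6 mm top facet, 2.4 mm height, 45 deg, n=2.2
trace = trace_prism(prism, beam_diameter=400, numerical_aperture=0.30)
print(f"reflections: {trace.total_reflections} "
      f"({trace.top_facet_reflections} on the sample facet), "
      f"path {trace.propagation_length:.1f} mm")

ev = penetration_depth(prism, wavenumber=1080.0)
print(f"d_p {ev.penetration_depth:.2f} um, sampling depth {ev.sampling_depth:.2f} um, "
      f"interaction length {ev.interaction_length:.1f} um")

manifest, results = run_study(StudyConfig(), seed=7)   # full 2-setup study, ~1 min
for setup in ("transmission", "atr"):
    g = results[setup]["l5ocv"]["glucose"]
    print(f"{setup:12s} glucose L5OCV: RMSECV {g['rmsecv']:5.1f} mg/dL, "
          f"R2 {g['r2']:.3f}, {g['n_lv']} LVs")
```

prints

```
reflections: 9 (5 on the sample facet), path 30.5 mm
d_p 1.72 um, sampling depth 4.48 um, interaction length 22.4 um
transmission glucose L5OCV: RMSECV   4.0 mg/dL, R2 1.000, 8 LVs
atr          glucose L5OCV: RMSECV  18.5 mg/dL, R2 0.992, 8 LVs
```

The prism trace reproduces the 9/5 reflection pattern and ≈30.5 mm path; the
evanescent interaction length of ≈22 μm against the 165 μm gap explains the
≈7× absorbance contrast between the setups, and that contrast in turn explains
why glucose cross-validation errors are a few mg/dL in transmission but
~15–20 mg/dL in ATR over the 0–800 mg/dL range (both well inside 5% of range,
with R² > 0.99).

A command-line interface mirrors the stages:

```bash
qclspec design --n 25 --seed 7 -o design.csv
qclspec simulate --design design.csv --setup atr --scans 10 --seed 11 -o raw/
qclspec process --raw raw/ -o spectra/
qclspec quantify --spectra spectra/ --scheme l5ocv -o results.json
qclspec study run --seed 7 -o out/        # everything end to end
qclspec optics trace --na 0.30            # prism ray trace
```

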