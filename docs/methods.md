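# Methods

This note records the models, parameter choices and numerical decisions
behind `aquafuzz`, in the order the assessment chain runs.

## Spectra and instrument model

All computation happens on a uniform wavelength grid, by default
225–900 nm at 1.5 nm (451 points), matching the emulated spectrometer.
Inputs on other grids are linearly resampled onto it first; resampling
refuses to extrapolate.  Intensities are raw detector counts; the
detector clips at 40,000 counts and any spectrum touching that ceiling
carries a saturation flag through the whole chain.  Spectrum files are
two-column CSV with `#`-prefixed header lines (modality, acquisition
temperature, blank flag, provenance steps) — self-describing and
diff-able; a JSON manifest groups the four sample spectra and their
pure-water blanks into a measurement bundle.

## Preprocessing

Order of operations: blank handling → temperature normalization →
zero-phase filtering → (UV/Vis only) turbidity compensation.

**Blank handling.**  UV/Vis counts become absorbance
A(λ) = log₁₀(I₀/I) — base 10, the absorbance convention.  Sample
intensities ≤ 0 are clipped to a configurable epsilon (default
10⁻² counts) before the division and flagged; a blank containing
non-positive values is a calibration error, since the blank defines the
reference intensity.  Emission channels subtract the blank,
F = I − I₀; negative values are preserved.  An optional baseline-shift
step (applied by default in the bundled chain) subtracts the 5th
percentile when it is negative, absorbing the slight negative offsets
submersible-probe measurements show after blank subtraction.

**Temperature.**  Each light source drifts with temperature; the model
is a multiplicative response linear in (T − 21.3 °C) per modality, and
the correction divides by it.  The default slopes (−0.35 %/°C UV/Vis,
−0.60 %/°C 440 nm LED, −0.50 %/°C 590 nm LED, −0.45 %/°C 850 nm LED)
are representative LED/lamp thermal coefficients; real deployments
supply calibrated values via configuration.  The linear model is treated
as valid to 30 °C; above that the correction is still applied but a
warning is attached, since non-linear thermal effects are expected.

**Filtering.**  A 30th-order (31-tap) linear-phase FIR low-pass with
passband edge 0.1 f_s and stopband edge 0.3 f_s, designed as a
Hamming-windowed sinc with the cutoff midway between the band edges and
taps renormalized to exactly unit DC gain.  It is applied forward and
backward (`filtfilt`) with odd-symmetric edge extension of 3× the filter
length, so the net phase is zero and symmetric peaks keep their argmax.
The design method and edge handling are implementation choices; only
the order and band edges are fixed by the instrument's processing spec.
Steady-state attenuation at 0.45 f_s is below 10⁻⁴ (squared single-pass
response); edge transients are confined to the extension zones.

**Turbidity.**  The mean blank-subtracted scattered-light intensity over
850 ± 10 nm divided by a calibration slope gives the turbidity estimate
in FNU, floored at 0.  The default slope is 1500 counts/FNU, placing
band saturation near 24 FNU — just above the ~20 FNU validity bound of
the compensation, so the low-confidence regime (20–24 FNU) is
observable before the estimate degenerates entirely; a saturated band
raises an error instead of returning a number.  Compensation subtracts
fnu · profile(λ) from the absorbance, where the per-FNU profile defaults
to a 1/λ shape normalized to 0.005 absorbance units at 850 nm
(particle scattering losses fall with wavelength); real calibrations
replace it via configuration.  Above 20 FNU the result is flagged
low-confidence but still computed.

## Reference spectra and R² features

A reference spectrum is a sum of Gaussians a·exp(−(λ−λ₀)²/c) with the
width c in nm² (denominator form, c = 2σ²).  Construction is iterative:
detect the tallest remaining peak, fit one Gaussian to it by least
squares in a ±3σ window (σ initialized from the half-maximum width; the
window limits coupling between overlapping bands), subtract, repeat.
The loop stops when the residual maximum falls below 2 % of the original
maximum, when no peak passes the significance thresholds, or after 12
components; a candidate component is only accepted if it does not
increase the residual RMS, so the residual RMS is non-increasing by
construction.  Peak significance uses two thresholds on a robust noise
scale (1.4826 × MAD of first differences, divided by √2): prominence
above 3× noise and height above 5× noise.  The height criterion matters
because the peak-to-valley prominence of pure white noise spans ~6σ —
prominence alone would fit noise wiggles indefinitely.  A spectrum with
no significant peak at entry raises an empty-reference error.

Scoring fits only the scale k, closed-form least squares
k = ⟨s,r⟩/⟨r,r⟩, and reports R² = 1 − SS_res/SS_tot over the **full**
wavelength grid (full-spectrum conformity, not peak regions).  Negative
R² — the reference describes the spectrum worse than its mean — floors
to 0; this "zero on poor fit" convention also covers missing channels
and degenerate references, so a 0 feature always means "this substance
is not recognizable in this channel".  R² is scale-invariant, which is
the point (concentration moves k, not R²) and also a limitation (see
feature space below).

The default library designates one reference per channel: the
chlorophyll-type emission (440 nm channel), the chlorophyll absorbance
(UV/Vis), the phycocyanin emission (590 nm) and the scatter line
(850 nm).  Each reference is built from a clean mid-concentration
synthetic training spectrum (25 % spinach dilution, 250 mg/L
phycocyanin, 10 FNU) run through the full preprocessing chain — the
same path a real training spectrum takes.

## Measurement uncertainty

Standard uncertainties combine by root-sum-of-squares; the expanded
uncertainty is U = k·u_c with coverage factor k = 2 (~95 %).  The
instrument-level budgets are not re-derived here; their published
results enter as configuration defaults: U = 5.90 % of the R² scale for
UV/Vis and 7.11 % for the fluorescence and scatter channels.  The
turbidity feature uses U = 0.5 FNU, a representative nephelometric
repeatability at low turbidity.

## Fuzzy pattern classifier

The one-dimensional membership function is the Bocklisch form of the
Aizerman potential function,
μ(x) = a / (1 + (1/b_s − 1)(|x − x₀|/c_s)^{d_s}) with side s chosen by
the sign of x − x₀: a is the height at the representative value x₀,
b the fuzziness (the membership reached at distance c), c the scope of
uncertainty, d the flank slope.  With the training defaults a = 1,
b = 0.5, d = 2 the flank is a Cauchy-like quadratic: μ(x₀ ± c) = 0.5,
μ(x₀ ± 2c) = 0.2.  Dimensions aggregate by the N-fold arithmetic mean —
idempotent, bounded by the per-dimension extremes, and strongly
compensatory: one dead dimension costs 1/N of the membership, never a
veto.  The aggregation is pluggable should a γ-parameterized
compensatory operator be needed.

Training derives each class automatically from its labeled objects:
per dimension x₀ is the member mean, and the scopes extend to the
extreme member values plus the expanded uncertainty,
c_l = (x₀ − min) + U and c_r = (max − x₀) + U.  Consequences: a
singleton class keeps scope U rather than collapsing to a point, every
training member retains membership ≥ b in its own class in every
dimension, and noisier channels (larger U) yield fuzzier classes.
Whether x₀ should be the mean rather than a mode or expert value is a
genuinely open choice; the mean is used because the training classes
are unimodal by construction and it keeps training closed-form.  Exact
membership ties break toward the earlier class in the canonical order
(blue algae, green algae, moderate turbidity, high turbidity/foreign,
unknown substance, no substance) and are reported.

**Feature space.**  The published conformity features are the four
per-channel R² values, and classifiers over exactly those four are used
whenever externally tabulated features are evaluated.  The full
pipeline adds two dimensions, both forced by identifiability:

* **Turbidity (FNU).**  R² measures shape conformity and is
  scale-invariant, so a 3 FNU and an 18 FNU sample fit the scatter
  reference equally well — the moderate- and high-turbidity classes are
  *indistinguishable* in any set of R² features.  The turbidity
  estimate, which the chain computes anyway, is the natural separating
  dimension.
* **Foreign-substance conformity.**  A substance whose spectra match
  none of the designated references (uranine is the training example)
  floors to 0 in every R² feature — exactly the pure-water signature.
  The R² of the 440 nm channel against the uranine reference separates
  the two: ≈ 1 for the dye, < 0.3 for water.

Class membership functions remain strictly one-dimensional per feature;
the feature list is configuration (`include_turbidity_feature=False`
recovers the pure four-feature classifier).

## Synthetic data generator

The generator is the testbed for every stage and defines the study
conditions.  Per channel it emulates: a noise-free blank (deuterium–
tungsten lamp curve for UV/Vis; stray excitation peak plus 200 dark
counts for the LED channels), substance signals as Gaussian band sums,
scattering proportional to total FNU through the same calibration slope
the estimator inverts, the multiplicative thermal response the
correction divides out, additive Gaussian counts noise (default
σ = 20 counts, a typical miniature-CCD noise floor), and clipping at
40,000 counts.  The UV/Vis sample is I₀·10^(−g(T)·A_total) with A_total
the substance absorbance plus the turbidity profile — so the
preprocessing chain inverts the forward model exactly in the noise-free
limit, and to ≤ 5 % relative RMS under default noise.

Substance fingerprints are spectroscopically motivated conventions, not
instrument measurements: chlorophyll-type extract absorbs at 270 (DOM),
435 (Soret) and 675 nm (Q) and emits at 680 nm with a 735 nm vibronic
shoulder; phycocyanin emits at 650 nm under 590 nm excitation, responds
below 10 % of that under 440 nm excitation (including the chlorophyll
remnant at 680 nm that cyanobacteria-derived pigment preparations
carry), and absorbs at 620 nm plus the 280 nm aromatic protein band;
uranine emits at 515 nm with the typical red tail and absorbs at 490
and 240 nm; the turbidity standard only scatters.  Sample heterogeneity
is emulated by per-bundle band jitter (centers ±2 nm, widths ±10 %,
amplitudes ±8 %) plus a multiplicative gain jitter (σ = 3 %) between
replicates.  One root seed drives spawned per-bundle substreams, so
corpora are bit-reproducible and order-independent.

The training corpus mirrors the documented campaign: 40 spinach
dilutions log-spaced over 0.25–40 % (green algae), 22 phycocyanin
solutions over 10–700 mg/L (blue algae), 12 + 12 turbidity standards at
2–10 and 10.5–20 FNU, 11 pure-water and 22 uranine samples — 119
bundles, all at 22 ± 0.3 °C with ambient turbidity up to 0.2 FNU.

**What the generator does not emulate** — and hence what passing tests
do not establish about field data: excitation–emission matrix structure,
stray light and detector non-linearity below saturation, multiple
scattering above ~20 FNU, biofouling and drift, colored-DOM
fluorescence background, and mixed natural communities whose pigment
ratios differ from the single-substance training classes.  End-to-end
label recovery of 100 % on held-out synthetic corpora shows the chain is
self-consistent under the stated noise model, not that field samples
classify this well.

## Problem sizes and determinism

Default runs use the 451-point grid, the 119-bundle corpus and a
same-sized held-out set; training and assessment complete in seconds on
one CPU, and the Gaussian-fit recovery study uses 100 seeded spectra per
noise level.  All randomness flows from explicit integer seeds; repeated
runs are byte-identical, including written model files.

## Known limitations

* The published classifier parameter table is not machine-readable
  here, so field-campaign membership values are reproduced only up to
  the classifier trained on the synthetic corpus; assignments (Class 1
  for the August objects, Class 2 for September) reproduce robustly,
  the membership magnitudes land within ≈ 0.05–0.3 of the published
  figures depending on the object.
* The fifth published classifier dimension is not identified in the
  source material; the turbidity estimate is adopted on identifiability
  grounds (above).
* The turbidity compensation profile is a stand-in shape; deployments
  should supply a calibrated per-wavelength profile.
* Class scopes derived from min/max spread are sensitive to outlier
  training objects; a quantile-based spread would be more robust but is
  not what the mean-plus-spread training rule specifies.
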