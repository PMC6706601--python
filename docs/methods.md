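# Methods

This note records the model behind the package, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer should know about.

## Signal model and its assumptions

The measured quantity for every target channel is the internal-standard (IS)
ratio A(ch) = I(ch)/I(216), the peak height at the channel divided by the
peak height of the CDNT radical anion in the same spot. The package assumes

A(ch) = a(ch) + r(ch)·c(own group) + Σ_g κ(ch, g)·c(g) + noise,

linear in every concentration over the working range, with cross-terms κ
non-zero only where another analyte's ion lands on (or feeds) the channel.
In this assay the single modelled interference is TNT into the ADNT channels
m/z 197 and 181. Isomer groups (2-/4-ADNT; 2,4-/2,6-DNT) share channels and
enter through their summed concentration; all reported results are therefore
isomer sums.

Underlying assumptions: the IS is present in every deposit at a known
constant level (deposits without a detectable IS peak are rejected, not
guessed at); spot-to-spot variability acts multiplicatively and identically
on all peaks of a spot, which is exactly the component the IS ratio cancels;
no saturation within the calibration range (the model is linear by
construction, and no nonlinear calibration is offered).

## Channels

Each analyte group quantifies on its radical anion [M]·⁻ and, where the
assay observes one, its oxygen-loss fragment [M − O]·⁻ (nitro→nitroso
in-source reduction, −16 Da): TNT 227/211, ADNT 197/181, DNT 182/166,
DNB 168/152, CDNT 216/200. TNB and NT quantify on the parent ion alone
(213 and 137): their fragments are not observed in this assay, and a TNB
fragment would in any case sit at m/z 197, indistinguishable from the ADNT
parent at unit resolution — registering it as a quantification channel would
contaminate the ADNT estimate. Both species are still exposed by the
registry as ion species, with zero default response in the simulator.

The DAN matrix ions are stored as observed literals m/z 156/157 rather than
computed from C10H10N2 (nominal 158): they arise from reduction chemistry at
the amino groups that the mass arithmetic does not model. Anion m/z values
ignore the electron mass (≤ 0.0006 Da against a 0.5 Da extraction window).
Nominal masses use integer mass numbers; monoisotopic masses use standard
lightest-isotope exact masses (note Cl's −0.031 Da mass deficit puts CDNT's
monoisotopic mass at 215.9938, below its nominal 216).

## Synthetic spectra

The generator renders what the analysis assumes, with known ground truth:

- Grid 120–300 Da at 0.01 Da; Gaussian peaks with σ = 0.05 Da
  (reflectron-like sharpness at unit resolution; the peak shape is a design
  choice, no instrument lineshape is modelled).
- Peak heights: A(ch) × IS scale × shared per-spot lognormal multiplier
  (default CV 0.08) × independent per-peak lognormal (default CV 0.03),
  plus a half-normal additive baseline (sd 10⁻⁴ of the IS height) and a
  global per-spectrum mass shift (sd 0.1 Da) to exercise recalibration.
  The shared spot multiplier is the reason IS normalization works, and the
  generator makes that mechanism explicit.
- IS at 25 ng/µL in every deposit, including blanks (normalization is
  impossible without it); DAN ions at fixed relative heights.
- Triplicate spots per sample; every sub-seed derives from one master seed
  via `numpy.random.SeedSequence` spawning, so studies are reproducible.
- Calibration series 0 (blank), 1, 5, 10, 25, 50, 75 ng/µL: endpoints are
  the assay's measured range, interior levels are this package's choice.
  Interference grid: full 4 × 4 cross of {0, 5, 25, 75} ng/µL TNT × ADNT.
- Default response factors: ~0.02 per ng/µL for parent ions, roughly half
  for fragments, NT an order of magnitude lower (it ionizes poorly);
  κ defaults to 25% of the ADNT response. These produce replicate RSDs of a
  few percent for quantified TNT — within the single-digit-to-20% precision
  band reported for manually deposited spots.

Not emulated: desorption physics, suppression/saturation at high load,
isotope satellites (off by default), soil-matrix chemical noise beyond the
generic baseline, shot-level raster structure (a spot is one averaged
spectrum), or non-linear mass-axis warp. Passing tests therefore demonstrate
the correctness of the analysis chain under its own signal model — not
robustness to every pathology of real MALDI data.

## Preprocessing

Order: recalibrate → TIC-normalize → extract → average replicates. TIC
normalization is scale-only, so its order relative to recalibration is
immaterial (asserted by test). Recalibration matches reference ions (default
216 and 156) within ±0.5 Da, refines apexes by 3-point parabola, fits a
shift (1 anchor) or shift+stretch (≥2), and resamples onto the standard
grid. "Ion abundance" is the window maximum within ±0.5 Da, not an
integrated area — at fixed peak width they are proportional and the maximum
is robust; an area option exists (`mode="area"`). Unit-resolution channels
are ≥2 Da apart, and the closest pair (211/213) stays separable at 0.5 Da.
Baseline subtraction is omitted — the simulated baseline is small; real
spectra with structured baselines would need an upstream step. Peak
detection uses a MAD-based noise floor and parabolic apex refinement.
Normalization happens per spot, then spots are averaged (the IS logic is
per-deposit, so the ratio must be formed before pooling).

## Calibration and inversion

Fits are unweighted ordinary least squares ("classical"); a 1/x weighting
switch exists but is off by default. Blanks are included as calibration
points. Simple fits need ≥3 distinct levels; the bivariate interference fit
needs ≥6 points and a full-rank [1, c_own, c_TNT] design (collinear designs
are rejected by name). A constant-response channel yields a flagged
degenerate model (slope 0, R² 0, LOD undefined) rather than an error, so one
dead channel does not abort a run. LOD = 3.3 σ_resid/slope (ICH-style);
published instrument LODs for this assay are empirical values of a specific
spectrometer and are treated as documentation, not as targets for the
synthetic pipeline. The linear range is reported as [lowest non-zero level,
highest level].

Inversion: negative estimates are flagged but not clamped (clamping biases
replicate means upward near blank). Below-LOD channel estimates are excluded
from the per-analyte average unless every channel is flagged. In sequential
mode a below-LOD TNT point estimate is still propagated into the ADNT
correction — substituting zero would systematically inflate ADNT. Channel
averaging is unweighted; no outlier rejection between disagreeing channels
is attempted. TNT estimates are identical under simple and sequential modes
by construction.

## Validation statistics

PCA: column-centered covariance eigendecomposition, no variance scaling by
default (abundances share the IS-normalized scale; scaling is an option),
deterministic sign convention (largest-magnitude loading positive).
Two-way ANOVA: classical balanced decomposition with interaction, response =
IS-normalized abundance, factors = channel × concentration level; unbalanced
or incomplete layouts are rejected rather than silently re-weighted
(Type-II/III sums of squares are out of scope). Both implementations are
textbook-direct and are cross-checked in the tests against independent
library implementations.

## File formats and reproducibility

Spectra: two-column CSV (full `%.17g` precision, metadata as `#` comments)
or mzML. The mzML support is a compact reader/writer for the format's
profile-spectrum core (64/32-bit float arrays, zlib or uncompressed); the
writer's output is verified in the tests against an independent mzML
implementation. Non-uniform axes are resampled onto the standard grid with
a logged warning; descending axes and negative intensities are errors.
Tables (designs, abundances, models, results) are CSV/JSON. Every CLI
artifact records the master seed and a hash of the run configuration;
re-running with the same seed and configuration reproduces every number
exactly.

## Problem sizes

The shipped tests and the acceptance computation use the study geometry
described above: 7-level calibration series or 16-point interference grids
at 3 spots each, triplicate samples, and 20–50 seeded trials for the
Monte-Carlo properties. These sizes give stable medians for the quantities
checked while keeping a full run in the tens of seconds on one core.

## Known limitations

No uncertainty propagation beyond replicate SD (no calibration-band
prediction intervals); no saturation modelling; no baseline subtraction; no
positive mode, adducts, or multiply charged species; interference handling
is specific to the TNT→ADNT pair — generalizing to k mutually interfering
analytes would need a joint multivariate inversion rather than the
sequential pass.
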