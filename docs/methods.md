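# Methods

This note records the models, the tunable parameters that matter, the
numerical choices, and what the synthetic generators do and do not
emulate.

## Pulse model

The arterial pulse is modeled as a harmonic series at the cardiac
fundamental ω_H (rad/s):

    p(t) = a₀ + Σ_{k=1..N} (a_k cos(ω_H k t) + b_k sin(ω_H k t)) · e^(−k·z/c)

The exponential attenuates higher harmonics with subject-to-lens distance
z (m) over wave speed c (m/s); at z = 0 the series is unattenuated. In
practice only the first one-to-three harmonics are visible in webcam rPPG,
so the generator defaults to a fundamental plus two weaker harmonics.
Defaults: ω_H = 2π·1.2 (72 bpm, resting adult), 20 fps (commodity webcam),
10 s capture (the measurement duration used throughout), pulse amplitude 5
intensity units on a green-channel baseline of 120 (8-bit units; a
realistic webcam modulation depth of ~4%).

The rendered frames quantize to 8 bits with clipping. A static per-pixel
sub-LSB dither field is added before rounding, emulating the spatial
texture of real skin: averaging over the ROI then resolves intensity
changes finer than one quantization step, exactly as spatial averaging
does on real sensor data. Without such texture a uniform patch would
quantize coherently and cap the round-trip fidelity of ROI means.

## ROI extraction and normalization

The palm quadrilateral passes through landmarks 1 → 5 → 17 → 0 in cyclic
order, scaled to pixel coordinates. Pixel membership uses the even-odd
(ray-casting) rule on pixel centers at (col + 0.5, row + 0.5), 0-based —
deterministic and orientation-independent. Channel means are arithmetic
means over interior pixels.

Normalization is a z-score per channel over the whole capture window (not
sliding), with the population SD (divide by n) to match the covariance
convention of the ICA preprocessing; a constant channel maps to zeros.
Normalization runs before ICA by default (`prenormalize`), which makes
each channel's contribution scale-free; it can be disabled when raw
intensities should reach the separation stage.

Consequence worth stating plainly: z-scoring destroys absolute amplitude.
What distinguishes subjects after normalization is waveform *shape*
(harmonic content) — sharper systolic peaks push the mean retained peak
value of a unit-variance signal upward. The synthetic cohorts therefore
vary harmonic content across subjects; a cohort of identical pure
sinusoids would have identical features and a non-identifiable
calibration, and `fit_nmpso` flags that case as degenerate.

## ICA

Standard chain: center; eigendecompose the sample covariance; drop
eigenvalues below `var_threshold` (default 1e-6, relative to total
variance — rejects numerically null directions without discarding weak
pulse signal); rescale to unit variance. FastICA is deflationary
(one-unit, sequential) with Gram–Schmidt decorrelation, matching the
sequential update of each unmixing row; the contrast is log-cosh
(g = tanh), with a cubic (kurtosis) alternative. Initial rows are drawn
from a seeded standard normal, so runs are reproducible. Convergence is
|⟨w_new, w_old⟩| > 1 − tol (default 1e-6) or `max_iter` (200); a
non-converged unit is reported, not raised.

Semi-blind separation — when the mixing matrix A is known — is simply
S = pinv(A)·(X − E[X]), exact on noise-free mixtures.

Component selection keeps the component with the largest fraction of
spectral power in the physiologic band (default 0.7–3.0 Hz, 42–180 bpm),
computed from the FFT periodogram; the band's upper edge must lie below
Nyquist. Sign is aligned so the sharper excursions point upward (flip when
mean(peaks) + mean(valleys) < 0), making peak/valley features comparable
across captures; ICA leaves sign arbitrary, so some deterministic rule is
required.

## Peak/valley features

Extrema are strict 3-point local maxima/minima after collapsing
equal-value runs to their first sample (plateaus are common in 8-bit
data). The refractory filter removes any peak/adjacent-trough pair closer
than round(0.25 s · fps) samples — at 20 fps, 5 samples; at 120 bpm a
beat spans 10. Removal is greedy left-to-right (a discarded member leaves
the sequence immediately), then same-type neighbours left behind are
collapsed to the more extreme member, repeated to a fixed point. The
retained sequence provably alternates peak/valley with the minimum
spacing. A trace shorter than three samples yields an empty result rather
than an error.

The measurement feature comes from ten consecutive, non-overlapping
1-second windows: per window, detect + filter + average to one peak and
one valley value; E_peak/E_valley are means of the per-window values, and
`windows_used` records how many windows actually contributed (windows with
no surviving extrema are skipped; if all ten are empty, that is a no-beats
error). When a window retains several peaks their mean is used.

## NM-PSO

Coefficients: reflection α=1, expansion γ=2, contraction β=0.5, inertia
w=0.5, acceleration c₁=c₂=1.5, 3N+1 particles, 100 iterations, speed and
position bounded by 120 — the standard table for this hybrid. Readings of
underdetermined details, made once:

* "maximum and minimum speed 120/0" is read as a magnitude clamp
  |v| ≤ 120 (a hard v ≥ 0 would forbid leftward motion and break the
  algorithm); the position box [0, 120] is per-dimension and overridable —
  calibration widens it to [−120, 120] because intercept corrections can
  be negative.
* shrink factor 0.5 (the canonical simplex σ).
* per iteration: sort by fitness (stable, ties by index); one simplex step
  on the best N+1; PSO update of the poorer 2N only, attracted to the
  global best; simplex-moved particles get velocity 0 (no velocity rule
  exists for simplex moves). A vertex that a simplex move pushes outside
  the box is clamped and re-evaluated.
* early stop when the fitness spread over all particles is < 1e-10,
  otherwise the full iteration budget.

For blood-pressure calibration the fitness is the mean squared error of
the formula against the device readings over one BMI interval's records —
the minimal loss consistent with RMSE reporting. The landscape is an
ill-conditioned quadratic valley (x and x·BMI are highly correlated), so
`fit_nmpso` runs 300 iterations by default and restarts 3 times from
derived seeds, keeping the best run; an unlucky initial swarm can collapse
the simplex and stall for hundreds of iterations. The restart is plain
multi-start; each run is the unmodified algorithm.

Default BMI stratification: [<18.5), [18.5, 24), [24, 27), [≥27) kg/m²
(the Taiwanese MOHW convention), half-open intervals with boundary values
belonging to the upper interval, fully overridable. Lookups outside every
interval are errors — no extrapolation.

## Regression

OLS via `numpy.linalg.lstsq` (rank-revealing, mathematically equal to the
normal equations (XᵀX)⁻¹Xᵀy on full-rank designs; the test suite asserts
agreement to 1e-8). Rank-deficient designs raise rather than silently
pseudo-inverting. SBP and DBP are independent fits with their own
coefficient triples.

## Pipeline and provenance

Because both estimators' coefficients absorb the scale of the features,
calibration output embeds a 16-hex-digit SHA-256 fingerprint of the
preprocessing configuration (normalization flag, ICA settings, band,
refractory interval, window count). `measure` refuses parameters whose
fingerprint differs from the active configuration. A measurement requires
at least the full 10-window capture duration. Calibration and measurement
use the identical feature path and window count.

## Evaluation conventions

Sample SD uses n−1; the 95% CI of a mean is the normal approximation
mean ± 1.96·SD/√n. The AAMI criterion is mean |error| ≤ 5 mmHg and error
SD ≤ 8 mmHg. BHS thresholds (A: ≥ 60/85/95% of |errors| within 5/10/15
mmHg; B: 50/75/90; C: 40/65/85; else D) are the published protocol values
and are passed in as an overridable table.

## What the synthetic data does and does not show

The generators emulate: harmonic pulse waveforms with subject-specific
shape, additive Gaussian sensor/device noise, known linear mixing of
artifact sources, 8-bit quantization with spatial texture, and cohorts
whose device readings follow the calibration formulas exactly up to
device noise. They do not emulate: motion of the hand (landmarks are
static per sequence unless supplied per frame), illumination drift or
flicker, skin-tone diversity, specular reflection, arrhythmia, or any
physiological link between waveform shape and pressure beyond the assumed
formulas. Passing closed-loop tests therefore demonstrates that the
chain is self-consistent and that calibration recovers a recoverable
signal at the stated noise levels — not that the formulas hold
physiologically on real subjects, which requires a clinical cohort.

Problem sizes used by the test and acceptance suites — 200-subject
cohorts (150 train / 50 held out) over ten seeds, 9–10 subject closed-loop
calibrations on 32×32-pixel, 10.5-second frame sequences — were chosen as
the smallest sizes at which the statistical assertions are stable across
seeds.

## Known limitations

* Feature scale depends on the entire preprocessing path; cross-device
  transfer of coefficients is not supported (by design, enforced via
  fingerprints).
* The deflationary FastICA extracts at most as many components as survive
  whitening; with two constant channels (synthetic frames) it degenerates
  to a sign-aligned z-score of the single informative channel.
* The refractory filter's greedy removal can retain a spurious extremum
  in place of a true one when an artifact lands within the refractory
  window of a beat; counts and downstream averages are unaffected, which
  is what the features consume.
* `BPFormulaParams` tables assume non-overlapping intervals; this is
  asserted only at lookup time (exactly one match).
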