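# Methods

This note documents the models and procedures `swaybalance` implements,
the defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical decisions that make results
reproducible bit-for-bit.

## Video motion-tracking pipeline

**Frame differencing.** Motion is segmented by thresholding the absolute
intensity change between consecutive frames of a static-camera video:
pixel *p* is moving in frame *i* iff |I_i(p) − I_{i−1}(p)| > θ, with
θ = 0.15 on normalized [0, 1] intensities. A difference exactly equal to
θ counts as static; the event has measure zero, the rule exists so the
boundary is deterministic. Raising θ can only remove mask pixels
(monotonicity), which the tests assert.

**Normalization.** Each frame is independently min-max normalized after
ROI cropping. Per-frame normalization neutralizes global brightness
flicker, which is its purpose; a global (whole-clip) mode and a
no-normalization mode are available in `MotionConfig` for sensitivity
analysis. A constant frame maps to all-zeros rather than dividing by
zero.

**Morphology.** The binary mask is opened (disk radius 1), closed (disk
radius 2), and cleared of 8-connected components smaller than 20 px.
Defaults are sized to remove single-pixel speckle while preserving a
trunk-scale silhouette; all three are configuration values, not
constants. Note that opening with a Euclidean disk shaves the corners of
perfectly square regions — it preserves interiors, not corner pixels.

**Centroid tracking.** The centroid (mean row, mean column of 1-pixels)
of the denoised mask of frames (i−1, i) is assigned to frame i, so N
frames yield N−1 trajectory samples at the video frame rate. x is the
image column (mediolateral); y is the image row. In a frontal camera
view the image row mixes vertical body motion with anteroposterior sway;
the pipeline reports image-plane axes and leaves the anatomical
interpretation to the user. Empty masks (no pixel above threshold) are
handled by `empty_mask_policy`: `carry_forward` (default) repeats the
last valid centroid and back-fills leading gaps; `mark_missing`
interpolates linearly. A trial in which *every* mask is empty is an
error, not a zero — a subject that produces no detectable motion cannot
be scored.

Carry-forward makes the extracted trajectory hold still exactly when the
subject's inter-frame motion is too small to detect. This biases
velocity parameters downward for very quiet subjects and upward-biased
jumps follow gaps; in practice the mapping from true to tracked mean
velocity stays monotone, which is what parameter-level correlation
needs. The bias is a property of any thresholded motion detector, not of
this implementation.

## COP conditioning

Force-plate COP arrives as two-channel mm series at 100 Hz (the package
defines a plain CSV format: `time_s, cop_x_mm, cop_y_mm`; the rate is
inferred from the median time step and cross-checked against any
declared rate, warning at >1% mismatch). Each axis is filtered with a
fourth-order Butterworth low-pass at 10 Hz. Zero-phase
(forward–backward, `scipy.signal.sosfiltfilt` with odd reflective
padding of 3·(order+1) samples) is the default because phase lag would
distort velocity metrics; the effective magnitude response is the design
filter's squared, so the gain at the cutoff is 0.5 rather than 1/√2.
A causal single-pass mode is provided, and the mode used is logged with
every run. Whether a given historical analysis filtered causally or
zero-phase is generally unstated in the literature; reporting both modes
sidesteps the ambiguity.

## Sway parameters

Nine per-trial metrics (see README): mean speed, SD of speed, and path
length per axis x, y, r. Three readings fixed here:

* "Mean velocity" is the mean *absolute* step displacement × rate, i.e.
  path length over time — the signed mean is ≈0 for stationary sway and
  clinically meaningless.
* "SD velocity" is the sample SD (n−1) of the instantaneous speed
  series, not the SD of position: the quantity is named a velocity.
* "Total displacement" is cumulative path length Σ|d|, not range — the
  only reading consistent with the Vmean·T = Ctotal identity.

No resampling happens in this module: video trajectories arrive at the
camera rate, COP at 100 Hz, and the modalities are compared at the
parameter level only. Pixel→mm conversion is an explicit calibration
factor (object of known width W mm spanning P px ⇒ mm/px = W/P);
correlation-based validity is scale-invariant, so the factor does not
affect the validation statistics.

## Synthetic data generator

The generator emulates a two-group (CP-like vs control), four-condition
(eyes open/closed × feet apart/together) quiet-stance study with paired
video and COP per trial.

**Sway model.** Band-limited Gaussian noise: white noise per axis,
low-pass filtered (order-4 zero-phase Butterworth at `bandwidth_hz`),
mean-removed, rescaled so each axis's sample SD equals its amplitude
exactly. This is the simplest stationary process with independently
controllable amplitude and bandwidth — matching how sway is summarized
(velocity, displacement), not a biomechanical model. Defaults:
amplitude 6 px (x) / 4 px (y), bandwidth 1 Hz, 30 s at 30 Hz. The
amplitudes are set so that even the quietest simulated subject produces
inter-frame steps the 0.15-threshold detector can register on some
frames; smaller amplitudes are valid inputs but approach the detector's
physical floor (see limitations). Order 4 for the shaping filter keeps
>95% of realized power below the nominal bandwidth.

**Renderer.** One frame per trajectory sample: an ellipse
(half-axes 12 × 24 px) at frame centre + trajectory offset on a plain
background (0.95), carrying a rigidly-translating texture. The texture
is a separable triangle-wave plaid (wavelength 6 px, contrast 0.5 around
foreground level 0.5, spanning [0, 1] without clipping). A triangle wave
has constant gradient magnitude, so a rigid sub-pixel shift changes
interior intensities uniformly — the mask fills the whole silhouette
once the step exceeds ≈ θ·λ/(2·contrast) ≈ 0.9 px, and partial detection
below that. Smooth low-contrast textures produce thin threshold-crossing
stripes that morphological opening deletes; the plaid is what makes
interior motion, not just edge motion, visible to frame differencing.
An untextured mode (contrast 0) is kept for edge-only robustness tests.
Frame size defaults to 64 × 96 px and grows automatically (never
shrinks) when a trajectory excursion would push the silhouette out of
frame — Gaussian sway is unbounded, so a hard frame bound would fail
with small probability at any seed. Rendering defaults to 30 fps
(smartphone-typical).

**COP coupling.** The COP signal is the COM trajectory linearly
resampled to 100 Hz, scaled to mm, plus independent Gaussian coupling
noise (default SD 0.2 mm) and a 30 Hz sinusoidal "tremor" (default
0.5 mm) that the 10 Hz Butterworth stage removes almost entirely
(analytic gain 1/(1+3⁸) ≈ 1.5·10⁻⁴). This makes the ground-truth
image↔COP correlation a tunable quantity — the property the validation
statistics must recover, with the noise knob providing a monotone
degradation axis.

**Cohort structure.** CP-like subjects use amplitudes × 2.0 (default);
the four conditions scale amplitudes by (1.0, 1.3, 1.5, 2.0) — harder
stances sway more; each subject carries a log-normal amplitude factor
(CV 0.3, mean 1, shared across their four trials) so parameters spread
continuously between subjects as in real cohorts. Every trial derives
its own sub-seed from the cohort seed, so the full dataset is a pure
function of the specification.

**What the generator does not emulate:** physiologically realistic CP
sway dynamics (rambling/trembling, intermittent control), human-shaped
or articulated bodies, non-rigid motion, camera perspective, lens
distortion, sensor noise, lighting gradients, compression artifacts.
Passing tests therefore demonstrate that the pipeline recovers known
ground truth under clean conditions and that the statistical chain
behaves correctly — not that the method is validated on real children.

## Validation statistics

Normality is screened with Shapiro–Wilk (verdict gates on p < 0.05
alone; skewness, excess kurtosis, and CV are reported descriptively,
since no principled combination rule exists for the four). Non-normal
variables may be natural-log transformed; zero/negative values use
log(v + c) with c the smallest positive observation, and the offset is
logged. Group comparisons use the Mann–Whitney U test: exact p by
enumeration when n₁·n₂ ≤ 400 with no ties, otherwise the normal
approximation with continuity and tie correction (midranks). Pearson
correlations carry strength labels at |r| bands 0.2/0.4/0.6/0.8
(boundary values belong to the lower band); the band edges are
configurable. Predictors for each COP outcome are image parameters with
|r| > 0.25 and p < 0.05; among any pair with mutual |r| > 0.80 the one
with the weaker outcome correlation is dropped, ties broken
deterministically by canonical column order (Vmean x,y,r; Vstd x,y,r;
Ctotal x,y,r). Regression is ordinary least squares with all selected
predictors entered simultaneously ("Enter"); simple regression is the
one-predictor special case, and R² = r² there is asserted to 1e−12.
Effect sizes use Cohen's R² bands 0.02/0.13/0.26. Raw p-values are
reported without multiple-testing correction, matching standard practice
in concurrent-validity studies; correlations can be computed pooled
across groups (default) or within the CP-like group only (`scope`).

## Problem sizes and numerical choices

* End-to-end cohort checks run 20 + 20 subjects × 4 conditions at
  64 × 96 px, 10 s trials, 30 fps — large enough for stable correlations,
  small enough to run on one CPU in a few minutes. Statistical power
  loops (100 seeded replicates) run on the generator's ground-truth
  trajectories rather than re-rendering video each time; the rendering
  and tracking stages are validated separately (centroid within 1 px of
  ground truth per frame; trajectory correlation > 0.95 at sway
  SD ≥ 5 px), so tracked and true parameters agree up to small
  monotone-preserving noise.
* Filter edge handling: odd reflective padding, length 3·(order+1),
  fixed so outputs are reproducible exactly.
* All RNG flows through `numpy.random.default_rng` seeds; cohort trials
  use `SeedSequence` spawning, giving byte-identical regeneration.
* AVI I/O uses an uncompressed 8-bit grayscale RIFF container written
  and read by the package itself (bottom-up DIB rows, 4-byte stride,
  grayscale palette, `idx1` index): every mainstream decoder opens it,
  frame data round-trips exactly up to 8-bit quantization, and no codec
  dependency is needed. Compressed input (MP4) is delegated to imageio
  + ffmpeg when installed (`[mp4]` extra).

## Known limitations

* A thresholded frame-difference detector has a hard floor: inter-frame
  displacements whose induced intensity change stays below threshold
  everywhere are invisible. At 30 fps this floor corresponds to roughly
  0.5–1 px/frame against the default texture; very quiet subjects are
  under-measured, and a perfectly still "subject" is an error by design.
* Tracked velocity parameters are biased (downward for quiet trials,
  with occasional post-gap jumps); between-subject ordering is
  preserved, which suffices for correlation/regression validity but not
  for absolute velocity calibration.
* The anteroposterior axis from a frontal camera is a proxy measurement.
* Test–retest reliability is out of scope, as are frequency-domain
  posturography, sway-ellipse areas, and COP computation from raw force
  channels.
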