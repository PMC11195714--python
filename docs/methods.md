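# Methods

This note documents the models, conventions and numerical choices behind the
package, what the synthetic generator does and does not emulate, and the
known limitations.

## The estimation pipeline

**Landmark extraction.** A landmark localization is *valid* in a frame when
at least one pixel of its probability map reaches the fixed threshold of 0.5
(inclusive: "at least 50%"). The coordinate is the centre of mass of all
supra-threshold pixels, weighted by probability. Two deliberate consequences:
(a) the threshold is independent of acquisition settings, so validity is a
property of the map, not of the image statistics; (b) a multimodal map (true
landmark plus a clutter blob) yields a fused coordinate between the modes
rather than an arbitrary choice of one mode — the resulting frame-to-frame
jump is then caught by the displacement filter, which is the intended
division of labour. An unweighted centre of mass is available via
`extract_track(..., weighting="uniform")`; on symmetric blobs the two differ
negligibly.

**Rotation correction.** The annulus does not move along the image y-axis,
so each wall's valid coordinate scatter (in mm) is rotated about its centroid
to align its first principal axis with y. The principal-axis estimate is
data-driven per wall and recording; no probe geometry is assumed. Two details
are not determined by the principal axis itself:

- *Sign.* The orientation is chosen by a dwell rule: in each cycle the
  annulus spends systole plus the early-diastolic return (about 0.78 of the
  cycle, half of it below mid-excursion) moving, and the rest dwelling near
  the end-diastolic position, so with ED oriented as the maximum more than
  half of all samples lie above the robust midrange (mean of the 5th/95th
  percentiles). The rule needs no ECG and is insensitive to where the
  recording window starts. It assumes the atrial-kick residual is clearly
  below half the total excursion, which the generator enforces
  (`atrial_kick_mm <= min(mapse)/3`).
- *Degenerate motion.* When the motion is closer to circular than linear
  (principal/secondary standard-deviation ratio < 2) the projected range
  understates the true path; such tracks are flagged (`low_anisotropy`) and
  logged, not rejected.

**Peak detection.** ED/ES candidates are alternating maxima/minima of the
rotated y(t), found after linearly bridging invalid frames (bridging is used
for detection only; estimates are read from observed frames). Peaks must be
separated by at least one minimal cycle, 60/hr_max s with hr_max = 200 bpm by
default, and have prominence ≥ max(1 mm, 20% of the 5th–95th percentile
y-range). The 1 mm floor sits below any plausible MAPSE signal (clinical
single-wall range ~3–24 mm) and suppresses jitter peaks; the 20% term adapts
to large excursions. First/last samples never count as peaks, which avoids
spurious ED/ES at the recording boundary.

**Cycle definitions.** With an ECG, one cycle per consecutive R-R pair,
boundaries at the frames nearest the R times (R-waves beyond the recording
are clipped with a warning; fewer than two usable R-waves is an error).
Without an ECG, one cycle per consecutive pair of detected maxima; fewer than
two maxima is a non-feasibility outcome, not an error.

**Filters.** Applied per wall, in order, each cycle carrying at most one
discard reason so the bookkeeping reconciles exactly
(`n_cycles = n_estimates + n_validity + n_jump + n_unphysiological +
n_no_peak_pair`):

1. *Validity*: discard when the valid-frame fraction is < 0.6 (strict: a
   cycle at exactly 60% is retained). In ECG mode the fraction is weighted by
   the normalized exponential kernel w(d) ∝ λ·e^(−λd) on the frame distance d
   to the cycle's R-wave, λ = 0.1 per frame; the λ prefactor cancels in the
   normalization but is kept for recognisability. The weighting prioritises
   frames around end-diastole, where the estimate is anchored. ECG-free mode
   uses the unweighted fraction (it has no R-wave to centre the kernel on).
2. *Jump*: discard on a frame-to-frame displacement > 5 mm (strict: exactly
   5 mm is retained). Displacement is measured between consecutive *valid*
   frames using the full 2D coordinates (clutter events are 2D; a y-only
   variant exists behind `jump_use_2d=False`). In ECG mode the containing
   cycle is discarded; in peak mode the peak nearest the jump and hence both
   cycles it bounds (conservative; `discard_both_adjacent=False` restricts it
   to the containing cycle).
3. *Physiology*: within a surviving cycle ED is the valid-frame maximum and
   ES the minimum occurring after it; a cycle whose y rises monotonically
   yields no estimate. Estimates must lie in (0, 30] mm; the 30 mm ceiling is
   a configurable guard well above the clinical maximum (~24 mm).

**Aggregation.** Wall MAPSE is the arithmetic mean over surviving cycles; a
wall is feasible iff at least one cycle survives. Recording-level reporting
counts feasible walls; the cohort tally in `stats.feasibility_table` follows
the standard two-view convention (inferoseptal/anterolateral from the
4-chamber view, inferior/anterior from the 2-chamber view).

## Agreement statistics

- Bland–Altman: bias = mean(a−b), LoA = bias ± 1.96·sd(a−b) with the n−1
  denominator.
- ICC for consistency: two-way mixed model without interaction, single
  measures — ICC(3,1) = (MS_rows − MS_err)/(MS_rows + MS_err) for k = 2 —
  with the F-based CI. The model variant is configurable to average-measures
  ICC(3,k); single-measures is the default because the compared quantities
  are single measurements per subject and method. An exactly consistent table
  (b = a + c) is detected via a relative floor on the residual sum of squares
  and reported as ICC = 1 exactly.
- Pearson r with the Fisher-z interval tanh(atanh r ± z₀.₉₇₅/√(n−3)).
- Correlation comparison: independent-samples Fisher z. The dependent-sample
  (Steiger) variant for correlations sharing a variable is provided as
  `compare_correlations_dependent`; the independent form is the default
  because the comparison protocol does not specify the dependence structure.
- Fisher's exact test: two-sided by the "probabilities ≤ observed" rule
  (scipy's convention, checked against exact hypergeometric enumeration).
- Missing pairs are dropped listwise per statistic with n reported.

## The synthetic generator

**What it emulates.** Annular kinematics as a smooth periodic excursion:
raised-cosine systolic descent over `systole_fraction` (default 0.35) of the
cycle, raised-cosine early-diastolic return to an atrial-kick residual,
diastasis, and a gentle late raised-cosine closing the residual at the next
R-wave. Max−min per cycle equals `mapse_truth_mm` by construction; R-waves
anchor end-diastole. Recordings span `n_cycles` cycles plus a 0.4-cycle
lead-in/out so every ED maximum is interior and prominent — mirroring real
recordings, which do not start on an R-wave. Defaults follow the clinical
setting being emulated: 74 bpm, 38 frames/s, 3 cycles, 10.7 mm per wall, a
90° sector for rendered images. Heatmaps are Gaussian blobs (σ = 2 px, peak
uniform in 0.6–0.95) at the true position; noise comprises per-frame dropout
(map stays below threshold), Gaussian jitter of the blob centre (1 px),
clutter (a second supra-threshold blob displaced 30 px, probability 0.02),
and a ×3 boost of dropout/clutter in the last 15% of each cycle emulating
the post-atrial-contraction quality drop. All noise draws are made for every
frame regardless of whether they take effect, so different noise levels under
one seed are monotonically coupled — this is what makes the degradation
sweeps well-posed.

**Study-grid design.** The clean recovery grid (50 recordings) spans heart
rate 42–153 bpm and MAPSE 3–24 mm with the two co-varied inversely, which is
the physiological covariation (tachycardia curtails filling and excursion).
A free cross product would contain combinations (e.g. 24 mm at 153 bpm)
whose true frame-to-frame displacement at 38 frames/s exceeds 5 mm, i.e.
inputs the method's own jump filter rejects by design. Recovery is judged
against max(0.5 mm, pixel spacing + one-frame discretization bound), the
bound being measured on the ground truth itself (amplitude lost by sampling
the continuous trajectory at the frame grid).

**What it does not emulate.** Ultrasound physics (speckle in the B-mode
renderer is plain multiplicative noise, not coherent speckle), 3D/elevational
motion, valve anatomy, arrhythmic cycle-length variability, probe motion
other than a sinusoidal lateral drift, and realistic CNN error statistics
(real networks err in structured, image-dependent ways). Passing the
synthetic studies therefore demonstrates that the post-processing logic is
correct and robust to the modelled failure modes — not that any particular
network achieves clinical accuracy.

## The toy trainable localizer

A three-layer fully-convolutional network in numpy (im2col convolutions,
manual backpropagation, Adam) with per-pixel sigmoid outputs so multimodal
maps remain representable, trained with positively re-weighted binary
cross-entropy against Gaussian label maps (σ = 2 px; empty maps for
landmarks invisible in a frame). Normalized row/column coordinate channels
are appended to the grayscale input so the purely local network can separate
the left from the right wall. Augmentation is random rotation (±10°) and
random cropping (≥ 0.9 of the field) applied jointly to image and labels.
Default budget: 500 training frames at 64×64 (0.8 mm/px), 6 epochs, batch 8,
learning rate 2·10⁻³ — a few CPU-minutes, after which the end-to-end chain
(render → infer → localize → estimate) recovers MAPSE on clean held-out
recordings to well under 1 mm mean absolute error. Training is bit-exact
reproducible for a fixed seed. This module demonstrates the output contract
and the trainability of the task at desk scale; it makes no claim about
clinical-grade localization.

## Numerical choices and degenerate inputs

- Threshold comparisons: validity threshold ≥ (inclusive), validity filter
  < 0.6 (strict), jump filter > 5 mm (strict) — boundary cases are covered by
  dedicated tests.
- Fewer than 2 valid frames per wall → "degenerate track" error, surfaced as
  a non-feasible wall with the reason recorded, since non-feasibility is a
  measured outcome rather than a crash.
- Ties in peak alternation keep the more extreme of two same-kind peaks.
- The recording container stores heatmaps as float32 and times as float64;
  round-trips are bitwise.
- All stochastic components take explicit integer seeds; identical configs
  and seeds reproduce outputs bit for bit.

## Known limitations

- Lateral annular translation inflates the estimate (total rather than
  strictly longitudinal displacement is measured); the generator can inject
  it (`lateral_translation_mm`) but the pipeline does not correct for it.
- Defining ED/ES from trajectory peaks can absorb pre-/post-systolic motion.
- The dwell-based orientation rule can fail on pathological waveforms where
  the annulus dwells near end-systole (e.g. extreme tachycardia with
  prolonged systole); such traces would be mis-oriented rather than flagged.
- ECG-free mode needs at least two detectable ED maxima; very noisy or
  low-excursion traces fall back to non-feasibility, which matches the lower
  feasibility reported for ECG-free operation on clinical data.
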