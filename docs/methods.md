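# Methods

## Voxelwise T2* relaxometry

Each voxel's multi-echo magnitude signal is modeled as monoexponential
decay, `S(TE) = S0·exp(−TE/T2*)`, sampled at 8 echo times from 5 to 75 ms.
Parameters are estimated by unweighted Levenberg–Marquardt least squares
(scipy `least_squares`, method `lm`, analytic Jacobian, `ftol 1e-10`,
`xtol 1e-12`, ≤200 function evaluations), initialized from an ordinary
least-squares fit of `ln S` on TE over the strictly positive samples.
No noise-floor offset term and no magnitude-bias (Rician) correction are
applied: at the SNR of tissue voxels the bias on T2* is small, and the plain
least-squares form keeps the estimator identical to the standard clinical
analysis. This is a documented limitation at low SNR, where the Rician
floor inflates late-echo signal and biases T2* upward.

Fit failure is data, not an exception. A voxel is invalid — NaN estimates,
`valid=False`, excluded from every downstream statistic — when fewer than
two samples are positive, the solver fails, or T2* leaves `(0, 1000] ms`.
The 1000 ms cap flags runaway fits in air/CSF; the fraction of valid voxels
is logged with every volume fit so masking cannot pass silently.

## Registration and resampling

Sessions an hour apart are aligned with a 12-parameter affine transform
estimated by SimpleITK's registration framework: mean-squared intensity
metric (same modality pre/post; Mattes mutual information behind a flag),
regular-step gradient descent (learning rate 1.0, min step 1e-5, ≤300
iterations/level, relaxation 0.5), a 3-level pyramid (shrink 4/2/1,
smoothing σ 2/1/0 mm), and full voxel sampling so results are deterministic.
The BOLD series is registered via its temporal-mean image and the single
recovered transform is applied to every repeat and to the same session's
T2* map (one intra-session geometry per visit).

Transforms live in world millimetres (RAS, NIfTI affine convention) and map
reference (pre) points into moving (post) space, which is exactly what the
resampler consumes. Resampling is trilinear via `scipy.ndimage`, with an
explicit in-field mask: voxels whose interpolation stencil leaves the
source field of view carry a fill value and are invalid downstream —
out-of-field voxels never enter a statistic.

## Change maps and ROI statistics

BOLD percent change is `100·(mean_post − mean_pre)/mean_pre` on temporal
means over the 60 repeats (mean rather than median, for variance
efficiency; switchable). Voxels whose pre-session mean falls below a signal
floor — 3× the background noise estimated from the Rayleigh mean of
low-intensity voxels — are invalid, preventing division blow-ups in air.
ΔT2* is map-minus-map (ms) from independently fitted sessions. Validity is
intersected: both sessions valid, in-field after resampling.

ROI summaries use only valid ROI voxels and report the valid fraction
alongside. Threshold fractions use strict `>` (a boundary voxel at exactly
the threshold does not count), which matters on quantized maps; the ladders
default to 1/2/5/10 ms (ΔT2*) and 1/2/5/10 % (BOLD). The cohort waterfall
sorts patients by the fraction above an anchor threshold (default 5 ms),
breaking ties by patient id for run-to-run stability, and flags responders
by `fraction ≥ 0.25` at the anchor — an explicit reporting convention, not
a validated clinical rule.

## Bioluminescence quantification

The peak of a luciferin timecourse is the sample maximum (earliest time on
ties), with no kinetic model: the 2-min/25-min sampling grid is dense
enough to bracket the peak, and curve fitting would import shape
assumptions the data do not constrain. Peaks are normalized per animal to
the animal's own baseline session; group effects are tested with two-sided
Student's t-tests (paired within animals, equal-variance unpaired between
groups, Welch behind a flag). Both SD and SEM are always computed. A test
with zero-variance differences and a nonzero effect is reported as
degenerate rather than given a fabricated p-value; identical inputs yield
the exact null (t=0, p=1). No multiple-testing correction is applied.
Caliper volume is the modified ellipsoid `½·L·W²` (mm³) with the longer
axis as L; swapped inputs are corrected with a warning.

## The phantom generator

The imaging phantom emulates the statistical structure the analysis
assumes: an ellipsoidal tissue object (S0 = 1000, T2* = 35 ms by default)
in a 32×32×12 grid of 1.6×1.6×4 mm voxels, a centered ellipsoidal tumor
ROI, monoexponential echo decay at the acquisition's echo times, 60-repeat
BOLD series, and Rician noise applied to every magnitude sample (background
voxels are pure Rayleigh noise, so masking logic is exercised; a Gaussian
option exists for analytic tests). The post-dose session adds a known ΔT2*
increment and fractional BOLD change on exactly the upper-x half of the ROI
— a crisp 50/50 split so fractional-volume recovery has an exact target —
and is acquired through a known affine misalignment whose inverse is the
registration truth, stored in a ground-truth sidecar. The post BOLD level
is exactly `baseline·(1 + bold_change)`, deliberately uncoupled from the
T2* increment so each change map has an independent exact truth.

What the phantom does **not** emulate: B0 inhomogeneity and susceptibility
gradients, within-series motion and physiological drift, spatially
correlated noise, partial-volume anatomy, deformable inter-session motion,
and scanner intensity nonuniformity. Passing tests therefore demonstrate
correctness of the estimators and their plumbing under the assumed model,
not robustness to every artifact of real acquisitions. One consequence
visible in the simulated cohort: trilinear interpolation across the sharp
changed-region boundary after registration attenuates threshold fractions
below their noiseless value, exactly as partial-volume effects would in
real data.

The flux phantom uses a gamma-variate rise-then-decay
`f(t) = peak·(t/tp)^k·exp(k(1−t/tp))` with peak time tp = 10 min and shape
k = 2 — a smooth single-peak curve consistent with luciferin kinetics —
sampled at 0, 2, …, 24 min, with i.i.d. multiplicative lognormal reading
noise (CV 0.1 by default, mean-corrected). Because the same noise law acts
on baseline and treatment, the peak-selection bias cancels in the
treated/baseline ratio and the imposed fold is recovered unbiased to first
order. Cohort defaults are six animals per group.

All generators derive their random streams from `numpy` `SeedSequence`
keyed on the spec seed plus a fixed per-product stream id, so a fixed spec
reproduces bit-identical phantoms, and pre/post sessions get independent
noise.

## Problem sizes and runtime choices

Default grids (32×32×12) keep a full per-patient chain (two volume fits,
registration, change maps, ROI stats) around 20 s on one CPU; the simulated
nine-patient cohort runs in ~3 min. Recovery checks use 10⁴ voxels for the
noisy-fit oracle comparison (dense T2* grid search with the amplitude
profiled out in closed form, 0.25 ms grid) and 10⁴ simulated null cohorts
for t-test calibration. These sizes give Monte-Carlo standard errors well
below the tolerances tested.

## Known limitations

* No conversion of ΔT2*/ΔBOLD to absolute pO₂ — no calibration model is
  assumed.
* No deformable registration or within-series motion correction.
* T2* fitting assumes a single compartment; multi-exponential decay in
  voxels mixing tissue classes biases the estimate toward the dominant
  component.
* ROI masks are inputs; no tumor segmentation is provided.
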