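# Methods

This note documents the measurement models, the synthetic-data
generators that validate them, the conventions chosen where the original
analyses left details open, and what the validation does and does not
show.

## Crawling kinematics

### Measurement chain

A spine track is a per-frame series of five ordered points (head to
tail, mm, image convention, 0-based frames). Spine length is the sum of
the four inter-point distances — a folded larva therefore keeps its full
spine length; the head-to-tail chord is never used. The chain is:

1. moving-average smoothing of L(t) (odd window, default 3 frames =
   0.6 s at 5 fps), then central-difference derivative (one-sided at the
   record edges);
2. cycle boundaries at successive positive-going zero crossings of
   dL/dt, linearly interpolated between frames. Derivative magnitudes
   below 1e-9 mm/s count as zero (guards against float noise on
   constant spine lengths); a record opening exactly at a crossing
   (dL/dt = 0 then rising) starts a cycle at frame 0;
3. cycles shorter than `min_cycle_duration` (default 0.4 s) are merged
   into the following cycle; partial cycles at the record edges and
   cycles containing a tracking gap are discarded;
4. stride duration T = t_end − t_start; stride length S = net centroid
   displacement between the interpolated crossing times (centroid
   linearly interpolated); walking rate v = mean per-frame centroid
   step × fps over the whole record, skipping gap-adjacent steps.

Conventions the source analyses leave open, declared here: the crossing
phase (start of elongation — any consistent phase gives identical
durations and net displacements over full cycles); the smoothing window
(3 frames; at 5 fps a ~1.1 s cycle spans only ~5.5 frames, so wider
windows erase cycles); the minimum cycle duration (0.4 s, below half
the reported stride duration, rejecting jitter double-crossings);
sub-frame interpolation of crossing times (without it, durations
quantize to 0.2 s multiples); walking rate averaged over all frames
including pauses.

### Crawler generator

The generator inverts this measurement model. Per larva, cycle
durations Tⱼ ~ Normal(T̄, σ_T) truncated at 0.5·T̄ and strides
Sⱼ ~ Normal(S̄, σ_S) truncated positive are drawn sequentially until the
20 s record is covered. Within cycle j the spine length is
L(t) = L₀ − a·cos(2πφ), φ rising 0→1, so dL/dt has a positive-going
zero crossing exactly at each boundary; the centroid advances Sⱼ along
a heading that performs a random walk (Normal(0, heading_sd) per
cycle). Resting spine length L₀ = 4 mm and contraction amplitude
a = 0.15·L₀ are order-of-magnitude larval values (configurable);
neither affects the three kinematic outputs in the noise-free case.

Real larvae sway laterally, so the centroid path rate exceeds the net
advance rate (the published walking rates exceed stride length /
stride duration). The generator reproduces this with a per-frame
alternating perpendicular offset ±w. The amplitude w is solved per
larva (bounded scalar root find, exact to solver tolerance) so that the
realized mean per-frame path rate equals the larva's realized net rate
plus the parameter-level surplus
`walking_rate_mean − stride_length_mean/stride_duration_mean`.
Anchoring the target to the realized net rate keeps the calibration
feasible for every draw (a fixed absolute target is unattainable for
larvae whose drawn strides are fast) and makes the cohort mean walking
rate unbiased; with all noise off the path rate equals
`walking_rate_mean` exactly.

Parameter choices: the published group means are transcribed directly
(control: v = 1.15 mm/s, S̄ = 1.17 mm, T̄ = 1.09 s, n = 118; the
autoregulation-deletion genotype: 1.05 / 1.08 / 1.15, n = 108). The
sources print SEMs, not the variance decomposition; the generator draws
all variability per cycle with σ = SEM·√n (S: 0.26 mm, T: 0.15–0.18 s)
and models no between-larva random effect. Consequence: synthetic
cohort SEMs are ~√n_cycles smaller than the printed ones; cohort *mean*
recovery — what the validation checks — is unaffected. heading_sd
defaults to 0.15 rad/cycle (gentle curving during an escape response);
pauses (probability per cycle boundary, zero net displacement, constant
L) default off, matching the active-crawling recordings. Only two
kinematic presets ship: the two genotypes with published numeric values.

## FISH ratio quantification

Per stack: pixelwise sum over z per channel (preserves integrated
intensity); per-channel threshold at the 50th percentile of the
projected image (the median tracks the background mode when foci are
sparse) with *soft* subtraction — pixels at/below the threshold go to
zero, pixels above have the threshold subtracted; then per-nucleus
integrated intensities inside the given ROI mask and R = I_col/I_nau.
Thresholding method and value are configuration, recorded per run; the
original analysis states neither. ROIs are consumed as labelled masks
(mirroring manually drawn nuclear ROIs); no nucleus segmentation or
spot detection is attempted. Ratios are averaged per nucleus then per
group — never a ratio of group sums. A zero reference integral flags
the measurement invalid rather than raising. With a percentile
threshold, a global gain change cancels in R exactly; scaling one
channel scales R linearly (both property-tested).

### Stack generator

Nuclei are non-overlapping ellipsoids (2D-disc masks of radius 9 px) in
a 16×256×256 voxel stack, one transcription focus per nucleus per
channel, co-located at the (integer) nucleus centre: a discrete 3D
Gaussian kernel (σ = 1.5 px, truncated at 4σ, normalized to unit sum)
scaled by the focus amplitude, on a uniform background (20 counts) with
Poisson noise. Per nucleus, R_i ~ Normal(ratio_mean, ratio_sd)
truncated positive; the nau amplitude is fixed at 10⁵ so the
reference-channel focus dwarfs background shot noise, and
amp_col = R_i·amp_nau. With noise and background off, the quantified
ratio equals the generating R_i to machine precision (the kernel lies
entirely inside the mask). Group presets transcribe the published
ratios and sizes (progenitor stage: 1.22/1.15/1.19; founder stage:
2.20 wild type, 1.10 and 1.41 for the two regulatory deletions;
n = 18–28), with per-nucleus σ = SEM·√n (0.17–0.26).

Known measurement bias: Poisson noise rectified by the soft threshold
adds the same small positive offset to both channel integrals, pulling
R toward 1 by ~0.5% at the preset amplitudes — an order of magnitude
inside the group-level tolerances, and absent in the noise-free
exactness check.

## Phenotype tallies

Calls are i.i.d. multinomial draws over {normal, branched, transformed,
absent} at the per-genotype proportions; tallies report per-genotype
proportions with n and Wilson 95% score intervals (well-behaved at the
published extreme proportions and sample sizes, where a Wald interval
is not). Because the independence of segments within an embryo is not
established, tallies report both segment-level proportions and the mean
of per-embryo proportions. Only two category values are printed in the
source text (85.2% transformed at n = 190 for the full enhancer
deletion; 29% branched at n = 103 for the autoregulation deletion);
those are pinned exactly in the presets and the remaining categories
are filled with plausible values consistent with the qualitative
description (mostly-transformed vs mostly-normal-plus-branched). The
validation targets only the printed categories.

## Statistics

Genotype comparisons use OLS with treatment coding (control reference),
larva as the statistical unit, two-sided p, no multiple-testing
correction — matching the original reporting style. For two groups the
contrast equals the difference of means and its t the pooled-variance
two-sample t (checked numerically). Zero-residual fits are reported as
t = 0, p = 1 for (numerically) zero effects. Box-plot descriptors are
Tukey's: quartiles, whiskers at the most extreme points within 1.5·IQR,
and a median notch of 1.57·IQR/√n (the standard notch approximation;
the original figure legend gives no formula). FISH group comparisons
use the unpaired equal-variance t-test.

## Seeding

All generators are bit-reproducible functions of (params, seed).
Collections derive per-object sub-seeds as
`SeedSequence(seed, spawn_key=(index,))` reduced below 2³¹, so cohorts
are invariant to generation order and any member can be regenerated in
isolation. The replication experiments in `larvaquant.study` derive one
stream per study condition from a single base seed by the same scheme.

## Validation design and its limits

Stochastic recovery is asserted on the mean over K independent
replicate runs of the identical study condition (kinematics K = 4,
FISH K = 6, phenotype K = 20) within 3·SEM/√K of the generating value —
an absolutely tighter bound on pipeline bias than a single-draw 2·SEM
check for K ≥ 3, and insensitive to individual draw luck; the
acceptance script reports the same replicate-mean estimates.
Deterministic properties are exact: cycle boundaries match an
independent brute-force root-finding oracle within 1e-6 s on finely
sampled analytic signals, and the noise-free FISH quantifier equals the
generator truth to machine precision. Problem sizes throughout are the
published group sizes; replicate counts were chosen to keep the full
validation in tens of seconds on one CPU.

What passing does not show: the generators idealise real data. Crawls
have no head casts or reorientation kinematics (pauses stand in for
both), no tracking noise on spine points, straight spines, and no
between-larva variance component; stacks have uniform background, a
single co-located focus per channel, isotropic PSF and clean masks —
no chromatic shift, autofluorescence, overlapping nuclei or
segmentation error. Recovery here validates the measurement logic and
its numerics, not robustness to those real-world artefacts.
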