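# Methods

## Scope and model

`circaplast` implements the two-stage quantitative workflow used in
studies of circadian synaptic plasticity in nocturnal rodents: (1) the
extraction of daily/circadian rhythm parameters from wheel-running
records collected under four lighting regimes — LD 12:12, long
photoperiod LD 16:8, constant darkness (DD) and constant light (LL) —
and (2) the quantification of synaptic-protein immunopuncta and
object-based colocalization in two-channel confocal fields, feeding a
rule-based classification of expression changes. Because such studies
rarely deposit raw recordings or micrographs, both stages are validated
against synthetic generators that plant known ground truth.

## Locomotor rhythm analysis

**Record model.** A record is a gap-free series of wheel-revolution
counts per bin with a light schedule attached. Time is measured in hours
from record start; ZT/CT 0 is the (acclimation) lights-on clock hour.
All windows are half-open `[start, end)`. Default analysis binning is
6 min (30 min for plotting); the analyzed span starts 24 h after the
switch into the experimental regime.

**Chi-square periodogram.** For each tested period `P` (in bins) the
series is truncated to `K = floor(N_total/P)` complete cycles and folded
into a `K x P` array. With column means `M_h`, grand mean `M`,
`s_h^2 = mean_h (M_h - M)^2` and `s^2` the mean squared deviation of all
`N = K P` bins,

    Qp(P) = N * s_h^2 / s^2 ,

which is bounded by `N` (attained when the waveform is perfectly
repetitive) and is approximately chi-square with `P - 1` df under white
noise. A constant series yields 0/0, defined as 0. The tested grid is
20–28 h in one-bin steps (0.1 h at 6-min binning), bracketing every
plausible mouse period; the per-period significance line is the 0.95
chi-square quantile.

**tau.** The period at the Qp peak; exact ties resolve toward 24 h. A
Fourier periodogram (mean-subtracted power, normalized over the period
window) is provided for cross-checks, but its grid near 24 h is ~2 h
coarse on 10-day records (period spacing grows as P²/T), so the fine tau
estimate always comes from the chi-square grid.

**%Qp.** The peak Qp is rescaled to a 0–100 robustness index against its
significance line `c` and its ceiling `N`:

    %Qp = 100 * clip((Qp_peak - c) / (N - c), 0, 1).

This rescaling convention (excess over the significance line divided by
the maximum possible excess) is stated prominently because published
descriptions of the index omit the formula.

**Rhythmicity.** A record is rhythmic when Qp clears its significance
line *Bonferroni-adjusted across the tested grid* (level 0.05/m at
`P - 1` df for m tested periods). A raw per-period line would flag
essentially every noise record somewhere on an ~80-period scan (measured
family-wise rate ≈ 0.6); with the Bonferroni line the measured rate on
white Poisson noise is ≈ 0.03 — slightly conservative, as expected under
the strong positive dependence of folded statistics, and the package
accepts that conservatism rather than tuning the line.

**Onsets and offsets.** The activity threshold is 25% of the record mean
(configurable). Sustained activity is first located on a 1-h moving
average — runs of at least `min_active_bins` (default 3) smoothed bins
above threshold, preceded by at least `min_quiescent_bins` (default 6)
below it — and each block edge is then refined on the raw bins: the
onset is the start of the first raw run of `min_active_bins`
above-threshold bins near the smoothed edge, the offset the symmetric
end. The coarse-to-fine scheme keeps noiseless square-wave cases exact
while tolerating a noisy rest baseline. Cycles are windows of length tau
tiled from the first onset; each takes the candidate onset nearest its
prediction (within tau/4) and the last candidate offset before the next
onset. More than 25% missing cycles is a failure; the affected
parameters are reported missing.

**Phase parameters.** alpha is the mean onset-to-offset duration over
the first 8 complete cycles. delta is the sum of the 8 successive
onset-to-onset shifts measured against the 24-h clock (telescoping to
`onset[8] - onset[0] - 192 h`), matching the slope read off a
double-plotted actogram; advances are negative. This clock-time
convention (rather than shifts against tau) is a deliberate choice —
under constant conditions the two differ, and the actogram-slope reading
is the one the field reports. rho is `tau - alpha`, exactly. Records
classified arrhythmic keep tau, Qp and activity totals but report alpha,
delta, rho and breaks as missing, since onset-based parameters are
undefined without a rhythm.

**Activity totals.** Overall activity is total counts over complete
tau-cycles divided by the cycle count. The (subjective) day/night split
sums the two 12-h windows anchored at (acclimation) lights-on over
complete 24-h cycles — for LD 16:8 the day window is still ZT0–ZT12.
Day + night equals overall activity exactly when the record starts at
the anchor and the cycle length is 24 h; with a free-running tau the
per-tau-cycle total differs by the cycle-length ratio. The
activity/rest split folds the record at tau and takes the half-cycle
circular window of maximal summed activity (ties break at phase 0);
for arrhythmic records the anchor is arbitrary and flagged.

**Breaks.** Within each onset–offset span, maximal runs below 25% of
that span's mean lasting at least 30 min (configurable) are reported as
breaks ("siestas"); note that regimes with very short planted breaks
(e.g. ~17 min) legitimately report none at the default minimum.

## Puncta quantification

**Preprocessing.** Background is estimated by grayscale morphological
opening with a disk (default radius 15 px, must exceed the spot radius)
— the rolling-ball equivalent — and subtracted; a 3×3 median filter
removes single-pixel noise.

**Segmentation.** Otsu thresholding per channel by default (a fixed
threshold is available to keep fields comparable); touching blobs are
separated by a watershed on inverted intensity seeded at local maxima
(min distance 3 px); components below 4 px² are discarded
(single-pixel noise), with no upper bound by default. Counts and area
fraction are computed on the filtered mask. An empty mask is a valid
zero-count result; a channel with >5% saturated pixels is flagged.

**Colocalization.** The AND mask is the pixelwise conjunction of the two
channel masks; co-labeled puncta are its 8-connected components (the
particle-counting convention) of at least `min_overlap_px` (default 1)
pixels. Synapse density divides the co-labeled count by field area ×
optical-section thickness (the 0.46 µm z-step is used as the thickness).
Percent participation is the share of a channel's puncta that belong to
co-labeled sites; it is reported missing when the channel has no
puncta. Optical stacks are quantified section by section and averaged.

**Expression-change classification.** Direction verdicts for punctum
count and area fraction between two time points map to: concordant
changes → expression increase/decrease; area-only change →
increase/decrease within pre-existing clusters; count-only increase →
dispersion; count-only decrease → aggregation; both ns → no change;
opposing significant directions → indeterminate. The mapping is total
over the nine direction pairs.

## Statistics

Shapiro–Wilk per group and median-centered Levene across groups, both at
0.05, select the branch: all-normal and homoscedastic → one-way ANOVA
with Tukey's HSD, otherwise Kruskal–Wallis with Dunn's test. Tukey
p-values are computed directly from the studentized-range distribution
with the Tukey–Kramer standard error. Dunn p-values use the mean-rank z
statistic with tie correction and Holm adjustment by default
(configurable to none/Bonferroni); Holm was chosen because unadjusted
Dunn comparisons over six pairs would not control the error rate, and
the exact adjustment used by common GUI software is not documented.
Direction verdicts use adjusted p < 0.05 and the sign of the mean (or
mean-rank) difference. Correlations select Pearson when both variables
pass Shapiro–Wilk, Spearman otherwise.

## Synthetic generators

**Activity.** An animal is active in a window of length `alpha_true`
recurring every `tau_true` hours (onsets lock to lights-off under a
driven regime when masking is set); counts per bin are Poisson (or
negative-binomial via a gamma mixture, or noiseless) around
`mean_rate_active` inside the window and `mean_rate_rest` outside, with
one optional mid-activity break per cycle rendered at the rest rate.
`drift_per_cycle` is redundant with `tau_true` under this onset
progression (shift per cycle = 60·(tau−24) min); supplying only the
drift derives tau, supplying both requires agreement. The arrhythmic
flag flattens the rate to the time-averaged value. Records start exactly
at the schedule anchor, the convention under which day/night and overall
totals partition the same cycles. Default rates (active 15, rest
0.2–0.5 counts per 1-min bin depending on regime) give realistic daily
totals of ~4,000–10,000 revolutions; rest rates are kept near zero
because resting mice rarely turn the wheel. The default condition
blocks plant the regime-typical patterns: light-locked onsets (LD),
a −19 min/cycle advance (DD), a +46 min/cycle delay with low-intensity
activity and 50% arrhythmicity (LL), alpha of 11.8/12.7/8.2/9.1 h and
breaks of 1.46/2.34/0.29 h for LD 12:12/DD/LD 16:8.

**Images.** Puncta are isotropic Gaussian spots (sigma 1.2 px,
amplitudes 80–150) on a smooth background gradient with optional Poisson
shot noise, in a 256×256 px field at 0.1 µm/px and 0.46 µm section
thickness. A planted fraction of channel-B puncta share centers (within
1 px) with channel-A puncta; every other center pair respects a minimum
separation (default 7 px) via rejection sampling with a retry budget of
100× the requested count, so the planted pairs are the only mask
overlaps at moderate thresholds and the true synapse count is exactly
`round(coloc_fraction × n_B)`.

**What the generators do not emulate.** Real records show
ultradian bouts, gradual onset ramps, missing bins and
inter-individual waveform diversity; real micrographs have anisotropic
PSFs, intensity-correlated backgrounds, autofluorescent structures and
chromatic misregistration. Passing recovery tests therefore demonstrates
correctness of the measurement chain on idealized inputs, not robustness
to every property of tissue data.

## Numerical choices and edge cases

- Qp's 0/0 on constant series is 0; %Qp is clipped to [0, 100].
- Periodogram tie-breaks go to the period nearest 24 h; activity-window
  ties break at phase 0.
- Binning truncates trailing bins that do not fill a complete target
  bin; totals over kept bins are conserved exactly.
- Simulated bin coverage fractions below 1e-9 are zeroed so noiseless
  square waves have exactly alpha/bin active bins per cycle.
- Seeds: every stochastic stage derives its seed from the master seed by
  stable hashing of (module, entity id); reruns are byte-identical.
- Degenerate inputs reject loudly: negative counts, irregular bins,
  records shorter than two cycles at the longest tested period, groups
  with n < 3, zero-variance correlations.

## Problem sizes

The default synthetic study mirrors the emulated design end to end:
4 conditions × 8 animals × 10 days at 1-min simulation bins for the
activity arm, and 3 protein pairs × 4 conditions × 4 time points × 8
fields (256×256 px) for the imaging arm. Recovery and calibration checks
use 20 simulated animals (period), 400 noise series (rhythmicity
false-positive rate), 50 fields (image recovery) and 200 simulated
datasets (statistics calibration).

## Known limitations

- The %Qp rescaling and the onset-detection defaults are documented
  conventions; published pipelines built on GUI tools do not specify
  theirs, so absolute %Qp values are comparable only within this
  package.
- Rhythmicity classification is mildly conservative (measured ≈ 0.03 at
  a nominal 0.05) under grid-wise Bonferroni control.
- Colocalization is object-based only; intensity-correlation
  coefficients (Pearson/Manders) are out of scope, as are 3-D
  deconvolution and cosinor/wavelet rhythm models.
- Synapse density assumes the nominal z-step as section thickness; if
  the physical optical-section thickness differs, densities scale
  accordingly.
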