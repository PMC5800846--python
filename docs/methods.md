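# Methods

This note records the models, conventions and numerical choices behind
`finsomnia`, in the spirit of a package's statistical methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Behavioural sleep definition and scoring

Sleep in small fish is scored behaviourally: a sleep bout is a maximal run of
immobility of at least `min_sleep_s = 60` s, the duration at which immobility
correlates with an elevated arousal threshold.  The scorer makes that
definition operational in four deterministic steps.

**Speed.**  Per-frame speed is the Euclidean displacement between consecutive
*resolved* frames divided by their time difference, assigned to the later
frame.  Frames the tracker lost carry no speed value.  A rolling median of
width `round(smooth_window_s × frame_rate)` (default 1 s at 15 Hz = 15
frames) suppresses single-frame jitter without masking real locomotion; a
width of one frame is exactly the identity.

**Immobility.**  Frame *i* is immobile iff `speed[i] < speed_threshold`,
with strict inequality, so a frame sitting exactly on the threshold is
mobile.  The threshold is not part of the behavioural definition itself and
must be chosen; the default of 4 mm/s is of the order of one body length per
second for an adult *A. mexicanus* and is recorded in every provenance
manifest.  Sensitivity to this choice is exactly what the simulator's
monotonicity tests probe (total sleep is non-decreasing in the threshold).
Frames with no speed value inherit the preceding frame's call; the leading
frames (frame 0 has no preceding displacement) take the first defined call.

**Bouts.**  Mobile runs strictly shorter than `min_interrupt_s` (default
1 s) that are flanked by immobility on both sides are absorbed, so one noisy
frame cannot split a sleep bout; setting it to 0 recovers the strictest
reading in which any supra-threshold frame terminates a run.  Maximal
immobility runs of at least `min_sleep_s` become sleep; everything else is
wake.  Intervals are frame-edge aligned (frame *i* owns
`[i/fr, (i+1)/fr)`), half-open, and partition the recording exactly —
sleep + wake time equals the analysed window length by construction.

**Metrics.**  Over an analysis window (default: the whole recording, with
optional zeitgeber day ZT0–14 / night ZT14–24 splits; phase intervals are
half-open so the lights-off boundary belongs to night): total sleep minutes;
bout count by the midpoint rule (a bout counts in the window containing its
midpoint, and its full duration enters the mean bout length, while only its
overlapping portion enters totals and profile bins); waking activity as the
time-weighted mean speed over wake intervals only, which separates genuine
sleep gain from lethargy; and a per-bin sleep profile (default 60-min bins)
whose bin sum equals total sleep to numerical precision.

**Missing data.**  Interior gaps of at most `fill_max_gap_s` (default 1 s =
15 frames) are linearly interpolated; longer gaps stay missing and their
frames carry no speed.  Recordings with more than 20% missing frames are
rejected as unusable (the limit applies to recordings of at least 30 frames;
shorter tables are judged by content alone).  Failures are reported per
fish, never silently dropped.

## Factorial statistics

The study design crosses population (surface vs cave morph) with treatment,
so the primary model is a two-way ANOVA with interaction.  With unbalanced
cells the package uses partial (each-effect-adjusted-for-all-others,
Type-III-style) sums of squares under sum-to-zero contrasts, the convention
of the commercial packages these analyses are usually run in; in the
balanced case it reduces to the textbook decomposition
(SS_A + SS_B + SS_AB + SS_err = SS_total), which the tests verify against a
brute-force cell-means oracle at 1e-8.  A design containing a cell with a
single observation is rejected outright rather than silently losing the
interaction error term.  Two-group comparisons are the pooled-variance
unpaired *t* or the two-sample rank-sum test with normal approximation and
tie correction (the reported statistic is the standardized rank-sum z, so
swapping groups negates it).  Post-hoc families are corrected with
Holm–Šidák: sort ascending, `adj_(i) = 1 − (1 − p_(i))^(m−i+1)`, enforce
monotonicity, cap at 1.  The comparison family is always an explicit list
supplied by the caller — the package never infers which contrasts to run.
All tests are two-sided at α = 0.05.  Under a seeded null simulation the
per-effect type-I error of the ANOVA is required (in the acceptance suite)
to lie in [0.03, 0.07].

## Relative expression (ΔΔCt)

Technical replicates are collapsed by arithmetic mean; replicate SD above
0.5 cycles flags the sample but never drops it — transparency over silent
exclusion.  When samples span instrument runs, a shared calibrator sample
measured in every run defines a per-run, per-gene additive Ct offset
(anchored to the first run in sorted order; fold changes are invariant to
the anchor).  Then ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt = ΔCt − mean ΔCt of the designated calibrator group, and
fold = (1+E)^(−ΔΔCt) with amplification efficiency E = 1 by default
(2^(−ΔΔCt)).  Anchoring on the calibrator group's arithmetic-mean ΔCt —
a geometric mean in fold space — makes that group's geometric-mean fold
exactly 1, matching the convention of normalizing all samples to the
surface-fish controls.  Which group anchors the scale is a required
argument, never guessed.

## Cell detection and fluorescence quantification

Stacks are merged by per-pixel maximum across z (the max-fluorescence
projection used to view and delineate cells).  For detection the projection
is Gaussian-smoothed (σ = 1 px), thresholded at the lower-half median plus
`threshold_k = 4` robust (MAD-based) SDs, labelled with 8-connectivity,
filtered to an area band, and touching somata are split by watershed on the
mask's distance transform wherever distance maxima are at least
`min_separation` apart — distance maxima, unlike intensity maxima, are
stable on plateau-topped cells.  ROI ordering is deterministic (centroid y,
then x).  A label-mask import path lets manually drawn ROIs be quantified by
the same code.

Intensity is *not* summed on the max projection: the maximum is a nonlinear
operator that raises the apparent background between cells (the maximum of
K independent noise draws) while leaving bright cores at their single-slice
values, so any flat background subtraction on it is biased.  Integrated
intensity is instead accumulated across slices (a sum projection) over each
ROI expanded by `dilate_px = 3` px to capture the soma's sub-threshold
skirt, minus `n_slices ×` the per-voxel background estimated from pixels
well away from any detected cell.  Background subtraction is applied
unclipped per pixel with the per-cell total clipped at zero; clipping per
pixel would add `≈ 0.4σ` per background pixel and bias integrated
intensities upward.  Both background-subtracted mean and integrated
intensity are reported, since per-cell figures in this literature use
"intensity" without committing to either.

## The synthetic-data generator

The activity generator is a two-state semi-Markov model: alternating wake
and rest bouts with exponential (memoryless) durations truncated at one
frame — the minimal model given that only summary architecture metrics are
available to anchor it.  During wake the fish performs a bounded correlated
random walk (per-frame speeds gamma(shape 4, scale 5) mm/s ≈ 20 mm/s mean;
heading diffusion 0.4 rad/frame; triangle-wave reflection in a 300 × 150 mm
arena); during rest the position jitters around an anchor with 0.05 mm SD
Gaussian noise, giving smoothed speeds well below the 4 mm/s threshold.  The
emergent sleep fraction is

    f = μs/(μs+μw) · e^(−60/μs) · (1 + 60/μs),

the second factor being the time-weighted probability that an exponential
rest bout reaches 60 s.  Presets are plausibility anchors chosen to encode
the qualitative phenotypes, not estimates of real fish: surface control
μs/μw = 220/240 s (f ≈ 0.46), cavefish control 45/280 s (f ≈ 0.085, i.e.
>80% less sleep than surface), and cavefish under any sleep-promoting
treatment (orexin-receptor antagonist, starvation, lateral-line ablation)
90/150 s (f ≈ 0.32) — longer rest bouts *and* shorter wake bouts, so bout
duration and bout number both increase.  Surface presets are treatment-
insensitive.  The qPCR generator plants per-group ΔCt shifts (reference Cts
N(15, 0.2), replicate noise, per-run instrument offsets shared by both
genes) and the stack generator plants Gaussian-profile somata (peak
amplitude 50 ± 20%, σ = 2 px, Gaussian acquisition noise of SD 2.5 — a
Gaussian stand-in for Poisson-like noise) at rejection-sampled positions
honouring a minimum separation.  Every generator is bit-reproducible from
(params, seed).

What the generator deliberately does **not** emulate: circadian modulation
of bout rates within a day, non-exponential (e.g. heavy-tailed) bout-length
distributions, tracker artefacts such as identity swaps or reflections,
arena-wall thigmotaxis, and staining/batch variation in images.  Passing the
recovery tests therefore shows that the pipeline is correct and well
calibrated under the stated model, not that the model is a faithful portrait
of real recordings.

## Problem sizes and runtime choices

The validation experiments use sizes chosen to make their statistical point
at desk scale: 24-h recordings (the study's actual recording span) for the
50-seed-per-preset sleep-fraction recovery check, and shorter 0.5–2-h
recordings for the many-replicate experiments (200-replicate cohort power,
100-seed end-to-end phenotype reproduction), where the surface-vs-cave
effect is so large that brief windows already separate the groups decisively.
The end-to-end check scores in-memory cohorts; the file-based pipeline is
exercised separately on a packaged study.  The acceptance script runs
reduced-size versions of the same computations (200 oracle series, 12
recovery recordings, 500 null ANOVA replicates, 10 stacks) so that a full
from-scratch reproduction stays under a minute.

## Known limitations

Unbalanced Type-III results depend on the sum-to-zero coding convention, as
in any package; the rank-sum p uses the normal approximation (adequate for
the n ≥ 8 group sizes of these designs, less so for very small n); cell
detection assumes sparse, roughly isotropic somata and a spatially flat
background — densely packed or highly elongated cells should be delineated
manually and imported as a label mask; and the tracker-export adapter
handles the common delimited layout (preamble followed by a
`Trial time`/`X center`/`Y center` header) but is not validated against
every export version, which is why the generic CSV is the canonical
interchange format.
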