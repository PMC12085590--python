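# Methods

This note documents the models and procedures implemented in `sociotouch`,
the choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Assay timeline

A presentation bout is a 5 s touch period (platform stopped) followed by a
5 s ISI during which the platform withdraws 1 cm and returns at a constant
1.65 cm/s — a 1.2 s round trip, so a 30-min session holds exactly 180 bouts.
All trial-aligned quantities use t = 0 at the platform stop; absolute
session time is kept separately in the trial table.  The platform position
trace is modeled as a trapezoid per ISI (out at +speed, hold at the
withdrawn position, back at −speed): the stimulus stays out of reach for
the whole ISI and the platform is in motion for exactly the round-trip
travel time.  No acceleration ramp is modeled; only the constant speed is
specified.

## Firing-rate estimation and PSTHs

Spike counts are binned in half-open 50 ms bins [t, t+Δ) and divided by the
bin width, so Σ rate·Δ equals the spike count exactly; a spike on a bin edge
belongs to the later bin.  Smoothing is a centered 250 ms moving average
with a shrinking window at the edges (no padding), which keeps constants
fixed and preserves total mass.  Trials are aligned on the platform stop
over [−2, +7] s and averaged elementwise; trials extending past the
recording are dropped and reported.  The z-score normalizes to the
pre-touch ISI baseline: mean and SD are pooled over all baseline bins (and
trials, when a per-trial matrix is given).  A zero baseline SD is replaced
by a floor of 0.1 and the unit flagged rather than dropped.  The whole
bin→smooth→align chain is linear in the spike train, which the tests assert
directly.

## Response clustering

Units are clustered by the shape of their z-scored trial-averaged PSTH.
PCA keeps the smallest component set explaining >95% of variance; k-means
is restarted from fresh random centroids (10,000 by default; tests and the
pipeline use 100–200, which is converged for the problem sizes here), the
restart with the lowest within-cluster sum of squares gives the final
assignment, and the fraction of restarts in which each unit pair shares a
cluster is reported as a consensus (co-assignment) matrix.  Clustering is
made invariant to the order of input units by sorting rows canonically
before fitting and mapping the results back.  Cluster labels are numbered
by descending mean stim-window z of the centroid.

K is chosen by the gap statistic against a uniform reference drawn from the
bounding box of the scores (B = 50 draws, seeded), using the original
one-standard-error rule: the smallest k with Gap(k) ≥ Gap(k+1) − s(k+1).  A
global-max-minus-SE search (the default of a common commercial
implementation) is selectable but is noise-sensitive when the gap curve is
flat.  A known limitation, visible on the synthetic sessions: z-scored PSTH
populations have multi-scale structure (blob spread grows with blob
amplitude, largely because the baseline-SD estimate contributes ~±20%
multiplicative noise to each unit's z amplitude), and on such data the gap
curve can rise monotonically past the true cluster count, so the
conservative rule returns K = 1.  The clusterer therefore accepts a fixed
`k` (used for archetype-recovery tests, where the planted count is known),
and the raw gap-selected K is exposed separately; merging or overriding K
after inspection is left to the caller, mirroring practice.

Clusters are merged into response classes by the centroid's mean z over the
0–5 s touch window: excited above +0.25, suppressed below −0.25, weak
otherwise.  The 0.25 threshold is a configurable default chosen so that
baseline-level noise (|z| ≲ 0.1 after trial averaging) never promotes a
flat cluster.

## Modulation index

MI = (FR_stim − FR_ISI)/(FR_stim + FR_ISI), where the two rates are means
over variant-specific windows relative to the platform stop: STIM uses the
full 5 s touch vs. the following 5 s ISI of the same bout cycle (the
within-cycle ISI; a preceding-ISI variant would differ only at block
edges); SHORTSTIM uses [0, 3] vs. [−3, 0]; PLATFORM uses [−1, +1] vs.
[−3, −1].  The per-unit MI is the MI of trial-averaged rates, since the
index is defined on mean firing rates; per-trial MIs are also available and
are what the aversion-epoch split uses.  MI is antisymmetric and invariant
to rescaling both rates; both are property-tested, and for a Poisson unit
with stimulus gain g the trial-averaged MI converges to (g−1)/(g+1), which
the simulation tests verify at 200 trials.  When both rates are zero the MI
is undefined and reported as missing.

## Stimulus preference (decision-variable ROC)

For each unit the per-trial firing rate over the 5 s presentation is mapped
to a decision variable: for social trial i, DV = t_i · (mean of the other
social trials − mean of all object trials); object trials analogously with
the leave-one-out mean on the object side.  The multiplicative form is
implemented literally, including its sign behavior when the mean difference
is negative; one consequence, asserted in the tests, is that the DV-based
auROC is invariant (not complemented) under swapping the two contexts,
because the swap negates and role-swaps the DV sets.  The auROC is the
tie-aware trapezoidal area (equal to the pair-count statistic
P(DV_s > DV_o) + ½P(=), against which it is cross-checked by brute force
and by the Mann–Whitney U statistic on the DVs).

Significance uses a permutation null: context labels are reshuffled across
the pooled trials (without replacement; a with-replacement variant is
selectable), the DV→auROC statistic recomputed for each of 1000 draws, and
the two-sided p-value computed with the add-one correction (r+1)/(n+1).
Under a true null the fraction of significant units stays at α plus
binomial error, which the calibration test checks at α = 0.05.  Labels:
touch-excited units with significant auROC > 0.5 are social-preferring and
< 0.5 object-preferring; for touch-suppressed units the mapping reverses;
non-significant units are unlabeled.  An exactly-0.5 auROC is guarded to
"none" regardless of p.

## Population decoding

The decoder is a soft-margin RBF-kernel classifier with box constraint 1
and no hyperparameter tuning.  Each of 100 iterations draws a random unit
subsample (1–20 units where subsampling applies) and a stratified
train/test split with equal class counts; the default test fraction is 0.20
(16 of 80 trials), with an explicit `n_test` override for other splits.
Accuracy is reported as mean ± SE over iterations; 10-fold CV accuracy on
the training split can be recorded alongside.  Time-resolved decoding fits
an independent classifier per 50 ms bin over [−1, +2] s; behavioral
decoding bins each feature at 100 ms.  Controls: shuffling the held-out
labels at scoring time; reshuffling the context labels of a configurable
fraction (default 80%) of presentations before the split; and permuting
neural feature columns across trials while leaving locomotion columns
intact — informative neural features collapse to chance under the last
control while locomotion-borne signal survives it, which the tests plant
and verify.  Units whose baseline rate in a second session deviates from
the first session's mean baseline by strictly more than 1.5 SD are excluded
from decoding; a unit whose baseline SD is undefined (single trial) is kept
and flagged.

## Linear encoding model

Per session, 13 regressors × n trials (80 for the standard two-block forced
design): context (0/1), running avoidance (0/1), orbital (eye) area,
whisker protraction (0/1), motion energies of whisker/eye/pupil/mouth/nose
labels, pupil size, running motion energy, saccade net direction, and
locomotion (0/1).  Continuous rows are z-scored across trials; binary rows
stay {0, 1}; a constant continuous row is kept as zeros and flagged.  Two
pupil-derived regressors are deliberately distinct: pupil motion energy
(marker displacement) and pupil size (mean marker distance from the pupil
centroid).  Each unit's per-trial mean rate is regressed on the design by
ridge; the penalty is chosen per unit from a log grid 10⁻³–10³ by K-fold
(default 5) cross-validated prediction error, and cvR² = 1 − CV-SSE/SS_tot
may be negative.  Weights are normalized per unit by the sum of absolute
weights, preserving sign — a signed normalization is required because the
raw weight sum can vanish or flip sign.  A session (animal) whose mean cvR²
is negative is excluded from group summaries; per-unit flags are also
emitted.  The group summary drops binary regressors except context, leaving
10 rows for the standard design.  At zero penalty on a full-rank design the
fit equals ordinary least squares, checked against normal equations;
with planted dominant couplings the two largest mean |β_norm| regressors
are recovered.

## Behavioral features

Marker motion energy is the Euclidean displacement between frames t−2 and t
(the first two frames are zero).  Eye area is the shoelace polygon area of
the eye-outline markers; orbital tightening marks frames with area below
(1 − 0.3) × the session median.  The whisker-protraction proxy is the mean
forward (x) displacement of the whisker-follicle labels relative to its
session median, thresholded at median + 4 robust SDs (1.4826·MAD) — the
threshold is data-driven because the underlying angle definition lives in
prior work and is exposed as a parameter.  Aversive-expression bouts are
contiguous supra-threshold epochs ≥0.5 s after merging gaps <0.25 s.
Saccades are runs of |dx/dt| of the pupil centroid above a velocity
threshold, labeled temporal for positive dx and nasal for negative (a sign
convention; the generator uses the same one).  Running avoidance is the
fraction of running time (ball motion above threshold) with negative signed
direction inside the trial window; 0/0 is reported as missing.  Excluded
frames (blinks, grooming, occlusion) are NaN-masked out of every feature
and are never interpolated; a masked gap inside a bout splits it only if
the gap reaches the merge threshold.

## Synthetic sessions: what they emulate, and what they do not

One synthetic session is four blocks of 40 bouts — (voluntary, forced) ×
(object, social), 5 s stim / 5 s ISI, separated by 30 s gaps (a desk-scale
stand-in for the hour-scale separation of real sessions).  Units are
inhomogeneous-Poisson with rate = baseline × archetype profile(t) × context
gain × exp(Σ β·z(t)): profiles are 1 outside the touch window and, inside
it, 1 + 5·exp(−t/0.4) (transient), 1.8 (sustained), 0.4 (suppressed) or 1
(unmodulated); baselines are uniform on 5–7 Hz.  Context preference is a
gain ratio r = 4 split as 2r/(1+r) vs. 2/(1+r), so the across-context mean
response is conserved — archetype identity, not preference or baseline,
dominates the response geometry, which is what makes archetype-membership
recovery a well-posed test.  Optional behavior→firing coupling is
log-linear (exponential link) so rates stay positive; recovery tests use
small couplings where the log-linear and linear models agree.  Spikes are
drawn per 10 ms bin with uniform jitter within the bin.

Behavior is rendered at 120 FPS: 23 face labels plus a 6-point eye outline
and 4 pupil markers, with planted whisker-protraction bouts (forward label
displacement), orbital-tightening bouts (40% area drop), avoidance epochs
(signed ball direction) and alternating-direction saccades; planting
probabilities are context-dependent (object 0.5 vs. social 0.15 for AFEs,
0.5 vs. 0.1 for avoidance), reproducing the behavioral asymmetry the assay
is designed to expose.  A single seed drives units, spikes and behavior
through independent sub-streams, so behavior can be regenerated without
changing the spikes.

Deliberately not emulated: realistic firing-rate heterogeneity (narrow 5–7
Hz baselines keep archetype recovery well-posed; real populations span
orders of magnitude), response-shape variability within an archetype,
adaptation across bouts, correlated noise between units, whisker mechanics,
and video itself (pose labels are generated directly).  Passing the
recovery tests therefore shows the estimators are correct and calibrated on
their stated model, not that real recordings will cluster as cleanly.

## Numerical conventions

Half-open windows everywhere (time bins, depth intervals, trial windows);
boundary spikes go to the later bin; the regular-spiking waveform boundary
at 400 µs is inclusive; QC thresholds are strict inequalities
(isi_violation < 0.10, amplitude_cutoff < 0.10, median amplitude > 50 µV);
the baseline-drift exclusion is strictly greater than 1.5 SD.  Degenerate
inputs are reported, not silently fixed: missing QC metrics reject the unit
with a named reason, zero-SD baselines are flagged, MI and β normalization
return missing values on all-zero inputs, and an empty aversion class
yields a missing MI for that class.  All stochastic procedures take
explicit seeds; test problem sizes (e.g. 100 k-means restarts, 200
Monte-Carlo trials, 60-unit calibration populations) were chosen as the
smallest sizes at which the asserted statistics are stable across seeds.
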