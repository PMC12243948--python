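# Methods

`emodyn` implements an analysis pipeline for a dynamic-emotion music
fMRI design, together with a synthetic-data generator that reproduces
the design's statistical structure so every stage can be validated
end-to-end without access to scanner data.

## The design

Two ~15 min musical pieces (A and B) are each composed as 16 emotional
events drawn from five categories — calm, happy (positive valence), sad,
anxious (negative valence), and dreamy/nostalgic (mixed valence,
bookending each piece).  Every piece exists in two versions containing
the same events in a different order, so the *context* (the valence of
the preceding event) of a given event differs between versions.  Event
onsets/offsets are integers in seconds; events last 27–72 s and are
joined by short interludes.  The fMRI grid is TR = 1.5 s: a run is 6 s
silence + 896 s music (597 TRs) + 9 s silence = 607 images.

Counting adjacent non-nostalgic pairs in the shipped tables gives 7
same-valence and 6 different-valence transitions per version (13 scored
pairs; two transitions touch a nostalgic bookend and are excluded).
Twelve events (4 in piece A, 8 in piece B) have a same-valence
predecessor in one version and a different-valence predecessor in the
other; only these enter the paired timing contrast.  One interlude
(piece A version 2, events 3→4) is 13 s; timeline validation therefore
accepts gaps up to 15 s.

## Synthetic data model

Latent signal.  Each unique event has a fixed latent pattern (unit
variance, `n_features` dimensions, independent across events).  During a
run the current event's pattern is held constant; it *persists through
the following interlude* until the next event's onset.  This lingering
model gives each boundary a single well-defined switch TR, which is what
makes ±1-TR recovery a meaningful target; interludes of pure noise would
leave the boundary position unidentifiable within the gap.

Context effect.  With `context_shift = c`, the pattern evoked by event
E after predecessor P is `(1-c)·pattern(E) + c·perturb(E, P)`, where the
perturbation is a fixed random pattern keyed to the (event, predecessor)
pair — shared by every listener who hears that ordering, which is
exactly what makes same-version listeners more alike.

Timing effect.  When the incoming transition crosses valence, the
previous pattern persists `timing_delay_tr` extra TRs (default 4 TRs =
6 s) before the switch.

Subjects and noise.  The latent course is causally smoothed (half-
Gaussian, width `hrf_smooth_tr` = 2 TRs — a pattern-persistence
surrogate for hemodynamic blurring; the analyses here concern pattern
stability, not amplitude shape), pushed through a subject-specific
semi-orthogonal map into `n_units` voxels, scaled by `snr`, and summed
with unit-SD noise: a stationary AR(1) process (`ar_coef` = 0.4,
weight 0.95), white measurement noise (weight 0.05), and a slow
sinusoidal drift per voxel (amplitude 0.3, 0.5–2.5 cycles/run).  Data
are z-scored per voxel.  `snr` is the ratio of signal SD to noise SD and
is the single knob reproducing the "varying noise levels" design logic;
the operating point matching real data is unknown, so it is a free
parameter (0.5 default — the level at which group boundary recovery is
good but imperfect, the interesting regime).

An alignment run (496 TRs by default) shares one smooth latent course
across all subjects, mapped through each subject's own voxel map: the
ground truth that functional alignment must recover.  The option
`shared_voxel_map=True` gives every subject the identical map (ideal
anatomical alignment); validation suites for the *statistics* use it so
they are not confounded with alignment quality, which is tested
separately.

Behavior.  Raters mark an event with probability `press_prob` = 0.5
(about half of real raters select the intended label during an event),
turning it ON at onset + lognormal latency (mean 3 s, σ = 0.4, plus a
9 s penalty when the transition crosses valence) and OFF when the next
event arrives; spurious presses occur at 0.2/min.  Retrospective
ratings are the intended-emotion profile plus an event signature shared
by all subjects, a version-keyed offset scaled by `context_effect`, and
subject noise, rounded to 1–7.

What the generator does *not* emulate: volumetric geometry, motion and
physiological artifacts, inter-subject variability in hemodynamics, and
any relation between the acoustic signal and the neural patterns.
Passing tests therefore demonstrate that the estimators recover the
effects they target under the assumed signal model, not that those
effects exist in real recordings.

## Event segmentation HMM

States 1..K are visited in order: the transition matrix has stay
probability `diag_prob` on the diagonal and advance probability
1 − `diag_prob` on the first off-diagonal; the chain starts in state 1
and is conditioned to end in state K.  `diag_prob` defaults to (K−1)/T
and is never adjusted during fitting.  The last state's row carries only
the stay probability (no exit mass); combined with the pinned end state
this makes the prior over boundary placements exactly uniform, so the
posterior boundary is the maximum-likelihood placement.

Emissions are isotropic Gaussians evaluated on row-z-scored data against
row-z-scored event patterns (scale-invariant, correlation-like), with a
single shared variance estimated in the M-step (floor 1e-6).  The
forward–backward pass runs in log space; gamma columns are normalized.

Fitting is EM with deterministic multi-start: five contiguous-block
initializations (edge-warp factors 0.5, 0.25, 0.75, 0.1, 0.9) plus one
data-driven start that places initial boundaries at the K−1 strongest
checkerboard-kernel novelty peaks of the TR×TR correlation matrix.  The
run with the best final log-likelihood wins.  Two failure modes of a
single equal-block start motivated this: (i) with a boundary near the
run's edge, equal-block means are nearly identical and EM drifts to a
noise-driven optimum; (ii) at high snr the estimated variance collapses
after one E-step and misaligned boundaries freeze (a one-event global
misalignment that no local move repairs).  The novelty start cures both;
a K=2 exhaustive-placement oracle verifies global optimality on 100
seeded instances, and noiseless 16-event recovery is exact.  Each EM run
stops when the log-likelihood gain falls below `tol` (1e-4) or at
`max_em_iter` (100); likelihood is non-decreasing within a run.

Derivatives: per-TR Shannon entropy of gamma (natural log, in [0,
ln K]) indexes boundary uncertainty; the expected event index (labels
0..K−1) summed over a window indexes transition speed; boundaries are
TRs where the argmax event increments, ties breaking toward the earlier
event.

## Shared response model

Deterministic SRM: given time×voxel matrices X_i from a held-out
alignment run, find per-subject transforms W_i with orthonormal columns
and a shared course S minimizing Σ‖X_i − S W_iᵀ‖².  Alternation —
S ← mean(X_i W_i), then W_i ← orthogonal Procrustes of X_iᵀS — where
each step is the exact minimizer (‖S W_iᵀ‖ is W-invariant because
W_iᵀW_i = I), so the logged objective is non-increasing.
Initialization is QR of seeded Gaussians; a fixed 10 iterations keeps
runs deterministic (no early stopping).  k defaults to 80 (10% of the
largest region this design targets); transforms fit on the alignment run
are applied unchanged to music runs, keeping fitting and analysis data
disjoint.  Acoustic (or other nuisance) regressors are removed from the
shared features by ordinary least squares with an intercept.

## Permutation statistics

All tests are one-sided with the plus-one rule p = (1 + #{null ≥
observed}) / (1 + n_perm), so p is never 0; z = (observed − null mean) /
null SD.

* Boundary pattern test: mean timepoint-pair correlation within events
  minus across *adjacent* events (interlude/silence TRs excluded),
  computed via event-block sums of the correlation matrix.  Null:
  reorder the event blocks end-to-end over the labeled TRs (lengths
  preserved).
* Entropy match test: mean posterior entropy at transition TRs;
  null permutes the inter-transition segment lengths.  An optional
  ±`window_tr` evaluation window absorbs the one-TR shift that causal
  smoothing introduces; synthetic group posteriors are much sharper than
  real ones, so cohort-level checks here use window_tr = 1 (default 0).
* Context test: per piece, subjects are split into fixed random halves
  within each version; the statistic is the geometric mean of the two
  within-version half-pair correlations (averaged over events, floored
  at 1e-6 if negative, then averaged over pieces) minus the mean of the
  four cross-version pairings.  Null: shuffle version labels at the
  whole-piece level, reusing the same half split.  Event means can be
  restricted to each event's second half (floor split) as a spill-over
  control.
* Timing contrast: per eligible event, the difference in 2-state HMM
  transition sums between its same-valence and different-valence
  presentation; observed statistic is the one-sample t (mean/SD) over
  events and the headline quantity is the mean difference × 1.5 s.
  Null: random sign flips.  Predecessor windows are cropped at their
  start and (where printed durations differ between versions) event
  windows at their end, so paired windows match and the transition
  neighborhood is intact.  When recovery is exact the per-event
  differences are identical and the t statistic diverges; the
  permutation p remains valid, and the shift in seconds is the quantity
  to read.
* Behavioral tests: transition-locked pressing (per-window rater counts
  summed over windows vs uniformly re-placed non-overlapping windows;
  window −1.5 to +5.7 s around each transition), intended-emotion
  match (per-category mean rater counts vs shuffled event labels),
  time-to-threshold latency (time until 90% of an event's maximum
  ON-count; different- minus same-valence predecessor contrast within
  each polarity vs permuted class labels), and rating context
  (within- minus across-version inter-subject rating correlations vs
  shuffled version labels).

## Surface statistics

A triangulated grid graph (8-neighbour) stands in for the cortical
mesh; real meshes can be ingested as edge lists.  Searchlights are all
vertices within a hop radius of each center (default assignment mode
writes a searchlight's z to its center; a mean mode averages over
covering searchlights).  Cluster correction: clusters are connected
components of vertices with p < 0.05 uncorrected; the null distribution
is the maximum cluster size per permutation map, and clusters above its
95th percentile survive.  Family-wise error under a global null is ≤
0.08 in 200-map simulations on a 20×20 grid.

## Acoustic features

Per-event descriptors on scipy.signal STFT primitives (2048-sample
frames, 512 hop, 22.05 kHz working rate after polyphase resampling):
frame RMS mean/SD (dynamics); attack-phase log-slope of the Hilbert
envelope between 10% and 90% of each onset peak (articulation); 12-bin
chroma (FFT bins folded to pitch classes), its centroid mean/SD and
maximum (pitch content); 6-d tonal-centroid (tonnetz) maximum and
frame-to-frame harmonic-change SD (harmony); spectral centroid, spread,
roll-off (85%), and positive spectral flux (novelty).  Published
feature–rating correlation values are treated as a schema reference, not
reproduction targets, since the original frame parameters and audio are
unavailable.

## Problem sizes

Validation suites run at desk scale, chosen once: cohorts of 8–20
subjects, 24–80 voxels, 12–40 latent features; permutation counts 200 in
repeated-calibration loops (200 repeats) and 1000 elsewhere; power
curves with 10–20 repetitions.  The K=2 oracle suite uses T ≤ 20,
noise SD 0.6.  Full-scale runs (e.g., 40+ subjects, 1000 permutations,
100 power repetitions) use the same code paths through `run_pipeline`
or the CLI.

## Known limitations

* The timing contrast needs group-level pattern changes; at very low snr
  the 2-state fits lock onto noise and the low-confidence flag should be
  consulted.
* The geometric-mean context statistic is undefined for negative
  within-version reliabilities; flooring at 1e-6 biases the statistic
  toward zero at very low snr (count of floored values is reported).
* The stay probability (K−1)/T is implemented as specified even though
  it is a near-zero stay rate for K ≪ T; with the end-pinned,
  sub-stochastic last row the placement prior is uniform, so segment
  structure is driven by the emissions, but other conventions for the
  same model family scale the *advance* rate this way instead —
  `HmmConfig.diag_prob` exposes the choice.
* Statistical calibration is verified under the generator's null (snr
  = 0); real fMRI noise is richer, and temporal leakage between events
  (hemodynamic or lingering affect) can mimic context effects — the
  second-half control exists precisely for that and should be reported
  alongside the full-event statistic.
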