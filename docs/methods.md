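# Methods

`dynfc` estimates *dynamic functional connectome patterns* (DFCPs) from
multi-subject ROI time series and compares them between two groups. This
note documents the model, its assumptions, the tunable parameters, the
synthetic cohort generator, and the numerical choices made where the design
was genuinely open.

## Pipeline

### 1. Sliding-window dynamic functional connectivity

Each subject contributes a matrix `T` of shape `n_roi × M` (mean BOLD per
ROI per time point, repetition time TR in seconds). A window of fixed
*duration* `D` (default 36 s) is converted to a length in time points,
`W = round(D / TR)` — 12 volumes at TR = 3.0 s, 18 at TR = 2.0 s — and slid
with step 1. For window `b` the dFC matrix is the Pearson correlation of
every ROI pair over the `W`-point segment, with the diagonal forced to 0.
Raw `r` is used throughout; no Fisher transform is applied because every
downstream quantity (strength sums, centroid averages, the 0.75
visualisation threshold) is defined on the `r` scale. A zero-variance
segment yields correlation 0 with a logged warning rather than NaN.

The *dFC strength* (dFCS) of ROI `i` in window `b` is
`Σ_j |dFC(i, j, b)|`, a nonnegative number in `[0, n_roi − 1]`; stacking
the per-window vectors gives the `n_roi × n_windows` dFCS matrix.

### 2. Automatic quasistable segmentation

The dFCS matrix is treated as piecewise stationary along time. Let `d_i` be
the Euclidean distance between the dFCS vectors of windows `i` and `i+1`.
Window `i` ends a segment iff `d_i` is a *strict* local maximum
(`d_i > d_{i−1}` and `d_i > d_{i+1}`). Plateaus produce no boundary, the
first and last distances are never peaks, and a curve with no peaks yields
one whole-run segment; no smoothing and no minimum segment length are
imposed. Each segment is time-averaged into a single *WQCP* vector
(whole-brain quasistable connectome pattern) carrying its subject, group
and segment length. The weighted mean of a subject's WQCPs (weights =
segment lengths) equals its global mean dFCS column exactly, a conservation
property the tests assert.

### 3. Twice-clustering with Davies–Bouldin selection

WQCPs pooled over all subjects are clustered in two stages: Ward-linkage
agglomerative clustering cut at `K` fixes the initial centers, which plain
Lloyd iterations then refine (no random restarts — the procedure is fully
deterministic given the data). Ward linkage was chosen because its
variance-minimising objective matches K-means'; Euclidean distance is
forced by K-means compatibility. Inertia is asserted non-increasing at
every iteration; a cluster that empties is reseeded with the sample
farthest from its assigned center (logged). `K` is selected by minimising
the Davies–Bouldin index (mean over clusters of the worst
`(s_i + s_j)/d_ij` ratio) over an inclusive range, default 2–30, rerunning
the full twice-clustering at each candidate; ties break toward the smaller
`K`. The Ward tree is built once per dataset and cut at each `K`, which is
equivalent to refitting the hierarchy per `K` and much cheaper.

WQCP vectors are deliberately not normalised before clustering: dFCS
entries share a common scale by construction, and rescaling would distort
the strength profile that distinguishes the patterns.

### 4. Specific vs general patterns

Every sample gets a cluster label 1..K. Per subject, the occupancy ratio of
pattern `k` is the fraction of the subject's WQCP *samples* labelled `k`
(samples counted equally, not weighted by segment length; rows sum to 1).
Per pattern, an equal-variance two-sample Student t-test compares the
occupancy ratios between groups; the pattern is *specific* iff
`p < α/K` with `α = 1e-4`, otherwise *general*. Degenerate columns (zero
variance in both groups, equal means) are defined as `p = 1`, never NaN.
The threshold is parameterised as `α/K` rather than hard-coding any
particular `K`, so reduced-scale analyses scale correctly.

### 5. Edgewise group differences in general patterns

The unit of analysis is the *subject*: for each general pattern, each
subject contributes the mean of its window-level dFC matrices within that
pattern (subjects with no windows in the pattern are excluded; a pattern
with fewer than two subjects in either group is skipped with a warning).
Windows within a subject are strongly dependent — adjacent windows share
`W − 1` time points — so treating them as independent samples would
invalidate the test. Each of the `n_edges = n_roi(n_roi−1)/2` upper-triangle
edges (30,135 at 246 ROIs) is tested with the equal-variance t-test at
`p < α/n_edges`; edges significant in *every* general pattern form the
intersection set.

### 6. Hub extraction on centroid matrices

A pattern's centroid (group-scoped mean dFC matrix) is binarised over a
density grid of proportional thresholds, default 0.10–0.40 in steps of
0.01 (31 points): at density `ρ` the top `round(ρ · n_edges)` edges by
**absolute** weight are kept (centroids contain negative correlations and
anticorrelations must not be silently dropped); ties at the cutoff break by
ascending `(i, j)` order for determinism. Per binary graph the node degree
and the participation coefficient `P_i = 1 − Σ_s (k_is/k_i)²` are computed,
the community partition coming from greedy modularity maximisation on the
same thresholded graph (deterministic; a user-supplied partition is also
accepted — the "right" partition for this statistic is genuinely
underdetermined). Each metric is integrated over the density grid with the
trapezoid rule (AUC) to remove single-threshold arbitrariness. *Critical
ROIs* are nodes whose degree AUC **and** participation AUC both exceed the
across-node mean by more than one sample (n−1) standard deviation (strict
inequality; all-equal AUCs select nothing). The same selection applied to
the group-mean static FC matrix provides the static-connectivity
comparison.

### 7. Reproducibility harnesses

Subject-level resampling: fractions 0.5 and 0.9 of each group's subjects
are drawn without replacement (4 runs per rate by default), the model is
refit at the reference `K`, and the rerun's cluster centers are matched to
the reference centers by Pearson correlation with greedy highest-first
assignment. Each run reports whether the cluster matched to the reference
specific pattern was itself flagged specific and its matched correlation.
Greedy (not optimal-assignment) matching suffices because matched
correlations are near 1 in this setting. The same refit-and-match loop runs
for alternative window durations (12 s and 60 s).

## Quality control

Input series must be finite; optional 6-column rigid-body motion files
(translations in mm, rotations in degrees — degrees assumed since the
threshold is printed as 1.5°, with a radians switch available) exclude a
subject when any |translation| > 1.5 mm or any |rotation| > 1.5°, strict
inequality. The first 10 volumes of a raw run are dropped before analysis.

## Synthetic cohort generator

The generator emulates the kind of two-site clinical resting-state study
this model targets, with ground truth for every stage:

* **Design**: two groups ("patient"/"control") of `n` subjects, group
  TRs 3.0 s / 2.0 s and retained lengths 150 / 215 volumes by default.
* **States**: `S` latent connectivity states, each a block-structured
  correlation matrix — unit diagonal, `within_r = 0.9` inside a block,
  `between_r = 0.0` across blocks, repaired to positive definiteness by
  eigenvalue clipping if needed. Block sizes follow a geometric 1:2:4:8
  proportion and the ROI-to-block assignment is permuted per state. Unequal
  sizes are essential, not cosmetic: with equal blocks the dFCS row sums
  are permutation-invariant, making all states identical in WQCP space.
  The dominant block gives each state a distinct hub module.
* **Dynamics**: a first-order Markov chain (the simplest process producing
  quasistable epochs). The chain stays in state `i` with probability
  `1 − 1/mean_dwell`; on a jump the next state is drawn with probability
  `∝ occupancy_j / mean_dwell_j`, which makes the stationary occupancy
  exactly the configured one. Exact occupancy and exact nominal dwell
  cannot both hold in such a chain; occupancy is prioritised, and the
  realised dwell is `mean_dwell/(1 − q_i)`. Default `mean_dwell = 40` time
  points.
* **Signal**: given the state at time `t`, the ROI vector is an
  independent multivariate-normal draw with that state's covariance plus
  isotropic observation noise (sd 0.2). There is no haemodynamic response,
  no temporal autocorrelation within states, no scanner drift and no
  subject-level random effects — passing tests therefore demonstrate the
  pipeline's statistical behaviour under its own assumptions, not
  performance on real fMRI.
* **Planted group difference**: state 0's occupancy defaults to 0.45 in
  patients vs 0.05 in controls, the rest spread evenly. At least ~5 states
  are needed for a clean "exactly one specific pattern" readout: with two
  states the occupancy columns are complementary and share the same |t|,
  and the complementary mass spread over `S − 1` states keeps each
  non-differential difference (0.4/(S−1)) below the conservative `α/K`
  threshold.
* **Determinism**: per-subject streams are spawned from the cohort seed
  (`SeedSequence(seed, spawn_key=(group, subject))`), so cohorts are
  bit-reproducible regardless of generation order.

The defaults were calibrated once, jointly, so that the planted structure
is detectable at desk scale (40 ROIs): the two-TR design induces a small
group-level offset in dFCS baselines (windows of 12 vs 18 points have
different |r| sampling bias), and state separation must dominate both this
offset and the short-segment averaging noise, otherwise the Davies–Bouldin
selection splits state clouds by group.

## Problem sizes

Tests and the acceptance script run at 40 ROIs with 10 subjects/group for
state-count recovery and 34 subjects/group for the detection, null and
resampling analyses; `K` is searched over 2–8 there since at most 5 states
are planted. The full 246-ROI scale is supported throughout (the 246-edge
arithmetic, atlas bookkeeping and per-window memory are exercised
directly); a full-scale cohort mainly costs memory for the per-subject dFC
tensors (~0.1 GB per subject at 246 ROIs × 200 windows).

## Known limitations

* Segment boundaries are noise-sensitive: every strict local maximum of
  the adjacent-distance curve is a boundary, so typical segments are only
  a few windows long and WQCPs retain most single-window noise. This
  matches the published procedure; a minimum segment length or smoothing
  would change the sample set.
* The participation coefficient depends on the community partition, which
  is itself estimated per thresholded graph; results for nodes near the
  selection boundary can shift with the partition.
* The pooled clustering can split states by group when group-specific
  window lengths differ and state separation is weak (see calibration
  note above); real-data analyses pooling different TRs inherit the same
  caveat.
* Student (equal-variance) t-tests are used wherever a two-sample test is
  specified; no FDR or permutation alternatives are provided.
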