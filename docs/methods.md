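# Methods

`maskqc` implements an unsupervised, training-free quality-control (QC)
procedure for brain-extraction masks. The premise: a cohort of trusted
ground-truth masks B defines, through its morphological feature
distribution, what a plausible brain mask looks like; a candidate mask is
flagged when its features sit too far outside that distribution. No image
intensities and no labeled failures are needed — only binary masks.

## The model

**Features.** Each mask is reduced to 23 scalar shape descriptors computed
from the binary label in physical (mm) units: foreground count and volume;
exposed-face surface area, its volume-border portion and their ratio;
elongation √(λ1/λ2) and flatness √(λ2/λ3) from the eigenvalues λ1 ≥ λ2 ≥ λ3
of the second central moment matrix (the population covariance of foreground
voxel positions); roundness; equivalent-sphere radius and surface; the three
equivalent-ellipsoid diameters (volume-matched via the gamma-function n-ball
relation); the maximum caliper (Feret) diameter; the three principal
moments; the centroid offset from the volume center; and the three
bounding-box extents. All foreground voxels count, deliberately without
largest-component filtering: spurious disconnected blobs are exactly the
failures QC must see. Features are z-scored with the baseline's own
population mean and standard deviation (constant features map to 0).

The supported catalogue holds one further descriptor (border foreground
voxel count, redundant with the border-surface features); any ordered
23-name subset can be configured — the scoring machinery is list-agnostic.

**Baseline.** The normalized baseline features are partitioned by k-means.
k is selected from 2..10 by a stability criterion: at each k, 500
differently-seeded single-init runs are performed and the mean pairwise
adjusted Rand index over a seeded subsample of run pairs measures how
reproducible the partition is. The adjusted (chance-corrected) index is
essential: the raw Rand index drifts upward with k through chance agreement
and selects spuriously fine partitions on unstructured data. Exact ties
break toward the **largest** tied k: every stable coarsening of genuinely
clustered data also saturates the stability score (merging two of three
well-separated groups is often perfectly reproducible), and among equally
stable candidates the finest partition resolves the most structure. The
final partition is the lowest-inertia run at the chosen k; any singleton
cluster triggers a refit at k−1 (down to 2).

**Distances.** Each cluster C_i is summarized by its mean and a regularized
covariance. The shrinkage target is a scaled identity and the intensity is
`max(ledoit_wolf, p/n_i)`, capped at 1, with a 1e-6 floor. The Ledoit-Wolf
estimate minimizes covariance error but badly under-regularizes the
*inverse* needed for Mahalanobis distances when a cluster's size n_i is
close to the feature count p = 23; the p/n_i floor keeps out-of-sample
distances calibrated against in-sample ones at small cluster sizes and is
negligible for the hundreds-strong clusters of a production baseline. A
candidate vector v gets per-cluster Mahalanobis distances d(v, C_i), the
minimum d_min(v) (local similarity: closeness to *some* plausible shape
mode), and the weighted mean d̄(v) = Σ_i d(v, C_i)/|C_i| (global
similarity). Note the division by cluster size: small clusters dominate
this sum. That is the statistic as specified; a conventional size-weighted
mean (Σ|C_i|d_i/Σ|C_i|) and a median variant are available through
`d_bar_mode`.

**Thresholds and score.** t_min and t_mu are the nth percentiles (linear
interpolation; default n = 90) of the baseline's own d_min and d̄
distributions. The similarity score is

    r = (2/π) · arctan( γ·d_min/t_min + (1−γ)·d̄/t_mu ),   γ = 0.75,

and a mask passes iff r ≤ r_max = 0.5. With the 2/π constant, r lies in
[0, 1) and a mask sitting exactly on both thresholds scores exactly 0.5 —
which is what makes 0.5 a meaningful default cutoff. A literal π/2 constant
(range [0, π²/4)) is available behind `arctan_constant="literal"` for
compatibility with the alternative normalization. γ > 0.5 weighs local
similarity above global: a mask resembling a legitimate minority mode of
the baseline should not be rejected merely for deviating from the average
trend.

## Parameters that matter

| parameter | default | effect |
|---|---|---|
| `gamma` | 0.75 | weight of d_min/t_min vs d̄/t_mu in r |
| `percentile` | 90 | threshold percentile; lower ⇒ stricter QC |
| `r_max` | 0.5 | pass cutoff on r (boundary passes) |
| `k_min..k_max` | 2..10 | cluster counts considered |
| `clustering_runs` | 500 | stability runs per k |
| `d_bar_mode` | inverse_size | d̄ statistic (as specified / size-weighted / median) |
| `shrinkage_floor` | 1e-6 | lower bound on covariance shrinkage |
| `min_baseline` | 30 | minimum |B| accepted for fitting |

By construction roughly (100−n)% of the baseline itself scores r > 0.5, so
the method can never be 100% specific; lowering `percentile` trades
specificity for sensitivity.

## Evaluation harness

Dice overlap 2|A∩B|/(|A|+|B|) (both-empty = 1, one-empty = 0) and the
symmetric 95th-percentile Hausdorff distance (HD95) between mask surfaces —
face-connected boundary voxels, distances in mm, percentile per direction
with linear interpolation, maximum over the two directions — grade candidate
masks against ground truth. A candidate is *sanity-positive* (expected to
fail QC) iff Dice < 0.95 or HD95 > 15 mm, both strict. QC verdicts against
sanity labels populate a confusion matrix (flagging a faulty mask is a true
positive); undefined ratios are reported as NaN, never 0.

## Synthetic cohorts

The generator makes brain-like masks so every stage is testable without
data downloads: a jittered triaxial ellipsoid implicit function plus
band-limited Gaussian deformation, thresholded to a single connected,
border-free component. A cohort draws each subject's base semi-axes from
three discrete population modes (typical, larger-headed, and a flatter
post-operative-like shape), emulating the multi-site, mixed pre/post-op
composition of real ground-truth cohorts — this mode structure is what gives
the baseline genuine clusters for k-means to find. Within a mode, variation
is deliberately low-rank: 3.5% per-axis size jitter, 1.5 mm center jitter,
and a smooth deformation of amplitude 0.03 at 24 mm correlation length,
reflecting that real brain outlines differ mostly in overall size,
proportions and position rather than independent fine-scale surface noise.

Corruptions emulate characteristic skull-stripping failures: over-erosion,
over-inclusion (dilation), internal holes, spurious extracranial blobs,
axial truncation, and misregistration-like translation. Magnitudes are
solved by stepping or bisection to land in a target Dice band (default
0.70–0.90) against the clean original, so cohort composition is controlled,
not left to luck; the extracranial blob is instead placed ≥ 25 mm from the
brain surface so HD95 exceeds 15 mm while Dice stays high — exercising the
HD95 arm of the sanity rule.

What the generator does *not* reproduce: cortical folding, modality- or
method-specific failure signatures, intensity information, and the long
anatomical tails of real populations. Passing the synthetic screen shows
the machinery separates plausible from implausible shapes under controlled
contrast; it does not certify performance on any particular clinical
cohort, where the baseline's composition and the feature list must be
validated per use case.

## Numerical choices and degenerate inputs

- Central moments use unit voxel weights at voxel centers (0-based index ×
  spacing); the matrix is the non-negative population covariance. Single
  voxel ⇒ zero matrix; empty masks raise.
- Eigenvalue-ratio features floor the denominator eigenvalue, and the
  equivalent-ellipsoid diameters fall back to the equivalent sphere when a
  moment vanishes, so degenerate (planar/linear) masks stay finite.
- Mahalanobis squared distances are clipped at 0 before the square root
  against floating-point round-off; a cluster of identical points falls
  back to the pseudo-inverse.
- Percentiles (thresholds and HD95) interpolate linearly between order
  statistics.
- Near-identical baseline features raise a degenerate-clustering error
  rather than silently fitting thresholds of zero.
- Batch scoring isolates per-mask failures (e.g. an empty file) as error
  rows with a fail verdict instead of aborting the cohort run.
- All randomness flows from explicit integer seeds; refitting with the same
  inputs and seed is bit-identical, and pipeline reruns write byte-identical
  score tables.

## Problem sizes used in the shipped checks

The end-to-end screen fits 60 clean baseline masks and scores 40 clean +
40 corrupt test masks on 96³ grids at 1 mm isotropic spacing (one seeded
generation stream); unit and property tests run on 12–48 voxel grids.
Cluster counts in the screen resolve to the generator's population modes
(k = 2 with the two closest modes merged, or k = 3).

## Known limitations

- The d̄ statistic as specified is inverse-size weighted; with very uneven
  cluster sizes a tiny cluster dominates the global term. Use
  `d_bar_mode="size_weighted"` if that is not the intent for your cohort.
- With a small baseline (|B| near `min_baseline`) the percentile thresholds
  carry sampling noise of order 1/√|B| and out-of-sample specificity sits
  measurably below the in-sample (100−n)% by construction.
- r is a rank-style score, not a calibrated probability; comparisons are
  meaningful against one fitted baseline, not across baselines.
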