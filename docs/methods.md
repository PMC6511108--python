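# Methods

`svdconn` implements an analysis chain for studying how white-matter damage
from cerebral small vessel disease (SVD) relates to apathy through the
topology of the structural connectome: deterministic tensor tractography,
length-corrected connectome construction, whole-brain graph metrics,
edgewise permutation inference (the network-based statistic, NBS), and
cohort-level mediation / ANCOVA statistics. A synthetic-cohort generator
provides fully reproducible inputs with known ground truth, so every stage
is testable end to end without imaging data.

## Tractography

The tracker operates on a field of symmetric diffusion tensors with
non-negative eigenvalues. Streamlines are seeded on an evenly spaced grid
(default 0.5 mm) at every point whose interpolated fractional anisotropy
(FA) clears the tracking threshold, and are propagated in both the
orthograde and retrograde directions along the principal eigenvector of the
interpolated tensor. Propagation terminates when FA < 0.2, when the turning
angle between successive principal eigenvectors reaches 45°, when a maximum
length (default 300 mm) is reached, or when the streamline leaves the
volume. FA is the standard normalized eigenvalue dispersion,
sqrt(3/2)·‖λ − λ̄‖/‖λ‖ ∈ [0, 1].

Numerical choices:

- **Integration** is fixed-step Euler with a default step of 0.5 mm (half
  the voxel pitch of typical diffusion acquisitions). At this step the
  worst-case chord error on curved trajectories is well below the voxel
  size; the geometry tests verify straight-bundle lengths to within one
  step of the analytic chord and full traversal of arcs whose per-step
  tangent rotation is below the angle threshold.
- **Interpolation** is component-wise trilinear interpolation of the six
  unique tensor components, followed by eigen-decomposition at the tracking
  point. The interpolatable region is the box spanned by the centres of the
  boundary voxels; stepping outside it terminates the streamline.
- **Eigenvector sign** is chosen for continuity with the previous step
  direction (positive dot product); the first step uses a fixed
  first-nonzero-component-positive convention. A leading-eigenvalue tie
  (gap ≤ 1e-10 relative) is a termination signal, not an error: the
  principal direction is undefined there, as at orthogonal fiber crossings.
- **Seeding below the FA threshold** is pointless (the streamline would
  terminate immediately), so such seeds are skipped.
- **Duplicates are kept.** Several seeds along one trajectory reconstruct
  the same streamline; the connectome stage's 1/length weighting is the
  correction for exactly this multiplicity, so the tracker does not
  deduplicate.

## Connectome construction

Nodes are the regions of an integer parcellation (90 regions, 45 per
hemisphere, in the standard whole-brain configuration). A streamline
contributes to the edge (i, j) when its two terminal points fall in regions
i ≠ j; the edge weight is

    w(e_ij) = Σ_{n ∈ N_ij} 1 / (κ · l_n)

with l_n the streamline length in mm and κ the seed density in seeds per
millimetre (default 2.0 for the 0.5 mm grid). Dividing by κ·l cancels the
along-track seed multiplicity — a streamline of length l collects about κ·l
seeds — so long connections are not weighted up merely because they carry
more seeds. Cross-sectional seeds reconstruct *distinct* parallel
trajectories and are deliberately retained; the tests assert exact
invariance for along-track refinement and approximate invariance for the
tracked phantom. Edges below the threshold (default 1.0) are removed as
likely false positives; the comparison is keep-if-≥ with a 1e-9 relative
tolerance so exact-boundary weights survive floating-point accumulation.
Thresholded weights are retained, not binarized. A terminal point exactly
on a voxel boundary belongs to the upper voxel (floor of the corner
coordinate). Streamlines with an unlabeled endpoint or both endpoints in
one region contribute to no edge.

## Graph metrics

Density is the ratio of observed to possible edges. Connection weights map
to lengths as 1/w; global efficiency is the average inverse weighted
shortest-path distance over ordered node pairs, with disconnected pairs
contributing zero (disconnected pairs are common in SVD networks, and the
measure remains well defined). Local efficiency of a node is the global
efficiency of the subgraph induced by its neighbors (nonzero-weight ties,
original weights retained); nodes with fewer than two neighbors contribute
zero, and the network value is the mean over all nodes. Under a uniform
multiplicative attenuation of all weights by c, every shortest-path
distance scales by 1/c and global efficiency by exactly c — the property
the synthetic generator exploits. Shortest paths use Dijkstra's algorithm;
an independent Floyd–Warshall enumeration serves as the test oracle
(agreement < 1e-10 on random graphs).

## Network-based statistic

An ordinary-least-squares GLM is fitted at every edge that is nonzero in at
least one participant (the coverage rule is configurable); the contrast
t-statistic is thresholded at t ≥ 3.1 by default (approximately the
one-sided p = 0.001 tail at cohort-scale degrees of freedom), and connected
components of suprathreshold edges are measured by *extent* (edge count).
Familywise error is controlled by permutation: each permutation's maximal
component extent forms the null distribution, and a component of size s
gets corrected p = (1 + #{null ≥ s})/(1 + B), which is always positive and
attains 1/(1 + B) as its minimum. Tests are one-sided; a two-tailed
analysis runs the ± contrasts separately at α = 0.025 per tail.

Nuisance covariates are handled with the Freedman–Lane scheme: the reduced
model (columns with zero contrast weight) is fitted, its residuals are
permuted and the reduced fit added back, and the full model is refitted on
the reconstructed data. With no nuisance terms this reduces to permuting
the outcome rows, which is distributionally identical to permuting the
predictor of interest (verified numerically). Edges with a (near-)perfect
fit carry no evidence and are assigned t = 0.

A calibration caveat documented by the type-I-error study: extent is an
integer statistic, so at sparse primary thresholds its null distribution
has very few support points and the permutation test is conservative (the
attained level can fall well below nominal). The calibration study
therefore uses primary threshold t = 2.0 on 30-node null networks, where
the null extent distribution is fine-grained and the attained familywise
error sits inside the binomial interval around the nominal 0.05. This is a
property of cluster-extent inference generally, not of the implementation.

## Cohort statistics

- **Group assignment**: apathy = AES ≥ 34 and CESD < 16; depression =
  AES < 34 and CESD ≥ 16; comorbid = both at or above the cuts; control
  otherwise. Both cut comparisons are inclusive (≥).
- **Transforms**: white-matter-hyperintensity (WMH) volumes and lacunar
  infarct (LI) counts are right-skewed; both are transformed as log(1 + x),
  which handles zero counts uniformly.
- **Correlations** are Pearson, with step-down Holm adjustment across the
  variable list.
- **Mediation** is sequential standardized OLS: β (total) from y ~ x,
  β′ (direct) from y ~ x + m, the a-path from m ~ x, the b-path as the
  mediator coefficient in the direct model; covariates may be added to all
  fits and several mediators may enter simultaneously. For a single
  mediator without covariates, β = β′ + a·b is an exact algebraic identity
  (asserted to 1e-10). Inference is normal-theory on the standardized
  coefficients, matching how before/after-conditioning path estimates are
  conventionally reported; for multiple simultaneous mediators the sequential
  fits coincide with the simultaneous-equations estimates for these
  quantities because each equation is exactly identified.
- **ANCOVA** uses type II sums of squares (each term tested against the
  model containing all other terms, no interactions) — the appropriate
  decomposition for the unbalanced group sizes that AES/CESD cut scores
  produce. An explicit full-vs-reduced residual-SS oracle verifies the
  implementation.
- **Post hocs** compare covariate-adjusted group means (cell-means coding
  with centred covariates, so each group coefficient is the adjusted mean).
  Tukey's honest significant difference uses the studentized range on the
  exact coefficient covariance; the Fisher option is the same contrasts
  with unadjusted t-tests. With two groups Tukey reduces to the pooled t.
- **Contingency**: Pearson chi-square without continuity correction (group
  sizes are large), plus 2×2 odds ratios with Wald p-values for named group
  pairs.

## Synthetic cohorts

The generator encodes the causal structure the pipeline is designed to
detect, with multiplicative weight attenuation chosen because global
efficiency is then *provably* proportional to the common factor:

1. SVD burden B_i combines z-scored log WMH volume (log-normal, default
   log-mean 1.5, log-sd 1.0 — a median of ~4.5 mL with a heavy right tail)
   and LI count (Poisson, mean 0.8, mostly zeros) with 0.7/0.3 weights.
2. Every edge of a base connectome (a connected weighted template: ring
   plus 15% random long-range edges, weights on the scale of thresholded
   length-corrected streamline counts) is scaled by
   exp(−svd_effect·B_i + ε_i), with svd_effect = 0.15 per SD of burden and
   participant-level integrity noise ε_i ~ N(0, 0.1). The integrity noise
   represents individual differences in network integrity not captured by
   the two lesion markers; without it, efficiency would be a deterministic
   function of burden and the efficiency→apathy direct path would be
   unidentifiable. Per-edge log-normal measurement noise (sd 0.1) is added
   on top.
3. The apathy latent loads on cohort-standardized global efficiency with
   standardized effect −0.8 (default) plus independent residual noise;
   a planted edge set is *additionally* attenuated by exp(−edge_effect·z_A),
   giving a regional deficit specific to apathy. Depression correlates with
   apathy (default r = 0.5) but never touches the weights, so the
   apathy/depression dissociation reported for SVD cohorts is testable.
4. AES and CESD scales are affine maps of the latents calibrated so the
   clinical cut scores land on the quantiles implied by the target group
   mix (default 26/48/32/225 out of 331 — apathy, depression, comorbid,
   control); scores are rounded and clipped to the instruments' ranges.
   Age, MMSE, education, sex, and antidepressant use are drawn with mild
   loadings on the latents (antidepressant use loads on depression, so the
   group-contingency analysis has signal).

What the generator does **not** emulate: anatomical geometry (regions are
axis-aligned boxes; topology, not anatomy, is what downstream stages
consume), realistic MRI noise or artifacts, raw diffusion-weighted signal
(tensors are generated directly), missing data, and the empirical
correlation structure of any particular cohort. Passing tests therefore
demonstrate the statistical machinery recovers known generative structure
at realistic sample sizes — not that a specific clinical dataset would
yield specific estimates.

## Problem sizes used in validation

The validation studies are sized for a single CPU: type-I calibration uses
500 null cohorts of 60 participants on 30-node networks with 1,000
permutations each; planted-subnetwork recovery uses 20 cohorts of 200
participants; mediation recovery uses 200 replicates of n = 1,000; the
qualitative mediation signature uses 20 cohorts of 331 participants on
30-node networks. The demo pipeline runs 60 participants with 1,000
permutations. All stages scale to 90-node, 10,000-permutation analyses by
configuration.

## Known limitations

- The tracker is single-tensor and deterministic; crossing fibers blend
  into oblate tensors (under the 'sum' policy) and terminate tracking, as
  is characteristic of tensor tractography.
- The edge-weight convention (κ in seeds/mm) is one of several in use;
  κ = 1 reproduces plain inverse-length weighting, and conclusions driven
  by relative weights are insensitive to κ's absolute scale.
- Permutation p-values inherit the discreteness of the extent statistic
  (see above); reported corrected p-values are exact but conservative at
  sparse thresholds.
- The mediation machinery is regression-based; it estimates path
  coefficients under the usual no-unmeasured-confounding assumptions and
  does not attempt causal identification beyond them.
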