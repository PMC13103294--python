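# Methods

This note documents the models and procedures implemented in `foca`, the
assumptions behind them, the defaults that matter, and what the synthetic
validation studies do and do not establish.

## The estimator

A subject's data are a T x V surface BOLD matrix with a per-frame framewise
displacement (FD) trace and a parcellation of the V vertices into K networks.
The topography map of network i is the Fisher-z correlation of the network's
mean time series with every vertex; correlations are clipped to
+/-(1 - 1e-7) before arctanh so maps stay finite (a vertex identical to its
seed maps to arctanh(1 - 1e-7) ~ 8.5).  The FOCA matrix is the K x K Pearson
correlation of these maps across vertices, with unit diagonal.  All
matrix-to-matrix comparisons (consistency, reliability, similarity to a
reference) correlate strict upper triangles only: the diagonal and symmetry
carry no information.

The Fisher-z transform is monotone, so the sign structure (convergent vs
divergent couplings) is identical to what raw-r maps would give; magnitudes
differ slightly.  The closed-form oracle in `synthgen.oracle_foca` is the
expectation of this estimator in the noise-free limit: the expected map of
network i is the latent coupling C[i, label(v)] expanded over vertices,
passed through the same clipped arctanh, then correlated.  Omitting the
transform (available via `fisher_z=False`) changes nothing when C = I —
both give off-diagonal entries of -1/(K-1) for equal network sizes — but for
general C only the z-scale oracle is the estimator's limit, because the
self-network value r = 1 is a large leverage point after arctanh.

## Individualization

Templates: per network, the seed series over the group mask, one Fisher-z
map per subject, subject-average, z-scored across vertices, thresholded at
z > 1 (retaining the top ~15.9% of a Gaussian map).  Matching: each vertex's
dense connectivity profile (Pearson r to every vertex, self-term included —
it is constant across candidate networks) is z-scored and binarized at the
same threshold, then scored against each binary template mask by the
symmetric eta-squared similarity; ties break to the lowest network index.
Binarizing both profile and template is the default because both sides are
thresholded with the same criterion; a continuous-profile mode
(`binarize_profiles=False`) is available.  Zero-variance vertices are
assigned the neighbourhood-majority label with a warning.

Within-network homogeneity — used to show individualized parcellations beat
the group atlas — is defined here as the mean pairwise Pearson correlation
of vertex time series within a network (singletons are reported missing);
the cohort-level comparison is a paired t-test with Cohen's d.  The metric
definition is a package choice; it is recorded in outputs.

## Preprocessing

Confound regression is ordinary least squares per vertex with an intercept
always included; rank-deficient designs are rejected naming the offending
columns.  Scrubbing censors (removes) frames with FD above 0.5 mm by
default and refuses to proceed with fewer than 50 surviving frames; removal
rather than spike-regressor insertion is equivalent at this scale and keeps
the contract simple.  Temporal filtering is a zero-phase 4th-order
Butterworth band-pass, defaulting to 0.01-0.08 Hz (the standard resting
band).  Surface smoothing builds row-normalized Gaussian weights over
graph-geodesic (shortest-path) distances on the mesh, truncated at 3 sigma,
with sigma = FWHM / (2 sqrt(2 ln 2)) (6 mm -> 2.55 mm); the same weight
matrix applies to every frame by linearity.  Global signal regression
removes the cortex-mean series (with intercept) from every vertex.  Every
operation appends to the scan's provenance history.

## Synthetic cohort generator

The generator emulates exactly the statistical structure the estimator
assumes, nothing more:

- **Latent couplings.**  K unit-variance network signals with correlation
  matrix C (symmetric, PSD, unit diagonal, signed).  A requested target is
  repaired to the nearest PSD correlation by eigenvalue clipping at zero and
  diagonal rescaling.
- **Labels.**  Contiguous rectangular patches tiling a grid mesh; each
  subject flips a fraction (`boundary_shift_rate`, default 0) of boundary
  vertices to an adjacent network's label — boundary-level individual
  variability without destroying topology.
- **Global signal.**  An independent unit-variance AR(1) series (rho = 0.3)
  added with weight g to every vertex.
- **Noise.**  White vertex noise with standard deviation `noise_sd`.
- **Motion.**  FD baseline |N(0.05, 0.02)| mm with Bernoulli(0.05) spikes at
  |N(0.8, 0.2)| mm, exercising the 0.5-mm censoring rule; degenerate
  all-spike draws are retried a bounded number of times.  The subject's
  `mean_fd` metadata is the mean of the generated trace.
- **Age effects.**  Slopes applied to targeted couplings on the Fisher-z
  scale, anchored at a reference age (default 40.5 weeks, the centre of the
  37-44-week postmenstrual window used for neonatal cohorts), then
  PSD-repaired.  The z-scale keeps couplings in range at any age.
- **Behaviour scores.**  Linear combinations of one network's Fisher-z
  coupling profile plus Gaussian noise.

Not emulated: hemodynamic convolution, spatially autocorrelated noise,
realistic mesh anatomy, distance-dependent motion artefacts.  Passing tests
therefore demonstrate correctness of the estimators and the direction of
method contrasts under the assumed generative structure — not performance on
real BOLD, where additional nuisance structure exists.  Noise levels for
neonatal vs adult groups are not separately calibrated; presets expose
`noise_sd` per cohort.

## Downstream models

**Clustering.**  Features are FOCA rows with self-entries masked: the
distance between networks i and j is 1 minus the Pearson correlation of
their rows over the K - 2 entries excluding both self-terms (the unit
diagonal would otherwise inflate similarity; with the diagonal's treatment
genuinely open, masking is the package's choice).  Agglomeration is average
linkage; flat cuts default to 6 clusters and 3 hyper-clusters, stored as
configuration rather than asserted on synthetic data.  A reference solution
can be projected onto another cohort's matrix (same K and ordering) for
developmental comparison.

**Axis regression.**  Each axis's per-network values are min-max scaled
(absorbing units) and turned into an alignment matrix, 1 - |v_i - v_j|.
Observations are the 190 unique pairs at K = 20 (diagonal excluded).  Each
of 100 repeats shuffles a 10-fold split; out-of-fold predictions are pooled
into an adjusted R^2 with n = edges, p = axes.  The permutation p-value
shuffles edge targets with no spatial structure preserved (a documented
simplification).  Feature contributions are |standardized beta| normalized
to 100%.

**Developmental screening.**  Per edge, coupling across subjects is
modelled as linear covariates (sex, mean FD, scan-birth interval) plus a
smooth function of age — a cubic B-spline basis (5 functions over the
observed range) with a second-difference penalty whose null space contains
linear trends, smoothing selected per edge by GCV over a log-spaced lambda
grid.  Smooth-term significance is the exact F-test of the unpenalized
spline block against the covariates-only model: under a Gaussian null these
p-values are exactly uniform, so Benjamini-Hochberg control across the 190
edges is calibrated — which the null-replicate study verifies.  P-values
from the penalized fit itself would need effective-degrees-of-freedom
approximations of uncertain calibration; the penalized fit is used for the
reported trajectories (covariates held at their means).  On strictly linear
data the GCV-penalized fit shrinks to the OLS line.

**Prediction.**  Behaviour: one regression per network (score on covariates
plus the network's K-1 couplings), significance by partial F of the coupling
block, BH-FDR across the K networks; both in-sample and 10-fold
cross-validated accuracy are reported since the accuracy convention is a
free choice.  Age: linear SVR (C = 1, epsilon = 0.1) on vectorized edges;
confounds are regressed from features and ages with coefficients fitted on
training folds only; accuracy is the Pearson r between held-out predictions
and residualized ages, pooled per repeat; permutation p shuffles ages;
method comparisons are paired t-tests over repeats.

**FC comparison.**  Conventional FC is the Fisher-z temporal correlation of
network-mean series on the same individualized parcellation.  The
GSR-stability metric is the upper-triangle RMSE between GSR and non-GSR
matrices divided by the mean |entry| of the non-GSR matrix — the absolute
mean, because the signed mean of a matrix with negative couplings can sit
near zero and destabilize the ratio.  Negative-edge analyses freeze the edge
set from the group-mean matrix of the corresponding method and condition.

## Reliability

The duration-reliability procedure holds out a fixed reference block
(default 70 min) at the end of the censored-surviving frames, then samples
contiguous runs of surviving frames (respecting temporal autocorrelation;
an arbitrary-frame mode exists) of each requested duration from the
remaining pool, computing the upper-triangle correlation with the reference
per repetition.

## Validation study sizes and numerical choices

The frozen studies in `foca.benchmarks` use 20 x 20 = 400-vertex meshes with
K = 5-6 planted networks for signal-level analyses and the K = 20 / 190-edge
layout for matrix-level analyses; cohorts of 20-50 subjects with 300-frame
runs; a 9000-frame (300-minute at TR = 2 s) single scan for reliability with
vertex noise sd 20 — a low per-vertex SNR regime in which short scans are
visibly less reliable, mirroring the regime where scan duration matters.
Oracle agreement uses 5000 frames with zero noise.  Null error control uses
200 replicate cohorts of 60 subjects.  Correlation clipping is 1 - 1e-7
everywhere; PSD repair tolerates eigenvalues down to -1e-8; degenerate
inputs (constant maps, empty networks, zero-variance seeds, rank-deficient
designs, all-spike FD) raise errors naming the offender rather than
propagating NaNs.

## Known limitations

- Network-pair resolution only: no vertex-level coupling maps, no dynamic or
  time-varying topographies.
- The eta-squared variant (binarized profiles) and the homogeneity metric
  are package choices among reasonable alternatives; both are configurable
  or recorded in outputs.
- The permutation scheme for axis regression ignores spatial autocorrelation
  of edges, so its p-values are optimistic for spatially smooth axes.
- The generator's simplifications listed above mean directional
  FOCA-vs-FC results on synthetic cohorts demonstrate mechanism, not
  real-data effect sizes.
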