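# Methods

## Overview

`mtdnet` characterizes dynamic brain functional networks (DBFNs) by
*multi-threshold derivative* (MTD) features and classifies two-group cohorts
with an SSA-tuned support vector machine. The pipeline is:

1. **Windowing.** An M x P ROI time-series matrix is cut into
   D = floor((M - L)/s) + 1 sliding windows of length L and step s
   (defaults L = 85, s = 3 for M = 100).
2. **Network construction.** Each window's P x P Pearson correlation matrix
   is computed as the cross-product of the column-standardized window; the
   Fisher R-Z transform z = atanh(r) is applied by default to stabilize the
   variance of the correlation estimates. Diagonals are fixed at zero:
   self-connections carry no information and r = 1 has no finite image
   under atanh.
3. **Threshold filtration.** Each weighted window is binarized over an
   increasing threshold grid (default 0.01 to 0.35 in steps of 0.01, i.e.
   35 thresholds), with an edge present iff |w| > pr. Absolute-value
   thresholding is the default because Fisher-transformed correlations are
   signed; a signed mode (`use_absolute=False`) is available.
4. **Topological curves.** On each binary graph, four measures of network
   integration and segregation are computed: mean clustering coefficient
   (cc), global efficiency (Eglobal), local efficiency (Elocal), and
   characteristic path length (Lp). Values are averaged across windows,
   giving one curve per metric per subject (per-window curves are an
   option).
5. **MTD features.** Each curve is smoothed with a penalized cubic B-spline
   and differentiated; the derivative sampled on the grid is the MTD
   feature (35 values per metric). Concatenating cc, Eglobal, Elocal, Lp
   in that fixed order gives the 140-dimensional fused feature.
6. **Classification.** Repeated stratified 10-fold CV; inside each training
   fold: standardization, lasso feature selection, and a sparrow-search
   (SSA) optimization of the RBF-SVM's (C, Gamma). ACC/SEN/SPE/AUC are
   reported as mean +/- sd over folds x repeats.

## Graph-metric conventions

Brain Connectivity Toolbox conventions are used throughout: nodes of degree
< 2 contribute 0 to cc and Elocal; Eglobal counts unreachable ordered pairs
as 0; Lp averages over mutually reachable ordered pairs only and returns 0
for an edgeless graph (the reciprocal-distance handling of disconnection is
already captured by Eglobal, so Lp restricted to reachable pairs carries
complementary information). Distances come from an in-package breadth-first
all-pairs routine; unit tests check all four metrics against naive
brute-force enumeration (triangle counting, Floyd-Warshall relaxation) and
against networkx to 1e-12.

## Penalized spline details

- Basis: cubic B-splines (order 4), default 10 basis functions for a
  35-point grid, interior knots at equally spaced quantiles of the grid.
- Penalty: lambda * integral of the squared second derivative of the fitted
  curve. The penalty Gram matrix is computed exactly by per-knot-span
  Gauss-Legendre quadrature (the integrand is piecewise polynomial of
  degree 2 on each span for cubic splines).
- Solver: augmented least squares ([B; sqrt(lambda) R^(1/2)] against
  [y; 0]), which is stable down to lambda = 0; an unpenalized fit with more
  basis functions than points is rejected with guidance.
- lambda selection: generalized cross-validation, GCV(lambda) =
  n RSS / (n - tr H)^2, over the ladder 1e-6 ... 1e2. GCV is applied per
  curve; it sees no group labels, so it cannot leak test information.
  A fixed lambda may be passed instead.
- As lambda grows the integrated squared second derivative decreases
  monotonically toward 0 (straight-line limit) and the residual sum of
  squares grows monotonically; both are asserted in tests.

## Sparrow search algorithm

Minimization with discoverer / follower / alerter roles as described in the
module docstring. Choices where the printed recurrences are ambiguous:

- The follower "hungry" branch (rank > n/2), Gamma * exp(x_worst - x), is
  applied per dimension and clamped to the search box.
- The well-fed follower correction |x - x_p| . A+ uses a fresh random +/-1
  row vector per follower with A+ = A'/d.
- alpha in the discoverer decay is drawn uniformly from (0, 1] per
  discoverer per iteration; the multiplicative decay term pulls positions
  toward the origin, which is why the sphere benchmark converges fast.
- delta = 1e-50 guards the alerter update against division by zero.
- The incumbent best is tracked outside the population, so the reported
  best-so-far trace is non-increasing by construction.

Defaults follow the stated role intervals: n = 20, T = 50, 20% discoverers,
15% alerters, safety threshold 0.8.

For hyperparameter tuning inside cross-validation the package defaults to a
reduced budget (n = 8, T = 12) over log10 C in [-2, 3] and log10 Gamma in
[-4, 1], with fitness = 1 - mean accuracy of an inner stratified 5-fold
split of the training fold. With 80-subject cohorts and <= 140 features the
accuracy surface is coarse (steps of 1/8 per inner fold), so a compact
population explores it adequately; the full n = 20, T = 50 budget can be
passed explicitly.

## Classification protocol

- Stratified k-fold (default k = 10) x repeats (default 10); fold seeds are
  derived deterministically from the master seed.
- All per-fold artifacts (scaler statistics, lasso support, C, Gamma) are
  functions of the training fold only; `FoldModel.checksum()` exposes a
  digest so tests can verify invariance to held-out label permutation.
- Lasso: scikit-learn `LassoCV` on the 0/1 labels with an internal 5-fold
  split of the training fold. An empty selection (extreme regularization or
  a null cohort) falls back to the full standardized feature set rather
  than failing — the SVM then sees all features and performs at chance on
  null data.
- AUC is computed from SVM decision scores by the rank statistic
  (Mann-Whitney form); ties share average ranks.
- The patient-analog group ("positive") is the positive class for SEN/SPE.

## Synthetic cohorts

The generator emulates only what the pipeline consumes: an inter-regional
correlation structure. Regions fall into modules (default P = 20, 4 equal
modules; P = 90 with 6 modules mirrors a whole-brain AAL-style
parcellation); within-module correlation is `intra_corr` (default 0.6),
between-module `inter_corr` (default 0.1); subjects are i.i.d. rows of a
zero-mean multivariate Gaussian (M = 100 timepoints by default). The
"patient" group reduces `intra_corr` by `effect`, emulating weakened
within-module integration; `effect = 0` is an exact null. An AR(1)
temporal-smoothing coefficient is available but off by default — a
stationary white-in-time generator keeps every oracle check closed-form.

Not emulated: hemodynamic response, scanner drift, head motion, spatial
smoothing, non-stationarity of connectivity within a subject. Passing tests
therefore demonstrate the machinery (bookkeeping, statistics, no-leakage
discipline, sensitivity to a planted covariance difference), not
performance on real fMRI; absolute accuracies on synthetic cohorts are not
comparable to patient-data results.

Problem sizes used by the test suite and the acceptance script — cohorts of
40+40 (null calibration, acceptance script) and 20+20 (the multi-seed power
study), P = 20, M = 100, L = 85, s = 3, 35 thresholds, CV with one or two
repeats and the reduced SSA budget — are the package's desk-scale defaults,
small enough to iterate on a laptop while keeping every fold's class split
non-degenerate.

## Degenerate inputs and numerical choices

- Zero-variance regions in a window are rejected naming the region; |r| = 1
  is rejected by the Fisher transform (only possible for exactly linearly
  dependent series).
- Correlations are clipped to [-1, 1] after the cross-product to absorb
  roundoff; matrices are exactly symmetrized.
- Thresholds must be strictly positive; `binarize` uses a strict > cut.
- A fold whose training data contain one class is rejected with fold
  diagnostics; k is reduced automatically when a class has fewer than k
  members.
- `feature_weight_percentages` of an all-zero weight vector reports NaN per
  block (undefined shares) rather than raising.

## Known limitations

- The comparison harness targets qualitative orderings (fused >= single
  metric, MTD >= simpler features) on synthetic cohorts; it does not try to
  reproduce patient-data accuracy values.
- Proportional (density-based) thresholding, weighted-graph metric
  variants, betweenness/small-world indices, and persistent-homology
  features are out of scope.
- The SSA fitness surface from small inner folds is piecewise constant;
  different (C, Gamma) in a plateau are equivalent, so chosen
  hyperparameters are reproducible only under a fixed seed.
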