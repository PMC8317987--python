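# Methods

## Model and assumptions

The pipeline treats each subject's brain as an undirected network over N
cortical parcels. Connectivity is the Fisher-z-transformed Pearson
correlation of parcel time series; the transform variance-stabilizes r but
is monotone, so edge rankings (and hence all thresholded graphs) are
identical whether r or z is ranked. Because there is no accepted absolute
connectivity threshold, graphs are defined *proportionally*: at density d
the `round(d·N(N−1)/2)` strongest edges (by signed z, most positive first)
are kept and binarized, and node metrics are averaged over
d ∈ {0.150, 0.175, …, 0.300} so that no single density drives group
contrasts. Negative and weak correlations are simply never retained at
these densities; an absolute-value variant was deliberately not
implemented.

Metric conventions follow common connectivity-toolbox practice:

* DC(i): row sum of the binary adjacency; range [0, N−1].
* CC(i): 2·t(i)/(k_i(k_i−1)) with t(i) the triangle count through i;
  CC = 0 when k_i < 2.
* BC(i): unnormalized Brandes betweenness with each unordered pair counted
  once; pairs with no connecting path contribute 0. Normalization is
  monotone at fixed N and therefore irrelevant to ranking and
  classification.
* LE(i): mean of 1/d(j,k) over ordered neighbor pairs of i, distances
  measured inside the neighbor-induced subgraph; unreachable pairs
  contribute 0; LE = 0 when k_i < 2.

Betweenness is computed by a source-vectorized Brandes recursion (path
counts accumulated level-by-level from the BFS distance matrix, then
dependencies swept from the deepest level inward); local efficiency uses a
dense boolean-product BFS on each neighbor subgraph. Both are validated to
1e-9 against exhaustive path-enumeration oracles and against networkx.

## Feature selection

Plain Enet fits elastic-net-penalized logistic regression over the grid
λ ∈ {0.1..0.9} (penalty strength) × α ∈ {0.0001, 0.0011, 0.0021, 0.0031,
0.0041} (l1 mixing), choosing the winner by 4-fold stratified CV AUC (ties
prefer larger λ, then smaller α — the more parsimonious model). Nonzero
coefficients define the selection, ranked by |coefficient|. The near-ridge
α range is intentional: with hundreds of correlated node metrics and ~35
training subjects, a larger l1 weight zeroes whole correlated groups
erratically; a small one keeps groups together while still producing exact
zeros. The glmnet-style λ maps to scikit-learn's C as C = 1/(n·λ).

Enet-subset then evaluates nested subsets of the ranked features
(sizes step, 2·step, … plus always the full nonzero set; step = 25) by
4-fold stratified CV AUC of a linear SVM inside the training split, and
keeps the best subset, ties resolving to the smaller one. The coefficient
ranking is computed once and reused across subsets; coefficients are not
refit per subset. Selection statistics (including the internal
standardization) always come from the rows passed to `fit`, so test
information cannot leak into selection.

## Evaluation protocol

Each iteration draws a stratified split with per-class training counts
`round(0.70 · class size)` (19/27 HC and 17/24 LBP at the study sizes),
selects features on the training rows, standardizes with training
statistics, tunes the SVM cost C ∈ {1..10} by stratified 4-fold CV
repeated 5 times (criterion: accuracy; AUC exposed as an option; ties take
the smaller C), refits on the whole training split, and scores the test
rows. HC is the positive class. AUC uses the SVM decision values with
midrank tie handling, so identical scores give 0.5. The protocol repeats
(default 100×) with iteration seeds derived as `seed + i`, and reports
arithmetic means plus per-feature selection counts.

One documented inconsistency in the protocol's provenance: the source
description of the repeated CV says both "repeated five times" and
"repeated three (K−1) times" for K = 4; the standard reading — 4 folds,
5 repeats — is implemented.

## Statistics

* Per-(node, metric) two-sided rank-sum tests: exact enumeration when both
  groups are below 10 and untied, midrank normal approximation otherwise;
  BH adjustment applied jointly across all node × metric tests (a
  per-metric family is available via direct calls).
* Permutation significance: labels are shuffled once per permutation and
  the *entire* protocol — including feature selection — is re-run, so the
  null distribution reflects the whole pipeline and the p-value is not
  optimistically biased. The add-one estimate
  p = (1 + #{null ≥ observed})/(1 + B) is used, which cannot be 0.
  Per-permutation iteration counts may be reduced for tractability (and
  are logged). When the observed statistic uses more iterations than the
  permuted ones, its variance is smaller than the null replicates', which
  makes the test conservative under the null (verified in the calibration
  suite); matching the counts restores exact exchangeability.

## Synthetic cohorts

The generator emulates the study's two-group design (default 27 HC vs 24
LBP; 360 parcels; 2,250 timepoints ≈ six 5-minute runs at TR 0.8 s). The
control covariance is modular — parcels are randomly assigned to
communities (~N/12), within-community correlation 0.35, between 0.03, plus
a ±0.02 symmetric jitter that makes edge weights generically distinct —
and repaired to positive definite by eigenvalue clipping at 1e-4. The
patient covariance multiplies off-diagonal entries on the rows/columns of
`n_affected` randomly chosen parcels by (1 + effect_size), clips to ±0.98
and re-repairs; effect_size = 0 leaves the matrix bit-identical, giving an
exact null cohort. Time series are zero-mean correlated Gaussian draws
plus independent N(0, 0.5²) observation noise, which attenuates all
correlations mildly and uniformly.

Injecting the effect at the covariance level means graph-metric group
differences arise mechanistically through thresholded connectivity, as in
real data — including the realistic complication that proportional
thresholding spreads an affected parcel's perturbation into unaffected
parcels' edge sets. This is why affected-node recovery is scored as
*enrichment in the top half of the selection-frequency ranking* (against a
hypergeometric null) rather than exact identification.

What the generator does **not** model: temporal autocorrelation and
hemodynamics (Pearson correlation, the only consumer, is unaffected in
expectation), motion and scanner artifacts, spatial geometry of parcels,
and any anatomically meaningful placement of affected regions —
"affected nodes" are a construct of the generator, labeled as such in all
outputs. Passing tests therefore demonstrate the pipeline's statistical
machinery and calibration, not clinical effect sizes.

Disability scores are truncated normals on [0, 100] with group defaults
(HC 5.63 ± 5.60, LBP 33.3 ± 15.3) matching the clinical score table; the
truncation at 0 raises the realized HC mean slightly above the nominal
one, which the tests account for explicitly.

## Problem sizes and numerical choices

Validation suites run at desk scale as the package's own choice of
experiment size: 60-node cohorts with 25+25 or 27+24 subjects and 200
timepoints, 25–100 protocol iterations, 99–200 permutations with
single-iteration permuted statistics, and small selection grids (a single
near-ridge (λ, α) point and a single SVM cost) inside repeated loops —
the grids are method configuration, not study conditions, and all are
exposed. Edge-count rounding is half-up; ties at the density cutoff break
by ascending (i, j) edge index; grid ties prefer larger λ, smaller α,
smaller subsets, smaller C — every tie rule is deterministic, so a full
report is reproducible bit-for-bit from (cohort seed, evaluation seed).
Degenerate cases: constant time series are rejected naming the node (with
a magnitude-relative tolerance, since a literally constant row has
floating-point noise variance); zero-variance features are dropped with a
warning before SVM training; one-class test sets mark AUC undefined;
rank-sum on fully tied data returns p = 1 with a warning.

## Known limitations

* No weighted-graph metric variants and no global metrics (path length,
  modularity, participation).
* No partial correlation or global-signal options in connectivity; one FC
  matrix per subject over the full (concatenated) series, with no per-run
  averaging.
* The elastic-net fit uses scikit-learn's saga solver; coefficients at
  loose tolerance can differ in the last decimals from other coordinate
  descent implementations, which can reorder features with near-tied
  |coefficients|. All contracts are therefore stated on selection behavior,
  not on raw coefficient values.
* Permutation tests with reduced per-permutation iteration counts are
  conservative, not anti-conservative (see above).
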