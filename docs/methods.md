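# Methods

## Model and assumptions

The predictor is a bilinear graph regression. The association graph (an m×n
lncRNA × disease matrix A, binary, count-valued or real-valued) and two
similarity graphs (S_r over lncRNAs, S_d over diseases) are each compressed
into low-rank factor spaces; two multi-response regressions stitch the
similarity spaces to the association space. The five terms of the objective
— three Frobenius-norm factorizations and two regressions — are solved
*independently and in order*, not jointly: SVD gives the associating factors
A_r = U√Σ, A_d = V√Σ; eigendecomposition of each similarity matrix gives the
latent feature factors F_r = U√Λ₊, F_d; partial least squares (PLS) gives
B_r : F_r→A_r and B_d : F_d→A_d. The only coupling is the product
Θ = B_r B_dᵀ used by the bilinear predictors Ã = F Θ Fᵀ. This "minimize the
items individually" solution trades optimality for transparency and
determinism; no alternating optimization is attempted (out of scope by
design).

Implicit assumptions worth stating:

* similarity matrices are informative about association structure — the
  cold-start scenarios have no other signal;
* zero entries of A mean "no *known* association", not confirmed absence;
  CV_T1 therefore blinds test entries by zeroing them;
* similarity matrices need not be positive semidefinite (1/(1+dist) is
  not); negative eigenvalues are clipped to zero before the square root,
  so F Fᵀ reconstructs the PSD part of S.

## Numerical choices

* **Uncentered PLS.** The predictors have no intercept, so the regression
  must not center or scale. scikit-learn's PLS always centers; the package
  therefore implements uncentered PLS2 directly: each weight vector is the
  dominant left singular vector of X_kᵀY_k (the fixed point of the NIPALS
  inner iteration, computed non-iteratively for determinism), X is deflated
  by the score direction, and coefficients are assembled as
  B = W(PᵀW)⁻¹Cᵀ. With n_components ≥ rank(X) and an exactly linear
  response the fit is exact. An optional ridge term shrinks the final
  regression of Y on the scores (default 0 = plain PLS); it exists as an
  escape hatch for degenerate spectra and is off everywhere in the tests.
* **Sign convention.** Every singular/eigen vector is flipped so its
  largest-magnitude entry is non-negative, making factors reproducible
  across linear-algebra backends.
* **Ranks.** Default ranks r, p, q keep the spectrum above 1e-10 × largest
  value (a relative "numerically non-zero" test). The same relative
  tolerance drops PCA directions after Z-scoring. Zero-variance feature
  columns Z-score to all-zero rather than NaN so distances stay finite.
* **Cold-start projection.** A new entity with similarity row s_x to the
  training entities is embedded as F_x = s_x U Σ^(−1/2) (Nyström). For a
  full-rank embedding, projecting a training row reproduces its latent row
  exactly; this identity is asserted in the tests at 1e-8.
* **Segmentation.** A length-L sequence split into s segments gives the
  first L mod s segments ⌈L/s⌉ residues and the rest ⌊L/s⌋, left to right
  — deterministic and balanced. k-mer frequencies are per segment (each
  block of the concatenated vector sums to 1); the normalization granularity
  is a documented choice, not an external constraint.
* **Metrics.** AUC is the Mann–Whitney statistic with midrank ties
  (delegated to scikit-learn, cross-checked in tests against a brute-force
  pair-count oracle at 1e-12); AUPR is step-curve summation without
  interpolation, ties forming one threshold block; "Correlation" is Pearson
  by default (Spearman behind a flag) between predicted scores and
  association intensities.

## Cross-validation protocol

K folds per task, unit sizes differing by at most one, fully determined by
the seed. CV_T1 blinds entries (zeroed in the training matrix); CV_T2/T3
blind rows/columns (removed, then scored via the projection); CV_T4 crosses
K row-folds with K column-folds into K² fold pairs where the model sees only
the train-row × train-column block and the two mixed blocks join neither
side. Standard K rounds are run (each fold tests once). Aggregation is the
fold mean; entry pooling is available behind a flag. For non-binary
matrices, AUC labels come from the binary matrix entry-by-entry; the
Correlation truth defaults to the evaluated matrix itself and can be set
explicitly — the variant-comparison experiments use the continued matrix as
the common intensity truth for all three variants, since it is the graded
quantity the prediction is meant to track. Folds whose test labels are
single-class are skipped with a warning and reported.

## The synthetic generator

`synthetic_data` plants a latent-cluster model: each lncRNA, gene and
disease gets a one-hot cluster centre (latent_dim clusters) plus a uniform
mixing term of weight 0.25; interactions are bilinear scores thresholded at
the quantile matching `interaction_density` (default 0.2 = 1/latent_dim, the
density at which thresholding recovers cluster co-membership). The three
association variants are then built through `association_builder`, so
builder invariants hold by construction. `noise_sd` perturbs only the
latent vectors entering the *observed* similarity matrices: the association
truth stays clean while the side information degrades, which is exactly the
axis the cold-start tasks depend on. Defaults (m=60, g=40, n=80,
latent_dim=5, noise 0) are the package's study conditions for the recovery
experiments; recovery fits use ranks = latent_dim (the oracle rank — with
full default ranks the PLS step interpolates the training matrix exactly and
no held-out signal remains, which is informative about the method, not a
bug). Each artifact (clusters, noise, sequences, proteins, descriptor
forest) draws from its own named random stream, so regeneration is
bit-identical and adding a stage never perturbs earlier outputs.

What the generator does **not** emulate: real lncRNA sequence composition
or length distributions, true MeSH content, curation biases of association
databases, and entity-degree heterogeneity beyond what random cluster sizes
induce. Passing the recovery tests therefore shows the machinery is correct
and self-consistent under the stated assumptions — not that real-data
performance reaches any particular level.

## Disease semantics

Each disease's descriptor DAG is built by upward BFS through an explicit
child→parent edge list, or, when none is given, by dot-truncation of the
descriptor tree numbers themselves (C04.588.180 → C04.588 → C04). A node
reachable at several depths takes the *minimum* depth (maximizing its
contribution, deterministically). Contributions decay as decay^depth with
decay = 0.5 by default (the standard constant of decay-based semantic
similarity; configurable). Disjoint DAGs score exactly 0, so the disease
similarity domain is [0,1] — unlike sequence similarities, which are
strictly positive.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| k (RNA) / segments | 4 / 35 | segmented k-mer featurization (8960 dims) |
| k (protein) | 3 | 3-mers on the 7-group alphabet (343 dims) |
| decay | 0.5 | per-level decay of descriptor contributions |
| rank_assoc / rank_lncrna / rank_disease | auto | latent dims r, p, q (auto = numerically non-zero spectrum) |
| n_components | min(p, r) | PLS components per regression |
| ridge | 0 | shrinkage of the score regression |
| K / seed | 10 / — | folds and determinism of CV plans |

## Known limitations

* The item-wise solution is not a minimizer of the joint objective; Θ
  inherits whatever the independent SVDs and PLS fits deliver.
* The continued matrix can assign values ≥ 1 to pairs sharing no gene when
  protein similarities are large off-diagonal; the raw product is reported
  and thresholding is left to the caller.
* Leave-one-out is exposed as K = number of units; it is O(units) model
  fits and meant for small matrices only.
* Problem sizes in tests and the acceptance script are desk-scale (tens of
  entities); the dense SVD/eigh implementation is O(n³) and intended for
  matrices up to a few thousand entities.
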