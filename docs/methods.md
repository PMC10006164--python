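# Methods

## Model and procedure

The generator produces one synthetic record ("avatar") per original
record in three stages: a lossless mixed-data factor projection, a
per-record stochastic local model, and an exact inverse transform.

**Projection (FAMD).** Continuous columns are standardized with the
population standard deviation; dates are first embedded as integer days
since 1970-01-01 (a monotone numeric embedding, so distances between
records are preserved) and then treated as continuous; booleans are
two-level categoricals. Each categorical level's indicator is divided
by √(proportion) and centered at the proportion, so a disagreement on a
level of proportion p contributes 1/p to squared distance — the
chi-square weighting that puts rare levels on the same footing as large
z-score deviations. Optional per-variable weights multiply the encoded
columns, scaling a variable's influence on every downstream distance.
The axes are the right singular vectors of the encoded matrix and *all*
non-null components are retained: the model is full-rank by
construction, which makes `inverse_transform(transform(x)) = x` exact
(continuous to 1e-8 relative, categoricals exactly) and means pairwise
distances in coordinate space equal distances in encoded space.
Dimension reduction exists only in the neighbor search, which uses the
first `nd` components (default: the smallest count reaching 90%
cumulative explained variance) to avoid the curse of dimensionality.

**Local model.** For each record, the k nearest other records are found
by exact all-pairs search in the `nd`-dimensional space (ties broken
toward the lower row index). Neighbor i receives the raw weight
P_i = D_i·R_i·C_i: D_i the inverse of its distance, R_i an
Exponential(λ) draw (λ = 1 by default), and C_i = (1/2)^j with j a
uniformly shuffled [1..k]; under the alternative `equal` contribution
law C_i ≡ 1. Normalized weights W_i = P_i/ΣP are non-negative and sum
to one, so the avatar — placed at the W-weighted center of the
neighbors' *full-rank* coordinates — is a convex combination of real
neighbors: every continuous avatar value lies within the range its
neighbors span. Averaging in full rank while searching in reduced rank
is deliberate: the search is where dimensionality hurts, and full-rank
averaging keeps the inverse exact.

**Output.** Avatar coordinates are inverse-transformed (categorical
levels decoded by argmax of the reconstructed indicators; ties go to
the higher-proportion, then lexicographically earlier level — a
deterministic rule that favors the likelier level) and the rows are
shuffled with the run RNG. The original→avatar linkage exists only in
memory for metric computation and is never serialized.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 20 | local model size; larger k blends more records into each avatar: more privacy, smoother data |
| `nd` | 90%-variance count | components used for neighbor search only |
| `distance` | euclidean | `mahalanobis` = Euclidean on variance-standardized component scores, which is the Mahalanobis distance in an orthogonal factor basis |
| `contribution_law` | halving | the (1/2)^j contribution; `equal` removes it |
| `exponential_rate` | 1.0 | λ of the random factor R_i |
| `column_weights` | 1.0 each | per-variable multiplier on encoded columns |
| `perturbation_level` | 0 | *experimental* — see below |
| `seed` | 0 | single RNG stream; fixed draw order (per row: shuffle j, then the R vector; finally the output shuffle) for cross-platform reproducibility |

**Zero-distance neighbors.** Exact duplicate records make D_i = 1/0
undefined, and real data (notably graded ordinal tables) contains
duplicates. Distances are floored at ε = 1e-9 × the median positive
pairwise distance in the search space, so duplicates receive the
largest finite inverse-distance and "nearer ⇒ heavier" is preserved.
For the median estimate the pairwise scan is subsampled above 3000 rows
(deterministically); ε only matters at distance ≈ 0, where any
consistent tiny floor behaves identically.

**Perturbation.** When nonzero, the avatar's encoded representation is
shrunk per-variable toward the unweighted neighbor centroid. The
parameter's intended semantics are not settled; this reading is a
placeholder and the feature is flagged experimental.

## Privacy metrics

All metric distances are computed in the full-rank projection space
fitted on the original data, with synthetic data placed into that space
via `transform`; the space is recorded in every report. A single
declared space keeps avatar audits, holdout baselines and cross-method
comparisons on the same ruler — but note absolute DCR/NNDR values do
depend on this choice, so only comparisons within one space are
meaningful. Local cloaking uses strict inequality: a tie with the own
avatar does not hide the individual (conservative for the attacker and
deterministic under duplicates). NNDR defines d2 = 0 (synthetic point
coinciding with duplicated real points) as ratio 1, the maximally
non-isolated reading; conversely a synthetic record coinciding with a
*unique* real record scores 0, the worst case.

## Synthetic fixtures

The fixture generators emulate the features the pipeline must survive:

* `generate_mixed` — spherical-Gaussian clusters (mixture weights,
  separation ~6 sd by default) with a cluster-linked categorical column
  (0.9 dominant-level probability) and an optional fraction of exact
  duplicate rows.
* `generate_survival` — two arms (Bernoulli 0.5), exponential event
  times with the arm-1 rate = HR × arm-0 rate (default HR 0.5, baseline
  rate 0.1/time unit), independent Uniform(0, u) censoring with u solved
  by root-finding so the expected censored fraction matches the stated
  rate (default 20%).
* `generate_classification` — 1–10 graded integer features (Gaussian
  draws, sd 1.5, clipped and rounded) with class-conditional mean
  offsets, emulating ordinal diagnostic grading; an optional feature
  with disjoint class ranges makes AUC = 100 achievable.

What the fixtures do *not* emulate: correlated continuous blocks with
heterogeneous covariance, informative censoring, missingness (rejected
by design), rare categorical levels, and real-data idiosyncrasies such
as coding artifacts. Passing tests therefore demonstrate correctness of
the mechanics and the direction of the privacy/utility trade-offs, not
performance guarantees on any particular real dataset.

## Numerical choices

* Rank: singular values above `max(n, m)·eps·s₀` are kept; explained
  variance ratios are non-increasing by construction.
* Neighbor ties: stable argsort ⇒ lower row index wins.
* Weight normalization asserts ΣW = 1 within 1e-12.
* Cox fits use Efron tie handling (recorded in the report); the SVM uses
  an RBF kernel with default regularization, features standardized on
  the training split; 70/30 splits are stratified on the outcome and
  seeded.
* Experiment seeds derive from the base seed via `SeedSequence` spawn
  keys, so adding runs to a plan never perturbs earlier runs.
* The 10×70/30 DCR/NNDR protocol pools per-record values across
  samplings before taking medians and (0.05, 0.95) quantiles.

## Problem sizes

The default test and audit runs use fixtures of 200–2000 rows: large
enough for the asymptotics that matter (cluster proportions, Cox CI
coverage at n = 2000, monotone cloaking medians over 10 repetitions at
n = 1000) and small enough that the full suite runs on a laptop in a
few minutes. All protocols accept arbitrary n.

## Limitations

* FAMD is the only projection shipped; the generator takes any fitted
  model with the same surface, but t-SNE/autoencoder projections are
  out of scope (and would lack an exact inverse).
* Continuous avatar values are convex combinations of neighbors, so
  strictly bounded or integer-valued variables may need post-hoc
  rounding by the caller; no marginal-distribution calibration is done.
* No differential-privacy accounting: the privacy evidence is
  empirical (distance-based metrics), not a mathematical guarantee.
* Single-table data only; relational schemas and time series are not
  supported.
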