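# Methods

This note documents the statistical model behind `symptomnet`, the defaults
and why they are set where they are, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer would want
written down.

## Data model

The unit of analysis is an n × p matrix of ordinal item scores on a
four-point scale {0, 1, 2, 3}, with each item pre-assigned to exactly one
community (for the DASS-21 preset: items 1–7 Stress, 8–14 Anxiety, 15–21
Depression). Communities are an input, never inferred. Ingestion applies
listwise deletion: any row with a missing value among the named items is
dropped. Scores outside 0–3 are treated as invalid-and-missing (the
instrument admits only four categories) and drop the row with a logged
warning; `strict=True` raises instead. Listwise deletion is idempotent —
re-reading a retained matrix drops nothing.

Descriptive sample tables report `100·count/n` rounded half-away-from-zero
to two decimals (computed in exact decimal arithmetic from the integer
counts, so printed tables reproduce bit-for-bit).

## Nonparanormal transform and correlations

Each column is transformed by average ranks → `rank/(n+1)` → Winsorization
into `[δ_n, 1−δ_n]` with `δ_n = 1/(4 n^{1/4} √(π log n))` → standard-normal
quantile. This is the shrunken/truncated empirical-CDF estimator standard in
the regularized-network literature; it is bounded, deterministic, and maps
ties to equal values, making the whole pipeline invariant to monotone
recoding of items. Correlations are Pearson on the transformed scale,
symmetrized by averaging with the transpose and clipped to [−1, 1].

**Limitation (important for interpretation).** With only four categories the
transformed variable takes at most four values, and its Pearson correlation
is *not* a consistent estimator of the latent Gaussian correlation: with the
default right-skewed thresholds, a latent correlation of 0.40 has a
population nonparanormal correlation near 0.31 (attenuation ratio roughly
0.6–0.85 depending on magnitude; the bias is systematic and does not shrink
with n). Signs and the ordering of association strengths are preserved, so
network topology and centrality rankings are meaningful, but edge weights
are conservative relative to the latent scale. Recovering latent magnitudes
would require polychoric correlations, which are out of scope (a possible
alternative backend).

## Graphical lasso and EBIC selection

The precision matrix maximizes `log det K − tr(RK) − λ‖K‖₁,off` (diagonal
unpenalized). The solver is a numba-compiled block coordinate descent
(lasso subproblem per column), warm-started along a descending λ path;
outer tolerance 1e-4 on the mean absolute covariance update, inner
tolerance two orders tighter. It was written in-package because the
pipeline re-solves the full path thousands of times inside the
case-dropping bootstrap; the test suite cross-checks it elementwise against
an independent ADMM solver of the same objective and against
`sklearn.covariance.graphical_lasso`, and against the closed-form inverse
at λ = 0.

The path uses 100 log-spaced penalties from `λ_max = max off-diag |r|` down
to `0.01·λ_max` (both configurable). Model selection minimizes
`EBIC = −2ℓ + E log n + 4Eγ log p`, `ℓ = (n/2)(log det K − tr(RK))`, `E` the
upper-triangle edge count, with γ = 0.50 by default; additive constants are
dropped identically across the path, and ties resolve to the sparser model
(parsimony, in keeping with the purpose of regularization). Borderline
non-positive-semidefinite correlation inputs are repaired by eigenvalue
clipping at 1e-8 with renormalized unit diagonal, and logged. Selected edge
weights are `w_ij = −K_ij/√(K_ii K_jj)`; the sparsity pattern is exactly the
selected precision's off-diagonal support.

A property worth knowing: with a strong, dense signal the single global λ
trades shrinkage bias on true edges against false inclusions, so EBIC
selection admits some false edges at large n; with weak signals near the
EBIC boundary the criterion can tip between the empty model and a
many-edged model on nearly identical data. Both behaviours are visible in
the bootstrap.

## Centrality and bridge statistics

Strength `s_i = Σ_j |w_ij|`; bridge strength is the same sum over edges
whose other endpoint lies outside `i`'s community; within-strength is the
complement, so `strength = within + bridge` holds exactly and is tested on
random networks and partitions. Bridge betweenness converts weights to
lengths `1/|w|`, runs Dijkstra with Brandes-style fractional path counting
(ties within relative tolerance 1e-9 share credit equally — deterministic
and order-independent), and accumulates, for every unordered cross-community
pair, the fraction of shortest paths through each intermediate node;
disconnected pairs contribute nothing, so leaves always score 0. Bridge
closeness is available but excluded from default reports, as this index
family is rarely stable under case-dropping. z-scores standardize each index
over the p nodes with the sample (n−1) standard deviation; a constant index
vector yields all zeros with a warning.

## Predictability

For each node, a lasso regression of its (transformed, centered) column on
all others over a 100-point penalty path; the penalty minimizes the Gaussian
EBIC `n log(RSS/n) + k log n + 2γk log(p−1)` with γ = 0.25, the convention
of the nodewise-regression predictability literature. `R²` is then computed
from an **unpenalized least-squares refit on the selected neighbours**
(relaxed-lasso style) against the intercept-only model, clipped to [0, 1].
The refit choice is deliberate: predictability should measure the variance
the selected neighbours explain, not the shrinkage level of the path point —
an exact duplicate of another item scores R² = 1 and an empty support scores
exactly 0. Computed on the transformed scale, so it shares the attenuation
caveat above.

## Case-dropping bootstrap and CS-coefficient

For each drop proportion in 0.05–0.75 (step 0.05) and each of B replicates
(default 1000; 250 is a reasonable desk-scale setting), a uniform
without-replacement subsample is drawn and the *entire* pipeline re-run;
the replicate records the Pearson correlation between the subsample's
node-index vector and the full-sample one. RNG streams are spawned per
(proportion, replicate) from the master seed, so any subset of the grid
reproduces the identical draws. A degenerate subsample index (constant
vector, typically an empty selected network) is recorded as correlation 0 —
it recovers none of the full-sample ordering, and this keeps all recorded
values in [−1, 1] and the mean-degradation curve well defined. At drop 0 the
subsample is the full sample and the correlation is exactly 1.

`CS(cor = 0.7)` is the largest grid proportion at which at least 95% of
replicate correlations are ≥ 0.7, 0 if none qualifies; labels follow the
usual reading: < 0.25 insufficient, 0.25–0.50 (inclusive) acceptable,
\> 0.50 preferred. The 0.7 threshold and 95% level are configurable; CS is
monotone in both, which is property-tested.

## Synthetic generator

`make_truth` builds a 21-item, 3 × 7-community truth: within-community
edges placed independently with probability 0.3 at nominal partial
correlation 0.25, plus 2 bridge edges per community pair at 0.15. Edge
magnitudes follow the principle that a survey-scale sample (n ≈ 318) should
yield an estimable but genuinely sparse network; the 0.3 within-density
keeps the conditional-independence structure sparse while the implied
*marginal* correlations are dense within blocks, matching the
dense-within/sparse-between topology of empirical distress networks. The
nominal precision `I − W` is repaired to SPD, when needed, by uniform
diagonal inflation with a conditioning floor of 0.05 on the smallest
eigenvalue; since inflation shrinks the implied partial correlations, the
recorded truth is always the *realized* `partial_correlations(K)`, keeping
the generator self-consistent (round-trip tested). Latent draws come from
the unit-diagonal-rescaled covariance; items discretize at thresholds
(0.3, 1.0, 1.8), giving category masses (0.618, 0.223, 0.123, 0.036) — the
right skew typical of symptom endorsement.

What the generator does *not* emulate: the strong item intercorrelations of
real student-survey data (empirical DASS-21 networks reach mean
predictability near 0.6 and strength CS above 0.5, whereas this synthetic
world sits near 0.1 and CS ≈ 0 at n = 318 — its edges are intentionally
weak), demographic covariates, non-response bias, or item wording effects.
Passing recovery and stability tests therefore demonstrates correctness of
the estimators under a known copula truth, not expected performance levels
on real survey data.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own desk-scale conventions: recovery simulations
use n = 2000 over 10 seeds; predictability is validated against the
closed-form conditional-variance oracle `1 − 1/(K_ii Σ_ii)` at n = 10,000;
stability behaviour is exercised at the study scale n = 318 with B = 250
for strength/bridge strength and B = 100 for the (costlier) predictability
bootstrap; solver oracles run at p ≤ 6 where exhaustive enumeration and
high-precision ADMM are exact.

## Known limitations

- Edge weights and predictability are attenuated on coarse ordinal scales
  (see the nonparanormal limitation above).
- EBIC's global-λ behaviour can admit false edges under dense strong
  signal, and flips to the empty model near the detection boundary; CS
  values on weak networks should be read with that in mind.
- No handling of missing data beyond listwise deletion; no survey weights;
  no sum-score severity cutoffs (the network view deliberately avoids sum
  scores).
- Bridge betweenness tie-handling (fractional credit) is one of several
  defensible conventions; alternatives (single-path counting) would differ
  on graphs with exactly tied path lengths.
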