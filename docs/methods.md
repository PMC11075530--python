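# Methods

## Document representation

A document is tokenized into lowercase word tokens (maximal runs of
letters/digits, internal apostrophes and hyphens kept; the regex is
configurable) and cut into consecutive chunks of `chunk_size` tokens
(default 25). A trailing remainder shorter than half a chunk is merged into
the preceding chunk — near-empty chunks produce high-variance mean
embeddings — while a remainder of at least half a chunk stands alone; the
rule is configurable (`merge`/`keep`/`drop`). Stopwords are kept: removal
changes which tokens carry a chunk's position and is left to the caller's
tokenizer override.

Each chunk becomes the unweighted arithmetic mean of its in-vocabulary
token vectors (word2vec text or binary format; any embedding table with
consistent dimension works). The mean is the minimal-assumption aggregate;
a unit-norm option normalizes token vectors first. Chunks with no
in-vocabulary token are dropped and counted. The surviving ordered points
`x_1 … x_T` are the document's semantic path. Documents with `T < 2` are
flagged (no speed or volume), and `T < 3` is flagged for circuitousness
(with both endpoints fixed, `T = 3` admits a single visiting order, so
circuitousness is identically 1 there); flags propagate through the
pipeline instead of raising, so corpora always process to completion.

## Features

**Speed** is the mean consecutive Euclidean distance, total distance over
`T − 1`.

**Volume** is the Lebesgue volume of the minimum-volume enclosing ellipsoid
of the path points. With `T ≈ 22` points in a 300-d ambient space the
full-dimensional ellipsoid is degenerate (volume zero), so the points are
first expressed in an orthonormal basis of their affine hull via SVD;
the effective dimension `d` is the number of singular values above
`rank_tol` (default 1e−9) times the largest, `d ≤ min(T−1, D)`. Pairwise
distances are preserved exactly, so the ellipsoid is geometrically
meaningful and `d` is reported with every row.

The MVEE itself is solved in the dual D-optimal design form by the
Khachiyan iteration with Wolfe–Atwood away steps: at each step either the
weight of the point with the largest Mahalanobis value is increased, or the
weight of the active point with the smallest value is decreased, until both
optimality gaps fall below `tol` (default 1e−7, max 10,000 iterations;
non-convergence raises with diagnostics). The returned shape matrix is
rescaled so the farthest point lies exactly on the boundary — containment
is then exact rather than `(1+tol)`-approximate, at the cost of a volume
overshoot bounded by `(1+tol)^(d/2)`. Volumes are tracked in log space
(`log U_d − ½ log det A`) because `det A` under/overflows around `d ≈ 20`.
A useful special case: when `T = d + 1` (points in general position, the
common case for whole essays) the optimal weights are exactly uniform and
the iteration converges immediately.

Because documents differ in length, the reported volume is normalized.
The default, `dim_root`, is `volume^(1/d)` — a per-dimension length scale
comparable across documents of different effective dimension; `per_chunk`
(`volume^(1/d)/T`) and `raw` are alternatives, and `T` and `d` are always
emitted so downstream analyses can control for length directly. The exact
normalization is a declared design choice of this package, exposed as a
config option rather than hard-coded.

**Minimum required speed** divides the length of the shortest Hamiltonian
path with endpoints fixed at `x_1` and `x_T` by `T − 1`. Up to
`exact_max = 12` interior points the optimum is found by Held–Karp dynamic
programming over interior subsets (`O(2^m m^2)`; sub-second at `m = 12`),
with ties broken toward the lexicographically smallest order by a
forward-greedy reconstruction. Beyond that a 2-opt local search runs from
the identity order, a nearest-neighbor construction, and `restarts` seeded
random interior orders, taking the best local optimum; since the identity
order is always a candidate, the heuristic never exceeds the observed path
length, so circuitousness from the heuristic is ≥ 1 by construction as
well. The solver used is recorded per document.

**Circuitousness** is `speed / min_required_speed`. A path whose points all
coincide has both speeds zero and is assigned circuitousness 1 with a
degenerate flag (zero minimum with positive speed is impossible and
raises). The identity `log speed = log circuitousness + log min required
speed` holds to machine precision because circuitousness is computed as the
ratio.

Zero-distance consecutive points are retained — no deduplication rule is
imposed. All features are invariant under rigid motions; scaling the
embedding by `c` scales speed, minimum required speed and `dim_root` volume
by `c` and leaves circuitousness unchanged; permuting interior points
changes speed and circuitousness but not volume or minimum required speed.

## Pipeline and association

Per-document features are log-transformed (their distributions are
right-skewed), z-scored across the corpus's non-flagged documents (sample
sd, `n − 1`), and averaged per author. The default order — standardize at
the document level, then average per author (`mean_of_z`) — is a design
choice; `z_of_mean` (average logs per author, then standardize across
authors) is available. Zero-variance columns standardize to zeros with a
warning rather than NaN.

The association layer z-scores the outcome and all continuous predictors,
expands categorical fixed effects into indicator contrasts (reference =
first level in sorted order, which affects the intercept but not the focal
coefficients), and fits OLS via QR. Collinear designs are rejected with the
aliased column names listed (pivoted-QR detection), never silently pruned.
p-values use the t distribution with `n − p − 1` degrees of freedom; no
robust or clustered errors are provided. The ridge variant solves
`(X'X + λI)b = X'y` on centered columns (intercept unpenalized), with λ
chosen by 10-fold cross-validation over a log-spaced grid including 0 and
seeded fold shuffling; λ = 0 reproduces OLS to numerical precision.
`decompose_speed_effect` fits the volume+speed model next to the model in
which speed is replaced by its two components — minimum required speed
(what the selected concepts force) and circuitousness (how suboptimally
they are ordered) — whose logs sum to log speed exactly.

Rows with missing values in the used columns are dropped and counted.
Externally computed covariates (topic weights, style scores, demographics)
pass through the corpus file as ordinary numeric or categorical columns;
their computation is out of scope.

## Synthetic data

The synthetic module exists so every stage is testable deterministically,
with no downloads and no natural language.

**Hash store.** Each word's vector is a unit-normalized Gaussian draw from
a PCG64 generator seeded by a BLAKE2b hash of `(seed, word)` — identical
across platforms, call orders and vocabulary subsets.

**Planted paths** emulate the two illustration regimes of the measures: a
smooth low-curvature curve (unit direction vector given a small
perpendicular perturbation per step, default 0.12 rad) with consecutive
steps of length `step`, globally magnified by `scale`. `scale` is a pure
homothety: at a fixed seed, doubling it doubles every distance — speed,
minimum required speed, and the `dim_root` volume scale — exactly. It is
*not* an independent spread target: on a low-curvature curve the spread is
geometrically tied to `(T−1) × step`, so spread and step cannot be set
independently without folding the curve and destroying the near-optimal
ordering that makes the sorted mode useful (sorted-mode circuitousness
stays within a few percent of 1). `shuffled` mode permutes the interior
points of the same point set, which raises speed and circuitousness while
leaving volume and minimum required speed unchanged.

**Synthetic corpora** emulate the emulated study's design: `n_authors`
authors × 2 documents × ~550 tokens (22 chunks of 25), with an author-level
outcome `β_vol · z(log volume) + β_speed · z(log speed) + ε`,
`ε ~ N(0, 1)` by default and `β = (+0.15, −0.05)`. Each document's chunks
mix three kinds of words: an anchor shared by all its chunks, one fresh
"topic" word per chunk with token share `p` (pushing the chunk points apart
in ~T−1 independent directions — the volume carrier), and an alternating
word pair with share `q` (adding `≈ √2·q` to every consecutive step while
occupying only two of the cloud's axes — the speed carrier). Author-level
targets for log-volume and log-speed are drawn independently
(sd 0.15, small per-document jitter) and inverted through this response
(`dim-root volume ∝ p`, `speed² ∝ 2p² + 2q²`), so the two planted features
vary near-orthogonally (empirical correlation ≈ 0.15–0.2 after token-count
quantization and clamping). The outcome is built from the features
*measured on the generated texts* by the same code path the pipeline runs,
so recovery tests probe the regression layer without attenuation from
target-vs-realized mismatch.

What the generator does **not** emulate: natural-language statistics
(Zipfian frequencies, syntax, topic structure), out-of-vocabulary tokens,
covariate structure correlated with the planted features, or documents of
varying length. In this corpus, minimum required speed is nearly collinear
with volume (both reflect how far apart the selected concepts sit;
empirical correlation ≈ 0.998), so decomposition regressions here must
plant effects on the speed components directly. Passing tests therefore
demonstrate the correctness of the geometry, the transforms and the
estimators — not that real essays satisfy the model.

**Oracles.** The exact path solver is cross-checked against full interior
enumeration (`T ≤ 9`, lexicographic tie-break); the MVEE against the same
iteration at `tol = 1e−12` plus an independent check of John's optimality
conditions (containment, and nonnegative weights on boundary points
reproducing the center and shape matrix, solved by nonnegative least
squares).

## Problem sizes and statistical calibration

The test suite exercises the oracle comparisons on 100 seeded instances
each, geometric invariances on 54 property cases, and end-to-end recovery
on 20 replicate corpora of 2000 authors — the replicate count is the
package's own choice of desk-scale problem size; at it, the Monte-Carlo
standard error of a mean standardized coefficient is about
`1/√(20·2000) ≈ 0.005`. The per-replicate standard error of a single
coefficient at `n = 2000` and unit outcome noise is `≈ 1/√2000 ≈ 0.022`,
so an individual replicate's estimate of a planted −0.05 carries a ~1.3%
chance of landing on the wrong side of zero; sign checks on individual
replicates are correspondingly fragile even when mean recovery is exact.
Invariance tests tighten the ellipsoid tolerance to 1e−10 so that solver
tolerance does not masquerade as geometric non-invariance.

## Known limitations

- The 2-opt heuristic carries no approximation guarantee; its solutions
  are only certified to lie between the optimum (when checkable) and the
  observed order.
- The MVEE tolerance trades accuracy for iterations; very flat point
  clouds (condition numbers beyond ~1e9 across the affine hull) can slow
  convergence.
- Cosine or other non-Euclidean metrics are not offered; the geometry of
  the decomposition identity presumes Euclidean distance.
- Per-author averaging assumes authors' documents are exchangeable; no
  hierarchical model is fit.
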