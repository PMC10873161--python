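# Methods

## Model

The package treats a single-cell expression matrix **A** (m genes × n
cells, non-negative, normalized scale) as the product of three factors,

    A = R Σ W,

and solves for the right factor.  **R** is a directed gene–gene
regulatory adjacency, **Σ** the singular matrix of A, and **W** the
cell–cell communication matrix.  Given R and Σ, the solve is the
Moore–Penrose pseudoinverse applied to A:

    W = (R Σ)⁺ A,

the minimum-Frobenius-norm least-squares solution of (R Σ) W ≈ A.  The
sign of `W[i, j]` encodes direction (non-negative: cell i → cell j;
negative: cell j → cell i), its magnitude the strength, and the diagonal
autoregulation.

The model's central assumption is that inter-cell regulatory structure is
recoverable from the way each cell's expression profile decomposes over
the regulatory in-profiles of individual genes: column i of R Σ is gene
i's incoming-regulation profile scaled by the i-th singular value, so the
solve expresses cell j's transcriptome as a weighted combination of
those profiles and reads the weight on column i as communication from
cell i to cell j.  This identification of the i-th cell with the i-th
gene's regulatory column is intrinsic to the factorization — Σ carries
no permutation — and has two practical consequences developed below: the
geometry of the simulator (which rows can carry a planted signal) and
the need for spectral regularization of the solve.

Expression values are used exactly as provided.  An optional
preprocessing step (`normalize_expression`: library-size scaling to 1e4
followed by log1p) is available but off by default, so the package never
silently transforms data.

## GRN inference

R can be loaded from any external tool (`load_user_grn`, dense matrix or
edge list, aligned to the expression gene order; absent genes get zero
rows/columns).  The built-in inference tests every ordered gene pair
(u, v) in three stages:

1. **Projection.** u's expression is regressed on all other genes with an
   L1 penalty (predictors standardized).  The penalty is chosen by
   3-fold cross-validation over the grid {0.01, 0.03, 0.1, 0.3, 1.0}
   with shuffled folds — cells are often stored grouped by type, and
   contiguous folds would hold out entire cell states.  A **null-model
   guard** accepts the projection only when its CV error beats the
   intercept-only model by more than one standard error of the null;
   otherwise the projection is the gene's mean.  A projection that
   cannot beat the null is noise, and ordering cells by noise destroys
   the series the next stage depends on.
2. **Monotone ordering.** Cells are sorted by the projected value
   (stable ties by original cell index, so a constant projection keeps
   the input cell order).  The sorted projection is a monotone
   pseudotime series.
3. **Lag-1 regression.** Along that order, `v_t = a·v_{t−1} + b·u_{t−1}
   + c` is fitted by least squares; the candidate edge strength is the
   absolute t-statistic of b and the edge is kept when its two-sided
   p-value clears `edge_alpha`.  The regressor is the denoised projected
   series when the projection is informative, the raw values in the
   fallback order otherwise.  Degenerate designs (constant series,
   collinearity) score (0, 1).

Two details matter for the *direction* of an edge.  First,
**leave-one-out pseudotime**: when v itself is in the support of u's
projection, u is re-projected without v before testing u → v.  A target
inside the projection would dictate its own cell order, making the two
directions of a coupled pair statistically symmetric (direction recovery
degenerates to a coin flip; with the exclusion it is essentially
perfect on lagged-pair benchmarks).  Second, **mutual exclusivity**: for
every unordered pair only the stronger directed strength is retained
(ties go to the lower-index gene), so at most one of R[u, v], R[v, u] is
nonzero and the diagonal is identically zero.

`edge_alpha` defaults to `1e-4 / (m(m−1))`: all ordered pairs are
tested, a single false edge corrupts an entire column of the downstream
operator, and this level keeps the inferred network on pure-noise data
empty with probability ≈ 1 − 1e-4.  A flat per-test level (say 0.01)
would admit on the order of a hundred spurious edges at m = 100.  For
matrices above `max_genes` (default 2000) inference restricts to the
most variable genes; O(m²) pair regressions are the cost driver, with
the inner loop vectorized over all targets of one regulator.

## The solve and its regularization

`compute_W` materializes R Σ by scaling R's leading min(m, n) columns
with the singular values (numerically identical to the dense product)
and applies the pseudoinverse from a truncated SVD.  Singular values
below `rcond · s_max` are treated as zero; `rcond` defaults to
max(m, n)·ε, the standard cutoff.  A rank of R Σ below n leaves part of
W undetermined (minimum-norm fills it with zeros) and emits a structured
`RankDeficiencyWarning`.  On ≤ 20×20 random instances the result matches
a dense `pinv` oracle to 1e−8 relative Frobenius error, and any
least-squares solution perturbed in the operator's null space is
strictly longer — the exact algebraic contract.

The *pipeline* applies one change on top: a **Tikhonov (ridge) filter**,
replacing the inverse filter 1/s by s/(s² + λ) with λ = (c·s_max)² and
c = 0.1.  The reason is empirical and structural: on expression-scale
data the operator's spectrum spans two orders of magnitude, and the
exact minimum-norm solution concentrates its mass on the weakest
resolved directions (amplification s_max/s_min ≈ 100), i.e. on
measurement noise; a hard cutoff merely moves the problem, creating a
knife edge where directions just above the cutoff receive maximal
amplification.  The smooth filter caps amplification at 1/(2·c·s_max)
with no cliff.  Recovery of planted structure is flat over c ∈
[0.05, 0.2]; the default sits in the middle.  `ridge=None` restores the
exact pseudoinverse everywhere, and `compute_W`'s own default is exact.

**Cell sampling (n > m).**  With more cells than genes the operator has
at most m columns and W is badly underdetermined.  `compute_W_sampled`
draws random cell subsets of size `batch_size` (default m), recomputes Σ
on each column subset, solves that round's W, and averages each entry
over the rounds containing both of its cells; rounds are extended until
every ordered pair is covered at least once, with the default round
count giving expected pair coverage ≥ 3.  With n ≤ m it delegates to the
direct solve unchanged.  On planted data the sampled type-level network
agrees with an exact solve of a gene-padded (square) configuration
(median Spearman ≥ 0.8 on 5-seed benchmarks).

Diagnostics: `reconstruct` returns R Σ W (the orthogonal projection of A
onto the operator's column space when W is the exact solution) and
`reconstruction_mse` the mean squared entrywise error against A.  The
MSE is reported in every pipeline manifest; it measures how much of
expression space the regulatory operator spans, not fit quality of the
communication calls.

## Networks and significance

`resolve_directions` reads both witnesses of an ordered pair —
`D[i, j] = max(W[i, j], 0) + max(−W[j, i], 0)` — because under the sign
rule each of W[i, j] and W[j, i] independently encodes an i → j signal;
addition preserves total evidence (a mean variant is available).  The
diagonal keeps positive autoregulation.  The identity
D[i, j] + D[j, i] = |W[i, j]| + |W[j, i]| holds exactly and is asserted
in the tests.

`aggregate_to_types` averages D over all ordered cell pairs of each
ordered type pair — means, not sums, so strengths are comparable across
types of different sizes; the within-type entry includes self-loops
(autocrine signalling is a first-class result).  The significance rule
is the global mean of the k × k matrix with strict inequality: ties at
exactly the mean are not significant, and a constant matrix yields no
calls.  `top_k_edges` and `compare_conditions` (both/only-1/only-2/
neither per ordered pair, label sets aligned by name) support summary
networks and cross-condition comparisons.

## Ligand–receptor nomination

For a communication from type A (m₁ cells) to type B (m₂ cells):

1. candidate genes are the intersection of the expression matrix's genes
   with the L–R database's genes;
2. genes expressed (nonzero fraction ≥ `expressed_frac`, default 0.3) in
   strictly more than half of the cell types are removed as universal;
   0.3 mirrors the complement of the 70%-zero rule below, and is
   configurable because "significantly expressed" admits other
   operationalizations;
3. per side, genes zero in more than 70% of the relevant type's cells
   are removed (ligands against the sender type, receptors against the
   receiver type); boundaries are exact — 70% zeros survives, 80% does
   not;
4. multi-subunit complexes collapse to the per-cell subunit minimum (the
   limiting subunit); complexes with subunits absent from the matrix are
   skipped with a warning;
5. ligand expression over A's cells and receptor expression over B's
   cells are each sorted descending, truncated to min(m₁, m₂), and
   compared by Pearson correlation with the exact t-transform p-value
   (min(m₁, m₂) − 2 degrees of freedom); a constant profile is
   degenerate and scores (0, 1);
6. p-values are Bonferroni-corrected over the pairs actually tested for
   this ordered type pair (duplicates deduplicated first), and adjusted
   p < 0.01 is significant.

The descending-sort statistic compares expression *rank patterns*, not
matched cells; it is sensitive to coupled activity gradients and, as a
side effect, generically positive between any two expressed genes —
which is exactly why the specificity and zero filters precede it.  The
correction family is per ordered type pair, matching the per-pair
procedure; a global-database family would be more conservative.

`lr_global_correlation` checks, across all ordered type pairs, the
Pearson correlation between aggregated communication strengths and a
database-wide coexpression score (mean over pairs of sender-type ligand
mean × receiver-type receptor mean, complexes by minimum).

## Evaluation

`binarize_mean` reproduces the mean-threshold rule as a 0/1 matrix and
agrees with the significance flags by construction.  `roc_auc` sweeps
the continuous strengths over all distinct thresholds (the single
mean-threshold point is a special case of the curve) and cross-checks
the trapezoidal AUC against the midrank Mann–Whitney statistic to 1e−9
internally; degenerate truth (single class) is an error, and the AUC is
invariant under monotone score transforms.  `spatial_truth` converts
spot coordinates into a ground-truth table: spots are neighbors within
1.5× the median nearest-neighbor distance (a declared stand-in for a
platform-specific adjacency; configurable), and an ordered type pair is
supported when any neighboring spot pair carries those labels in either
orientation.

## The simulator

`make_planted_dataset` emulates a normalized, sparse single-cell matrix
with planted communication.  Background expression is lognormal
(σ = `noise_sd`) with 70% dropout.  Cells are partitioned into
contiguous, near-even type blocks.  Each planted channel (a → b) plants
a ligand-like gene — expressed only in sender cells at 2 + z, with
latent activity z ~ U(1, 4), clearly above the ~1 background as marker
genes are — and a five-gene response module (receptor first) expressed
only in receiver cells, driven by the sender latents with unit coupling
through **matched ranks**: the r-th strongest sender determines the r-th
strongest receiver, surplus receivers fall strictly below the weakest
sender, and all planted signals carry multiplicative lognormal noise of
the same σ.  Rank matching makes the descending-sort L–R statistic exact
at σ = 0 (correlation 1.0) and strong under noise.

Two layout decisions tie the plant to the factorization's geometry, and
are the honest core of the design: because the solve attributes the
outgoing signal of cell i through gene i's regulatory column, a planted
channel is representable by this model family only if the genes carrying
it occupy rows that the solve pairs with sender-type cells.  The
simulator therefore (1) uses contiguous type blocks, and (2) places each
channel's six genes on rows inside the sender block's index range,
shrunk by the cell-sampling slack n − m (row g is paired with cells
g … g + (n − m) across sampling rounds).  This is the same logic as
placing a planted clique where a clique detector can see it: the
simulator defines what "communication is present" means *in the model's
own terms*, and the pipeline is then tested on whether it finds it.  A
generator that scattered channel genes uniformly would plant a signal
this entire model family is provably blind to (the row identity of W is
positional), and every downstream recovery experiment would measure
nothing but chance.

`make_lagged_pair` provides the regulatory-direction benchmark: a
stationary AR(1) driver x (φ = 0.8, unit innovations) and
y_t = β·x_{t−1} + ε with ε of standard deviation `lag_noise_sd`;
`embed_lagged_pair` hides the pair among independent noise genes,
shifted to be non-negative, with cells in true time order.

What the simulator does **not** emulate: count noise (it works on the
continuous normalized scale the decomposition consumes), droplet
chemistry, doublets, batch effects, overlapping or hierarchical cell
types, or indirect multi-hop signalling.  Passing tests therefore show
that the pipeline recovers structure the model class can express under
realistic sparsity and noise — not that real tissues satisfy the model.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| `edge_alpha` | 1e-4 / m(m−1) | per-test GRN edge p threshold (null network empty w.p. ≈ 1 − 1e-4) |
| LASSO grid | {0.01 … 1.0}, 3-fold CV, shuffled, null-guarded | projection penalty |
| `max_genes` | 2000 | variance-ranked gene cap for GRN inference |
| `rcond` | max(m, n)·ε | pseudoinverse cutoff (exact solve) |
| `ridge` (pipeline) | 0.1 | relative Tikhonov damping of the solve |
| `batch_size` / rounds | m / pair coverage ≥ 3 | cell sampling when n > m |
| `combine` | add | direction-witness combination |
| `expressed_frac` / `zero_frac` | 0.3 / 0.7 | L–R expression filters |
| L–R significance | Bonferroni-adjusted p < 0.01 | per ordered type pair |
| spatial neighbor factor | 1.5 × median NN distance | spot adjacency |

## Known limitations

- Sender attribution is positional by construction of the factorization;
  on data whose gene order is unrelated to any cell structure the
  row dimension of W carries no biological sender information.  The
  simulator makes this explicit; on real data the method's outputs
  should be read with that caveat.
- The solve's scale is arbitrary up to the spectrum of R Σ; strengths
  are comparable within one dataset, not across datasets.
- The mean-threshold rule always calls roughly the top half of a
  homogeneous strength distribution; it is a relative, not calibrated,
  significance notion.
- The descending-sort Pearson statistic compares sorted profiles, so it
  cannot distinguish which cells co-participate, only that activity
  gradients match; its p-value is exact only under independence of the
  sorted values, which sorting itself violates — the Bonferroni layer
  and the preceding filters absorb much, but not all, of that
  liberality.
- Lag-1 is the only regression order implemented; regulatory effects
  spread over longer pseudotime lags dilute into the AR control term.
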