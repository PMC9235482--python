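# Methods

## Problem and model

Bulk RNA-seq measures a mixture: each sample's expression vector is a
convex combination of cell-type expression profiles weighted by the
cell-type composition of the tissue.  Writing B (m genes x n samples)
for the bulk matrix, C (m x K) for the profiles and F (K x n) for the
fractions, deconvolution seeks B ~ CF with C >= 0, F >= 0 and each
column of F on the probability simplex.

When annotated single-cell data from related samples of the same
patient exists, it yields a reference profile matrix S (m x k) that is
informative but imperfect: it is distorted by dropout, comes from a
different site or time point, and may miss populations entirely.  The
model therefore *penalizes* rather than *fixes* the first k profile
columns:

    min  ||B - CF||_Fr^2 + lambda ||C1 - mu S||_Fr^2
    s.t. C >= 0, F >= 0, F columns sum to 1

with C = [C1 | C2].  C2 holds y extra cell types with no reference
counterpart (e.g. populations that never migrated to the sampled
metastases).  mu is a free scalar absorbing scale differences between
reference and bulk units, and lambda trades the data term against the
reference prior.  lambda = 0 recovers complete deconvolution (S then
only informs the initialization); lambda -> infinity approaches
partial deconvolution with C1 pinned to mu S.

### Assumptions

- Mixing is linear in linear expression space (no log transform inside
  the loss); inputs are CPM-normalized by default so that all columns
  share a scale and mu stays near 1.
- The reference cell types are a subset of the bulk cell types; the
  remaining bulk populations are representable by y additional
  non-negative profile columns.
- Gene identifiers match exactly across B and S; unmatched genes are
  dropped (with a warning) before fitting.

## Optimization

Block coordinate descent, one pass per sweep in the order
F -> C1 -> C2 -> mu, each block solved to optimality:

- **F**: for each sample b, min_f (1/2) f'C'Cf - b'Cf over the simplex.
  Solved with a primal active-set method on the bound constraints with
  the sum-to-one equality kept inside the KKT system.  C'C is positive
  semidefinite; when it is singular on the simplex the minimizer is
  not unique and the deterministic pivoting order breaks the tie.
- **C1**: rows are independent; with F partitioned into F1 (known) and
  F2 (unknown) and Bbar = B - C2 F2, each row solves a non-negative
  least squares with stacked design [F1'; sqrt(lambda) I] and target
  [bbar; sqrt(lambda) mu s].  Solved by Lawson-Hanson NNLS, with a
  vectorized shortcut: the unconstrained least-squares solution is
  computed for all rows at once and accepted wherever it is already
  non-negative (a feasible unconstrained minimizer is the constrained
  minimizer).
- **C2**: same row structure without the penalty term.
- **mu**: closed form <C1, S> / <S, S> (no-intercept least squares).

Because every block update is exact, the objective never increases;
the per-sweep trace is checked to be non-increasing up to a *relative*
slack of 1e-9 (at CPM scale the objective is O(1e9), where an absolute
slack below double-precision resolution would be meaningless).

**Initialization.**  C1 = S and mu = 1 ("reference" mode; the
recommended informed start), or C1 uniform on [0, max B] ("random"
mode, the no-prior condition); C2 is always drawn uniformly on
[0, max B] from the run seed.  F is produced by the first F-update, so
it never needs its own start.  An explicit `start=` mapping supports
warm starts.

**Convergence.**  Relative objective change below `tol` (default 1e-6)
or `max_sweeps` (default 100).  Coordinate descent on this objective
approaches its limit slowly in the flat directions left by few bulk
samples; in practice the recovered C and F stabilize long before the
objective meets a tight tolerance, which is why the default sweep cap
is modest.

**Numerical conventions.**  QP tolerances are applied after rescaling
each subproblem by its largest coefficient.  Tiny negative solver
outputs are clamped to zero and F columns are renormalized to sum
exactly to one.  y = 0 skips the C2 update; a reference with zero
columns is rejected (without S and without the penalty the C1/C2
split is meaningless); y larger than the number of bulk samples
triggers an ill-posedness warning but not an error.

## Reference construction

From a genes x cells matrix with one cell-type label per cell:

1. CPM-normalize the cells (every column scaled to 1e6 total).
2. Average cells per type (columns ordered by first appearance of the
   label) to get Cs, then CPM-normalize the aggregated profiles again.
3. Fit the dropout model on the cell-level CPM matrix: for each gene,
   the all-cell mean u_j (zeros included) and the observed zero
   fraction P_j.  The Michaelis-Menten curve
   P_dropout = 1 - u / (K_M + u) inverts exactly at one point:
   K_M = u_j P_j / (1 - P_j).  This per-gene closed form is the
   default; a `global_curve_fit` mode instead fits a single K_M to all
   (u_j, P_j) pairs by bounded least squares, for users who prefer the
   one-curve reading of the dropout literature.
4. Correct: S = Cs / (1 - P_dropout(Cs)) = Cs + K_M at every positive
   entry.  Zeros stay zero (a zero entry implies predicted dropout 1
   and carries no recoverable signal); genes never detected in any
   cell are flagged, stored with K_M = 0, and skipped with a warning.

Genes with dropout generated by the Michaelis-Menten mechanism are
recovered exactly in expectation by this correction: if the true value
is t, the observed type mean is t(1-p) and the estimated K_M is tp, so
the corrected value is t.  The CPM re-normalizations in between
perturb this identity slightly; the residual error shrinks with the
number of cells (verified in the test suite and the acceptance
script).

**Marker selection.**  For every gene and cell type, a two-sided
Wilcoxon rank-sum test compares log2(CPM+1) in that type's cells
against all other cells (ranks are invariant to the monotone
transform, so the pseudocount choice is inert).  Benjamini-Hochberg
correction is applied jointly over the whole gene x type family — the
conservative, reproducible choice when the family is otherwise
unspecified — and a gene is kept when any corrected p-value is at most
alpha (default 0.001).  Types with fewer than two cells are skipped
with a warning.

## Simulator

The generator emulates pseudo-bulk mixtures built from a cell-type
profile matrix, the standard validation device for deconvolution
methods (real bulk data has no knowable ground truth).

- **Base profile**: either user-supplied or generated — a shared
  log-normal baseline per gene, mild log-normal type-to-type
  variation, and a dedicated block of strongly up-regulated marker
  genes per type (fold change 8-32), CPM-normalized per column.
  Defaults: 5000 genes, five known types plus one unknown.  When a
  larger profile is supplied, genes are subsampled uniformly without
  replacement (seeded).
- **Component noise**: profiles are moved to log2(1+x) space and each
  gene's entries perturbed with Gaussian sd sigma_j / 5, where sigma_j
  is that gene's across-type sd in the transformed space, then mapped
  back (inverse transform clamps at zero).  The pseudocount 1 keeps
  zero expression representable; the /5 attenuation keeps per-sample
  profiles recognizably the same cell types.
- **Fractions**: the base simplex vector (default: geometric decay
  0.7^i, renormalized — a realistically uneven composition) is
  perturbed once in the same transformed space with sd sigma_f / 2
  (sigma_f: across-type sd of the transformed frequencies) to give the
  tissue-level composition, replicated per sample, perturbed again
  per sample with the inter-sample rule (sd sigma_f / 5, the same
  /5 attenuation used for the component matrices), inverse-
  transformed, clamped and renormalized.  A degenerate all-zero column
  triggers a seeded resample (at most 100 attempts).
- **Convolution**: B[:, j] = component_j @ F[:, j] exactly, so the
  construction identity B - component * fraction = 0 is bit-true.
- **Reference noise**: `perturb_reference` degrades S with the same
  log2-Gaussian scheme at sd s_noise * sigma_j — a reconstruction of
  reference-quality noise, exposed as its own operation.
- **Dropout fixture**: `simulate_dropout_cells` draws annotated single
  cells from a profile with per-gene Michaelis-Menten dropout, for
  validating the reference-construction pipeline end to end.

What the simulator does **not** emulate: sequencing count noise
(draws are Gaussian in log space, not Poisson/negative-binomial),
library-size variation, batch effects between single-cell samples,
ambient RNA, or doublets.  Tests passing on this generator therefore
demonstrate correctness of the optimization and correction machinery
under the stated noise model, not robustness to every artifact of
real data.

All randomness flows from one integer seed through independent named
substreams, so every artifact is reproducible and sub-results
(components, fractions) are consistent between standalone and
end-to-end calls.

## Evaluation

Inferred unknown types carry no labels, so inferred columns are first
matched to truth columns: known types positionally, the rest by
maximum-total-Pearson bipartite assignment (undefined correlations
rank below all defined ones, so degenerate zero-variance columns are
matched last; surplus inferred columns stay unmatched and are excluded).
Metrics on the matched, scope-filtered matrices:

- L1 loss ||Chat - C||_1 / ||C||_1 (entrywise), scale-sensitive;
- profile Pearson r on the flattened matrices, reported raw and
  squared (the squared value is the headline score; both are kept
  because the two readings of a "squared correlation coefficient"
  differ);
- fraction MSE, mean over all scope-filtered entries;
- fraction Pearson r, raw and squared.

Correlations are computed on flattened linear-space matrices — the
same space as the loss — and undefined correlations are reported as
missing values, never coerced to zero.  The `known_only` scope mirrors
comparisons against methods that cannot infer unreferenced types; with
y = 0 both scopes coincide.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| lambda | 0.1 | loss weight | balances data and prior terms across the tested regimes |
| y (unknown types) | 1 | count | one free component absorbing bulk-only populations |
| max_sweeps | 100 | sweeps | C/F stabilize well before the objective tolerance |
| tol | 1e-6 | relative | scale-free stopping rule |
| alpha (markers) | 0.001 | BH-corrected p | stringent cutoff for marker credibility |
| CPM normalization | on | — | shared scale; mu absorbs the residual |
| noise multipliers | 1.0 | x sigma/5, sigma/2 | the generator's standard condition; 0 = off |

## Problem sizes used in tests

The suite exercises fits at 120-200 genes, 4-6 cell types and 1-4
bulk samples, dropout recovery at 100-800 cells, and Monte-Carlo noise
calibration at 10,000 draws; the acceptance script uses 200 genes (5
known + 1 unknown types), 800 synthetic cells, and 5 replicate seeds
for the reference-vs-no-reference contrast.  These sizes keep every
oracle cross-check (simplex grids at step 0.001-0.01, box grids at
step 0.01-0.02, SLSQP, exhaustive permutation matching) exact enough
to be decisive while the full suite runs in seconds.

## Known limitations

- Recovery of unknown-type profiles degrades sharply when bulk
  samples are few or compositions barely vary; with y greater than the
  number of samples the problem is ill-posed (warned, not refused).
- lambda and y are not selected automatically; no principled selection
  rule is provided.
- The active-set simplex QP returns one optimum when C'C is singular
  on the simplex; which one depends on the deterministic pivot order.
- The dropout correction cannot restore genes with zero aggregated
  expression in a type, and flagged (never-detected) genes pass
  through uncorrected.
- Gene identifiers are matched as exact strings; no alias resolution.
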