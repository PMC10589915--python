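# Methods

## Model

Expression of target gene `j` follows a non-linear ODE with first-order
decay, `dx_j/dt + c_j x_j = f_j(x_{R_j})`, where `R_j` is the pruned set of
candidate regulators.  Two discrete reductions supply supervised training
pairs: a forward difference over a lag of `b` sampling steps for
time-series data, and the equilibrium identity `c_j x_j = f_j(x_{R_j})` for
steady-state data.  Features are the regulator levels at the *earlier* time
of each difference window: the reduction leaves the evaluation time of the
right-hand side open, and earlier-time features preserve causal direction.
Time-series blocks (in experiment order) are stacked above steady-state
rows; the design has exactly `Σ_e (T_e − b) + S` rows.

The decay rate defaults to the single global constant `c = 1.0` (per-gene
overrides are available): per-gene decay rates are rarely identifiable from
benchmark data, a single constant is the convention of ODE-ensemble GRN
methods, and for steady-state-only data `c` only rescales responses without
changing any ranking.  The steady-state response is `c·x` (not `x`) so that
mixed time-series/steady designs stay on one response scale.  The lag
defaults to `b = 1`.  No feature standardization is applied — tree
ensembles are invariant to monotone feature transforms.

## MIC estimation

The Maximal Information Coefficient between two length-`N` vectors is the
maximum over all grids with `m, n ≥ 2` and `m·n < N^α` (strict; `α = 0.6`)
of `I(X;Y)/log2 min(m, n)`, where `I` is the mutual information (base 2) of
the grid's cell counts.  Cut points are placed only between consecutive
distinct sorted values, so tied values are never split and MIC depends on
the data through rank order alone — making it exactly invariant under
strictly increasing transformations.

Two search strategies:

* `N ≤ 25` (configurable): exhaustive enumeration of every admissible
  cut-point placement — the exact maximum.  Feasible because the grid bound
  admits only small grids at these sample sizes.
* `N > 25`: the MINE-style approximation.  For each admissible `(m, n)` and
  both axis orientations, one axis is equipartitioned by mass; the other is
  optimized by dynamic programming over at most `15·m_max` candidate
  boundaries (mass-equipartitioned "superclumps").  The result is a lower
  bound on the exhaustive maximum; both paths respect the strict bound.

Degenerate inputs are defined rather than fatal: constant vectors score 0,
and samples too small to admit any grid (`N ≤ 10` at `α = 0.6`) score 0
with a warning, so a flat gene simply attracts no regulators.  Note that
`MIC(x, x) = 1` requires an even mass split to exist; skewed two-valued
vectors legitimately score below 1.

For mixed data each gene contributes one pooled vector (all time points of
all experiments, then all steady rows).  The two data types are pooled
without rescaling by default — both are on the same expression scale in the
supported dialects — with an optional per-gene z-score switch (a no-op for
MIC itself, which is rank-based, but kept for config parity).  `N` in the
grid bound is the pooled sample count.

## Regulator pruning

Candidates with `MIC(i, j) > T_MIC` (strict inequality) are retained,
ordered by MIC descending with name-ascending tie-break.  When a
transcription-factor list is supplied, candidates are restricted to it
*before* MIC computation (cheaper; the surviving set is identical).  If
fewer than `min_regulators` (default 3) survive, the top 3 candidates by
MIC are kept instead: an empty design matrix would silently drop the
target, and the pruning is meant to shrink sets, not to drop targets.
Default thresholds by data profile: 0.15 for dense simulated data; for
sparse real data the cross-validation searches 0.2–0.7.

## Importance fusion

Per target, an XGBoost regressor (100 trees, depth 3, learning rate 0.1,
exact tree method, total split-gain importances) and a random forest
(100 trees, unlimited depth, `√M` features per split, impurity-reduction
importances) are fit to the same design.  These are each library's
canonical importance semantics.  The fused score is the elementwise
product — the rank-equivalent, square-root-free form of the geometric
mean — so a regulator must convince both learners; one found by only one
model scores 0 by construction.  Fused vectors are normalized to unit sum
per target before entering the global matrix (raw products are not
comparable across targets with different response variances); a flag
disables normalization for raw-score ranking.  Both models run
single-threaded with a fixed seed (default 42), so identical inputs give
byte-identical ranked outputs.  Ablation modes (`boosted_only`,
`forest_only`) reuse the same fitted models, making comparisons exactly
paired.

## Evaluation

The evaluated universe is every ordered non-self pair (TF→any under a TF
restriction); unlabeled pairs count as negatives (DREAM convention), with a
strict mode confined to explicitly labeled pairs.  Edges missing from a
ranking are appended at score 0 under the global tie-break so curves sweep
the full universe.  AUROC uses trapezoidal integration with equal scores
grouped into one threshold step (equivalently Mann–Whitney concordance with
half credit for ties).  AUPR uses the precision–recall *step* curve
(average precision); trapezoidal PR interpolation over-credits between
achieved points and is deliberately not used.  EPR divides early precision
by the `k/(n(n−1))` chance baseline; an optional flag substitutes the
TF-restricted density `k/(|TF|(n−1))`.

## Cross-validation protocol

Target genes are split randomly into two folds.  For each grid cell
(30 MIC thresholds × 10 learning rates by default) models are fit only for
training-fold targets and scored on gold edges *into* those targets
(target-based edge attribution matches the per-target model structure); the
best cell by training overall score is applied to the held-out fold, folds
are swapped, and the two held-out scores are averaged.  The MIC matrix, the
regulator sets per threshold, and the forest fits (independent of the
learning rate) are cached across cells.  An observer hook records every
target fit during selection, which the tests use to audit that selection
never touches held-out targets.

## Synthetic benchmark generator

Networks are uniform random digraphs with `round(density·G(G−1))` signed
edges (signs Bernoulli(½), strengths log-uniform in [0.5, 2]).  Dynamics
are Hill kinetics, `dx_j/dt = basal_j + Σ_i s_ij H_i(x_i) − decay_j x_j`
with activation `x^h/(K^h + x^h)` and repression `K^h/(K^h + x^h)`;
kinetic defaults are basal ~ U[0.25, 1.0], decay ~ U[0.5, 1.5], `h = 2`,
`K = 1` — order-one expression with responses in the sensitive part of the
Hill curve.  Time courses start from random states in U[0.1, 2] and are
integrated by fixed-step RK4 (step 0.05) with samples at unit spacing —
plain enough to re-implement identically anywhere.  Steady-state conditions
multiply every basal rate by an independent log-normal factor (sd 0.5 on
the log scale, emulating multifactorial perturbations) and integrate until
`|dx/dt| < 1e−6·|x|` everywhere (error if not reached within 400 time
units).  Measurement noise is multiplicative log-normal (default sd 0.05),
respecting non-negativity.  A gene with no inputs settles at the
closed-form fixed point `basal/decay`, which anchors the solver tests.

What the generator does **not** emulate: the mRNA/protein two-layer
kinetics and stochastic dynamics of full GRN simulators, realistic
perturbation designs (knockouts/knockdowns), batch effects, and the
time-varying perturbations of the DREAM4 time courses (all experiments
here relax toward the same attractor from different initial states).
Passing recovery tests therefore demonstrates correct mechanics and
meaningful signal recovery under idealized kinetics, not performance on
real expression compendia.

## Problem sizes in the test and acceptance runs

The recovery benchmark runs at `G = 20`, density 0.1 (38 edges),
5 time courses × 21 points + 40 steady conditions (145 pooled samples per
gene), noise sd 0.05, 10 seeds — a scale at which the full pipeline with
default ensembles completes in seconds per seed.  The cross-validation
checks run the full 30 × 10 grid with reduced ensembles (10 trees, depth
2/4), which leaves grid-cell *selection* behavior unchanged while keeping
600 cells cheap.  Measured under these conditions (seeds 0–9): mean fused
AUROC ≈ 0.70, mean EPR ≈ 3, fused overall ≥ each single-model overall,
label-shuffled controls at chance.  These numbers are recomputed — never
stored — by `tests/test_acceptance.py` and `scripts/acceptance.py`.

## Numerical and degenerate-input conventions

`0·log 0 := 0` throughout; MI of a table with a single non-empty row or
column is exactly 0.  Score ties in edge rankings break by (regulator,
target) lexicographic order, making outputs byte-reproducible.  Confusion
rates with zero denominators return a flagged 0.  Missing values in input
files are hard errors (the supported dialects carry no NA convention), and
gene identifiers match case-sensitively.  Data writers emit shortest
round-trip float representations so write→read is lossless; ranked-edge
scores are written with 10 significant digits.

## Known limitations

MIC above the exhaustive cutoff is a lower-bound approximation; thresholds
tuned on exact small-sample MIC values may transfer imperfectly to the
approximate regime.  The per-target models ignore regulator interactions
across targets (no joint sparsity), fused scores inherit both ensembles'
biases toward high-variance features, and supervised threshold selection
via cross-validation uses the gold standard — it estimates attainable
performance, not blind-prediction performance.
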