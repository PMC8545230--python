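# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic data the tests run on, and the design
choices made where the formulation was genuinely open.

## Search model

All optimizers minimize a scalar objective over an axis-aligned box
`[L, U]^d`; maximization is handled by negating at the harness boundary.
Positions are clipped to the box after every update. A run is a pure
function of `(algorithm, space, objective, params, seed)`: one
`numpy.random.Generator` stream seeded at entry drives initialization and all
iterations, so identical configurations reproduce results bit-for-bit on one
machine. The best-so-far curve is recorded after each full iteration and is
non-increasing by construction; the incumbent is tracked across iterations
even when the population itself degrades (moves are not elitist in the
squirrel-search family).

### Basic squirrel search (SS)

Parameters and defaults: population `n` (≥ 5; one hickory + three acorn +
at least one normal agent), iterations `t_m`, gliding constant `G_c = 1.9`,
predator probability `P_dp = 0.1`, Lévy exponent `β = 1.5`, gliding-distance
range `d_g ~ U(0.5, 1.11)`. Each iteration:

1. agents are sorted by fitness (stable sort, lower index wins ties):
   hickory = best, acorns = ranks 2–4, normals = rest; the normals are
   re-partitioned uniformly at random (independent fair coin per agent) into
   an acorn-bound and a hickory-bound group each iteration;
2. acorns glide to the hickory, acorn-bound normals glide to a uniformly
   chosen acorn, hickory-bound normals glide to the hickory — each agent
   independently abandoning its glide for a uniform random location with
   probability `P_dp`; the hickory agent itself does not move;
3. seasonal monitoring: with `S_c[k]` the Euclidean distance of acorn `k`
   to the hickory and `S_min = 10⁻⁶/365^{2.5 t/t_m}`, the condition
   `min_k S_c[k] < S_min` relocates **all** normal agents to
   `L + Levy·(U − L)` component-wise.

The Lévy step is `0.01·r_a·σ(β)/|r_b|^{1/β}` with `r_a, r_b ~ U(0,1)`
(`r_b = 0` redrawn) and `σ(β)` the usual Mantegna scale factor
(`σ(1) = 1` exactly). Because `r_a, r_b` are uniform rather than normal,
steps are predominantly small (median ≈ 0.003) with a heavy upper tail —
under seasonal relocation most normals land near the lower corner of the
box, an aggressive exploration reset.

### Advanced variant (ASSOA)

All SS parameters plus a per-iteration gate `p ~ U(0,1)`: if `p ≥ 0.5` the
iteration is exactly the SS gliding iteration (the two algorithms consume
identical random streams on this branch — asserted bit-for-bit in the
tests). Otherwise the normal agents move by one of three added families,
chosen by further per-iteration draws `P_a, a, P_d, d ~ U(0,1)`:

* **diagonal** (`P_a < a`): `x + v + c₁r(hickory − x) + c₂r(nearest acorn − x)`,
  with `c₁, c₂, r ~ U(0,1)` drawn per agent and `r` reused within the
  expression; "nearest" is Euclidean, which makes the single-acorn term
  deterministic;
* **vertical / horizontal** (`P_d < d`): one normal agent `x_rand` is drawn
  per iteration; agents for which `x_rand` is fitter move toward it
  (vertical), the others toward the hickory (horizontal), each plus the
  velocity term;
* **exponential** (otherwise): `x + |x_rand − x|·exp(bτ)·cos(2πτ)` with
  `b ~ U(0,1)` per agent and `τ = t/t_m`. With an integer iteration number
  the expression degenerates (`cos(2πt) ≡ 1`, `exp(bt)` overflows), so the
  normalized iteration is used in both factors; the move then sweeps from
  mildly expansive early to oscillatory-contractive mid-run.

Acorns and the hickory do not move on the `p < 0.5` branch. ASSOA's
seasonal relocation re-anchors each normal agent at
`x_ht + 2r(x_ht − x)(1 − ((x_ht + x)/x)²)` component-wise (zero denominators
replaced by `+1e−10`), a spread around the incumbent rather than a corner
reset.

**Velocity.** The velocity matrix is initialized to zero and never updated,
exactly as in the algorithm's listing, which provides no update equation;
the `v` terms above therefore vanish unless a caller seeds velocities.
Treating velocity as the previous displacement was implemented and measured:
it feeds the large random-relocation jumps back into the moves and degrades
sphere convergence by two orders of magnitude, so the literal zero-velocity
reading was kept.

**What the added moves buy.** On smooth unimodal objectives the gliding
cases are the stronger contractor, and SS converges deeper than ASSOA on the
sphere benchmark (medians ≈ 1e−7 vs ≈ 2e−4 at `d = 10`, `n = 30`,
`t_m = 200`; both far below the 1e−3 success threshold the tests use). The
added moves pay off on the discrete, plateau-heavy feature-selection
landscape, where partial pulls toward leaders generate intermediate masks
that pure overshoot-gliding cannot reach; there ASSOA is never significantly
worse than SS and typically matches the exhaustive oracle more often.

### Baselines

GWO: canonical alpha/beta/delta update, `a` decaying linearly 2 → 0 over the
run. GA: tournament selection (size 3), arithmetic per-gene crossover
(probability 0.9), per-gene uniform resampling mutation (probability `1/d`),
elitism 1. Both satisfy the same harness contracts (bounds, seeded
determinism, non-increasing best-so-far).

## Wrapper feature selection

Continuous positions live in `[0,1]^D`; component `j` is selected iff
`1/(1+exp(−10(x_j − 0.5))) ≥ 0.5`, i.e. iff `x_j ≥ 0.5`. A mask is scored
by `F = h₁·Err + h₂·|s|/D` with `h₁ = 0.99`: `Err` is the misclassification
rate, on the validation split, of a k-nearest-neighbours classifier
(`k = 5`, Euclidean, majority vote) fitted on the training split restricted
to the selected columns. k-NN is the conventional wrapper choice: cheap,
deterministic, no tuning; an MLP wrapper option exists for parity studies.
The all-zero mask scores `Err = 1` (ratio 0) rather than crashing; an
alternative force-one-random-feature policy is available. Mask evaluations
are cached by mask bytes — the objective depends on the position only
through its mask, and the cache typically cuts classifier fits by an order
of magnitude. `exhaustive_best_subset` enumerates all non-empty masks
(guarded to `D ≤ 20`), breaking fitness ties toward the lexicographically
smallest mask, and serves as the global-optimum oracle in the tests.

## Optimizer-trained perceptron

Architecture: one hidden layer, sigmoid hidden activation
`f(S) = 1/(1+e^{−S})`, **linear** output scores, class decision by argmax
(ties to the lower class index). Weights and biases live in `[−1, 1]`,
enforced by the search box, and are flattened in the fixed layout
`[W_in·hidden row-major, hidden biases, W_hidden·out row-major, output biases]`.
Inputs are min–max scaled per feature, `x' = (x − min)/(max − min)`, with
statistics frozen from the training split (constant features map to 0;
out-of-range values extrapolate). Hidden width defaults to `2·n_in + 1`,
the classic heuristic. Multi-class labels are handled by one output score
per class.

**Search fitness.** The raw misclassification rate is piecewise constant,
so a derivative-free population search stalls on its plateaus, and zero
error on a small validation split carries no margin information; measured on
the separable benchmark it yields ~1/10 runs at ≥ 95% test accuracy. The
default training fitness is therefore a tempered softmax cross-entropy
(temperature 4) over the pooled train+validation samples — the standard
smooth surrogate in evolutionary neural-network training — which steers the
same optimizers to margin solutions (8–10/10 runs at ≥ 95% across seed
families). The validation-error objective remains available
(`loss="error"`) and is what the reported error metrics use. The test split
is scored exactly once, after the search ends.

## Synthetic data

Three generators, each a pure function of spec + seed, emulate the
statistics (not the visuals) of pooled CNN features:

* **planted**: `k` informative columns with class means `δ` noise-standard-
  deviations apart (offset +2 so min–max scaling is exercised), optional
  jittered redundant copies, the rest class-independent noise; columns are
  shuffled and the permuted ground-truth indices returned. Because all
  informative columns carry the same class contrast they are
  interchangeable, and the optimal mask size grows with the evaluation
  sample: at 120 samples one informative column already reaches zero
  validation error, at 500 samples the ~2% single-column Bayes error
  (δ = 4) is visible and multi-column masks win.
* **separable**: two balanced classes placed at signed distance
  ≥ margin/2 from a random hyperplane through the origin (the unit normal is
  returned for oracle constructions); optional label-noise flips set a known
  error floor.
* **fixture**: 8 blocks of correlated rectified-Gaussian columns
  (non-negative, block-wise correlated), 3 classes, mild signal in 5% of
  columns — a shape stand-in for pooled deep-feature tables.

What passing on these generators shows — and does not. They give exact
ground truth and controllable difficulty, so they verify the mechanics
(global-optimum recovery, feature-frequency recovery, margin learning,
calibrated tests). They are Gaussian, independent-sample, noiseless-label
constructions; nothing here certifies performance on real extracted image
features, whose correlations and label noise are far less benign.

## Statistics

Wilcoxon rank-sum: midranks for ties; for pooled size ≤ 20 the exact
two-sided p-value is computed by enumerating all C(m+n, m) group
assignments (the null distribution of U is symmetric about mn/2, so the
two-sided p is the probability of an at-least-as-large deviation); larger
samples use the tie-corrected normal approximation with continuity
correction. One-way ANOVA is the classical between/within decomposition
(the sums of squares are exposed, and their conservation is asserted to
1e−9 relative); two groups reproduce the squared pooled t statistic.
Classification metrics use the standard confusion-count definitions, with
`None` markers (never NaN) for zero-denominator ratios; AUC is the
normalized Mann–Whitney statistic of the score ranking. Run-set statistics
report mean error, mean selected fraction, and mean/min/max/sd (ddof = 1)
of fitness, the usual feature-selection comparison table.

The comparison harness runs each algorithm M times (default 30;
the bundled experiments use 10) with paired seeds — run j of every
algorithm sees the same dataset realization and optimizer seed — and emits
the statistics table, pairwise Wilcoxon p-values against the reference
algorithm, a one-way ANOVA across all algorithms (degenerate all-identical
inputs are reported as F = 0, p = 1 rather than an error), and per-run
convergence curves.

## Numerical choices and edge cases

* Fitness of unevaluated agents is a NaN sentinel; any ranked read raises
  instead of silently comparing stale values.
* Sorting ties break toward the lower agent index (stable argsort), making
  role assignment deterministic.
* The seasonal threshold numerator is 10⁻⁶; at plausible `t_m` the trigger
  only fires once the elite agents have genuinely collapsed
  (distances < 10⁻⁶), which on plateau landscapes happens mid-run and acts
  as a built-in restart.
* `binarize` is exactly thresholding at 0.5 (the sigmoid is a monotone
  reparameterization); the boundary value selects.
* Empty validation/test splits, overlapping split indices, missing labels,
  non-numeric cells, and unknown config keys all fail fast with named
  errors; unknown config keys get a nearest-match suggestion.

## Problem sizes used by the bundled experiments

Sphere convergence: `d = 10`, `n = 30`, `t_m = 200`, 10 seeds. Oracle
equivalence: five 120×6 planted tables (2 informative, δ = 3), ASSOA
`n = 20`, `t_m = 50`, 10 seeds each, against full 2⁶−1 enumeration.
Feature recovery: one 500×30 planted table (4 informative, δ = 4), 10 ASSOA
runs at `n = 30`, `t_m = 100`. Classifier: 200×10 margin-1 separable
tables, ASSOA `n = 30`, `t_m = 100`, 10 seeds. Comparison: 10 paired runs
of 4 algorithms on 120×10 planted tables. Wilcoxon size: 2,000 null pairs
of 20 + 20 normals. These sizes make every experiment exact or
well-resolved while keeping the full suite in the tens of seconds.

## Known limitations

* The velocity matrix is vestigial under the zero-velocity reading; a
  principled momentum rule might improve the diagonal/vertical moves but
  would be an extension, not a reproduction.
* ASSOA's added moves help on combinatorial wrapper landscapes but slow
  deep convergence on smooth unimodal objectives relative to SS.
* The exact rank-sum enumerator is O(C(m+n, m)); above pooled size 20 the
  normal approximation is used unconditionally.
* No constraint handling beyond box clipping, no parallel evaluation, no
  gradient-based training anywhere.
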