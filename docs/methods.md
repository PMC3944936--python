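# Methods

## Problem and model

Expression matrices for tumour classification have far more genes than
samples; most genes are irrelevant to the class distinction and a small
subset of tissue- or tumour-specific markers carries the signal.  The
package implements wrapper feature selection: candidate gene subsets are
scored by the predictive accuracy of the very classifier that will use
them, so the search optimises exactly the quantity reported.

The searcher is a binary particle swarm.  Each particle's position is a
bit vector over the genes; its real-valued velocity follows the
global-best rule v ← w·v + c₁r₁(pbest − x) + c₂r₂(gbest − x) with fresh
per-dimension U(0,1) draws, clamped elementwise to [v_min, v_max], and
each bit is re-sampled as 1 iff σ(v) > U(0,1).  Because velocities decay
toward 0 wherever position, pbest and gbest agree, σ(v) → 0.5 and bits
keep exploring; the personal/global bests retain the progress, which is
why the best-fitness trace is non-decreasing by construction.

The classifier is a from-scratch C4.5 for continuous features only:
binary threshold tests `value ≤ t` with t at midpoints between
consecutive distinct sorted values, chosen to maximise gain ratio
(information gain over the entropy of the branch-size split) among
candidates with positive gain and both branches ≥ `min_samples_leaf`.
Multiway categorical splits, fractional missing-value handling and rule
generation are deliberately out of scope — expression features are
continuous and complete by contract.

## Parameters

| parameter | default | meaning |
|---|---|---|
| w | 0.4 | inertia weight; lower favours exploitation |
| c₁, c₂ | 2, 2 | cognitive / social acceleration |
| v_min, v_max | −4, 4 | velocity bounds; σ(±4) ≈ 0.018/0.982 caps per-bit certainty |
| T | 100 | iteration cap; early stop at fitness ≥ 1.0 |
| n_particles | max(2, n/100) | swarm size; benchmark practice ties it to gene count |
| init_one_prob | 0.5 | P(bit=1) at initialization (U(0,1) > 0.5 rule) |
| min_samples_leaf | 2 | smallest branch a split may create |
| pruning_confidence | 0.25 | binomial upper-bound confidence; smaller prunes more |
| k / inner k′ | 5 / 3 | outer evaluation folds / fitness folds (nested mode) |

The velocity update equation itself is the canonical Kennedy–Eberhart
global-best rule; the constants above are the values commonly used with
it for gene selection.  Velocities initialize to 0 (any bounded choice
works; 0 is reproducible), and r₁, r₂ and the bit draw are fresh
independent U(0,1) per dimension.

## Evaluation protocol

Fitness during search is *internal* stratified k′-fold CV accuracy on
the training portion only; the *outer* stratified k-fold supplies the
reported accuracy.  This nesting is the package's principal protocol
decision: running selection once on the full dataset and reporting its
CV fitness (the "naive" mode, kept behind a flag) overstates accuracy
because every sample has influenced the selection.  Both modes share all
other machinery, so their gap can be measured directly.

Per-fold work is seeded by SeedSequence(seed, fold), so a fold's
selection depends only on its own training rows and the run seed — the
property the leakage test asserts by deleting a fold's test samples and
reproducing its mask bit-for-bit.

An all-zero mask is given the training majority-class proportion as
fitness: degenerate particles are dominated by any informative subset
but do not crash the run.  The per-run "number of selected genes" is the
size of the union of the outer-fold masks; union is one of several
defensible conventions (per-fold mean, intersection) and is stated so
the reports are unambiguous.  Per-run summaries use the sample (n−1)
standard deviation; a single run reports std 0 with a degenerate flag.

Stratified fold assignment is implemented in-package: within each class
samples are shuffled and dealt so per-class per-fold counts differ by at
most one, with each class's remainder going to the currently smallest
folds so overall fold sizes also differ by at most one.  Both balance
guarantees together, plus exact determinism given the seed, are the
contract the harness and tests rely on.

## Numerical choices

- Entropies in bits (log base 2) throughout.
- Positive-gain gate implemented as gain > 1e-12: analytically zero
  gains compute to ~1e-16 in floating point and must not win a split.
- Split ties resolve by higher gain, then lower gene index, then lower
  threshold — fully deterministic, so fitness is reproducible across
  platforms.
- Leaf majority ties resolve by label order (sorted label set).
- Pessimistic pruning uses the exact binomial (Clopper–Pearson) upper
  confidence bound on the leaf error rate, N·BetaInv(1−CF; E+1, N−E);
  a subtree is replaced when the replacement leaf's bound does not
  exceed the summed bounds of its leaves.  The exact bound is
  conservative: subtrees that isolate a few training errors into small
  pure leaves generally survive, while near-parity uninformative splits
  collapse.  Pruning is off by default — it is irrelevant inside the
  fitness loop and only useful for final-model reporting.
- The sigmoid is computed piecewise (exp(−v) vs exp(v)) so it is stable
  for |v| up to at least 700.
- Floats are written with 17 significant digits and read back through
  numpy's parser, making file round-trips exact (pandas' fast float
  path is avoided deliberately).
- Fitness values are cached per mask within a fold; the fitness is a
  deterministic function of the mask given the fixed inner folds, so
  caching cannot change results, only skip repeated tree inductions.

## Synthetic data

The generator plants `n_informative` marker genes in an otherwise null
Gaussian matrix: every value is Normal(μ₀, σ) with μ₀ = 8 (a cosmetic
log2-intensity scale) and σ = 1; each marker is assigned one "up" class
(cycling through the classes so each gets markers) whose samples shift
by δ·σ, default δ = 3.  Class labels are exact largest-remainder counts
of the requested proportions, shuffled — guaranteeing every class is
populated for stratification even at small n.  Marker positions are
drawn at random, never a prefix block.

What this emulates: the low-sample/many-feature shape, class-conditional
mean shifts of tissue-specific markers, and a null background with
calibrated false-positive behaviour.  What it does not: probe-level
noise structure, batch effects, heteroscedasticity, gene–gene
correlation, or multi-class expression patterns per gene.  Passing tests
on this generator therefore demonstrate the machinery (search, nesting,
determinism, calibration), not performance on real microarray noise.

The benchmark configuration used by the validation experiments and the
acceptance script is 60 samples × 100 genes, 5 markers at δ = 3, two
balanced classes, a 20-particle swarm with T = 30, nested mode with
k = 5 / k′ = 3, 10 seeds — sizes chosen so the full battery runs in a
few minutes on one CPU while leaving the planted-recovery and null-
calibration effects far from their thresholds.

## Known limitations

- Accuracy-only fitness exerts no parsimony pressure: selected masks
  stay near half the gene count, so precision of marker recovery is low
  and redundant markers are not preferentially retained — with several
  markers per class, one suffices for a perfect tree, and the
  gene-frequency table separates markers from background only weakly at
  desk scale.  Recovery is therefore measured on the union mask.
- Greedy gain-ratio induction cannot split purely interacting features
  (XOR-like structure has zero marginal gain everywhere and yields a
  majority leaf); the synthetic model deliberately contains no such
  structure.
- The swarm-size default (≈ n/100) and the nested protocol are declared
  package conventions, not uniquely determined by prior practice; both
  are overridable (`n_particles`, `mode="naive"`).
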