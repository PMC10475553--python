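# Methods

## The problem

A fluorescence-optical-imaging (FOI) examination of both hands produces
three phase-summed images per patient (phases of the contrast-agent
dynamics). A reader annotates each phase image, per hand, with a subset of
20 one-letter image-feature acronyms. After fusing the two hands, each
patient is a vector of 60 binary indicators ("P2" = feature P seen in
phase 2) with one diagnosis label (RA, OA, or CTD). The question is which
small subset of indicators suffices for each pairwise and one-vs-rest
differential diagnosis, and in what order of importance.

The package implements the full two-step hybrid selection protocol over
these data and, because no reading data set is publicly deposited, a
synthetic cohort generator whose planted structure makes every stage
testable against ground truth.

## Preprocessing

Hand fusion takes the union of the two hands' annotations per phase (the
diagnosis is per patient, not per hand). Encoding yields the 60-column
binary matrix; featureless patients are dropped first, then all-zero
(never-observed) columns. The three-class label is decomposed into three
One-vs-One and three One-vs-Rest binary problems; within each problem,
columns constant across its observations carry no information and are
excluded (recorded on the problem spec).

The 90/10 train/holdout split is stratified by diagnosis and — by default
— performed once on the three-class table before problem construction, so
all six problems share the same holdout patients and a patient can never
be a training case in one problem and a test case in another. Both
choices go beyond the protocol's bare "split randomly"; stratification
guarantees both classes in a 10% holdout at these cohort sizes, and the
shared split matches the requirement that the holdout be retained from
*all* analysis steps. A per-problem split is available as a config switch
(`shared_split=False`). Problem-specific constant-column exclusion is
computed on training rows only, so the holdout cannot influence feature
handling.

Class imbalance is handled by random minority oversampling: minority rows
are duplicated uniformly at random with replacement until the classes
balance. Inside cross-validation this is applied to each *training fold
only*, never to validation folds — duplicating before the fold split
would place copies of a training row into validation and inflate AUC. The
label-permutation null test is the canary for this: with oversampling
correctly placed, CV AUC on permuted labels sits at 0.5.

## Step 1 — four importance metrics and candidate lists

* **Phi-coefficient**: Pearson correlation of two binary 0/1 variables,
  computed from the 2×2 contingency table,
  r_φ = (n₁₁n₀₀ − n₁₀n₀₁)/√(n₁·n₀·n·₁n·₀), tested two-sided via
  t = r√((n−2)/(1−r²)) with n−2 df. Features qualify at p < 0.05 and are
  ranked by |r_φ| — the sign encodes direction (which class the feature
  points to), not information content.
* **MultiSURF** relief weights: every instance is a target; instance j is
  a near neighbour of target i when d(i,j) < T_i − D_i, where d is the
  Hamming fraction, T_i the mean distance of i to all other instances and
  D_i half the (population) standard deviation of those distances.
  Feature-value differences among near misses raise a feature's weight,
  among near hits lower it; contributions are normalized per target by
  the near-hit and near-miss counts, then by n. Qualification: W > 0.
  The strict `<` at the dead-band boundary and the population-SD
  convention are recorded in the output (`neighbor_definition`) because
  the algorithm family leaves them open. Targets with no near neighbour
  contribute nothing (counted as `n_isolated`); identical instances
  therefore yield all-zero weights, and constant features always have
  weight exactly 0.
* **MDI** (mean decrease impurity): Gini importance of the
  gradient-boosted tree ensemble, averaged over the CV-trained models.
  Qualification: I_I > 0.
* **MDA** (permutation importance): baseline validation AUC minus the
  mean AUC after permuting one feature column within the validation fold
  (default 10 permutations; 3 in the reduced desk settings), averaged
  over CV models. Qualification: mean I_A > 0 (a feature may be negative
  on individual splits).

The embedded metrics come from an all-features GBM trained under the
step-1 CV (3-fold × 10-repeat = 30 models at protocol scale), with
hyperparameters grid-searched on the same splits.

## Step 2 — multi-list sequential forward selection

At each step the best-ranked not-yet-selected feature of each of the four
lists supplies at most four distinct candidates. Each candidate is
evaluated by repeated-CV AUC of a GBM on the selected set plus the
candidate (protocol scale: 5-fold × 20-repeat = 100 models); the best
mean wins and is added; losers stay eligible. The loop deliberately runs
until the union of the candidate lists is exhausted rather than stopping
at the first plateau, so late interaction effects are not cut off. Ties
within 1e−9 go to the candidate from the earlier list in the fixed order
(phi, MultiSURF, MDI, MDA), then to the lexicographically smaller name —
an arbitrary but deterministic rule. After each step a final model is
fitted on the full (oversampled) training data and scored on the holdout.

**Transition point**: the smallest step m such that (a) no later step's
mean CV AUC exceeds AUC_m + 0.01 and (b) the immediately succeeding
step's mean is ≤ AUC_m (vacuous at the last step). Condition (b) is
taken as non-strict "not better"; the strict reading would shift some
plateaus by one step. Since one feature is added per step, the step index
equals the feature count.

Hyperparameter tuning during selection defaults to "tune once per
problem on the all-features model, reuse at every step"; per-step
re-tuning is available (`retune_each_step`) but multiplies cost by the
grid size and the protocol does not state which was used.

## Gradient-boosting engine

sklearn's `GradientBoostingClassifier` (Gini impurity; the protocol does
not name a criterion). The default tuning grid is a documented
convention — trees {50, 100, 200} × depth {2, 3, 4} × learning rate
{0.1, 0.3} — and the default fixed setting is 100 trees, depth 3, rate
0.1. AUC is the rank-based (Mann–Whitney) statistic with ties counted ½.

## Synthetic cohorts

The generator emulates the statistical shape the pipeline assumes, not
FOI images or contrast kinetics:

* per-hand, per-phase annotation rows, with each annotated feature placed
  on the left, right, or both hands with equal probability, so hand
  fusion is a real union;
* a `study_like` default with cohort sizes 237/231/141, the 15
  never-observed indicators, 4/609 featureless patients, background
  prevalence 0.1, inter-phase correlation 0.7 on acronyms D and P,
  moderate planted effects on Y1, P2/P3, M3, C3 and one I1×V2
  interaction. Effect strengths are conventions (single-feature AUC
  ≈ 0.6–0.7); the study reports no per-class feature prevalences.
* **Planted univariate effects**: per-class Bernoulli prevalences; the
  analytic single-feature AUC p(1−q) + ½(pq + (1−p)(1−q)) gives
  parameter-recovery tests an exact target.
* **Planted interactions**: 2- or 3-way XOR parity with balanced
  marginals — each involved indicator is Bernoulli(0.5) in every class
  (univariate phi expectation 0) while the parity is class-informative.
  This is the canonical structure a relief algorithm can see and a
  univariate filter cannot.
* **Inter-phase correlation** by copy-with-noise: phase k+1 copies phase
  k with probability ρ and otherwise redraws from its own law. When
  consecutive phases share a law this preserves marginals and yields
  phi = ρ exactly (a plain XOR-flip mechanism would distort marginals
  away from p = 0.5); phases with differing laws are drawn
  independently, so planted phase-specific effects are never diluted.
* **Featureless patients** are a seeded quota of round(rate·n) patients,
  and all other patients are guaranteed at least one annotation
  (rejection sampling), so the cohort shape — 609 → 605 after filtering —
  is deterministic rather than merely expected.

What the generator does *not* emulate: reader disagreement and intra-
reader drift, correlated feature co-occurrence beyond the planted
structure, ordinal severity underlying the binary readings, and any
image-level physics. Passing recovery tests therefore show that the
pipeline finds structure of the planted kinds at study-like sample
sizes — not that the clinical readings contain such structure.

## Problem sizes used in the desk runs

The analysis scripts, tests, and the acceptance script run the protocol
at reduced CV (3-fold × 3-repeat), with small fixed GBMs where only
mechanics are under test and the package default GBM where learner
quality matters (parameter recovery, end-to-end runs). Recovery
experiments use n = 400 (two classes of 200), three planted effects with
analytic AUC 0.8, and 20 noise indicators at prevalence 0.3 — chosen as
a realistic moderate-signal regime. Full-protocol settings (10×3, 5×20,
18-point grid) remain the library defaults.

## Numerical choices and degenerate inputs

* phi is clipped to [−1, 1] against rounding; |r| = 1 maps to p = 0;
  constant vectors raise a dedicated error that candidate-list
  construction treats as "not a candidate".
* VIF uses least squares with intercept; R² ≥ 1 − 1e−12 is reported as
  +inf and flagged rather than a huge finite number.
* All randomness flows from one root seed through named substreams
  (synthesis, split, tuning, step1, step2, final), so any stage can be
  reproduced in isolation; reruns are bit-identical and manifests record
  a config hash that excludes the output path.
* Grid-search ties keep the earlier grid point; CV folds are shared
  across grid points and candidates within a call, so comparisons are
  paired.

## Known limitations

* The greedy one-feature-at-a-time wrapper can add pure-interaction
  features later than their joint informativeness warrants; the tests
  assert only the weaker property that planted XOR features are selected
  before noise when MultiSURF ranks them first.
* The transition rule is sensitive to plateau noise at small CV sizes:
  each step's recorded mean is a maximum over up to four noisy candidate
  means, which biases plateaus slightly upward and can defer the
  transition by a few steps when the learner underfits. The protocol's
  larger step-2 CV (100 models) exists precisely to damp this.
* MDI inherits the known redundancy-splitting behaviour: perfectly
  correlated features share the importance a single copy would get.
* One primary diagnosis per patient; no multi-label support, no per-hand
  analysis, no relief variants for continuous features.
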