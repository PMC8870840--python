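# Methods

## Model and procedure

The pipeline classifies labelled tabular data by (1) learning an
unsupervised representation with a restricted Boltzmann machine, (2)
ranking the hidden neurons by how well their activations separate the
classes, (3) deleting the lowest-ranked neurons without retraining, and
(4) scoring the pruned representation with a k-NN classifier under
repeated stratified cross-validation.

### RBM

Gaussian visible units, Bernoulli hidden units, energy

    E(v, h) = Σ_i (v_i − a_i)²/(2σ_i²) − Σ_ij (v_i/σ_i²) h_j w_ij − b·h.

Assumptions and choices:

* **σ_i ≡ 1, not learned.** Inputs are min-max scaled to [0, 1], where a
  unit visible variance is the conventional setting; σ is configurable
  on the model object.
* **CD-k, k = 1 by default.** Positive phase: hidden states sampled from
  p(h|v) at the data. Negative phase: k alternating Gibbs steps using
  hidden *samples* and visible conditional *means* — visible noise is
  never injected, a standard variance-reduction choice; the final
  negative statistics use the hidden probabilities.
* **Visible biases start at the training column means**, which removes
  the first-epoch drift toward the data centroid.
* **Features are hidden probabilities, not samples**, so the
  representation is deterministic given the trained model.
* Defaults: learning rate 0.01, 100 epochs, batch 32, weight init
  N(0, 0.01²). These are conventional small-data CD settings; nothing in
  the pipeline is sensitive to them at the scales tested, and all are
  exposed on `TrainConfig`.

A validity check ties the conditional to the joint: for d=1, h=2 the
hidden conditional computed by discretizing exp(−E)/Z on a fine visible
grid matches `hidden_probs` to machine precision.

### Discriminative measures

Eight scores, all oriented so larger = more class-discriminative:
Fisher score Σ_j n_j(μ_ij−μ_i)² / Σ_j n_j·var_ij; absolute Pearson
correlation with the class indicator (mean over one-vs-rest indicators
for >2 classes — symmetric in the classes, bounded, and equal to |r| in
the binary case); one-way ANOVA F (the statistic, not its p-value; the
two order identically at fixed degrees of freedom); information gain,
gain ratio and symmetric uncertainty in bits on the discretized column;
ReliefF (k=10 nearest hits/misses capped at class size − 1, all
instances sampled, Manhattan distance on range-normalized columns,
miss terms weighted by P(C)/(1−P(class))); and One-R, scored as one
minus the cumulative error of the per-bin majority rule.

Numerical conventions:

* **Discretization**: 10 equal-width bins over [0, 1] (activations are
  probabilities); the upper edge is closed; the bin count is an argument.
* **Conditional entropy** uses the standard non-negative form
  H(X|Y) = −Σ p(x,y) log₂ p(x|y).
* **Fisher denominator** uses the class variance once (Σ n_j·var_ij,
  population variances), the standard form of the score.
* **Undefined scores** (constant column, zero entropy) fall back to the
  measure's null value 0 with a warning, keeping rankings total; a
  column that separates classes perfectly with zero within-class spread
  gets a large sentinel (1e12) for the ratio-based scores instead, since
  the ratio is formally infinite.
* **Ties**: bin-majority ties in One-R break toward the lowest class
  code; equal neuron scores rank by ascending neuron index.

### Pruning and evaluation

Ranking happens on *training-fold* activations only. Pruning keeps the
top-ranked columns in their original order; retaining all h columns is
bit-identical to the unpruned baseline, and no retraining ever follows a
prune. One RBM is trained per fold at the full hidden size and all
retained counts are evaluated against that single model, which isolates
the ranking's effect from training noise.

k-NN: k = 5 and the Euclidean metric by default (Chebyshev and Manhattan
selectable). Determinism is enforced everywhere the voting rule is
silent: neighbour ties at the k boundary break by ascending training
index, vote ties by the smallest summed distance and then the lowest
class code.

The sweep aggregates fold errors into one error per repetition and
retained count, then reports the mean and the 95% normal-approximation
halfwidth 1.96·s/√n over repetitions (s = sample SD). Note that this
z-based interval undercovers for small repetition counts — at n = 10 its
exact coverage is P(|T₉| ≤ 1.96) ≈ 91.8%, not 95% — which is a property
of the interval definition itself; a t critical value would be needed
for nominal coverage.

The experiment grid mirrors the study protocol: hidden sizes
⌈m·d⌉ for m ∈ {0.5, 1, 2, 4, 6, 8, 16, 32}, 10 repetitions × 10-fold
stratified CV (both configurable). The retained-count axis is every
integer up to h = 40 and 20 evenly spaced counts (always including 1 and
h) above that.

## Preprocessing

Per training fold, never on held-out rows: missing values imputed by
column kind (numeric → mean, nominal → mode with ties to the smallest
code, ordinal → lower median, so the fill stays on an observed code);
redundant columns removed, operationalized as zero-variance columns plus
exact duplicates (keeping the lowest index); every retained column —
including integer codes — min-max scaled to [0, 1] with out-of-range
test values clipped, because the RBM's visible domain is [0, 1] and
codes are used directly (no one-hot expansion). Class balancing is
random minority oversampling with replacement to the majority count,
applied to training folds only. Application of a fitted preprocessing
model is idempotent (a fingerprint on the transformed dataset guards
against double scaling).

Stratified splitting deals each class's shuffled members cyclically
across a shuffled fold order with the deal pointer carried between
classes: overall fold sizes stay within one row and each class's
per-fold counts within one of proportionality; classes smaller than the
fold count simply land in distinct folds.

## Synthetic data

The generator emulates the statistical shape of small clinical tables:
class priors down to singleton classes, mixed column kinds, missing
completely at random, and appended duplicate/constant columns. Signal is
planted explicitly: informative numeric columns get equally spaced
class means c·effect_size with unit within-class SD (Fisher/ANOVA have
closed-form expectations there); informative nominal columns get
per-class Dirichlet-perturbed category distributions scaled by the
effect size (a discrete signal for the entropy measures); ordinal
columns discretize the shifted latent at its empirical quantiles.
Missing entries never hit the label column.

The three named profiles reproduce the benchmark shapes exactly
(instances, features, class distributions); their signal structure —
about half the columns informative, effect size 2.0 for the two binary
profiles and 1.0 for the 21-class profile, missingness 1%/10%/4% — is
this package's choice of a realistic emulation. Effect size 2 puts the
binary Bayes error near Φ(−1) ≈ 16% per informative column, a
moderately-hard regime comparable to the benchmarks' reported error
ranges.

What the generator does **not** emulate: feature correlations within a
class, informative missingness, ordinal monotone risk gradients, or any
actual clinical semantics. Passing tests therefore demonstrate that the
pipeline recovers planted statistical signal under realistic shapes and
noise — not performance on the original hospital data.

Problem sizes in the test suite are chosen for a desk-scale run: ranking
recovery uses n=500, d=20 over 20 seeds; the pruning-vs-anti-pruning
experiment runs the full pipeline on the 286×9 profile with 18 hidden
units over 20 master seeds; the full 8-multiplier grid is exercised on a
60×4 table.

## Known limitations

* Binary-visible RBMs, persistent CD, momentum/weight decay, DBNs and
  alternative classifiers are out of scope by design.
* "Redundancy removal" means zero-variance plus exact duplicates;
  near-duplicate or correlated-feature filtering is not attempted.
* ReliefF follows the common multi-class formulation documented above;
  no attempt is made to reproduce any particular historical variant.
* The z-based confidence interval is reported as defined; see the
  coverage caveat above.
* With very small minority classes (singletons), stratification and
  ReliefF hit their documented degenerate-case contracts (unstratified
  assignment; miss-only contributions with a warning).
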