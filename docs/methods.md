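# Methods

## Problem setting

Resting-state functional connectivity (RSFC) classifiers trained on pooled
multi-site cohorts generalize poorly to scanners they have never seen:
vendor, pulse-sequence and cohort differences shift the joint distribution
of connectivity features site by site.  Leave-one-site-out cross-validation
(LOSO-CV) makes this failure measurable — each acquisition site is held out
in turn as the test set — and *harmonization* is any strategy that closes
the gap.

This package implements a two-phase contrastive strategy for that setting:
labeled-pair invariant information clustering (a mutual-information
contrastive objective with an overclustering head) followed by
frozen-trunk transfer learning, plus the complete LOSO-CV evaluation
harness and a controllable multi-site simulator.

## Feature extraction

Each subject contributes a `T x R` matrix of ROI-averaged BOLD time
series.  Features are the classical RSFC vector:

1. Pearson correlation matrix (`R x R`);
2. Fisher z-transform `z = atanh(r)`, with `|r|` clipped to `1 - 1e-7`
   so degenerate correlations stay finite (the diagonal never enters);
3. strictly-lower-triangular vectorization in row-major `(i, j < i)` order,
   giving `R(R-1)/2` features — 5,995 for a 110-region parcellation,
   190 for the 20-region benchmarks.

Per-ROI temporal standardization before the correlation is immaterial
(Pearson r is affine-invariant) and is not performed.  Subjects with any
non-finite connectivity value (e.g. a flat ROI signal) are screened out
with a logged reason; a site whose surviving count falls below
`min_site_size = 2` can no longer serve as a held-out test site but its
subjects remain available for modeling.  Feature standardization (mean/sd
per feature) is always fitted on training data only; features constant in
the training set are mapped to 0 rather than dividing by zero.

## Network

A shared trunk of four blocks, each fully-connected layer -> batch
normalization -> ReLU, with three linear + softmax heads:

* `iic` — two-class contrastive head;
* `iic_oc` — overclustering head with `c_oc = 10` classes (the class count
  is a free choice; more clusters than classes absorb noise and latent
  subtypes);
* `classifier` — two-class supervised head used in the transfer phase.

Default widths are `(1024, 512, 256, 128)` for 5,995-dimensional input and
`(32, 32, 16, 16)` for the 190-dimensional benchmarks.  Initialization is
He-normal in the trunk and `sqrt(1/fan_in)`-normal in the heads, seeded and
bit-reproducible.  Batch normalization uses eps `1e-5`, momentum `0.1`,
biased batch variance, and requires batches of at least two rows in
training mode (enforced explicitly).  Everything, including backprop and
the Adam optimizer, is implemented directly in numpy: at these layer widths
dense matrix products are all that is required, and the explicit backward
pass is verified against finite differences in the test suite.

## Losses

For a batch of `n` pairs with softmax outputs `Phi(x_i)`, `Phi(x_i')` of
width `C`, the empirical joint class assignment is

    P = (1/n) * sum_i Phi(x_i) Phi(x_i')^T,

symmetrized as `(P + P^T)/2` (pair order is exchangeable; symmetrization
is exposed as a flag).  With row/column marginals `P_c`, `P_c'` the
entropy-weighted mutual information is

    I_lambda(z, z') = sum_{c,c'} P_cc' ln[ P_cc' / (P_c^lambda P_c'^lambda) ]
                    = I_1(z, z') + (lambda - 1) * (H(z) + H(z')),

with `lambda = 5.0` by default; the weighted marginal-entropy terms
penalize collapsing all inputs into one cluster.  The training loss is
`-I_lambda / ln C`, normalized per head by that head's own class count so
the two heads' losses are commensurate before summation.  Its ideal
two-class value is `-(2*lambda - 1) = -9`; a balanced but uninformative
assignment scores `-8`; independence with `lambda = 1` scores 0.  An
eps of `1e-12` inside every logarithm guards empty cells.

Pair construction replaces data augmentation: pairs with the *same*
diagnosis label contribute the IIC loss at both heads; pairs with
*different* labels contribute the IIC loss at the two-class head with the
second output complemented (`1 - Phi`, which for two classes is again a
distribution and represents the opposite class).  The complement trick
does not extend beyond two classes, so different-label pairs do not touch
the overclustering head.  The transfer phase minimizes the cross-entropy
`-ln(Phi(x)[y])` of the classifier head.

## Training protocol

**Phase 1 (contrastive prior learning).**  The pair pool is every
unordered subject pair of the training fold, reshuffled each epoch;
mini-batches of `batch_size` pairs (default 500) are drawn until a full
batch can no longer be extracted, the partial remainder being discarded —
that failure defines the epoch boundary, and one weight update per batch
is one iteration (iterations per epoch = `floor(pool / batch)` exactly).
Mini-batches count *pairs*, not subjects: pair pools are the only
population for which batch sizes in the thousands are meaningful at
cohort sizes of ~1,100.  Both pair members pass through the trunk in one
concatenated forward so batch-norm statistics are shared.  After each
epoch the summed pair loss is evaluated (in inference mode) on a fixed,
seeded validation pair set — fixed so the early-stopping criterion is
comparable across epochs, capped at 2,000 pairs — and training stops when
it has not strictly improved for `patience` epochs (default 10) or at
`max_epochs`; the parameters of the best validation epoch are restored.

**Phase 2 (transfer learning).**  `freeze_trunk` marks everything except
the classifier head's linear map non-trainable and freezes the batch-norm
running statistics.  The classifier head is then fitted by mean
cross-entropy over subject mini-batches with the same early-stopping rule
applied to validation cross-entropy (the only loss present in this phase).
A supervised-only ablation (`train_supervised`) trains all parameters of
the same architecture with cross-entropy and no freeze, as the natural
no-prior baseline — freezing a randomly initialized trunk would make the
comparison a straw man.

Adam is used throughout.  The full-scale default learning rate is `1e-4`;
the scaled-down benchmarks use `3e-2` (see *Optimization notes*).

## LOSO-CV protocol

For each eligible held-out site, the remaining subjects are split into
five folds stratified by (site x class) cell: members of each cell are
shuffled and dealt round-robin with the starting fold rotating across
cells, so every fold's site and class composition tracks the overall
proportions (fold class ratios are tested to within +-10 percentage
points).  Each fold serves once as the validation set, yielding five
models, each with its own standardizer fitted on its own four training
folds.  At test time each model standardizes the held-out subjects with
its own statistics; the five classifier outputs are averaged (the mean of
distributions is a distribution) and the mean class-1 score is rounded to
the label, a tie at exactly 0.5 going to class 1 (documented convention).
Per-site accuracy is tested against the 50% chance level with an exact
two-sided binomial test (the conservative choice of sidedness) at
significance 0.01.  Subject leakage between test and modeling sets is
asserted on every split.  One global seed fans out through
`numpy.random.SeedSequence` to per-site, per-fold and per-epoch streams,
making the whole report bit-reproducible.

## Synthetic multi-site generator

The simulator emulates the statistical structure a harmonization method
must overcome, on axes mirroring real multi-site heterogeneity:

* a shared base correlation matrix (random three-factor structure with
  moderate correlations);
* a class effect: `effect_size` (default 0.6) added on the Fisher-z scale
  to a fixed random subset of `effect_edges` (default 20%) of the edges
  for class-1 subjects;
* site effects: an additive z-scale mean shift on **all** edges (scanner
  bias), a per-site AR(1) coefficient for temporal autocorrelation (a
  proxy for repetition-time differences), and additive white measurement
  noise with standard deviation `noise_scale` (default 0.3), which
  attenuates observed correlations the way scanner noise does;
* per-site sample size, length of the series and class prevalence.

Shifts are applied on the z scale and back-transformed through `tanh`, so
correlations stay bounded; the resulting matrix is projected to the
nearest positive-definite correlation matrix by eigenvalue clipping at
`1e-6`.  Time series are drawn from the stationary AR(1) process whose
instantaneous covariance equals the target matrix, so long simulations
converge to their targets (verified at 5,000 time points without
observation noise, which by design attenuates sample correlations).

What the generator does **not** model: subject-level heterogeneity of the
class effect (all class-1 subjects share the same target shift; subject
variation comes only from finite-sample correlation noise), nonlinear or
edge-heterogeneous site effects, age or cohort composition, motion
artifacts, and global-signal structure.  Passing benchmarks therefore
demonstrate that the pipeline machinery works and recovers a linear
connectivity effect across sites at realistic noise levels — not that it
would reproduce accuracy levels on real cohort data.

### Benchmark study designs

* **Signal benchmark** — 4 sites x 50 subjects, 20 ROIs, 150 time points,
  identical scanner profiles, class effect 0.6 on 20% of edges, balanced
  classes.  Measures cross-site recovery of a clean effect; a
  permuted-label variant (five replicates at a shortened 25-epoch
  training cap, since there is nothing to converge to under the null)
  checks that accuracy sits at chance and sites are essentially never
  flagged significant.
* **Confounded benchmark** — 4 sites x 30 subjects, 100 time points,
  class effect 0.5, plus site mean shifts of +-0.2 whose sign is
  associated with 3:1 class prevalence, arranged so each held-out site's
  shift-label association is opposite to the one in its training sites.
  Used to compare the two-phase pipeline against the supervised-only
  ablation over five replicates.

Benchmark training settings: batch 500 pairs, learning rate `3e-2`,
patience 8, at most 80 epochs, transfer batches of 32 subjects.  These
sizes keep a full LOSO campaign to minutes on one CPU while leaving the
protocol itself (five folds, two phases, ensembling) at full scale.

## Optimization notes

The pair-MI objective has a plateau at the balanced-but-uninformative
assignment (loss -8 per two-class head at `lambda = 5`): every input is
assigned half-and-half, marginals are maximally entropic, and the
mutual-information gradient is second-order small.  Escaping it requires
either many iterations or aggressive steps; at the benchmark scale Adam
with learning rate `3e-2` leaves the plateau within a few epochs on the
clean-signal design, while `1e-3` can sit on it indefinitely.  The
validation-loss early stopping distinguishes the outcomes clearly
(converged runs reach about -26 of the ideal -27 total; plateaued runs
stay near -24).

A finding worth recording, established with the confounded generator: a
site-wide mean shift that is *strongly* label-associated is not merely a
nuisance for the contrastive phase — it is a competing local optimum of
the pair objective.  Same-label pairs then tend to share shift sign (via
the prevalence association), so clustering by site signature also earns
mutual information, and because the shift is coherent across all edges
its variance can dominate the class effect.  In that regime the prior
phase converges to the site clustering and transfers it, performing below
chance on held-out sites, while plain supervised training — for which the
class signal predicts training labels strictly better than the shift —
remains accurate.  Contrastive pairing protects against site structure
only while the class effect dominates the pair-space geometry.  At the
moderate confound strength of the shipped benchmark both arms classify
held-out sites near ceiling and the comparison is essentially tied; the
package reports the measured gap rather than asserting a direction.

## Numerical conventions

* Fisher z clip `1e-7`; log eps `1e-12`; joint symmetrization on by default.
* Constant features standardize to 0; sd uses the biased estimator.
* Ensemble tie at mean score 0.5 predicts class 1.
* Batch norm: eps `1e-5`, momentum `0.1`, training mode requires n >= 2,
  frozen trunks always use running statistics.
* Positive-definite projection floor `1e-6`; projected matrices are
  rescaled to unit diagonal.
* Partial final pair mini-batches are discarded; a batch size exceeding
  the whole pool raises a configuration warning (zero iterations/epoch).
* Early stopping uses strict improvement; ties count against patience.

## Known limitations

* The harmonization benefit of labeled-pair contrastive learning is
  regime-dependent (see *Optimization notes*); the package makes the
  comparison measurable rather than guaranteeing a direction.
* Plateau escape in the prior phase is stochastic at small sample sizes;
  benchmark seeds and sizes were chosen so it is reliable, but very small
  cohorts (under ~100 modeling subjects) may leave the trunk untrained,
  in which case the transfer phase degenerates to a random-feature probe.
* The simulator's site effects are linear and edge-homogeneous; methods
  that exploit nonlinear site structure are outside what it can measure.
* ROI time series are assumed pre-extracted; no volumetric I/O is
  provided.
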