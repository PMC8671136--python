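# eiic — contrastive harmonization for multi-site functional connectivity

Classifiers trained on pooled multi-site resting-state fMRI data tend to
collapse when evaluated on a scanner site they have never seen: vendor,
sequence and cohort differences shift the distribution of connectivity
features site by site.  `eiic` implements a two-phase contrastive
learning pipeline for exactly that setting, together with the
leave-one-site-out cross-validation (LOSO-CV) harness needed to measure
it, and a controllable multi-site simulator to exercise the whole stack.

It is aimed at researchers working on site harmonization and
generalization in functional-connectivity classification (e.g. ABIDE-style
autism vs control cohorts) who want a transparent, dependency-light
reference implementation they can probe and extend.

## The method

Subjects enter as ROI-averaged BOLD time series.  Features are the
classical RSFC vector: Pearson correlation matrix, Fisher z-transform,
strictly-lower-triangular vectorization — `R(R-1)/2` values per subject
(5,995 for a 110-region parcellation).

The model is a shared trunk of four FC + BatchNorm + ReLU blocks with
three softmax heads, trained in two phases:

**1. Labeled-pair contrastive prior learning.**  For a batch of subject
pairs with outputs Φ(x), Φ(x′), the empirical joint class assignment
P = (1/n) Σ Φ(xᵢ)Φ(xᵢ′)ᵀ has entropy-weighted mutual information

```
I_λ(z, z′) = Σ_cc′ P_cc′ ln [ P_cc′ / (P_c^λ P_c′^λ) ]
           = I₁(z, z′) + (λ − 1)(H(z) + H(z′)),      λ = 5
```

and the loss is −I_λ / ln C per head.  Pairs with the same diagnosis
label feed both the 2-class head and a 10-class overclustering head;
pairs with different labels feed the 2-class head with the second output
complemented (1 − Φ is the opposite-class distribution).  Labeled pairing
plays the role data augmentation plays in classical contrastive learning.

**2. Frozen-trunk transfer learning.**  All weights except the classifier
head's final linear map are frozen (batch-norm statistics included) and
the head is fitted by cross-entropy — a linear probe on the contrastive
representation.  Both phases use Adam, pair/subject mini-batches, and
early stopping on a validation loss with best-epoch restoration.

Evaluation is LOSO-CV: each site is held out in turn; the remaining
subjects are split into five site-and-class-stratified folds; each fold
validates one model; the five models' outputs are averaged and rounded to
the predicted label.  Per-site accuracy gets an exact two-sided binomial
test against the 50% chance level.

## Worked example

`examples/03_loso_benchmark.py` simulates the clean-signal benchmark —
four sites × 50 subjects, 20 ROIs, a class effect of +0.6 on the Fisher-z
scale over 20% of the edges, identical scanner profiles — and runs the
full pipeline for every held-out site (about a minute on one CPU):

```
$ python examples/03_loso_benchmark.py
  site  n  n_correct  accuracy      p_value  significant_0.01
SITE_A 50         50       1.0 1.776357e-15              True
SITE_B 50         50       1.0 1.776357e-15              True
SITE_C 50         50       1.0 1.776357e-15              True
SITE_D 50         50       1.0 1.776357e-15              True
```

Each row is one held-out site: with a clean effect and no site
differences, the ensemble classifies every unseen site perfectly and the
binomial test rejects chance at p < 0.01 everywhere.  Under permuted
labels the same pipeline sits at chance (mean accuracy ≈ 0.48–0.50) and
flags essentially no site.  The other examples cover feature extraction
(`01`), the loss landscape in closed form (`02`), and the confounded-site
comparison against a supervised-only ablation (`04`).

A thin CLI wraps the same library calls:

```
eiic simulate --config design.yaml --out data/
eiic extract  --timeseries-dir data/ --phenotype data/phenotype.csv --out features.csv
eiic loso     --features features.csv --out report.csv --seed 1 [--ablation no-prior]
```

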