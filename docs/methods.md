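# Methods

## Problem and model

`milrad` classifies a *subject* (patient) as lung cancer / not lung cancer
from the set of lung nodules found in their chest CT, where each nodule is
summarized by a 103-dimensional radiomics vector (13 shape, 17 first-order,
73 texture features). Only the subject-level diagnosis is used as a label;
individual nodules are unlabeled. This is a multiple instance learning
(MIL) problem under the standard assumption: a subject is positive iff at
least one of their nodules is malignant.

The classifier is an attention-based deep MIL network. Each instance
x_k (one nodule) is mapped by a transformation network — two fully
connected ReLU layers, 103 → 64 → 32, with dropout 0.5 — to an embedding
h_k. The bag embedding is an attention-weighted average

    z = Σ_k a_k h_k,   a_k = softmax_k( wᵀ tanh(V h_k) ),

and a final fully connected layer with a sigmoid produces the bag
probability p = σ(uᵀz + b). The attention weights a_k are non-negative,
sum to one, and act as per-nodule importance scores; this is what makes the
recommendation inspectable by a radiologist. A gated attention variant
(tanh·sigmoid) is available but off by default. Two baselines replace the
pooling: uniform mean pooling (naive MIL) and element-wise max pooling over
embeddings (an MI-Net-style embedding-level model).

The forward and backward passes are implemented directly in numpy; the
hand-derived gradients are validated against central finite differences at
1e-4 in the test suite on a small configuration.

### Hidden sizes

The transformation layer widths and the attention dimension are
configuration, not fixed constants; the defaults (64, 32, attention 16,
ReLU) are reasonable for a 103-feature input and ~100-subject datasets but
were chosen by us and are documented as such.

## Fixed-size bags by balanced duplication

The network takes a fixed max_bag_size × 103 matrix per subject
(max_bag_size = 12 in the emulated study data). Smaller bags are padded by
duplicating their own nodules as evenly as possible: with n nodules,
q = 12 // n and r = 12 mod n, exactly r nodules (chosen uniformly at
random) appear q+1 times and the rest q times — a 5-nodule bag becomes
three nodules ×2 and two nodules ×3. Padding is applied identically at
training and prediction time; slot order is randomized except for
already-full bags, which pass through unchanged. Duplication is fixed once
per materialization, not re-randomized each epoch. Per-nodule attention is
recovered by summing a nodule's slot weights, so the reported alphas still
sum to one per subject.

## Class-imbalance correction by bag simulation

Screening cohorts are imbalanced toward positives (the emulated study data
is 75% cancer / 25% not). Because every nodule of a non-cancer subject is
by definition non-cancerous, new negative subjects can be *simulated* by
drawing nodules from the pooled instances of the real negative training
subjects. Choices this package fixes, where the procedure is genuinely open:

- bag sizes for synthetic negatives are drawn uniformly from the multiset
  of real negative-bag sizes in the training split (preserves the empirical
  size distribution); a uniform 1..12 sampler is available;
- nodules are sampled *without* replacement within a bag (a synthetic
  subject never contains the same physical nodule twice — duplication is
  the padding step's job) and with replacement across bags;
- synthetic bags are regenerated per CV training split from that split's
  negatives only, and never enter a test split (asserted at run time).

The default adds 60 synthetic negatives to an 88-subject training split
(148 training bags). The mirror-image positive augmentation (a real
positive bag plus pooled instances) is implemented but disabled by default.

## Training and evaluation protocol

SGD with batch size 1 (one bag per gradient step), learning rate 1e-4, 500
epochs, no momentum, weight decay, schedule or early stopping; the loss is
the Bernoulli negative log-likelihood of the bag probability. Features are
z-scored per feature with moments fit on the real training instances only
(zero-variance features map to 0); leakage-free standardization is our
choice — raw radiomics scales span orders of magnitude and neural networks
train poorly on them.

Evaluation is 20 repetitions of 5-fold cross-validation: per repetition the
subjects are reshuffled and partitioned so each subject is tested exactly
once. Confusion counts are pooled over the five folds of a repetition
(per-fold counts are retained in the report for audit), and recall,
accuracy, PPV, NPV and AUC are computed per repetition; aggregation is mean
± SEM over the repetition values, with SEM = sd/√n over repetitions, the
replication unit. 0/0 metrics are flagged undefined (NaN) and excluded
from aggregation with a warning, never coerced to 0. AUC uses the
Mann–Whitney rank formulation with half credit for ties (verified against
an O(n²) pairwise oracle and scikit-learn). Dichotomization uses threshold
0.5, ties classified positive. Methods compared on identical splits are
tested with a two-sided paired Wilcoxon signed-rank test on per-repetition
values (Pratt zero handling; identical reports give p = 1). Per-fold
training seeds depend on the fold index only, so disabling shuffling makes
repetitions exact replicas; with shuffling, repetition-to-repetition
variability comes from the resplits, as intended.

## Synthetic data

The generator emulates the structure the method assumes, not real CT
radiomics. Background nodules are i.i.d. standard Gaussian vectors
(optionally with equicorrelated feature blocks to mimic radiomics
collinearity); signal nodules are shifted by `effect_size` standard
deviations on `signal_features` randomly chosen features; a subject is
positive iff it contains ≥1 signal nodule (enforced), with the number of
signal nodules binomial at rate `witness_rate` (≥1). Bag sizes follow a
geometric distribution truncated to 1..12 (mean ≈ 2.8 nodules/subject,
matching screening data); `simulate_lidc_like` pins the study marginals
exactly — 110 subjects, 82 positive / 28 negative, 310 nodules, max bag
size 12 — by adjusting the size draw to the fixed total.

What passing tests on this generator do and do not show: they validate the
pipeline's mechanics, the attention mechanism's ability to localize witness
instances, and the direction of the oversampling effect, under a correctly
specified MIL generative model with informative features. They do not
demonstrate performance on real CT radiomics, which have heavy
collinearity, batch effects, annotation noise, and no guarantee that the
MIL assumption holds exactly.

## Experiment scales in the shipped checks

The automated checks scale the protocol down to keep runtimes reasonable
while preserving the protocol's structure: the attention-sanity experiment
uses the full 500-epoch protocol on 5 seeds with a 20% held-out split; the
oversampling-direction experiment uses 10 repetitions × 5 folds at 200
epochs, levels 0 vs 60; determinism checks use 2 repetitions at reduced
epochs. The acceptance script reports the problem size used for each
quantity.

The oversampling-direction experiment runs at a weaker signal than the
generator default and with correlated feature blocks
(effect_size 0.6, block_size 10, block_rho 0.6): at effect size 3 the
synthetic task saturates (AUC ≈ 1 with or without oversampling), so an
imbalance-correction effect cannot materialize, and with clean independent
features the baseline model's rare negative calls are its most confident
and therefore most precise ones, which inflates its NPV. The
weaker-signal, collinear regime places the baseline where the studied
phenomenon lives — biased toward the majority class (recall near 1, a
handful of negative calls) with near-chance minority discrimination — and
there minority oversampling reproducibly improves AUC, PPV and NPV while
trading away recall, the directional pattern expected for minority
oversampling on an imbalanced cohort.

## Numerical and degenerate-input choices

- Zero-variance features standardize to 0; a single training instance
  standardizes to all-zeros.
- Softmax scores are max-shifted before exponentiation; predicted
  probabilities are clipped to [1e-12, 1-1e-12] inside the loss only.
- Non-finite training loss aborts with a diagnostic rather than continuing.
- Bags larger than the padding target are rejected explicitly (an
  `on_oversize="grow"` option raises the target instead).
- All randomness flows through seeded numpy Generators; CV fold seeds are
  derived with SeedSequence spawn keys, keeping every derived seed below
  2³¹.

## Known limitations

- The attention weights are comparable only within a subject; the report
  never compares alphas across subjects.
- Probability calibration is poor by construction (long training pushes
  outputs toward 0/1); thresholded metrics are meaningful, raw
  probabilities are not calibrated risks.
- The NPV direction under oversampling is generator-dependent: with clean
  independent features the baseline's few negative calls are
  high-confidence and NPV can favor the un-corrected model; the
  improvement reproduces in the collinear weak-signal regime (above).
- No image handling: the package starts from feature tables; extraction
  from DICOM (2 mm isotropic resampling, 103-feature signature) is a
  documented schema contract, not implemented functionality.
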