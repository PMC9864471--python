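# Methods

## Data model

The unit of classification is a single voiced frame: a real vector of
audio features sampled every 10 ms (`frame_period`, configurable).
Labels live at the subject level — a PHQ-8 total score in 0–24 — and are
broadcast to all of a subject's frames. The default severity scheme
maps 0–9 → Nondepression, 10–14 → First stage, 15–19 → Intermediate
stage, 20 → Final stage, and excludes subjects scoring ≥ 21 from the
study; the binary scheme splits at the standard diagnostic cutoff of 10.
The depressed-stage cut points follow the standard PHQ-8 bands and are
deliberately configurable (`SeverityScheme`) rather than hard-coded,
since different severity stagings exist in the literature. Subjects
known to carry wrong labels are handled by an explicit
`exclude_subjects` list in `build_dataset`, not auto-detected.

Broadcasting a subject-level diagnosis to every frame is itself a strong
assumption — depression-specific speech characteristics likely appear
only in parts of an utterance — and it is the main reason frame-level
models struggle on unseen speakers (see "Generalization gap" below).

## Preprocessing

Features whose sample variance is ≤ `tol` (default 1e-10) are removed
before anything else, because the Pearson correlation of a
near-constant column is numerically meaningless. Remaining features
are robust-scaled to median 0 and interquartile range 1. Quartiles use
the linear-interpolation convention (numpy's default), fixed and
documented because the quartile convention changes the fitted
parameters: for the column 1..9, Q1 = 3, median = 5, Q3 = 7, IQR = 4.

**Leakage policy.** The variance filter, the scaler and the similarity
graph are all fitted on training frames only and then frozen; test and
validation frames are only ever transformed. Inside the
speaker-independent cross-validation these statistics are re-fitted per
fold. Since the absolute Pearson correlation is invariant to
per-feature affine maps with nonzero slope, robust scaling does not
change the graph built from the same frames — but fitting on training
frames only does change it across folds, which is the honest choice.

## Similarity graphs

The similarity of two features is the absolute value of their Pearson
correlation over the training frames; the sign is discarded because a
strong negative coupling is as informative for convolution as a strong
positive one. For each feature the top-`m` entries form an ordered
neighbor list (descending similarity, ties broken by ascending feature
index so the graph is bit-reproducible). Per feature the induced graph
is a star: center connected to each neighbor, neighbors mutually
unconnected.

**Receptive-field convention (`include_self`).** The convolution
kernels span `m` taps, while a literal reading of "select m neighbors"
plus the center gives `m + 1` nodes. The default (`include_self=True`)
resolves this in favor of the kernel width: the receptive field is the
center (tap 0, similarity 1) plus the top `m − 1` neighbors, so the
width always equals `m` and matches kernel shapes like 1 × 9 × 64.
`include_self=False` keeps the literal reading (top `m` neighbors, width
`m + 1`); both are supported and tested, and this is the package's main
interpretation choice. `neighborhood_selection_counts` (the per-feature
"how often was I someone's neighbor" diagnostic) skips center entries,
so its total is `n_features × m` for `include_self=False` graphs and
`n_features × (m − 1)` otherwise.

## The classifier

Architecture: a stack of graph-convolution layers (ReLU), a flatten, a
stack of fully connected layers (ReLU, dropout), a final linear layer
and softmax. Kernel tap *k* is bound to similarity rank *k* of each
feature's receptive field — center first, then descending similarity —
a binding that has to be fixed arbitrarily for reproducibility since
graph neighborhoods, unlike pixel neighborhoods, have no canonical
order.

The reference profile (`GCNNConfig()` defaults) is conv channels
64/128/256/512 and FC sizes 4096/1024/256 with `m = 9`; with 65 features
the flatten width is 65 × 512 = 33,280. That model is intended for
corpus-scale data and is expensive on one CPU, so tests, examples and
the acceptance script use `desk_profile()` — identical topology at conv
8/16, FC 64/32 — which is sufficient for the synthetic cohorts used
here. Training: mini-batch Adam (lr 1e-3, batch 1024, β₁ 0.9, β₂ 0.999,
ε 1e-8), softmax cross-entropy, dropout 0.1 on hidden fully connected
layers only (a `conv_dropout` flag exists but is off by default), early
stopping on validation loss with patience 5 (desk profile: max 20
epochs, patience 3). The epoch budget and stopping rule are the
package's own choices; optional per-class loss weights exist but are
off by default, so class imbalance affects training exactly as it
affects any unweighted cross-entropy model.

Everything is NumPy: the forward pass, analytic backpropagation through
softmax/FC/flatten/graph-gather, and the optimizer are written out
explicitly. Correctness rests on two independent oracles, both in the
test suite: a triple-loop reimplementation of the graph convolution
(agreement to 1e-10) and central finite differences of the loss against
the analytic gradients on a tiny model (relative error < 1e-4; observed
~1e-8). Weight initialization is He-style normal scaled by fan-in with
zero biases; the true initialization of the reference architecture is
unknown, so this is documented as a default, not fidelity. Gathered
receptive-field tensors are cached per batch for the backward pass,
which is why the full-size profile should be trained with moderate
batch sizes on memory-constrained machines.

Numerical details: softmax is computed with max-subtraction;
probabilities are clipped at 1e-300 before the log; a non-finite loss
or activation aborts training with a diagnostic rather than continuing
silently; prediction ties resolve to the lowest class index
(numpy argmax convention, asserted in tests).

## Evaluation protocols

*Speaker-dependent* (Setting 1): frames of each class are shuffled with
the split seed and divided 80% train / 10% test / 10% validation
(stratified per class, floor rounding, remainder to validation). The
same subject may appear in all three partitions.

*Speaker-independent* (Setting 2): subjects of each class are shuffled
and dealt round-robin into k folds (default 5), so per-class fold sizes
differ by at most one and no subject appears twice. Each fold is tested
with a model trained on the other folds' subjects. The protocol only
defines train/test separation, so the validation set needed for early
stopping is carved subject-grouped from the training subjects (12.5% of
them, at least one subject) — keeping validation speaker-independent
too. Fold disjointness is asserted on every run.

Metrics are per-class one-vs-rest precision, recall and F1 from the
K×K confusion matrix, in percent, rounded to 2 decimals for display
while raw values stay in machine precision. A metric with a zero
denominator is reported as 0 with a warning — this is visible when a
minority class is never predicted, which is exactly how
speaker-independent four-class results collapse under imbalance.
Micro-averaged recall equals overall accuracy (trace/total); folds are
aggregated by the arithmetic mean of each per-class metric.

## Synthetic cohorts

The generator emulates the three statistical properties the method
depends on, via a per-block single-factor model:

    value = noise_sd · ( √ρ · block_factor + √(1−ρ) · ε )
            + class_shift[class, block] + speaker_offset

with `block_factor`, `ε` standard normal per frame and `speaker_offset`
drawn once per (subject, feature) from N(0, `speaker_sd`). The factor
form makes the expected within-block correlation exactly ρ and the
between-block correlation 0, which the tests verify empirically
(tolerance 0.05 at 50k frames). Default blocks (9, 25, 18, 13) echo the
sizes of the real feature families (glottal/spectral singles, MCEP,
HMPDM, HMPDD). Constant decoy columns are exactly constant, so the
variance filter catches them at any tolerance. Each subject's PHQ-8
score is drawn uniformly from its class's score band, exercising the
label-mapping path end to end. Frames per subject may be a fixed count
or a range.

Scenario presets (`reference_scenarios()`), chosen once as the study
conditions for all tests and the acceptance script:

- **separable** — 2 classes × 10 subjects × 2000 frames, class shift
  2.0 (≫ noise sd 1.0), no speaker effect: a sanity ceiling any sound
  classifier should reach (held-out accuracy ≥ 0.95; observed ~0.99).
- **speaker-confounded** — 2 × 10 × 500 frames, speaker offsets sd 3.0
  vs class shift 0.25: speaker identity dominates the signal.
- **imbalanced-4class** — subject counts (22, 5, 2, 2) × 200 frames:
  the majority class holds ~71% of frames, matching the skew of real
  depression corpora.

What the generator does **not** emulate: temporal autocorrelation
between consecutive frames, non-Gaussian marginals, gender-dependent
correlation structure, cross-block correlations, or any acoustic
realism. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its qualitative behavior (separability
ceiling, speaker-memorization gap, imbalance collapse) is reproduced —
not that any particular accuracy transfers to clinical recordings.

## Generalization gap

With speaker effects ≫ class effects, a speaker-dependent split lets
the network memorize each speaker's offset signature and look
near-perfect on held-out frames of the same speakers, while
subject-grouped cross-validation — the clinically relevant protocol —
falls toward the majority-class rate. The package reproduces this as a
directional property (gap ≥ 10 accuracy points on the
speaker-confounded scenario, for each of three seeds; observed ~40–55
points). The absolute accuracies of corpus-scale experiments are out of
scope here: they require the restricted clinical corpus and
GPU-scale training of the full profile.

## Problem sizes

Tests and the acceptance script run the desk profile on cohorts of
10k–40k frames with 65 features, which keeps a full run in the minutes
range on a single CPU while leaving every pipeline stage (including
5-fold × 3-seed cross-validation) exercised at realistic shape.

## Known limitations

- No GPU path, mixed precision or model compression; the full-size
  profile is impractical to train in this package on CPU.
- Conv-layer biases and initialization are assumptions (documented
  above), not reproductions.
- No focal loss / resampling for imbalance (weights are exposed but
  off), no noise robustness, no gender-specific graphs or models.
- The tool starts at feature tables; extracting features from
  waveforms is out of scope.
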