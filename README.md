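# corrgcn

Classification of depression and its severity from frame-level voice
features, using graph convolution over feature-correlation graphs.

## The problem

Clinical speech corpora such as DAIC-WOZ ship per-frame audio-feature
tables: one ~74-dimensional COVAREP-style vector (F0, glottal-source
measures, mel-cepstral and harmonic-phase-distortion coefficients) every
10 ms of voiced speech, plus one PHQ-8 depression score per subject
(0–24; scores ≥ 10 are diagnostically depressed, scores ≥ 21 excluded).
Voice features are not independent — they reflect coordinated movements
of the same vocal organs and come in strongly correlated families — so a
classifier should exploit the correlation structure rather than treat
features as an unordered vector.

`corrgcn` implements that idea end to end, for people who want to study
frame-level voice biomarkers of depression or scrutinize how such models
behave under honest evaluation protocols:

1. **Preprocessing** — drop near-constant features (their correlations
   are ill-defined), robust-scale the rest to median 0 / IQR 1, map
   PHQ-8 scores to severity classes (default bands 0–9 / 10–14 / 15–19 /
   20, binary split at 10).
2. **Similarity graphs** — the similarity of features *x*, *y* is the
   absolute Pearson correlation over the *n* training frames,

   S(x,y) = | Σᵢ(xᵢ−x̄)(yᵢ−ȳ) | / √( Σᵢ(xᵢ−x̄)² · Σᵢ(yᵢ−ȳ)² ).

   Each feature keeps its *m* = 9 most similar features as a star-shaped
   neighborhood (neighbors are not interconnected).
3. **Graph-convolutional classifier** — convolution kernels slide over
   each feature's receptive field (itself + neighbors ordered by
   similarity rank) instead of a pixel grid; conv layers are followed by
   fully connected layers, softmax, cross-entropy loss and Adam, with
   early stopping on validation loss. The network is implemented in
   NumPy with fully explicit, finite-difference-verified backpropagation.
4. **Evaluation** — per-class one-vs-rest precision / recall / F1 from
   confusion matrices, under two protocols: **speaker-dependent**
   (frame-level 80/10/10 split — seen speakers on both sides) and
   **speaker-independent** (subject-grouped 5-fold cross-validation —
   train and test speakers disjoint).
5. **Synthetic cohorts** — a generator with block-correlated features,
   class-conditional mean shifts, per-speaker offsets and class
   imbalance, so every stage is testable without the access-restricted
   clinical corpus.

## Worked example

`examples/01_metrics_from_reported_counts.py` recomputes per-class
metrics from published confusion-matrix counts:

```
binary classification (663,978 test frames, accuracy 96.88%):
               precision  recall     f1  support
Nondepression      97.75   97.84  97.80   470279
Depression         94.75   94.53  94.64   193699
```

Each row scores one class one-vs-rest in percent; the support column
shows the class imbalance (~71% nondepressed frames).

`examples/04_generalization_gap.py` shows why the evaluation protocol
matters. On a synthetic cohort whose per-speaker offsets (sd 3.0) dwarf
the class effect (0.25):

```
Setting 1 (seen speakers)  accuracy: 100.00%
Setting 2 (new speakers)   mean accuracy: 45.73%
generalization gap: 54.27 points
```

Seen-speaker evaluation lets the model memorize speaker signatures;
with unseen speakers it collapses toward chance. High speaker-dependent
accuracy therefore does not imply the model detects depression in new
patients — the central cautionary finding this package reproduces.

The other examples cover cohort simulation plus graph inspection
(`02_simulate_and_build_graph.py`) and a full speaker-dependent training
run (`03_speaker_dependent_training.py`, held-out accuracy 0.994 on the
separable cohort).

## Command line

```bash
corrgcn simulate --scenario separable --out cohort/
corrgcn build-graph --data cohort/ --out graph.json --heatmap heat.csv
corrgcn run-experiment --scenario speaker-confounded --setting 2 --out run/
```

## Layout

- `src/corrgcn/preprocess.py` — tables, scaling, severity classes
- `src/corrgcn/simgraph.py` — similarity matrix + neighborhood graphs
- `src/corrgcn/gcnn.py` — the classifier (NumPy forward/backward/Adam)
- `src/corrgcn/evaluate.py` — protocols, confusion matrices, metrics
- `src/corrgcn/synthcohort.py` — synthetic cohort generator
- `src/corrgcn/cli.py` — thin command-line layer
- `docs/methods.md` — model assumptions, parameter choices, limitations
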