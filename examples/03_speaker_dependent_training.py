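"""Train and evaluate the graph-convolutional classifier (Setting 1).

Runs the speaker-dependent protocol on a reduced separable cohort:
frames of every class are split 80/10/10 into train/test/validation,
the similarity graph and robust scaler are fitted on training frames
only, and a reduced desk-profile model is trained with Adam and early
stopping.
"""

import dataclasses

import corrgcn as cg

cohort_cfg = dataclasses.replace(
    cg.reference_scenarios()["separable"],
    n_subjects_per_class=(5, 5),
    frames_per_subject=500,
    seed=0,
)
tables, subjects = cg.generate_cohort(cohort_cfg)
ds = cg.build_dataset(tables, subjects, cg.binary_scheme())
print(f"{ds.n_frames} frames from {len(subjects)} subjects, "
      f"class counts {ds.class_counts().tolist()}")

model_cfg = cg.desk_profile(n_classes=2, seed=0, max_epochs=6, patience=2)
res = cg.run_speaker_dependent(ds, model_cfg, cg.SplitSpec(seed=0))

print(f"trained {res.history.n_epochs} epochs "
      f"(best validation epoch {res.history.best_epoch + 1})")
print(res.report.to_frame().to_string())
print(f"held-out frame accuracy: {res.test_accuracy:.4f}")

# The large class-conditional mean shift makes frames linearly separable,
# so the classifier should approach perfect held-out accuracy; precision
# and recall near 100% per class confirm the training loop works.
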