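"""Cross-validated six-movement classification on synthetic trials.

Generates one synthetic subject with well-separated classes, runs the
default pipeline (dmey wavelet packets, level 3, 400-sample windows,
PCA to 30 dimensions, KNN) with trial-grouped stratified 5-fold
cross-validation, and prints the confusion matrix and per-class metrics.
"""

from semgkit import PipelineConfig, SyntheticSpec, cross_validate, generate

spec = SyntheticSpec(n_subjects=1, n_trials_per_class=10, separation=2.0, seed=7)
recordings = generate(spec)
report = cross_validate(recordings, PipelineConfig(), n_folds=5, seed=42)

print(f"windows evaluated : {report.confusion.total}")
print(f"overall accuracy  : {report.overall_accuracy:.4f}")
print(f"fold accuracies   : mean {report.mean_fold_accuracy:.4f} "
      f"± {report.std_fold_accuracy:.4f}")
print("\nconfusion matrix (rows = true class):")
print("      " + "  ".join(f"{c:>4s}" for c in report.confusion.classes))
for cls, row in zip(report.confusion.classes, report.confusion.counts):
    print(f"  {cls}  " + "  ".join(f"{v:4d}" for v in row))
print("\nper-class metrics:")
print(report.per_class.to_string(float_format=lambda v: f"{v:.3f}"))
print("\nAn overall accuracy near or above 0.9 on well-separated classes shows")
print("the sub-band features carry the movement information end to end; the")
print("off-diagonal confusion counts show which grasps remain hardest to tell apart.")
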