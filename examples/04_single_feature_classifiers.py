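"""Evaluate one feature as a single explanatory variable with LR/SVM/RF.

Fivefold stratified cross-validation; the feature is standardized with
training-fold statistics; no hyperparameter search. Reported: accuracy, F1
(patient-positive) and AUC as mean +- SD over the five folds.
"""

from advoice import CohortSpec, FrameGrid, extract_speech, simulate_subjects
from advoice.evaluate import evaluate_feature, make_folds
from advoice.features import cohort_feature_table

spec = CohortSpec(n_patient=6, n_healthy=6, duration_s=30.0, seed=4)
table = cohort_feature_table(
    [(r.subject_id, r.group, extract_speech(r))
     for r, _ in simulate_subjects(spec)], 44100, FrameGrid(sample_rate=44100))

plan = make_folds(table, k=5, seed=4)
for res in evaluate_feature(table, "spectrum.kurtosis_sd", foldplan=plan):
    acc, acc_sd = res.mean_sd("accuracy")
    f1, f1_sd = res.mean_sd("f1")
    auc, auc_sd = res.mean_sd("auc")
    print(f"{res.classifier:3s}  accuracy {acc:.3f} ± {acc_sd:.3f}   "
          f"F1 {f1:.3f} ± {f1_sd:.3f}   AUC {auc:.3f} ± {auc_sd:.3f}")
print("\nAUC is the probability a random patient block scores above a random")
print("healthy block (ties one-half); 0.5 is chance, 1.0 perfect ranking.")
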