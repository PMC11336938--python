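"""Train the attention classifier and its plain residual baseline once.

Runs the full pipeline on the default synthetic cohort with one seed —
simulate, 50/20/30 stratified split, train both models, evaluate on the
held-out test set — and prints accuracy, AUC and the confusion matrices.
(The headline protocol repeats this over 5 seeds; see the README.)
"""

from hepatoscope import ExperimentConfig, run_experiment

att, base = run_experiment(ExperimentConfig().with_seed(1))

for report in (att, base):
    print(f"\n{report.model_name} on the {report.partition} partition "
          f"({report.n_subjects} subjects):")
    print(f"  accuracy {report.accuracy:.3f}   AUC {report.auc:.3f}")
    print(f"  confusion matrix (rows = truth, cols = prediction):")
    for row in report.confusion:
        print(f"    {row.tolist()}")
    print(f"  per-class misclassification: healthy {report.misclassification[0]:.3f}, "
          f"fatty {report.misclassification[1]:.3f}")
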