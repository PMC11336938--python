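# hepatoscope

Early-stage nonalcoholic fatty liver disease (NAFLD) is usually silent:
lipid droplets accumulate in hepatocytes long before symptoms, while the
window for dietary reversal is open. Because fat-infiltrated tissue is
anhydrous and conducts poorly at low frequency — lipid bilayers block
current below tens of kHz, while hydrated lean tissue conducts well — a
multi-frequency, multi-electrode skin impedance measurement over the
liver can in principle detect early disease non-invasively.

`hepatoscope` is a tested, reusable pipeline for studying that idea end
to end on synthetic data. It provides:

* **a physics-based cohort simulator** — each subject is a lumped
  circuit per electrode pair: two Randles contact interfaces
  `Z(ω) = R_d + 1/(jωC_dl + 1/R_e)` in series with a weighted mix of a
  liver and a background Cole dispersion
  `Z(f) = R∞ + (R0 − R∞)/(1 + (jf/f_c)^α)`. Six electrodes give 15
  pairs, each swept over 30 log-spaced frequencies from 1–100 kHz, so a
  subject is a 15 × 30 matrix of |Z|. Fatty livers carry an elevated
  low-frequency plateau `R0`; the default cohort is forty matrices,
  twenty per class, with log-normal between-subject variability and
  multiplicative measurement noise, all reproducible from a seed.
* **an attention-augmented residual classifier** (`AttentionResNet`) and
  its plain residual baseline — residual blocks with 1 × 1
  convolutions, gated per block by channel attention
  (`sigmoid(MLP(avgpool) + MLP(maxpool))`) then spatial attention
  (`sigmoid(conv7×7([mean; max]))`), built on a small NumPy
  reverse-mode autodiff engine whose gradients are finite-difference
  checked.
* **the evaluation protocol** — stratified 50/20/30
  train/validation/test split (20/8/12 for forty subjects), per-frequency
  z-scoring fitted on train only, full-batch Adam with early stopping,
  ROC/AUC (ranking definition = trapezoidal area), confusion matrices,
  and repeated-seed summaries.
* **a histology ground-truth pipeline** — synthetic stained liver
  sections, Otsu thresholding + particle analysis, droplet size
  histograms over equivalent-diameter bins 2–7 and 7–13 px, per-bin
  one-way (and two-factor) ANOVA, and a monotone droplet-count
  labelling rule.

See `docs/methods.md` for the full model description and the design
rationale behind every default.

## Worked example

```python
from hepatoscope import ExperimentConfig, run_experiment

att, base = run_experiment(ExperimentConfig().with_seed(1))
print(att.accuracy, att.auc, att.confusion.tolist())
```

Running `python examples/train_classifier.py` (which does the above and
prints both models) gives:

```
attention_resnet on the test partition (12 subjects):
  accuracy 1.000   AUC 1.000
  confusion matrix (rows = truth, cols = prediction):
    [6, 0]
    [0, 6]
  per-class misclassification: healthy 0.000, fatty 0.000

resnet on the test partition (12 subjects):
  accuracy 1.000   AUC 1.000
  ...
```

The attention model separates the twelve held-out subjects perfectly:
the six healthy and six fatty-liver test subjects land on the diagonal
of the confusion matrix, and an AUC of 1.0 means every fatty subject
outscored every healthy one. On these cleanly separated synthetic
cohorts the plain baseline usually reaches the same ceiling.

Other examples, each self-contained and printing what it computes:

* `examples/contact_impedance.py` — how raising the double-layer
  capacitance C_dl cuts contact impedance (8.4× at 1 kHz for 0.1 → 1 µF);
* `examples/simulate_cohort.py` — the cohort's low-frequency class
  contrast (healthy ≈ 678 Ω vs fatty ≈ 838 Ω, fully separated) and the
  lossless on-disk round trip;
* `examples/histology_groundtruth.py` — small-droplet excess in fatty
  sections (≈ 68 vs ≈ 7 per section), the per-bin ANOVA (p ≈ 1e-23 for
  the 2–7 px bin at n = 10), and the droplet-count labelling rule.

A thin CLI wraps the same library calls:

```bash
hepatoscope simulate --seed 1 --out cohort/
hepatoscope run-all --seed 1 --outdir run/
hepatoscope histology --seed 1 --sections 20
```

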