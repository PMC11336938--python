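# Methods

`hepatoscope` is a synthetic test-bed for non-invasive early-stage fatty
liver (NAFLD) detection from multi-frequency, multi-electrode skin
impedance measurements. It has three parts: a forward simulator that
generates labelled cohorts of impedance matrices with the statistical
structure such a study assumes, an attention-augmented residual network
(and a plain residual baseline) that classifies those matrices, and a
histology pipeline that emulates the droplet-counting procedure used to
ground-truth the labels. This note records the models, the defaults and
why they are what they are, and what the synthetic world does and does
not show.

## Measurement model

A six-electrode skin patch measured pairwise yields 15 electrode pairs;
each pair is swept over 30 log-spaced frequencies from 1 to 100 kHz, so
one subject is a 15 × 30 matrix of impedance magnitudes |Z|.

Each matrix cell is a lumped two-contact series circuit:

    Z_pair(f) = Z_contact(e1, f) + Z_contact(e2, f)
              + w_p · Z_liver(f) + (1 − w_p) · Z_background(f)

**Contact impedance** follows the Randles equivalent circuit: a series
skin/gel resistance `R_d` in front of a charge-transfer resistance `R_e`
in parallel with the double-layer capacitance `C_dl`,

    Z(ω) = R_d + 1 / (jωC_dl + 1/R_e),   ω = 2πf.

Its real part lies in [R_d, R_d + R_e], its reactance is capacitive, and
|Z| is strictly decreasing in `C_dl` at fixed f — the mechanism by which
high-capacitance electrode coatings improve signal fidelity. A `literal`
switch evaluates the dimensionally inconsistent series reading
`R_d + 1/(jωC_dl) + 1/R_e` for comparison; it is never the default
because only the parallel form is a Randles circuit and reproduces the
capacitance effect.

**Tissue paths** follow a Cole-type dispersion

    Z(f) = R∞ + (R0 − R∞) / (1 + (jf/f_c)^α),  0 < α ≤ 1,

with resistive plateaus `R0` (DC) and `R∞` (high frequency), a
characteristic frequency `f_c`, and a fractional exponent `α` that
broadens the relaxation as biological tissue does. |Z| decays
monotonically from `R0` to `R∞`. The fatty-liver contrast is encoded
here: lipid accumulation impedes low-frequency current, so the fatty
liver path carries a higher `R0`.

**Liver weighting.** Each pair's current path crosses the liver with
fraction `w_p`, a shipped constant that declines linearly with the rank
of the inter-electrode distance (0.5 for the closest pair down to 0.2
for the farthest, average ranks for ties, electrodes on a 2 × 3 grid).
This is a synthetic-world choice, not an electromagnetic solution; no
field solving or finite-element modelling is attempted.

### Default parameters

| parameter | healthy liver | fatty liver | background | contact |
|---|---|---|---|---|
| R0 / R_d (Ω) | 500 | 1000 | 400 | 100 |
| R∞ / R_e (Ω) | 200 | 300 | 150 | 10 000 |
| f_c (kHz) | 30 | 15 | 50 | — |
| α / C_dl | 0.8 | 0.8 | 0.85 | 1 µF |

Between-subject variability is log-normal around these class medians
with coefficients of variation 0.06 (liver plateaus), 0.05 (f_c), 0.04
(background), 0.08 (contacts); `α` is fixed. Measurement noise is
multiplicative log-normal per cell with scale 0.03 (median 1), because
magnitudes are positive and instrument error scales with magnitude.
These choices give a cohort in the high-hundreds-of-ohms range whose
fatty subjects exceed every healthy subject in mean low-frequency
magnitude — the noise-free separation property the acceptance suite
asserts, and which `examples/simulate_cohort.py` prints for a concrete
seed (a worst-case gap of a few tens of ohms, i.e. cleanly but not
trivially separated: each matrix still mixes the contrast with contact
and background variation across 450 cells).

All generation is a pure function of (parameters, seed); with
`noise_sigma = 0` the output is seed-independent.

## Classifier

The impedance matrix is treated as a 1-channel 15 × 30 image. The
network is a small residual CNN: a 3 × 3 stem convolution to 16
channels, three residual blocks, global average pooling, and a linear
two-class head. Each block is conv3×3 → norm → ReLU → conv1×1 → norm,
added to an identity shortcut (1 × 1 projection when widths change) and
rectified; the 1 × 1 second convolution keeps the parameter count down
(≈ 8.9 k parameters with attention, 8.2 k without).

With attention enabled, the block's branch output is gated by a channel
gate then a spatial gate (the convolutional block attention pattern):

* channel gate: `sigmoid(MLP(avgpool) + MLP(maxpool))` with a shared
  two-layer bottleneck MLP (reduction ratio 4);
* spatial gate: `sigmoid(conv7×7([channel-mean; channel-max]))`, one
  weight per location.

Both gates lie strictly in (0, 1); with zero parameters each is a
uniform ×0.5 gate, which the tests assert. Attention is applied inside
every block. Disabling it yields the plain residual baseline with an
otherwise identical trunk.

Normalisation is instance-style (per sample and channel over space) with
learnable affine, chosen because training batches of ten-odd subjects
make batch statistics meaningless. Inputs are standardised per frequency
column with statistics fitted on the training partition only —
magnitudes fall by an order of magnitude across the sweep.

The network and its training run on a small reverse-mode automatic
differentiation engine written on NumPy arrays (`hepatoscope.nn.autodiff`);
every operator's gradient is verified against central finite differences
in the test suite, and convolution is a sum of per-tap channel
contractions. Initialisation is He-normal from an explicit seed, so two
builds with the same seed predict identically.

## Evaluation protocol

Cohorts are split 50/20/30 into train/validation/test, stratified by
label with a per-class largest-remainder apportionment (ties favour
train over validation over test), so forty balanced subjects always give
20/8/12 overall and 10/4/6 per class, deterministically from the split
seed.

Training is full-batch Adam (learning rate 1e-3) on the two-class
cross-entropy for up to 200 epochs, with early stopping when the
validation loss has not improved by at least 1e-3 for 30 consecutive
epochs; the best-validation-loss weights are restored. These are this
package's defaults — on the default cohorts the optimum is reached well
before the cap — and every seed (generation, split, initialisation) is
explicit, giving bitwise-reproducible runs on CPU.

Test-set scores are summarised by accuracy at threshold 0.5, the
confusion matrix (rows = truth), per-class misclassification rates, and
the ROC/AUC. The AUC is computed from the ranking (Mann-Whitney)
definition — the probability that a random positive subject outscores a
random negative one, ties counting ½ — which equals the trapezoidal
area under the ROC; the suite property-tests this equivalence against an
independent implementation. Because single-split results on forty
subjects are seed-sensitive (test accuracy is a multiple of 1/12), the
headline comparison repeats the full pipeline over 5 seeds and reports
means.

## Histology ground truth

Synthetic stained sections are 256 × 256 images of bright disks
(droplets) on a dark background with additive Gaussian noise (scale
0.03). Healthy sections carry ~12 droplets of median radius 3.2 px;
fatty sections ~70 droplets of median radius 2.2 px, reflecting the
marked excess of small lipid droplets in early disease. Disks are
rejection-sampled to be non-overlapping.

Segmentation is Otsu's automatic global threshold followed by connected
components and a minimum-size filter (4 px); per-object area and
equivalent diameter are tabulated. Two conventions are documented
rather than hidden: touching droplets count as one object (no watershed
splitting), and a thresholded image whose foreground/background class
gap does not exceed four pooled within-class standard deviations is
declared empty (Otsu always "finds" a split, even in pure noise).

Diameters are binned half-open over edges (2, 7, 13) in pixel units —
small droplets 2–7, large 7–13. Groups are compared per bin by one-way
ANOVA (degenerate bins report F = 0, p = 1 by convention), with an
optional balanced two-factor (group × bin) decomposition. Sections are
labelled fatty when the small-bin count exceeds 30, a threshold
calibrated midway between the two synthetic regimes; the rule is
monotone, flipping exactly once as the threshold sweeps.

## What the synthetic world shows — and what it does not

The generator's defaults *are* the study conditions for every reported
number: forty subjects, twenty per class, the dispersion and contact
parameters above. Under them the attention model reaches mean test
accuracy ≥ 97.5% with per-seed test AUC 1.0, and does not trail the
baseline. This demonstrates that the pipeline — physics, splitting,
normalisation, training, evaluation — is wired correctly and that the
claimed contrast is learnable from 20 training matrices. It does not
demonstrate real-world performance: real electrode-skin interfaces
drift, anatomy varies beyond a scalar path weight, real cohorts carry
confounders, and the simulated class gap, though noisy at the
subject-parameter level, is by construction free of label error. The
plain baseline also often reaches AUC 1.0 here; separating the two
architectures would need a harder synthetic regime, which the shipped
defaults deliberately do not chase.

## Numerical choices and degenerate inputs

* Frequency grids are `geomspace` with endpoints pinned exactly; a
  single-point grid requires f_min = f_max.
* The max-reduction gradient splits ties equally; ReLU's subgradient at
  0 is 0.
* Zero-variance frequency columns standardise with unit divisor.
* Empty cohorts cannot be split; empty training partitions refuse to
  train; single-class score vectors refuse a ROC.
* Cohorts round-trip losslessly (float64 array container + CSV
  metadata + JSON provenance); checkpoints (weights + config +
  normaliser) reproduce predictions bitwise.

## Problem sizes

Defaults throughout are the study scale: 40-subject cohorts, 5-seed
repetition for headline numbers, 10–20 sections per group for the
histology statistics. The test suite exercises smaller variants (4–8
subjects, 1-block networks) where only the mechanism is under test.
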