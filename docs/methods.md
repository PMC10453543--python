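# Methods

`emoselect` implements an EEG emotion-recognition pipeline built around four
ideas: differential-entropy (DE) channel selection, decomposed
mutual-information (DMIM) window selection, class-conditional graph-EMD data
augmentation, and a lightweight 1D-CNN, all evaluated under
leave-one-subject-out (LOSO) cross-validation. Because the public emotion
corpora this family of methods targets (DEAP, MAHNOB-HCI, SEED) are
licensed, the package ships a synthetic generator that reproduces their
recording geometries and plants controllable class structure, so the whole
pipeline is testable end to end.

## Synthetic EEG generator

Each trial is pink (1/f) Gaussian noise, shaped in the frequency domain
(flat below 1 Hz to keep infra-slow power bounded), normalized to unit
variance per channel and scaled to `noise_scale` (default 10 µV — a typical
scalp-EEG RMS). Class structure is a set of band-limited sinusoids (delta 2,
theta 6, alpha 10, beta 22, gamma 40 Hz) with a fresh uniform random phase
per trial/channel/band, whose amplitude is `noise_scale x multiplier` with a
per-class multiplier map. Bursts are injected only into declared
*informative channels* and only inside declared *informative 2-s windows*.
Labels are drawn balanced per subject; rating-scheme profiles receive
integer SAM ratings consistent with the class on both the valence and the
arousal axis (ratings > 5 are "high", <= 5 "low").

What this emulates: realistic spectral slope, per-trial phase variability,
class-dependent band power confined to known channels/windows — exactly the
structure the DE- and MI-based selectors assume. What it does not emulate:
eye-blink/EMG artifacts, electrode drift, inter-subject anatomical
variability, volume conduction, or non-stationarity within a window. A
passing test-bench therefore demonstrates correctness of the machinery and
recoverability of planted structure, not performance on real recordings.

Built-in geometries: `deap_like` (32 subjects x 40 trials x 32 ch, 128 Hz,
60 s), `mahnob_like` (27 x 20 x 32 ch, 256 Hz, 60 s default; the source
clips vary 34–117 s and the duration is overridable — 60 s is chosen so the
canonical 15,360-sample trial shape holds), `seed_like` (15 x 15 x 62 ch,
128 Hz, 240 s, categorical labels). All randomness flows from a single
integer seed through one `numpy.random.Generator`; identical specs are
bit-identical.

## Channel selection

Channel amplitudes are symbolized into equal-frequency bins (default 8) per
channel over all trials. For a channel and a class C the score is

    E = -(1/|U|) * sum_{z in U} log2( overlap(z, C) ),

where U is the set of all trials and `overlap(z, C)` is the histogram
intersection `sum_b min(p_z(b), p_C(b))` between trial z's per-channel bin
distribution and the pooled class-C distribution. The notation in the
source formula leaves the set operation on symbol collections open; we read
the intersection-over-size ratio as *shared probability mass*, which keeps
the printed structure (a per-trial base-2 log ratio averaged over the
universe) while being monotone in distributional overlap. The naive
set-membership reading is degenerate for long trials — every bin occurs in
every trial, so every ratio is 1 and all scores collapse to 0 — and cannot
discriminate channels at all. Zero overlap is floored at `1/(n_samples+1)`
to keep the logarithm finite.

Scores are aggregated over classes by max (a channel relevant to any class
is kept), thresholded at 1.5 by default, and ordered by descending score
with montage order breaking ties. A fixed channel budget (`top_k`) is also
available, mirroring the canonical 10-channel operating point; selections
from several datasets can be intersected (`common_channels`), keeping the
k channels with the best mean rank.

## Window features and DMIM selection

Selected-channel signals are cut into non-overlapping 2-s windows (trailing
partial windows discarded; spans half-open `[kN, (k+1)N)` and each window
keeps its raw-sample span so selections can be mapped back). Each window is
scored by the Gaussian-surrogate differential entropy
`h = 1/2 ln(P) + 1/2 ln(2*pi*e*N)` with P the mean squared amplitude and N
the window length in samples.

Candidates are window ordinals; observations pool (trial, channel) pairs
(a per-(channel, window) granularity is available in `dmim_rank`). The DE
values are discretized into 4 equal-frequency bins and ranked greedily by

    DMIM(Xi) = MI(Xi, C) - max_{Xs in S} MI(Xi, Xs)
                         + max_{Xs in S} MI(Xi, Xs | C)

with the plug-in discrete MI (natural log); the conditional term is
`sum_c P(c) MI(Xi, Xs | C=c)`. With an empty selection the score is the
plain relevance, so the first pick maximizes MI with the class. Ties break
to the lower window ordinal, making runs deterministic. Equal-frequency
binning makes the whole ranking invariant under strictly monotone amplitude
rescalings. The default stopping rule is a fixed budget of 20 windows; an
accuracy-driven rule is available that traces a nearest-centroid proxy
classifier on a held-out quarter of the trials and cuts the ranking at the
best validation accuracy — retraining the CNN at every step would cost
orders of magnitude more for the same decision. Note that a window
duplicating an already-selected one is *intentionally* suppressed by the
redundancy term; recovery guarantees apply to planted windows that carry
independent noise, not to exact duplicates.

Selected spans concatenated per channel give `k x N` samples per channel
per trial — e.g. 20 windows x 256 samples = 5,120 at 128 Hz, or
20 x 512 = 10,240 at 256 Hz.

## Graph-EMD augmentation

An epoch is a signal on a graph. Two constructions are offered, since the
source family of methods leaves it open: *temporal* (a path graph over time
applied per channel — on a path, harmonic interpolation is exactly linear
interpolation with constant extension, so this mode is a classical-EMD
variant and serves as a cross-check) and *product* (Cartesian product of a
4-NN Gaussian-kernel electrode graph over 10–20 coordinates, kernel width =
median neighbor distance, with the temporal path graph).

Sifting: strict local extrema against graph neighbors (plateau ties are not
extrema; boundary vertices may be extrema of their single neighborhood),
upper/lower envelopes by harmonic interpolation (minimize the Laplacian
quadratic form subject to equality at the extrema), mean-envelope
subtraction until the normalized squared envelope mass falls below 0.2 or
10 sift iterations pass. Decomposition stops at 5 IMFs or when the residue
has fewer than 2 maxima or 2 minima; a constant signal yields zero IMFs.
Reconstruction (sum of IMFs + residual = input) is exact by construction up
to floating-point rounding and asserted at 1e-8 relative.

Synthesis is class-conditional: for each artificial epoch, 5 distinct
same-class contributor epochs are drawn uniformly without replacement and
the j-th IMF of the j-th contributor is summed (a missing IMF is the zero
signal). The artificial epoch inherits the class label; class proportions
are preserved at any augmentation ratio, and provenance (contributor
indices) is recorded. Artificial epochs omit the residual trend, so their
variance is usually below the contributors' — a per-channel variance guard
(contributor range with 1.5x slack) logs, but does not reject, outliers.
Classes with fewer than 5 epochs are skipped with a warning. In the
evaluation pipeline augmentation is applied after channel/window selection,
to training folds only.

## 1D-CNN

Input is one vector per window: `channels x window_seconds x rate` samples
(2,560 for the 10-channel / 2-s / 128 Hz operating point; 5,120 at 256 Hz;
a batch of 64 such vectors holds 163,840 / 327,680 elements). Defaults:
four conv blocks with (64, 32, 32, 16) filters, kernels (5, 5, 3, 1), batch
norm in blocks 1–3 (after the convolution, before the activation), dropout
0.25 in blocks 1–2, average pooling (2, stride 2) after block 3, then
flatten → dense(128) → dropout 0.5 → output. Binary heads use one sigmoid
unit with binary cross-entropy and Adadelta; 3-class heads use softmax with
categorical cross-entropy and Adam. Both losses clip predictions at 1e-7.
The activation is the standard rectifier; a softplus variant
`ln(1 + e^a)` is selectable (some descriptions print this formula under the
name ReLU), and it is also what the gradient-check test uses, because the
rectifier is non-differentiable exactly at 0 where upstream rectifiers park
exact zeros.

The network is implemented directly on NumPy: convolution as an im2col
GEMM forward with a hybrid GEMM/shift-matmul backward, standard batch-norm
and pooling gradients, seeded uniform fan-in initialization, float32 by
default (float64 for gradient checking). Optimizers: canonical Adadelta
(rho = the configured momentum 0.9, eps 1e-6, *no* learning-rate multiplier
— the original method defines its own step scale, and scaling it by the
configured 0.005 would make updates ~200x smaller than intended), Adam
(uses the configured learning rate), and plain SGD with optional momentum
(the literal `W <- W - eta dE/dW` update when momentum is 0). Training is
mini-batch with per-epoch loss and running training accuracy recorded;
early stopping (default patience 10 on a 1e-4 loss improvement, or three
consecutive epochs at >= 99.9 % training accuracy) truncates the recorded
history. Training is deterministic for a fixed seed and thread count. A
grid-search helper sweeps config overrides over the documented ranges
(layers 3–8, filters 16–128, kernels 1–7, batch 32–128, learning rate
0.0005–0.01, momentum 0.1–0.9, dropout 0.25–0.5, epochs 50–200), breaking
accuracy ties toward fewer parameters.

## Evaluation

LOSO: one fold per subject; augmented epochs never enter test folds
(asserted in code). Within each training fold, channel scores and window
rankings are re-fit from scratch; per-channel standardization uses training
statistics only. Trial predictions average window probabilities. Metrics
per fold: accuracy, precision, specificity, recall, F1 (index 1 = positive
class for binary tables — `high` when the classes are low/high — and macro
one-vs-rest for 3 classes; zero denominators yield 0 with a flag), plus a
p-score: a two-sided paired t-test between per-trial mean DE of the
selected windows and of all windows (identical vectors give the defined
limit p = 1 with a warning; the quantity is reported verbatim, without a
quality judgement — the originating literature reads higher p as better,
which is a non-standard interpretation we do not adopt). Cohen's kappa is
computed on the pooled confusion matrix (kappa = 0 with a warning when
chance agreement is 1). The selection-cost index

    CT = (1/F_T) * sum_c [ C_P ln(f_v) + (1 - C_P) ln(1 - f_v) ]

is evaluated literally as a dimensionless quantity (always <= 0 for
f_v in (0,1)); wall-clock timing is deliberately not an evaluation surface.

## Benchmark study conditions

`emoselect.benchmarks` pins the synthetic study conditions used by the
test-bench and by `scripts/acceptance.py`:

* **Learnability benchmark** — 8 subjects x 20 trials, 8 channels at
  128 Hz, 6-s trials; 4 informative channels, 2 informative windows;
  band-separated classes (low: theta burst x2.0; high: alpha x2.5 + beta
  x2.0). The pipeline selects 3 channels and 2 windows and trains the
  default CNN for up to 18 epochs — this benchmark converges well before
  the production default of 100 epochs, and the shorter budget keeps a full
  LOSO run at desk scale. The label-shuffled control runs all 8 folds with a
  10-epoch budget (calibration needs breadth across subjects, not
  convergence); chance bounds are two-sided 99 % binomial intervals at the
  trial count.
* **Planted-recovery conditions** — 6 subjects x 12 trials, 16 channels,
  60-s trials (30 windows); 10 informative channels and 20 informative
  windows, strong contrast; recovery demanded in >= 90 % of 20 seeds.
* **Augmentation-trend study** — a smaller 5 x 16 geometry with a reduced
  classifier (filters (16, 8, 8, 8), 25 epochs) used identically in both
  arms, isolating the effect of ratio-1.0 augmentation over 5 seeds.
* **Null calibration** — a pure-noise 4 x 8 geometry; end-to-end accuracy
  must sit inside the binomial chance band.

## Numerical choices and degenerate inputs

* Equal-frequency bin edges use linear-interpolated quantiles with
  duplicate edges dropped; constant channels collapse to one bin and are
  flagged.
* Plug-in MI treats zero-probability cells as contributing zero; joints are
  validated (non-negative, sum 1 within 1e-9).
* All-zero windows have differential entropy -inf and are excluded from the
  ranking with a warning.
* EDF files are 16-bit; the round-trip error bound is
  `(phys_max - phys_min)/65535` per channel. Fixture CSVs are written with
  `%.17g` and parsed with round-trip float precision, so they are
  bit-exact.
* Montage coordinates come from the bundled standard 10–20 table of the
  MNE library at run time; matching is case-insensitive and unknown
  electrodes are reported as unresolved rather than fatal.

## Known limitations

* The synthetic generator's simplifications (above) mean accuracy numbers
  here say nothing quantitative about DEAP/MAHNOB/SEED performance.
* The NumPy CNN is single-threaded BLAS-bound; it is meant for small
  problems, not GPU-scale training.
* The differential-entropy channel score depends on the binning resolution; scores (and
  hence the absolute meaning of the 1.5 threshold) are comparable only
  within a fixed binning scheme. The identity of the canonical 10 common
  channels is configurable and not asserted.
* Product-mode graph EMD solves one sparse system per envelope; it is
  practical for tens of channels and a few thousand samples per epoch.
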