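# Methods

## The scoring model

Each 20-s epoch (or an epoch plus its predecessor, 40 s) is rendered
as one square grayscale image: the top half is the raw EMG trace
rasterized against a fixed vertical range, the bottom half is the
epoch's EEG power spectrum — squared DFT magnitudes at integer
frequencies 1–20 Hz, one column per non-overlapping 1-s bin,
min–max-normalized per image to [0, 1], low frequencies at the
bottom. A VGG-style CNN (five blocks of conv3×3 → conv3×3 →
maxpool2×2, then dense 128 → dropout → dense 96 → dense 64 → dropout →
softmax) maps images to wake/NREM/REM probabilities. The two-epoch
variant labels each image by its latter epoch, giving the network
one step of temporal context without recurrence; the record's first
epoch has no predecessor and is dropped rather than padded.

Spectral choices the text of the problem leaves open, fixed here: FFT
bins are rectangular-windowed, non-overlapping 1-s segments, so an
integer-Hz tone is recovered leakage-free and the per-bin Parseval
identity is exact — this makes the spectral front end checkable
against a directly coded DFT oracle to 1e-9 relative. Normalization
is per-image (not per-row, not per-dataset), keeping each image
self-contained; a constant matrix maps to all zeros. An optional
log-power flag exists but is off by default. Rendering is pure array
painting: no plotting toolkit, no axis decorations (they are constant
across images and carry no class information), bit-identical across
platforms. The EMG axis is fixed at 6 global EMG standard deviations
so muscle tone is comparable across images.

## Class imbalance and the WGAN-GP

Mouse sleep is roughly 10:10:1 wake:NREM:REM by epoch, which
depresses REM recall, most severely on tiny training sets. Two
balancing strategies are implemented behind one dataset surface:
plain duplication of minority images, and appending fakes from a
per-stage WGAN-GP. The generator projects a 100-dim latent vector to
a 4×4 seed map and doubles resolution per upsample+conv block (7
blocks reach 512 px, 5 reach 128 px, 4 reach 64 px); the critic
mirrors this with stride-2 convolutions ending in one linear unit.
Training uses the canonical recipe: λ=10 gradient penalty at uniform
interpolates, 5 critic steps per generator step, Adam(β₁=0.5, β₂=0.9)
with two-timescale learning rates (critic 4e-4, generator 2e-4).
Weights are initialized DCGAN-style, normal(0, 0.02): both networks
start near-flat, so the critic's input-gradient norms grow from ~0
under adversarial pressure while the penalty pulls them toward 1 —
the training traces record the penalty and the gradient-norm
deviation so this dynamic is observable. The penalty's weight
gradient requires differentiating through an input gradient; the
engine supports this via `create_graph=True`. The norm inside the
penalty carries a 1e-12 stabilizer, so a constant critic yields
λ(1−1e-6)² rather than exactly λ.

Generated images are flagged `generated`, barred from evaluation sets
by construction, and evaluation is always split by animal, never by
epoch. Equalize-mode appends fakes until the minority count reaches
the largest other class; times-k mode appends (k−1)× the real count.
No fake-image rejection filter is applied; the generator's output
diversity is unfiltered.

## The post-filter

Predicted hypnograms occasionally contain short REM bouts inside long
wake runs — atypical, since REM is entered from NREM. The shipped
rule relabels every maximal REM run of length ≤ max_bout (default 1
epoch, the most conservative reading of "short") whose immediate left
and right neighbours are both WAKE; runs touching a boundary are left
alone. The rule is idempotent, conserves NREM counts, and is verified
exhaustively against a run-enumeration oracle on all 3⁸ length-8
hypnograms. It helps only when predictions are already accurate; on
poor labels it can remove genuine REM, so it is optional and separate.
No minimum surrounding wake-run length is imposed. Additional rules
can be composed via `apply_rules`.

## Scoring

All scores derive from the 3×3 confusion matrix: accuracy = trace/N;
per-class precision/recall with F1 defined as 0 when both are 0 (REM
can be absent from short stretches); macro-F1 unweighted;
κ = (p_o − p_e)/(1 − p_e) with p_e from the marginal products, set to
1 in the degenerate perfect-agreement case. The reporting unit is the
animal: scalar metrics are averaged per subject with equal weight,
and the pooled scores over the summed matrix are reported alongside —
the two differ whenever marginals differ across subjects, which the
tests demonstrate on a constructed pair.

## Synthetic data: what it emulates and what it does not

The generator exists so the full pipeline is testable offline.

* **Hypnograms** come from a first-order Markov chain over
  (WAKE, NREM, REM). The default matrix — rows
  W: (0.93, 0.07, 0), N: (0.04, 0.925, 0.035), R: (0.30, 0.05, 0.65) —
  was chosen analytically: REM is reachable only from NREM
  (P(W→R)=0), the stationary distribution is exactly 10:10:1
  (π_R(1−0.65) = 0.035·π_N and 0.07·π_W = (0.04+0.30·0.1)·π_N), the
  mean REM bout is 1/0.35 ≈ 2.9 epochs (~1 min), and wake/NREM bouts
  average ~14 epochs (~4.5 min), consistent with polyphasic mouse
  sleep cycling over minutes. Real bout-length distributions are
  heavier-tailed than the geometric bouts a Markov chain produces;
  no claim beyond the ratio and connectivity is intended.
* **EEG** per epoch is a fixed comb of sinusoids per band (delta
  1.5/2.5/3.5 Hz, theta 6.5/7.5/8.5 Hz, broadband 2–17 Hz) with
  per-epoch random phases and ±0.3 Hz jitter, weighted per stage
  (NREM delta-heavy: 25 µV band weight vs 6 theta; REM theta-heavy:
  20 vs 4; wake mixed), plus 1/f background noise. A band weight w
  contributes expected band power w²/2, giving closed-form
  expectations for oracle tests. **EMG** is zero-mean noise scaled
  per stage (wake 30, NREM 8, REM 4 µV RMS).
* One master seed drives everything through counter-based sub-seeding
  (one stream per epoch), so records are reproducible epoch by epoch
  under slicing.
* Deliberately absent: movement/chewing artifacts, electrode drift,
  spindles/phasic events, inter-animal variability, non-geometric
  bout lengths. Default sampling is 128 Hz (exact 1-s FFT bins) at
  20-s epochs. Synthetic stages are far more separable than real
  recordings — a depth-2 decision tree on delta/theta ratio + EMG RMS
  already scores ≥ 95 % — so passing benchmarks here demonstrates
  that the pipeline's machinery is correct and that its components
  interact as designed, not that these accuracy figures transfer to
  real mice.

## The numpy neural-network engine

No deep-learning framework is part of the dependency set; the
classifier and GAN run on `sleepscore.nn`, a small tape-based
reverse-mode autodiff over numpy arrays. Convolution is im2col + GEMM
(NHWC layout); every primitive's vector-Jacobian product is written
in terms of the same primitives, so gradients are differentiable
(double backprop for the gradient penalty). VJPs of exp/sqrt/
sigmoid/tanh recompute the forward value rather than capturing their
output node — capturing it would create closure reference cycles that
hold whole graphs until the cyclic GC runs. Finite-difference tests
cover first- and second-order gradients of every primitive used.

## Desk-scale profiles

Training sizes were chosen so the whole suite runs on one CPU:

* Benchmark: 6 synthetic subjects × 333 epochs (~2000 epochs), 64 px
  1-epoch images, halved filters (8, 16, 32, 64, 64), Adam lr 1e-3,
  batch 32, ≤ 12 epochs, early stopping patience 3 (the full-scale
  profile is 180 px, filters (16, 32, 64, 128, 128), lr 1e-4). Three
  subjects train, one is the early-stopping validation subject, two
  are held out for scoring.
* Augmentation experiment: 5 subjects × 250 epochs (2 train / 1
  validation / 2 held out), fixed 5 training epochs per variant. The
  REM WGAN-GP trains at 64 px for 300 steps on a corpus of 200 REM
  epochs synthesized by the same stage-conditioned process (held-out
  subjects contribute nothing to it) and supplies the equalizing
  fakes; 300 steps is where the fake/real spectral-profile
  correlation stabilizes above 0.5 at this scale.
* GAN default resolution is 512 px as a configuration ceiling;
  training at 512 needs GPU-class hardware and is not exercised by
  the tests.

## Known limitations

Single-channel EEG + EMG only; three stages (the softmax width is
configurable, but no 5-stage human PSG head is provided); no artifact
injection or rejection; no conditional GAN (one generator per stage);
no HMM/probabilistic smoothing; EDF input requires the optional `mne`
dependency and real EDF files are not part of the test fixtures.
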