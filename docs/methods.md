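# Methods

`crossmove` asks whether person identity expressed in one movement's 1D
signal survives translation into another movement's signal. It couples
three components: a synthetic movement simulator with a ground-truth
shared individuality factor, a class-conditioned cycle-consistent
adversarial translation model for 256-sample movement vectors, and an
SVM identification protocol scored against a zero-rule chance floor.

## The translation model

Two generators are trained jointly, G: (X, Z) → Y and F: (Y, Z) → X,
where X and Y are two movement domains (e.g. walking and running
vertical ground reaction force, or handwriting pen pressure) and Z is a
one-hot encoding of the subject. Two patch discriminators D_X and D_Y
score realism. The objective is

    L = L_GAN(G, D_Y) + L_GAN(F, D_X) + λ_CYC · L_CYC + λ_ID · L_ID

with λ_CYC = 10, λ_ID = 5. L_GAN is the log-loss
E[log D(real, z)] + E[log(1 − D(G(·), z))]; generators minimize the
non-saturating form −E[log D(fake, z)] (the saturating form stalls
early training; the logged values always use the log-loss form above,
so the loss log is interpretable as the printed objective). L_CYC is
the mean absolute error of both reconstruction cycles
F(G(x,z),z) ≈ x and G(F(y,z),z) ≈ y; L_ID penalizes changing inputs
already in the target domain, |G(y,z) − y|₁ + |F(x,z) − x|₁.

Conditioning: the one-hot subject vector is tiled along the time axis
and concatenated to the input as K extra channels, for generators and
discriminators alike. Discriminators see only correctly matched
(signal, class) pairs by default. A matching-aware option
(`TrainingPlan.class_mismatch_negatives`) additionally scores real
signals with a deliberately wrong class as fake; in our ablations at
small training budgets it slowed realism learning more than it
sharpened subject consistency, so it is off by default.

### Architectures

Generator (1D encoder / transformer / decoder): a kernel-7 stride-1
convolution to `base_filters` channels, two kernel-3 stride-2
downsampling convolutions doubling the channels, nine residual blocks
(two kernel-3 convolutions each), two nearest-neighbour ×2 upsampling +
kernel-3 convolution stages halving the channels, and a kernel-7
output convolution with a sigmoid, since the data live in [0, 1]. All
convolutions use TensorFlow-style "same" padding and weights drawn from
N(0, 0.02) with zero biases. Affine-free instance normalization
follows every convolution except the last. Upsampling is
resize-then-convolve rather than transposed convolution; it avoids
checkerboard artifacts and keeps the layer arithmetic simple.

Discriminator: a 70×1 PatchGAN — kernel-4 convolutions with filter
progression 64→128→256→512→1 and strides 2,2,2,1,1, leaky-ReLU slope
0.2. Each output unit scores one 70-sample receptive field; the map is
a 32-long score vector for a 256-sample input.

Normalization in the discriminator is per-time-step **channel**
normalization (mean/variance across channels at each sample, after
every hidden convolution except the first). Two facts force this
choice. First, with the pinned N(0, 0.02) initialization and no
normalization at all, activations shrink geometrically with depth and
the discriminator barely trains. Second, instance normalization (the
reference PatchGAN's choice) couples every time step through the
temporal mean and variance, which destroys the defining property of a
patch discriminator — that each score depends on exactly its 70-sample
window (we verify that property by gradient probing). Channel
normalization rescales activations without temporal coupling, so the
receptive field stays exact and training is stable.

### Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7, the Keras convention) for all
networks. The discriminators use a constant learning rate of 2e-4.
The generator learning rate depends on the domain pairing, expressed
relative to the plan's epoch budget T:

* locomotion pair — 2e-4 for the first T/2 epochs, then linear decay
  to 0;
* writing-involving pair — 2e-4 × batch_size for the first T/4 epochs
  (0.0128 at the reference batch of 64), 2e-4 × √batch_size for the
  next T/4 (0.0016), then linear decay of that value to 0.

Per batch, both discriminators take one step on real/fake
cross-entropy (`TrainingPlan.d_steps` allows several discriminator
steps per generator step), then G and F take one joint step on the
full objective; both mapping directions share the same four networks.
A least-squares adversarial variant (`gan_loss="least_squares"`,
scores regressed to 1/0 without a sigmoid) is available but off by
default, the log form being the printed objective. When the two
domains differ in size, each epoch covers the larger domain once and
resamples the smaller with replacement. All loss components are logged
per epoch in their evaluation form, and the generator pair from the
epoch with the lowest epoch-mean total objective is the selected
checkpoint. Training is a pure function of the data and the plan's
seed (batching, initialization and resampling all derive from it).

The model runs on a small reverse-mode automatic-differentiation
engine written in-package on numpy (`crossmove.autodiff`): strided 1D
convolution via per-offset matrix products, the two normalizations,
pointwise nonlinearities, nearest-neighbour upsampling and the scalar
loss reductions. Gradients of every operation are property-tested
against central finite differences (agreement ~1e-10 relative).

## The synthetic cohort

Because no recordings are distributed, the package ships a simulator in
which cross-movement individuality is true by construction and every
downstream claim is testable against ground truth. Each subject owns a
latent vector θ ∈ R⁴ ~ N(0, I) plus a body mass (68 ± 9.3 kg) and a
left/right asymmetry factor (1 ± 0.05). Each domain owns a linear
read-out `params = clip(b + A·θ + σ_trial · τ · ε)` onto its waveform
parameters, where τ is the between-subject SD of each parameter
(rows of A are unit directions scaled by τ) and σ_trial = 0.3 sets the
within-subject scatter at 30% of the between-subject spread — trial
variation clearly smaller than subject separation, as identification
studies presuppose.

Waveforms. Walking stance: a shape-preserving (PCHIP) curve through
(0, 0), (t₁, amp₁), (0.5, valley), (t₂, amp₂), (1, 0) — the classic
double peak at ~1.1 body weight with a mid-stance valley — sampled at
100 Hz over a stance of ~0.64 s and placed left-then-right with half a
stride period offset; the right foot is scaled by the asymmetry
factor. Running stance: early impact peak (~10% of stance, ~1.6 BW), a
dip, a dominant active peak (~45%, ~2.4 BW), shorter stance (~0.30 s)
and an aerial phase. Speed conditions (85/100/115% of preferred speed)
shorten durations proportionally and raise amplitudes mildly.
Handwriting: four Gaussian pressure humps (the W strokes, individual
heights ~1800–2200 device units of 4095) on a positive pen-down
baseline, with subject-specific stroke widths and three independent
inter-stroke gaps; pen-up samples are exactly zero. Six instructions
scale amplitude and duration (e.g. "bigger": ×1.3 amplitude, ×1.25
duration). Optionally the letter connects to a smaller 'e' through an
explicitly symmetric parabolic pressure valley whose unique minimum
sample is recorded as the ground-truth letter end. Stroke width is
capped at min(gap)/3.4 so the W is always legible as four humps.

What the simulator does not emulate: multi-segment kinematics, EMG,
3-component forces, pen x/y trajectories, drift or fatigue across a
session, sensor noise beyond parameter scatter, and any nonlinear
latent-to-waveform relationship. Passing the end-to-end tests
therefore shows the pipeline recovers a linear, low-dimensional shared
individuality under clean conditions — not that it would do so on real
recordings.

## Preprocessing

Locomotion: stance = maximal run of samples with force ≥ 50 N (runs
touching the recording boundary are dropped as incomplete); each left
contact pairs with the earliest right contact starting after it,
unpaired contacts are dropped; each contact is divided by body weight
(mass × 9.81 m/s²), linearly resampled to 128 points, and the pair is
concatenated left-then-right. Scaling to [0, 1] defaults to *global*
statistics computed on the translation-model training partition only
(preserving between-trial amplitude information that carries
identity); per-trial scaling is available.

Handwriting: first-order Savitzky–Golay smoothing with window 13
(identical to a 13-point moving average on interior samples; edges by
polynomial fit to the terminal window), with the pen-up zero mask
re-applied after filtering so smoothing never creates pen-down
samples; first-letter extraction keeps the first pen-down run,
requires at least four prominent strokes (otherwise the trial is
discarded as not written in one piece) and cuts at the pressure
minimum between the fourth and a fifth stroke when a connected 'e' is
present; then linear resampling to 256 points, z-standardization with
the trial's own statistics, and per-trial scaling to [0, 1].

## Identification protocol

Each domain's trials are split 90:10, stratified per subject (with a
largest-remainder allocation across conditions, so the held-out
condition mix mirrors the training mix). Baseline identification
trains on the 90% partition and tests on the 10%. For translation:
the model trains on the 90% partitions of both domains, the held-out
10% of the source domain is translated, and an SVM trained on the
held-out 10% originals of the target domain classifies the translated
trials — translation training, generation input and classifier
training are mutually disjoint.

The SVM search covers four kernels (linear, RBF, sigmoid, polynomial
degree 3; kernel coefficient 1/(n_features · Var(X))) and costs
C = 2⁻⁵, 2⁻⁴·⁷⁵, …, 2¹⁵ (324 configurations), 5-fold stratified
cross-validation maximizing mean fold accuracy, ties broken toward
smaller C and earlier kernel; the winner is refit on all training
data. Training rows are brought into a canonical sort first, so the
search result cannot depend on collection order. Reports carry the
confusion matrix, accuracy and macro-averaged precision/recall/F1 in
percent, the zero-rule baseline ZRB = 100 · (modal class count)/(all
training trials), and the F1/ZRB ratio.

## Problem sizes, seeds and runtime

The package's reference experiment (shipped as
`configs/scaled_down.yaml`, also exercised by the acceptance tests)
uses 5 subjects × 80 trials per domain, 25 epochs at batch 16, a
generator with 8 base filters and 3 residual blocks and a
discriminator with 32→256 filters (half the reference width, receptive
field unchanged at 70). It completes in roughly a quarter hour on one
CPU core. `configs/full_scale.yaml` records the full-scale settings
(17 subjects, ~628/963/59 trials per subject, 200 epochs, batch 64,
full widths) for use on faster hardware. A single master seed fans out
to per-stage seeds through `stage_seed(master, stage, *indices)`
(SeedSequence-based), so any stage can be rerun in isolation and the
whole experiment is reproducible to the byte.

## Known limitations

* The adversarial game at small epoch budgets is sensitive to the
  generator/discriminator capacity balance; the shipped scaled-down
  widths were selected by ablation (see the normalization discussion
  above) and other ratios can fail to transfer identity even when
  cycle losses look healthy.
* The boosted writing-pair schedule multiplies the generator rate by
  the batch size while the discriminator rate stays at 2e-4. At
  compressed epoch budgets this collapses the adversarial balance
  within the first schedule phase, and checkpoint selection by the
  lowest epoch-mean generator objective then prefers early,
  reconstruction-dominated epochs (the logged adversarial terms reward
  a weak discriminator). In the reference scaled-down experiment the
  locomotion pair transfers identity at several times the chance
  floor, while the writing-involving directions remain near chance at
  the selected checkpoint and reach at most ~1-2.7x chance with
  last-epoch generators and extra discriminator steps. Both the
  schedule and the discriminator rate are fixed parts of the training
  recipe, so this is reported as a limitation of the recipe at small
  scales rather than patched around; at the full 200-epoch scale the
  annealed second half makes the selection rule benign.
* The writing z-standardization uses trial statistics (the dataset
  alternative is not implemented); the locomotion [0, 1] scaling scope
  (global vs per-trial) is configurable because the convention is
  ambiguous in the field.
* `Generator.classes`/`target_domain` are attached at training time;
  translating with an untrained generator object is rejected rather
  than silently unconditioned.
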