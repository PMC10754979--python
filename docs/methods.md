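# Methods

## The decoding problem

Motor imagery (MI) modulates sensorimotor EEG rhythms: imagining a movement
produces band-limited power changes (ERD/ERS) over motor cortex. This
package decodes **six** upper-limb imagery classes — hand open, hand close,
forearm supination, forearm pronation, elbow flexion, elbow extension — from
epoched multichannel EEG (trials × channels × samples, 500 Hz at study
scale; 16- or 61-channel 10-20/10-10 montages).

## The network

An epoch enters as a `1 × n_channels × n_samples` map (feature channels ×
space × time). Three stages follow:

**Temporal extractor (TDFE).** A 1×7 temporal stem convolution (+BN+ReLU)
widens to the first feature width, then three *parallel residual blocks*
with 1×1 and 1×3 temporal kernels at widths 64 → 128 → 256. Each branch is
`ReLU(BN(conv(x)) + skip(x))`; branches are summed elementwise. The skip is
the identity, or a 1×1 projection when channel counts change. Setting
`tdfe_residual=False` removes the skips (the "NR" ablation);
`use_tdfe=False` removes the stage.

**Spatial extractor (SDFE).** Three parallel residual branches with 1×1,
3×1, 5×1 *spatial* kernels at width 512, summed, then a 2:1 spatial
reduction: max-pooling (default) or a stride-2 spatial convolution (the
"NP" ablation variant).

**Temporal decimation.** Before the parallel head the temporal axis is
average-pooled with the smallest integer stride that brings it to at most
`w_max` columns (default 64, i.e. 1500 → 62 columns at stride 24). The
head forms W×W similarity matrices per feature channel; at the raw W = 1500
those matrices would be unmanageable in time and memory, and nothing in the
head requires full temporal resolution.

**Time-spatial parallel head (TSPFE).** Per feature channel, the H'×W'
slice X is mapped through a shared orthogonal P and diagonal D:

    Q = (P X)ᵀ D (P X)

`P = exp(A − Aᵀ)` with A an unconstrained learnable square matrix, so P is
*exactly* orthogonal at every training step — the decorrelation property is
enforced by construction, not by a penalty. `softmax` over the columns of Q
and of Qᵀ yields two stochastic attention maps; `F_c = X·softmax(Q)` and
`F_r = X·softmax(Qᵀ)` are gated and concatenated (channel count doubles).
Global average pooling over space and time, a fully connected layer and a
softmax give six class probabilities; the loss is weighted cross-entropy
(weights default to 1; the protocol keeps classes balanced).

### Design choices in the head

- **Shared (P, D) across feature channels.** A per-channel parameterisation
  would add `C·H'²` parameters with no clear benefit; "processed per
  channel" is realised as per-channel application of shared weights.
- **Softmax axis.** Column-normalisation for Q and for Qᵀ; transposing Q
  exactly swaps the two branches (a tested invariant).
- **Depthwise ReLU gate, identity init.** The gate is
  `F ⊙ ReLU(w_c·F_c + b_c)` with one scalar weight and bias per feature
  channel, initialised to the identity (w=0, b=1), and σ is ReLU (not the
  conventional sigmoid). A single gate channel shared across all features
  was tried first and rejected: because post-ReLU feature maps are
  non-negative, `ReLU(w·F + b) = 0` over the whole map is an *absorbing*
  training state (zero gradient, zero head output, loss pinned at ln 6),
  and under ADAM's scale-free updates the shared gate reliably random-walks
  into it. The depthwise gate confines any closure to single channels. The
  two branches carry separate gate parameters.
- **Zero-initialised classifier layer.** Training then starts at exactly
  the uniform prediction (loss ln 6), so early gradients discriminate
  between classes rather than shrink large random logits — the shrink
  direction is what pushes gates shut.

## Training protocol

Per subject: stratified 70/30 train/test split, re-drawn with a fresh seed
for each of 10 repetitions; accuracy (argmax, ties to the lowest class
index) averaged over repetitions, reported mean ± sample SD. ADAM with
β₁ = 0.9, β₂ = 0.999, initial rate 10⁻³ dropped ×0.1 every 500 epochs, up
to 1000 epochs, mini-batches of 64, and gradient clipping — each
learnable's gradient is clipped to L2 norm 1 individually (the
per-learnable reading of a "gradient threshold"; global-norm clipping
throttled every step and slowed optimisation several-fold in practice).
Inputs are z-scored per trial and channel along time (zero-variance
channels map to zeros); batch normalisation keeps running statistics, so
evaluation is deterministic bit-for-bit.

Method comparisons use a pooled-variance two-sample t-test on the partition
accuracies (two-sided, significance 0.05). Chance level on balanced
six-class data is 1/6 ≈ 16.67%.

### Desk scale

The study-scale configuration (widths 256/512, 1500 samples, 1000 epochs)
is retained verbatim as the "paper profile", but the bundled experiments,
tests and acceptance runs use a reduced **desk configuration** chosen so
the full wiring is exercised on one CPU core in minutes: 16 channels,
128 samples (1 s) at 128 Hz, widths (12, 16, 24) / 32, `w_max = 32`, ADAM
at 5·10⁻³ with mini-batches of 16, a ×0.1 drop at epoch 30 and ≤ 50
epochs. Gradient clipping is applied per learnable (each parameter
array's gradient clipped to L2 norm 1); clipping the *global* norm
throttled every step at this scale and stalled optimisation. Narrower
desk widths proved capacity-limited (they fit the training set yet
plateaued near 73% test accuracy; the chosen widths reach ~95% under the
same data and seed), so the desk widths are the smallest that generalise,
not the smallest that train. All shape arithmetic, ablation switches and
the attribution pipeline are identical to study scale.

Standard desk problem sizes: learnability uses 60 trials/class (strong
effect 2.5 vs null 0). The head-ablation comparison is *paired at full
scale*: the no-head variant trains on the identical partition with the
identical seed and epoch budget as the learnability run, and the two test
accuracies are compared directly. Sample size matters here — with 16–30
trials/class both arms hover near chance and the ordering is noise,
whereas at 60 trials/class the gap is decisive (the full network reaches
~90–96% where the no-head variant stays near 45–50%); running many paired
partitions at that scale does not fit a CPU-minutes budget, so one
well-powered paired partition replaces several underpowered ones. The
bundled acceptance script uses 50 trials/class × 40 epochs for the same
comparisons to keep its total runtime near a quarter hour.

## Synthetic MI-EEG

The generator makes every stage testable without recordings. Each trial is

    x = background + effect_size · class_signal  (+ optional 50 Hz mains)

- **Background**: 1/f^x noise (default x = 1), synthesised in the frequency
  domain with Gaussian coefficients shaped by f^(−x/2), unit SD per channel
  — the canonical EEG spectral envelope.
- **Class signal**: a random-phase narrowband process (white noise through
  a zero-phase 4th-order Butterworth, unit SD) confined to the class's
  frequency band, injected *only* on the class's target electrodes and
  scaled by `effect_size` (amplitude relative to background SD, so
  effect_size 1 means in-band signal power equals total background power on
  that electrode). A pure-tone mode replaces the noise process with a fixed
  in-band sinusoid (δ 2 Hz, θ 5 Hz, α 10 Hz, β 20 Hz) with random phase per
  trial, used for attribution sanity checks.
- **Signatures**: six distinct (electrode, band) pairs. The default table
  places each class on a *different spatial-pooling row* (C3, P7, O1, F7,
  F3, T7 in the 16-channel board order): the spatial extractor halves
  electrode resolution by pooling adjacent channel-index pairs, so classes
  sharing a pooled row would be indistinguishable on the reconstructed
  scalp map regardless of how well the network separates them.
- Labels are exactly balanced (trials_per_class per class per subject) and
  the seed fully determines the output. Study-scale profiles reproduce the
  reference cardinalities: 10 × 6 × 300 = 18,000 epochs (16 channels) and
  15 × 6 × 60 = 5,400 (61 channels).

**What the generator does not emulate:** artifacts (EOG/EMG), inter-subject
and inter-trial nonstationarity, volume-conduction mixing across
electrodes, cue-locked temporal structure (no claim of cue alignment is
made; epochs are stationary within the window). Passing tests therefore
demonstrate that the implementation can discover band-power/spatial
structure when present — not that the reported study-scale accuracies on
recorded EEG are reproduced.

## Frequency-band attribution

For a trained classifier: (1) keep only correctly classified test trials
(accuracy on that subset is 1 by construction); (2) band-pass them into
δ 0.5–3, θ 3–7, α 7–13, β 13–200 Hz; (3) re-extract features at a tap point
(default: the parallel-head output; a pre-head tap supports before/after
comparisons); (4) average feature maps per class; (5) collapse to one
mean-|activation| score per pooled spatial row and linearly interpolate
back onto the electrode montage; (6) render as an interpolated disc image.

Two details make the localization readable; both were settled by
measurement on pure-tone data with known signatures:

- **Normalize broadband, then filter.** The per-trial z-score is part of
  the model's input convention, so the banded inputs are band-passed
  versions of the *normalized* trials. Re-standardizing each banded
  channel instead would force every channel to unit variance and erase
  precisely the cross-channel amplitude pattern the scalp map displays
  (doing so drops the localization check from 6/6 to 3–4/6, with the low
  bands failing first).
- **Tap and contrast.** Which layers constitute "the feature extractor"
  is a genuinely open choice. For electrode localization the built-in
  sanity check taps the temporal-extractor output: temporal-only stages
  are spatially equivariant, so per-row activation energy maps one-to-one
  onto electrodes there, and on pure-tone data the in-band peak lands on
  the injected electrode for all six classes. Downstream the picture
  degrades monotonically — the spatial convolutions smear the pattern over
  ±2 neighbouring rows (typically one class slips to an adjacent row) and
  the head's gating blurs it further — so deeper taps are kept for
  before/after comparisons, not for localization claims. The peak is taken
  on the class-contrast map (class map minus the across-class mean within
  the band), which cancels the shared background response — without it the
  1/f background, strongest in δ and θ, swamps the class-specific bump.

β's upper edge (200 Hz) reflects wideband acquisition and is kept verbatim
when the sampling rate allows; otherwise it is clipped to 0.45·fs with a
warning. The default filter is a zero-phase 4th-order Butterworth (flat
passband, no phase distortion of activations). Note that for a band as
narrow as δ, *any* smooth IIR filter keeps appreciable energy just outside
the nominal edges (measured in-band fraction ≈ 0.79 for δ at fs 500, and
raising the order does not fix it); a `brickwall` mode (zero-phase FFT
masking) is provided where exact spectral confinement matters more than
time-domain smoothness, and the band-partition property is stated there.

The montage uses a schematic azimuthal projection of the 10-20/10-10 grid
(vertex at the origin, outer 10% ring at radius 0.8): positions are derived
from the electrode name's row and lateral index, which is sufficient for
unique, well-spread scalp coordinates without a 3-D head model.

## Numerical choices

- Single precision for network computation; the orthogonal generator A and
  diagonal D live in float64 (the matrix exponential and its Fréchet
  derivative are computed there) and are cast into the feature dtype inside
  the graph.
- `‖PᵀP − I‖∞ < 1e-5` holds after any number of optimizer steps by
  construction of the exponential-map parameterisation (tested).
- Cross-entropy on probabilities clamps the true-class probability at
  1e-12 with a warning; training uses the equivalent log-softmax form.
- Argmax ties resolve to the lowest class index; "SD" in reports is the
  sample standard deviation (ddof = 1) over partitions.
- Zero pooled variance in the t-test resolves analytically: (t, p) = (0, 1)
  for equal means, (±∞, 0) with a warning otherwise.
- Average-pool decimation uses non-overlapping windows equal to the stride;
  a trailing remainder shorter than the stride is dropped.

## Known limitations

- Study-scale training (256/512 widths, 1500 samples, 1000 epochs per
  subject per partition) is out of reach of the bundled CPU implementation;
  the desk configuration demonstrates correctness and learnability, not the
  study-scale accuracy figures.
- The attribution algorithm band-passes (retains) each band rather than
  occluding it; the per-band maps show what the classifier sees *within*
  a band, and bands are analysed independently.
- The spatial interpolation from pooled rows back to electrodes is an
  interpretive choice; adjacent electrode pairs within one pooled row are
  not distinguishable.
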