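# tspnet

Six-class upper-limb motor-imagery EEG decoding with a time-spatial
parallel convolutional network, plus the full experimental harness around
it: a synthetic MI-EEG generator, the stratified-repetition training
protocol with ablation variants, and a frequency-band attribution pipeline
that renders scalp topographies of what the classifier uses.

**Who it is for.** BCI researchers who want a transparent, dependency-light
reference implementation of this architecture family that runs end to end
on a laptop CPU — trainable, inspectable, and testable without downloading
any EEG corpus.

## The model

An epoch (channels × samples) passes through three stages:

1. **Temporal extractor** — a 1×7 temporal stem convolution, then three
   parallel-residual blocks (1×1 and 1×3 temporal kernels, widths
   64→128→256), `ReLU(BN(conv(x)) + skip)` per branch, branches summed.
2. **Spatial extractor** — three parallel residual branches with 1×1 / 3×1
   / 5×1 spatial kernels at width 512, summed, then 2:1 spatial
   max-pooling (or a stride-2 convolution in the "NP" ablation variant).
3. **Time-spatial parallel head** — per feature channel X (space × time),

       Q = (P X)ᵀ D (P X),   P = exp(A − Aᵀ)

   with P exactly orthogonal by construction and D diagonal, both learned.
   Column-softmax of Q and of Qᵀ give two attention maps; X·softmax(Q) and
   X·softmax(Qᵀ) are ReLU-gated, concatenated, pooled (GAP), and classified
   by a softmax layer under cross-entropy.

Ablation switches reproduce the named variants (`TSPNet-w/o-TDFE`,
`TSPNet-TDFE-NR`, `TSPNet-w/o-SDFE`, `TSPNet-SDFE-NP`, `TSPNet-w/o-TSPFE`).
The network and its training loop run on a compact NumPy reverse-mode
autodiff engine bundled with the package (`tspnet.nn`, `tspnet._autograd`)
— no deep-learning framework required.

## Worked example

Generate a small synthetic session, train the desk-scale network, and ask
*where* on the scalp, and in which frequency band, the classifier finds
its evidence:

```python
import tspnet

# six classes, each a band-limited oscillation on one electrode
cfg = tspnet.SynthConfig(n_subjects=1, trials_per_class=60, fs=128.0,
                         n_samples=128, effect_size=2.5, seed=11)
epochs = tspnet.generate_epoch_set(cfg)

net = tspnet.desk_config(n_input_channels=16, n_samples=128)
train, test = tspnet.stratified_split(epochs, seed=0)
model, losses = tspnet.train_model(train, net, tspnet.desk_profile(), seed=0)
print(f"test accuracy {tspnet.evaluate(model, test):.3f}")

# attribution sanity on the pure-tone variant of the same classes
tone_cfg = tspnet.SynthConfig(n_subjects=1, trials_per_class=60, fs=128.0,
                              n_samples=128, effect_size=2.5,
                              pure_tone=True, seed=13)
tone_train, tone_test = tspnet.stratified_split(
    tspnet.generate_epoch_set(tone_cfg), seed=0)
tone_model, _ = tspnet.train_model(tone_train, net,
                                   tspnet.desk_profile(max_epochs=35), seed=0)
montage = tspnet.default_montage(tspnet.PROFILE_16)
hits = tspnet.attribution_target_hits(tone_model, tone_test, montage,
                                      tspnet.default_signatures())
print(f"in-band scalp peak on the injected electrode: {sum(hits.values())} of 6")
```

```
test accuracy 0.972
in-band scalp peak on the injected electrode: 6 of 6
```

A uniform random guesser on balanced six-class data scores 1/6 ≈ 16.7%, so
97% test accuracy shows the network has found the class-specific band-power
structure. The second line runs the band-attribution pipeline (filter the
correctly classified trials into δ/θ/α/β, re-extract features, average per
class, collapse to electrodes): every class's in-band scalp peak lands on
the electrode where its oscillation was injected.

The same flow is available from the shell:

```bash
tspnet simulate --profile dataset_I --trials-per-class 60 --n-samples 128 \
                --fs 128 --effect-size 2.5 --seed 11 --out epochs.h5
tspnet train --data epochs.h5 --seed 0 --out run/
tspnet viz --run run/ --data epochs.h5 --out maps/
```

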