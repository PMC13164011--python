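# frostgrip

Grasp-based multimodal tactile detection of frost-damaged citrus fruit.

Early frost injury degrades the internal tissue of citrus fruit before
any visual symptom appears, which defeats camera-based sorting. When a
robotic gripper grasps a fruit, however, the contact itself is a
measurement: a 6×6 pressure-matrix sensor records the slowly evolving
spatial load distribution (~20 Hz) and a piezoelectric film records the
transient vibration response (~200 Hz), both as 10-bit ADC counts.
Frost-damaged tissue is softer and more dissipative, so it loads more
slowly, spreads contact pressure differently, and crackles with
micro-slip events during loading. `frostgrip` implements the complete
analysis chain for this sensing concept, for researchers in postharvest
quality sensing and robotic tactile perception:

- **`simulate`** — a generative model of labeled grasp trials
  (exponential force ramp to a 20 N ceiling, 5 s hold, Gaussian contact
  footprint, damped contact transient, Poisson micro-slip events),
  with class effects expressed as shifts of mechanical ground-truth
  parameters scaled by an `effect_size` dial (0 = null, classes
  identical; 1 = default study conditions).
- **`preprocess`** — grasp segmentation, denoising, standardization of
  each trial to the fixed model-input shapes **50×36** (flattened
  pressure) and **50×1** (vibration), per-trial min–max / z-score
  normalization, and a causal second-order Butterworth high-pass
  (30 Hz) for the vibration channel.
- **`models`** — a dual-branch Transformer fusion classifier: per
  modality one pre-LN self-attention block
  `Y = Dropout(LN₂(X + MHA(LN₁(X))))` with 2 heads of key dimension
  32, fixed sinusoidal positional encoding, branch outputs concatenated
  (50×37), flattened and classified by a dense-64/dropout/dense-64/
  softmax-2 head; plus pressure-only and vibration-only ablations and
  RNN/CNN/LSTM baselines. Everything runs on a small NumPy autodiff
  engine included in the package — no deep-learning framework needed.
- **`evaluate`** — the repeated stratified-split protocol: 7:2:1
  splits, Adam (lr 0.001, batch 16), early stopping on validation loss
  (patience 20, max 300 epochs) with best-checkpoint restoration,
  per-class precision/recall/F1 and accuracy aggregated as mean ± SD
  over 10 repeats.
- **`attribution`** — residual-aware attention rollout: head-averaged
  maps Ā, residual adjustment Ã = RowNorm(Ā + I) = (Ā + I)/2, rollout
  R = Ã⁽¹⁾⋯Ã⁽ᴸ⁾ (= Ã for the single block), temporal scores
  s(t) = (1/T)Σ_q R_qt, per-sample min–max normalization, equal-weight
  fusion of the two modality profiles, peak times t* = argmax ŝ_fused,
  and peak-interval histograms.
- **`workbench` / CLI** — a reproducible end-to-end runner with YAML
  configuration, config-hash provenance stamps, and a dataset format
  validator. Real recordings in the same CSV layout are accepted
  interchangeably with simulated ones.

## Worked example

```python
import frostgrip as fg

# 240 fruit (120 per class), default full-effect study conditions
cfg = fg.SimulationConfig(n_per_class=120, seed=7)
trials, manifest = fg.generate_dataset(cfg)
inputs = fg.build_model_inputs(trials, fg.PreprocessConfig())

# one stratified 7:2:1 split, one training run of the fusion model
plan = fg.stratified_split([m.label for m in inputs], seed=0)
result, model = fg.train_run("fusion", inputs, plan,
                             fg.TrainingConfig(max_epochs=60, seed=0),
                             return_model=True)
print("test accuracy:", result.metrics["test"]["accuracy"])
print("best epoch:", result.best_epoch, "of", result.stopped_epoch + 1)

# where in the grasp does the model look?
test_inputs = [inputs[i] for i in plan.test_idx]
profiles, hist = fg.attribute_dataset(model, test_inputs)
print("peak-interval counts:", hist.counts.tolist())
```

Output from this exact script:

```
test accuracy: 0.9166666666666666
best epoch: 33 of 54
peak-interval counts: [16, 0, 0, 0, 0, 1, 0, 0, 0, 7]
```

The fusion model recovers ~92% test accuracy on this split, and the
fused attribution profile peaks in the first 5 standardized time steps
for 16 of 24 test samples — the contact-onset and early-loading window
where the simulator concentrates the class differences. (A minority of
samples peak in the final interval, at the release edge.)

The same protocol repeated 10 times over all three modality
configurations (`fg.repeat_protocol`) yields mean test accuracies with
the ordering fusion ≥ pressure-only > vibration-only, mirroring the
intended design of the generator: both modalities carry class
information, pressure more than vibration, and fusing them does not
hurt.

The equivalent shell workflow:

```bash
frostgrip simulate  --out runs/dataset --seed 7
frostgrip preprocess --data runs/dataset --out runs/inputs
frostgrip evaluate  --inputs runs/inputs --out runs --repeats 10 --seed 0
frostgrip attribute --inputs runs/inputs --out runs/attributions
frostgrip validate  --data runs/dataset
```

or `frostgrip pipeline --config config.yaml` for the whole chain with
provenance stamps.

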