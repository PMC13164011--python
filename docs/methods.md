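# Methods

## Problem and scope

`frostgrip` studies whether early frost damage in citrus fruit can be
detected from the tactile signals a robotic gripper records while
grasping: a 6×6 pressure-matrix stream (~20 Hz) and a piezoelectric
vibration stream (~200 Hz), both 10-bit ADC counts. Freeze–thaw injury
degrades tissue microstructure, so damaged fruit load more slowly,
distribute contact pressure differently, and respond with different
transient dynamics at contact. The package provides the full analysis
chain — signal simulation, preprocessing, a dual-branch Transformer
fusion classifier with ablations and baselines, a repeated
stratified-split evaluation protocol, and attention-rollout temporal
attribution — as tested, reusable code. Because no public recordings of
this kind exist, the simulator is a first-class component: it defines
the study conditions under which everything else is validated.

## Synthetic grasp model

Each trial follows the standardized grasp protocol: fingers close at
50 mm/s, load to a 20 N force ceiling, hold 5 s, release. The force
trajectory is

    F(t) = F_max · (1 − exp(−(t − t₀)/τ))   for t ≥ t₀,

clamped at `F_max`, with a linear ramp-down (0.2 s) at release and a
0.5 s pre-contact head plus 0.4 s tail at baseline. The loading phase
is taken to last 4τ, after which the grasp "holds" while the force
creeps through the exponential tail — so the hold phase differs between
classes only weakly, through that slow creep.

Pressure frames place a Gaussian spatial footprint (center uniform in
the middle of the grid, SD `spread`) over the 6×6 array:
`counts_ij = clip(round(8 + gain · w_ij · F(t) + ε), 0, 1023)` with
`gain = 40 counts/N` and the weights normalized to sum 1. The vibration
channel is an ADC midpoint of 512 counts plus a slow sinusoidal drift
(< 5 Hz, 15 counts), a damped contact transient
`A·exp(−ζω(t−t₀))·sin(ω_d(t−t₀))` (A = 180 counts), Poisson-timed
micro-slip transients during loading (70 counts, decay 6 /s, ring
90 Hz), and white noise. Timestamps carry ±2% uniform jitter so the
preprocessing must genuinely resample.

Class differences enter as shifts of the mechanical ground truth,
scaled by `effect_size`: frost-damaged fruit have a longer ramp
constant (τ 0.15 → 0.23 s), a slightly wider footprint (+0.15 grid
units), a lower and more damped transient (80 → 60 Hz, ζ 0.04 → 0.09),
and far more micro-slip events (1 → 9 Hz) — softer, more dissipative,
more crackly tissue. Both classes then receive 10% lognormal
biological jitter, so at `effect_size = 0` the two classes are
distributionally identical by construction (the null pipeline check
depends on this). Fruit diameter is drawn from the lot statistics
(73.54 ± 3.41 mm, truncated to the observed 66.31–81.34 mm range) and
carried as metadata.

Two consequences of these choices matter for interpretation. First,
the discriminative cues are concentrated at contact onset and early
loading (ramp shape, transient, micro-slip burst), so a faithful
attribution method should emphasize the early part of the standardized
sequence. Second, the pressure cues are deliberately stronger than the
vibration cues, so a pressure-only classifier should beat a
vibration-only one, with fusion at least matching pressure. The
micro-slip constants were settled while designing the generator: with
very short-lived events (decay ≳ 25 /s) the 50-step length
standardization destroys the vibration cue entirely and a
vibration-only classifier is exactly at chance; events lasting ~0.17 s
survive standardization as an early-window variance signature.

What the simulator does **not** model: contact mechanics beyond the
Gaussian footprint, thermal effects, sensor nonlinearity/hysteresis,
pose and curvature variation, or inter-cultivar differences. Passing
tests therefore show that the analysis chain recovers the signal
structure it assumes — not that real frost damage is detectable at any
particular accuracy.

## Preprocessing

Per trial, in order:

1. **Grasp segmentation.** The summed pressure frame is compared with a
   threshold `level + k·scale` (k = 5) estimated from the first 10% of
   frames; the segment end uses the symmetric rule on the trailing 10%.
   Level and scale are the median and the normal-consistent MAD
   (1.4826·MAD) rather than mean/SD: the leading window can overlap the
   force ramp (with a 0.5 s pre-contact head it always does), and the
   robust estimates keep the threshold anchored to the true baseline. A
   trial whose sum never crosses the threshold raises "no contact
   detected".
2. **Pressure denoising.** Centered moving average, window 3, per
   channel, shrunken at the edges — simple, linear-phase, exactly
   testable.
3. **Length standardization.** Linear interpolation of every channel
   onto 50 uniformly spaced points across the detected segment
   (endpoints preserved exactly). The 6×6 frames are flattened
   row-major (p00…p05, p10…p55) to 36 channels.
4. **Pressure normalization.** Joint min–max over all 50×36 entries of
   the trial, to [0, 1]. A single shared scale preserves the spatial
   load pattern across channels; per-channel scaling was rejected
   because it would erase exactly the spatial contrast the pressure
   modality is meant to carry.
5. **Vibration conditioning.** Mean removal, then a causal single-pass
   second-order Butterworth high-pass, 30 Hz cutoff designed at the
   nominal 200 Hz rate (bilinear transform with prewarping; gain at the
   cutoff is 1/√2, DC fully rejected). Zero-phase filtering was
   rejected as acausal and because it squares the cutoff gain. After
   resampling to 50 steps, each trial is z-scored (an addition beyond
   length standardization, for optimizer conditioning; ε = 1e−8 guards
   degenerate trials).
6. **Labels.** One-hot, index 0 = normal, index 1 = frost_damaged.

## Network

Each modality branch is a single-block Transformer encoder in pre-LN
residual form,

    Y = Dropout( LN₂( X + MHA( LN₁(X) ) ) ),

which satisfies both the listed layer order (LN, MHA, LN, dropout) and
the residual connection around the attention sub-layer. The
multi-head attention has H = 2 heads with key dimension d_k = 32
(per-head Q/K/V projections d → 32 with biases, output projection
64 → d), dropout rate 0.3, and exposes the post-softmax per-head maps.
Inputs are scaled by √d before the fixed sinusoidal positional
encoding is added — the original Transformer recipe; without the
scaling the unit-amplitude encoding swamps the [0, 1]-scale pressure
content and training stalls at chance long enough for patience-based
early stopping to kill runs. The encoding is the standard
sin/cos interleaving with base 10⁴; an odd feature width keeps the
unpaired trailing column on the sine term, so the 50×1 vibration input
receives a plain sin(t) column.

One deliberate deviation from the textbook form: **branches with a
single feature channel normalize over the time axis.** Feature-axis
layer norm on a 50×1 sequence maps every step to the LN bias —
normalizing one number always yields zero — which would annihilate the
vibration signal before it reaches attention or the head (a
vibration-only model then sits exactly at chance with a flat loss).
Time-axis normalization keeps LN a well-defined per-trial
standardization for that branch. The 36-channel pressure branch uses
standard feature-axis LN. A corollary worth knowing when constructing
inputs: feature-axis LN removes any spatially uniform offset, so class
information encoded purely as a global level shift is invisible to the
pressure branch by design.

Branch outputs are concatenated on the feature axis (50×37), flattened
(1850), and classified by dense-64 (ReLU) → dropout → dense-64 (ReLU)
→ softmax-2. Single-modality ablations keep one branch and the same
head on that branch's flattened output. The RNN (simple tanh
recurrence, 32 units), CNN (1-D convolution, 32 filters, kernel 5,
valid padding, global average pooling), and LSTM (32 units, forget
bias 1) baselines use one encoder per modality feeding the identical
head; they exist to exercise the comparison protocol, not to be
faithful reproductions of any particular reference implementation.
The fusion model as described has ~133k trainable parameters; the
achieved count is recorded in every run's result metadata.

All networks run on a compact reverse-mode autodiff engine over NumPy
(`frostgrip.nn`) written for this package and gradient-checked against
numerical differentiation; no external deep-learning framework is
used. Glorot-uniform initialization throughout, seeded per model.

## Training and evaluation protocol

Datasets are split 7:2:1 (train:validation:test) by per-class
stratified sampling — shuffle within class, floor allocation, largest
remainder top-up (exact for the 240-sample default: 168/48/24 overall,
84/24/12 per class). Optimization is Adam (lr 0.001, β = 0.9/0.999,
ε = 1e−7) on categorical cross-entropy, batch 16, at most 300 epochs,
early-stopped on validation loss with patience 20; a patience reset
requires strict improvement. The best-validation checkpoint is
restored before scoring. Metrics are per-class one-vs-rest precision,
recall, and F1 plus accuracy, on all three subsets; zero denominators
return 0 with a `degenerate` flag rather than NaN.

The protocol repeats 10 times; repeat r uses seed `base_seed + r` to
drive the split, parameter initialization, batch shuffling, and
dropout, so all model kinds see byte-identical subsets per repeat.
Aggregates are the arithmetic mean and the sample SD (n−1); per-run
metrics are averaged across runs (rather than pooling confusion counts
first). Reports are exactly recomputable from the stored per-run
results, and the test suite asserts this.

## Temporal attribution

For each sample and branch, the post-softmax per-head maps are averaged
(Ā), adjusted for the residual path by row-normalizing Ā + I — which
for a row-stochastic Ā is exactly (Ā + I)/2 — and rolled out across
the L stacked blocks by matrix product; with the single-block
architecture the rollout returns the adjusted map unchanged, and the
code keeps the general form. The temporal score s(t) is the column
mean of the rollout matrix (average incoming attention over all query
positions); it sums to 1 exactly because the rollout matrix is
row-stochastic. Scores are min–max normalized per sample
(ε = 1e−8 guards constant profiles, which map to all zeros), the two
modality profiles are fused by equal-weight averaging, and the peak
time t* is the argmax with ties broken to the earliest index. Peak
times are summarized as a fixed-width interval histogram (default
width 5 → 10 bins over 50 steps), optionally per class. Attention is
extracted in inference mode (dropout off). Attribution profiles are
post hoc, correlational descriptions of where the model attends — not
causal evidence.

## Problem sizes and numerical choices

The end-to-end checks run the protocol at the study scale (240 trials,
10 repeats) with training capped at 60 epochs for the full-effect
dataset and 40 for the null dataset; at these caps the runs routinely
early-stop and the aggregate means are stable, while a desk machine
completes the whole suite comfortably. `scripts/acceptance.py` uses
the same sizes. Floats are double precision throughout; attention
row-stochasticity holds to 1e−9 and the rollout algebra is checked
against a brute-force loop oracle at the same tolerance. Degenerate
inputs (constant trials, all-baseline grasps, empty subsets, even
denoising windows, cutoffs at Nyquist) raise explicit errors or are
ε-guarded as documented above.

## Known limitations

- The simulator's class effects are low-dimensional parameter shifts;
  real frost damage is spatially heterogeneous and interacts with pose
  and contact state.
- The vibration modality's learnable cue rests on the micro-slip event
  model; other plausible vibration signatures (spectral shifts within
  the pass band) do not survive 50-step standardization and are
  therefore not represented.
- Accuracy figures obtained on synthetic data characterize the
  pipeline, not the sensing concept; they are not comparable to
  measurements on real fruit.
- The printed parameter budget of compared baselines is matched only
  loosely (tens of thousands of parameters); the comparison protocol,
  not baseline tuning, is the point.
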