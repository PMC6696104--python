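# Methods

`respiradar` classifies 10-second windows of chest-displacement signal,
extracted from impulse UWB radar range-bin streams, into five respiration
patterns: eupnea, bradypnea, tachypnea, apnea, and motion artifact. This note
describes the models and procedures the package implements, the choices made
where the design was open, and what the synthetic data can and cannot show.

## Signal model and simulator

A breath cycle is modeled as an asymmetric raised cosine: a half-cosine rise
over the inspiration fraction of the cycle and a half-cosine fall over the
expiration fraction. The inspiration:expiration duration ratio is 1:e with
e ∈ [1.5, 2.0] (physiological resting range), so inspiration occupies
⌈n/(1+e)⌉ of the n = round(fs·60/rate) samples per cycle. Trough-to-peak
equals the configured amplitude, and the waveform is periodic and smooth at
cycle boundaries. The sampling rate defaults to 25 Hz, the radar frame rate.

Pattern classes are defined on breaths/min bands: eupnea owns the closed
interval [12, 20]; bradypnea is strictly below 12; tachypnea strictly above
20. The bands are made disjoint so that labels are deterministic. Class
amplitude factors relative to the eupnea baseline are 1.0 (eupnea), 0.7
(bradypnea, lowered depth), 0.5 (tachypnea, shallow), 0.05 (apnea — a ≥95%
reduction, comfortably inside the defining ≥90% bound), and 1.0 for the
breathing baseline under motion. Apnea traces must be at least 10 s long,
matching the clinical definition of an apneic event.

Successive cycles get independent uniform ±10% rate jitter, truncated to the
class band, so training data are not perfectly periodic. Motion superimposes
1–3 step-and-decay transients per 10-s block, each with amplitude 3–8× the
breathing amplitude, random sign, and an exponential decay constant of
0.5–2 s. Measurement noise is additive i.i.d. Gaussian (default s.d. 0.05,
i.e. 5% of the eupnea amplitude) — the simplest model consistent with the
scalar Kalman stage's assumptions.

Radar embedding places the trace on the range bin nearest the configured
sensor-to-thorax distance (default 20 cm). The default bin spacing is 3.0 cm,
one consistent choice within the device's specified 1.5–3.3 cm resolution
range (660 bins ≈ 19.8 m of coverage); 20 cm therefore maps to bin 7. The two
neighbouring bins carry a half-amplitude copy (finite range resolution), and
every bin carries i.i.d. Gaussian clutter. No RF propagation physics, antenna
modeling, or heartbeat component is simulated.

The dataset generator emulates the collection protocol: per subject, one
amplitude scale U(0.8, 1.2), one expiration share U(1.5, 2.0), and nominal
rates drawn uniformly inside each band (bradypnea U(7, 11), eupnea U(13, 19),
tachypnea U(22, 40)); 10 subjects × 5 patterns × 50 windows gives the
2500-window collection. Signal amplitude is in arbitrary units throughout —
the absolute displacement scale does not survive per-window standardization
and is never needed.

**What the simulator does not capture:** real radar recordings contain
heartbeat ripple, posture-dependent amplitude drift, non-Gaussian clutter,
multipath, and within-trace pattern transitions. Passing the synthetic
acceptance properties therefore demonstrates that the pipeline and the
classifier behave correctly under the designed study conditions; it does not
certify recognition rates on human recordings.

## Preprocessing

The raw range-bin series is smoothed with a scalar random-walk Kalman filter
with process variance q = 0.01 and measurement variance r = 0.1 (the
device-software defaults). Per measurement: P ← P + q; K = P/(P + r);
x ← x + K(m − x); P ← P(1 − K). Initialization is from the data (x₀ = first
measurement, P₀ = r + q) to avoid a startup transient on arbitrary offsets;
both can be overridden. r = 0 reduces the filter to the identity after the
first update.

Bin selection is distance-gated: within ±3 bins of the distance-implied bin,
the bin with maximal temporal variance is taken, ties broken to the lowest
index (the real acquisition GUI performs this selection invisibly; variance
gating is the minimal explicit rule).

Windows are 250 samples (10 s at 25 Hz) cut at offsets 0, S, 2S, …; the
nominal 0.5-s shift is 12.5 samples, so the default integer shift is S = 12
(0.48 s, a 4% deviation — windows must align to sample boundaries). The
window count from a trace of T samples is ⌊(T−L)/S⌋+1; a `max_windows` cap
subselects offsets at uniform stride, which reproduces the protocol's 500
windows per pattern from a 10-min recording without inventing a selection
criterion. Splitting is a seeded shuffle, class-stratified by default
(per class, round(0.6·n) to train); subject-wise splitting is available by
splitting the generator's metadata instead. 2500 windows split 6:4 give
exactly 1500/1000.

## Classifier

The network is depth × [1-D convolution (odd kernel, same padding, stride 1)
→ ReLU → max-pool 2] → flatten → dropout → dense → dense → 5-way softmax.
The reference configuration is depth 3 with kernels 29/25/21 and 64/64/128
filters, dense layers 2048/1024. Conventions chosen where unspecified:

- **Pooling** size 2, stride 2 after every conv layer — the only common
  convention under which the depth-3 stack stays viable on 250 samples
  (250 → 125 → 62 → 31; flatten 31 × 128 = 3968).
- **Padding**: same. Valid padding with kernels up to 41 is fragile at depth 3.
- **Dropout**: the ratio 0.6 is the *keep* fraction (60% of the serialized
  features used per step), applied after flatten, before the first dense
  layer; `build_model(..., dropout_as_drop_fraction=True)` flips the
  interpretation.
- **Optimization**: softmax cross-entropy, Adam at its conventional defaults
  (lr 10⁻³, β₁ 0.9, β₂ 0.999), He-normal initialization, ReLU activations —
  the standard stack for this architecture family.
- **Input scaling**: each window standardized to zero mean, unit variance
  (radar amplitudes have arbitrary scale).

Training defaults are 40 epochs at batch size 10. All stochasticity (weight
init, shuffling, dropout masks) flows from a single seeded generator, so a
fixed seed reproduces a run bit-for-bit on one machine.

The implementation is plain numpy in float32: convolutions as im2col + BLAS
matmuls, the conv adjoint as a same-padded convolution with the tap-flipped,
channel-transposed kernel (exact for odd kernels), pool gradients routed to
the earlier sample on ties, and a fused single-pass Adam update (numba) —
the update is memory-bound on the ~10.5M parameters, dominated by the
3968×2048 dense layer. An architecture whose pooled length would reach zero
is rejected at build time with the offending layer named.

## Parameter search

Stage 1 (depth search): for each depth in the grid, every combination of
per-layer (kernel size, kernel count) pairs and the two dense widths is
evaluated by a caller-supplied trainer; the depth with the highest mean
accuracy wins, ties to the smallest depth. Combination counts follow
(|KS|·|KC|)^depth·|DLNC|²: 800 / 40,000 / 2,000,000 at depths 1/2/3 for the
default grid (KS {5,9,…,41}, KC {32,…,512}, DLNC {256,…,2048}).

Stage 2 (range search): N repeated searches (default 10) at the fixed depth;
each iteration records its argmax-accuracy combination (ties to the first in
enumeration order), and the optimal ranges are the per-family [min, max] over
the N best combos, pooling kernel sizes and counts across all conv layers.
Enlarging N can only widen ranges.

Enumeration is lazy, in a fixed lexicographic mixed-radix order (layers most
significant; within a layer, kernel-size index × |KC| + kernel-count index;
the dense pair least significant), giving every combination a stable integer
sequence number with exact encode/decode. Exhaustive evaluation of the
depth-3 grid means 2,000,000 trainings — infeasible on a desk — so a seeded
uniform `subsample` is a first-class parameter; exhaustive mode remains for
small grids and mock trainers. A trainer failure on a combination is warned
about, recorded as missing, and excluded from means. By default a trainer
should report accuracy on the 6:4 validation split.

## Evaluation

Recognition rate is per-class recall (confusion-matrix diagonal over row
sum); the average recognition rate is the unweighted mean over classes —
with the protocol's balanced classes this equals overall accuracy. Classes
absent from a test set are excluded from the average with a warning.
Baselines are standard scikit-learn classifiers on the identical flattened,
standardized windows: LDA (svd solver), SVC with RBF kernel (C = 1,
gamma='scale'), and a single-hidden-layer MLP of 256 units; their
hyperparameters are recorded verbatim in every report. On the shipped-seed
synthetic fixture the expected ordering is CNN ≥ MLP and CNN ≥ SVM ≥ LDA;
on other seeds deviations in the baseline order are possible and are
reported, not fatal.

## Numerical and degenerate-input conventions

- Tie-breaks: argmax label → lowest class index; depth tie → smallest depth;
  combo tie → first in enumeration order; bin-variance tie → lowest bin
  index; pooling tie → earlier sample.
- A stratified class with fewer than two members goes entirely to train,
  with a warning.
- Zero-duration traces are valid and empty; apnea shorter than 10 s, empty
  signals, windows shorter than the window length, and distances outside the
  bin range raise errors.
- Text formats carry 6 significant digits — compact, and far below the
  simulated noise floor.

## Problem sizes used in the shipped checks

The acceptance run trains the reference architecture once on the full
2500-window collection (1500/1000 split, 40 epochs, batch 10) — roughly ten
to fifteen minutes of single-core CPU — and evaluates the three baselines on
the same split. Unit and property tests use reduced collections (≤ 2
subjects, ≤ 5 windows per pattern), a slim architecture on a separable
five-prototype toy problem, and small grids for search oracles, all of which
run in seconds. Search-algorithm checks against the published optima inject
the reported per-depth mean accuracies and the four published per-iteration
best combinations rather than re-training 2,000,000 networks.

## Known limitations

- The CNN is CPU-only and single-threaded; wall-time scales linearly with
  epochs × windows.
- The simulator's inter-subject variability is parametric (rate, amplitude,
  I:E share); it does not model per-subject waveform morphology.
- Only the conv→dense family is supported — no residual connections,
  batch-norm, or alternative pooling.
- The 6:4 split is class-stratified by default; whether the original
  protocol stratified by class or subject is unknowable from the published
  description, and subject-wise splitting may be the harder, more honest
  test for new data.
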