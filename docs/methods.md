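# Methods

## Problem and model

`wearssl` learns an encoder `f : x → h` for segmented multichannel
physiological waveforms `x ∈ R^{c×t}` without labels, such that frozen
representations `h` support downstream classification (probing) and serve as
a strong initialization for fine-tuning. Training is contrastive: every
segment is augmented into two views, a projector maps backbone
representations to l2-normalized projections `z`, and similarity is the dot
product of unit vectors (cosine).

Two mechanisms inject domain knowledge, both operating on a precomputed,
z-normalized domain feature vector `d_i` per segment:

1. **Neighbour positives.** Within a batch of `2B` views, the positive set
   of anchor `i` is `P(i) = {sibling view} ∪ S(i)`, where `S(i)` is the two
   candidate views closest to `d_i` in Euclidean distance (ties broken by
   ascending view index; the anchor's sibling is excluded from candidacy).
   Because sibling views share one feature row, `S(i)` normally holds both
   views of the nearest other segment. The loss averages, over `p* ∈ P(i)`,
   a softmax term whose denominator contains that positive plus the pruned
   negative pool `N*(i)` — the selected neighbours appear in no negative
   term for that anchor. With `S(i)` empty this reduces exactly to the
   standard one-positive batch loss (verified to 1e-12 in tests).

2. **Prototype contrast.** k-means (k-means++ initialization, 10 restarts,
   deterministic under seed) clusters the training-set domain features once,
   offline; assignments never change during training. Each cluster keeps a
   unit-norm prototype `c_k` updated per batch by an EMA of its member
   projections (momentum `α`), and a per-cluster temperature
   `τ_k = (Σ_i ‖z_i − c_k‖₂) / (n_k ln(n_k + m))` recomputed at each epoch
   end from distances accumulated while streaming (using the `z` and `c`
   current at each batch, rather than a second full pass), then rescaled by
   one constant so that mean(τ_k) equals the base temperature — an
   idempotent normalization. Clusters unseen in an epoch keep their previous
   temperature. The loss pulls each view toward its own prototype against
   all `K`, each denominator term using its own cluster's temperature.
   Prototypes are treated as constants by the optimizer (they evolve by EMA
   only).

The total loss ramps the prototype term in,
`L = L_ins + min(max((T−T0)/Tmax, 0), 1)·L_proto`, because early prototypes
are poor. Note the ramp denominator is the total epoch count `Tmax`, so with
`T0 > 0` the weight does not reach 1 within a run; an alternative
`Tmax − T0` denominator is available behind `ramp_denominator=
"tmax_minus_t0"` (off by default). Epochs are 0-indexed, so epoch 0 always
carries ramp weight 0; during ramp-0 epochs member projections are
accumulated per cluster, and prototypes are initialized from those means
(unit-normalized) when the ramp activates.

Two deliberate choices where the formulation is ambiguous: `z` in the EMA
and the prototype loss is the projector output (the same space as all other
similarities), and prototypes are re-normalized to unit length after each
EMA step so `z·c_k` stays a cosine (switchable via
`normalize_prototypes=False` for the literal un-normalized update).
Logarithms are natural throughout.

## Domain feature banks

Three documented banks cover the families practitioners extract per
modality; vector length and ordering are fixed and recorded in
`feature_names`.

- **cardiac** (ECG/PPG-like): beat detection is an energy detector —
  band-limit (0.5 Hz to min(18, 0.9·Nyquist) Hz), square, 150 ms
  moving-window integration, adaptive threshold at 40% of the envelope's
  98th percentile, 200 ms refractory period, peak refinement to the local
  filtered-signal maximum. From detected beats: mean/median/min/max
  inter-beat interval, SDNN and RMSSD (population normalization, so the
  closed test cases are exact), a pNN50-style proportion (successive
  differences > 50 ms), rate, peak-amplitude statistics, mean pairwise
  Pearson correlation of beat-centred windows (a quality index; half-width
  40% of the median interval), and beat coverage. Segments with fewer than
  two beats carry NaN sentinels for interval features. Per-channel absolute
  and relative band powers complete the bank.
- **spectral** (EEG-like): band powers only, over configurable bands
  (defaults 0.5–4, 4–8, 8–13, 13–30 Hz), from Welch's averaged modified
  periodogram (Hann window, `nperseg = min(T, 256)`, 50% overlap). Relative
  powers per channel sum to 1 over the band set; an all-zero channel is
  defined as 0.
- **motion** (tri-axial accelerometry): per-axis mean/std/range, vector
  magnitude mean/std, dominant frequency and power of the summed DC-removed
  per-axis periodograms, normalized spectral entropy, and roll/pitch from
  the mean gravity vector (`pitch = atan2(gx, √(gy²+gz²))`,
  `roll = atan2(gy, gz)`, degrees).

Feature matrices are z-normalized per column with population σ; NaNs are
mean-imputed first; constant columns map to 0. Normalization statistics
default to train-split-only (leak-free) with the fitted statistics applied
to held-out splits; computing them on all unlabeled data is available by
simply fitting on the full matrix.

## Augmentations

A modality-agnostic chain in fixed order — jitter (circular temporal shift,
which preserves length without edge artifacts) → per-channel scaling
(factor ~ N(1, σ²)) → magnitude warp (pointwise multiplication by a cubic
spline through 4 knots ~ N(1, σ²)) → additive Gaussian noise → cutout (a
contiguous window zeroed). Defaults: max shift 50 samples, σ_scale 0.2,
σ_warp 0.2, σ_noise 0.05, cutout fraction 0.1; application probabilities
0.5 except noise (always). The fixed order plus a single RNG stream makes a
view chain deterministic; gates are always drawn so the stream advances
identically regardless of outcomes. Both views of a segment share its
domain feature row — the pairing contract the neighbour search relies on.

## Encoder and optimization

The backbone is a residual 1-D convolutional network in pure NumPy with
explicit backward passes (finite-difference-checked in the test suite):
three strided conv stages (widths 8/16/32, kernels 7/5/3, stride 2, each
followed by a two-conv residual block), global average pooling to a 32-d
representation, and a Dense(32)–ReLU–Dense(16) projector with row-wise l2
normalization. Probes and fine-tuning consume the backbone representation;
projections exist only for the contrastive losses. Optimization is Adam
(lr 1e-3) with linear warm-up over the first 5 epochs. Incomplete final
batches are dropped during pretraining so neighbour pools and cluster
occupancies are comparable across steps. A NaN loss aborts with diagnostics.

Randomness is hierarchical from one master seed (named SeedSequence streams
for weight init, k-means, and each epoch's shuffle + augmentations), which
makes runs bit-reproducible and checkpoint resumption exact: checkpoints
(NumPy archives embedding the config digest) store weights, Adam moments,
prototype state and history at epoch boundaries, and a resumed run
reproduces the uninterrupted trajectory.

## Presets and parameter choices

| parameter | desk default | rationale |
|---|---|---|
| batch size B | 32 | fits the ~70-segment synthetic train split |
| epochs | 20 (desk) / 60 (comparisons) | see below |
| τ (base temperature) | 0.1 | common contrastive practice; not printed in the protocol this follows |
| K (clusters) | 4 | keeps ~B/8 = 8 members per cluster per batch — the same occupancy the full-scale protocol (K=128 at B=1024) implies; sparser clusters make the per-batch EMA noise-dominated |
| α (EMA momentum) | 0.5 | full-scale protocol value |
| m (temperature smoothing) | 10 | full-scale protocol value |
| T0 (ramp start) | 10% of epochs | not printed in the protocol; config-exposed |
| neighbours | 2 | both views of the nearest other segment |
| fine-tune | 20 epochs, lr 5e-4, balanced softmax | reduced-lr downstream recipe; see limitations |

`fullscale_config()` exposes the full-scale protocol (1000 epochs, batch 1024,
K=128, warm-up 5) for users with the hardware; all tests and examples use
desk scale.

The 20-epoch desk preset is the determinism/runtime reference. Pretraining
*comparisons* (probe orderings, label efficiency) train for 60 epochs: with
two optimizer steps per epoch at this data size, 20-epoch runs measure
initialization noise rather than representation quality, while 60 epochs
approach the loss plateau in seconds of CPU time.

## Synthetic data generator

The generator emulates the statistical skeleton such methods rely on, not
any clinical waveform. Each segment is an impulse train at a class-specific
rhythm rate convolved with a class-specific morphology template (a narrow
Gaussian bump plus a broader delayed secondary bump), with inter-beat
intervals jittered by 3% for quasi-periodicity; subject nuisance is applied
afterwards — multiplicative gain U[0.5, 2.0], additive baseline N(0, 0.5²)
and white noise with σ ~ U[0.05, 0.25] per subject. The default preset is 4
classes × 12 subjects × 10 segments, 1 channel, 100 Hz, 10 s windows;
classes spread ±18 bpm around 72 bpm with widths 33–57 ms
(`class_sep` scales all between-class spreads; 0 makes classes identical).
Ground-truth beat indices and generating parameters are retained as
metadata, making the beat detector and rhythm features exactly testable,
and classes are 1-NN separable from generating parameters by construction.

By design, domain features carry the class signal (rate, morphology) while
raw amplitude/offset carries the subject signal — reproducing the failure
mode in which instance-level contrast organizes embeddings by subject. What
passing tests show is therefore that the machinery works and that domain
guidance recovers class structure *under these conditions*; they do not
show clinical-grade performance on real ECG/EEG/IMU data, where feature
quality, artifacts and label noise differ substantially.

Signals are per-channel z-normalized during preprocessing (the standard
resample → band-pass (zero-phase Butterworth) → window → z-normalize
pipeline; named presets carry typical band/window/rate combinations per
modality). Without this step raw gain/baseline dominate both the encoder
input and every probe.

## Numerical choices

All softmax-style terms use max-shifted log-sum-exp. Unit-norm guards use
1e-12 floors. InfoNCE with an empty negative set is 0 by definition
(denominator equals numerator). Constant-feature columns (σ < 1e-12)
z-normalize to 0; an all-NaN column is an error naming the column. KNN vote
ties break by smaller mean neighbour distance, then lower class index. The
linear probe is scikit-learn multinomial logistic regression (L-BFGS,
tol 1e-6, C = 1.0) — no early stopping, a fixed convex tolerance instead.
F1 uses the 0 convention for empty denominators. k-means with fewer rows
than K reduces K with a warning.

## Known limitations

- At the desk-scale label budget (10% ≈ 7 labeled segments) fine-tuning is
  high-variance, and the advantage of pretrained initialization is measured
  under the brief 20-epoch schedule: with much longer fine-tuning both
  initializations converge to the few-sample interpolating solution and the
  gap closes. Multi-seed means are the only fair read at this scale.
- The feature banks are documented generic families (rhythm/morphology/
  quality, band powers, motion descriptors), not any published clinical
  feature list; the framework consumes any feature table via CSV.
- The beat detector targets clean quasi-periodic signals; it is not a
  validated clinical R-peak detector.
- Single-device, single-process training only; no momentum encoders,
  queues, or re-clustering of deep embeddings (the clustering is offline on
  domain features by design).
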