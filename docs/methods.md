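# Methods

This note records the modeling and numerical decisions behind the
package, the defaults and why they hold, and what the synthetic
experiments do and do not demonstrate.

## Signal model and preprocessing

The classification unit is one 30 s epoch of C = 3 channels (frontal
EEG, parieto-occipital EEG, horizontal EOG) sampled at 100 Hz — 3000
samples per channel. Epochs are classified independently (one-to-one);
no neighboring-epoch context is used anywhere, which keeps the model
small at the cost of occasional implausible stage transitions in
rendered hypnograms.

Each channel is framed with a 2 s periodic Hamming window at 50 %
overlap (hop 1 s) with **no edge padding**, giving exactly
T = ⌊(3000 − 200)/100⌋ + 1 = 29 frames. Each frame is zero-padded to a
256-point FFT; the one-sided power spectrum has 129 bins, reduced to an
even F = 128 by dropping the Nyquist bin (dropping the DC bin is
available via `StftConfig.bin_reduction`). Powers are floored at
ε = 10⁻¹⁰ before the natural log; the floor only matters for silent
signals and makes the log total. Finally each channel's 29×128 matrix
is standardized to zero mean and unit population variance **per epoch**
(per-channel). A per-recording variant can be emulated by standardizing
stacked arrays externally; per-epoch is the default because it makes
every sample self-normalizing and removes inter-subject amplitude
scale, which the synthetic generator deliberately jitters. A constant
channel raises rather than silently dividing by zero.

Because standardization removes affine constants, the power spectrum is
the plain squared magnitude of the windowed DFT with no window-energy
normalization.

`pool_frequency_bins` averages adjacent bins in groups (e.g. 128 → 32,
≈1.6 Hz per pooled bin). It exists for reduced-size configurations:
every stage-discriminative band (0.5–2 Hz slow waves, 4–7 Hz theta,
8–12 Hz alpha, 12–14 Hz spindles) remains separable at that resolution.

## Network

* **TemporalConv** (one per channel, parameters not shared): transpose
  to [B, D, L], depthwise 1-D convolution (groups = D, channel
  multiplier 2, kernel 3, zero-padded to preserve L), exact (erf-form)
  GELU, 1×1 convolution back to D, transpose back. A dense variant in
  which the widening convolution mixes features is available
  (`dense_temporal_conv=True`); the depthwise form is the default
  configuration. No normalization layers are used inside the block.
* **Fusion layer** (independent parameters per layer, default 2
  layers): one shared linear map to 3D features produces Q/K/V for all
  channels; heads H = 4 with d_h = D/H. Attention is computed per
  ordered channel pair: softmax over key positions of
  Q_i K_jᵀ/√d_h, then an **unnormalized sum** over key channels j of the
  weighted values — the per-pair softmax means each query position
  receives total attention mass C, and no ÷C normalizer is applied. A
  joint softmax over (channel, position) is deliberately not
  implemented. The merged heads are projected by W_O; the gate
  G = σ(mean over channels and time of the layer's input · W_G + b)
  scales the projected output before the residual addition
  Y = X + G·O′. Gate parameters are zero-initialized, so training
  starts with a half-open gate (G = 0.5) and an unbiased residual.
  There is no layer normalization and no positional encoding; temporal
  order information enters only through TemporalConv.
* **Classifier**: mean over the 29 frames (max and last-frame are
  selectable; mean is the default because it uses the whole sequence
  and keeps the block permutation-insensitive in time), flatten to
  C·D = 384, linear → 512, ReLU, dropout 0.5 (training only), linear →
  5, softmax. The loss consumes logits through a log-softmax for
  numerical stability; the softmax output is for reporting.

Parameter accounting: with the default configuration the depthwise
build has 433,799 trainable scalars (temporal convolutions 101,760,
two fusion layers 132,354, head 199,685); the dense variant has
≈0.73M. Published descriptions of this architecture quote ≈0.63M,
which matches neither reading; `count_parameters` reports the actual
per-module counts rather than forcing agreement with a printed figure.

## Autodiff and optimizer

All layers run on `mcafnet.autodiff`, a ~350-line tape-based
reverse-mode differentiator over float64 NumPy arrays supporting the
ops the model needs (broadcast arithmetic, batched matmul, shape ops,
reductions, softmax/log-softmax with detached max-shift, GELU/ReLU/
sigmoid, padding/slicing). The test suite checks every op and the full
assembled network against central finite differences (agreement to
~10⁻⁹).

AdamW uses decoupled weight decay: per step the parameter is first
shrunk multiplicatively by lr·wd, then moved by the bias-corrected
moment ratio lr·m̂/(√v̂ + ε). Defaults follow the published protocol —
lr 5·10⁻⁶, wd 10⁻², β = (0.9, 0.999), and the unusually large ε = 10⁻²
(kept because it is stated explicitly; it damps the effective step for
small-gradient coordinates and is configurable). A hand-coded update on
a 2-parameter quadratic agrees to < 10⁻¹⁰ over 100 steps.

Early stopping tracks the best validation accuracy with strict
improvement (ties keep the earliest pass) and stops after 20 stale
passes; a `max_epochs` bound of 200 is added as a safety net. The
returned model carries the best-validation parameters.

Subject-wise k-fold: subjects are shuffled once (seeded) and split into
k near-equal groups; fold f uses group f as test, group f+1 (cyclic) as
validation — satisfying the equal-size validation/test convention — and
the rest for training. Subject leakage across the three roles is
structurally impossible and tested.

## Synthetic generator

`synthetic_psg` emulates the spectral structure a sleep stager
exploits: W — 8–12 Hz alpha (posterior-dominant, 30–45 µV) with
frequent EOG step deflections; N1 — 4–7 Hz theta with 1.5 s slow eye
movements; N2 — theta background plus 12–14 Hz spindle bursts (1 s,
Hann-enveloped) and biphasic K-complexes; N3 — 0.5–2 Hz slow waves at
100–140 µV; REM — low-amplitude mixed EEG with rapid (0.25 s) EOG
saccades. Oscillations are narrowband-filtered Gaussian noise
(4th-order Butterworth band-pass applied forward-backward, scaled to
the RMS of a sinusoid at the configured peak amplitude) rather than
pure tones; transients are Poisson-counted with uniform placement,
rejection-resampled to lie fully inside the epoch. Each synthetic
subject applies a single amplitude (±15 %) and frequency (±5 %)
jitter to all recipes. Stage quotas use largest-remainder allocation,
and epochs are dealt round-robin to subjects, so class counts are exact
and every subject sees every stage. All randomness flows from one seed
through `numpy.random.SeedSequence` spawning; a seed fully determines
the dataset bit-for-bit.

What passing the synthetic experiments shows — and does not. The five
classes are separable by construction, so the desk-scale experiments
demonstrate that preprocessing preserves the discriminative bands, that
the model can learn them, and that the machinery (splits, early
stopping, metrics) is sound. They do not model stage-transition
structure, artifacts, electrode drift, inter-scorer ambiguity, or the
heavy class imbalance of clinical data, so synthetic accuracies
(high 90s) say nothing quantitative about performance on real
recordings.

The `eog_only_cue_config` variant clones the N1 EEG recipes into REM so
the REM/N1 distinction exists only in the EOG; it is the test bed for
showing that cross-channel fusion exploits a cue an EEG-only model
cannot see (fused REM F1 ≈ 1.0 vs ≈ 0.5 for the single-EEG model in the
seeded acceptance run).

## Problem sizes used in the checked experiments

The desk-scale learning run uses a reduced configuration — frequency
bins pooled 128 → 32, H = 2, one fusion layer, 128 hidden units, lr
10⁻³ — on 1200 balanced epochs over 12 subjects (800 train / 200
validation / 200 held-out test), chosen as the smallest cohort at which
per-subject jitter and subject-wise splitting are still meaningful. The
ablation comparison uses 1000 epochs over 10 subjects under the
EOG-only-cue recipes. Oracle comparisons (attention vs scalar loops)
sweep B ≤ 2, C ≤ 3, L ≤ 4, D = 4, H ≤ 2, where the brute-force
reference is exact and cheap.

## EDF I/O

Reading uses MNE for both signals and EDF+ annotations; stage labels
follow the standard archive vocabulary ("Sleep stage W/1/2/3/4/R",
"Movement time", "Sleep stage ?"), mapped R&K → five classes with S3+S4
merged into N3 and MOVEMENT/UNKNOWN excluded. Non-100 Hz inputs are
polyphase-resampled with a warning. The in-bed trim keeps 30 min before
the first and after the last non-wake epoch (configurable), the
convention of the established preprocessing pipelines for these
archives; all-wake recordings pass through unchanged with a warning.

Writing produces one plain-EDF PSG file (16-bit samples over ±1000 µV,
one 30 s data record per epoch) plus one EDF+ annotation-only hypnogram
file per subject, mirroring the public archives' file layout. The
quantization step is ≈0.03 µV; round-trip error is bounded by half a
step and labels round-trip exactly (N3 is written as S3).

## Known limitations

* One-to-one classification only; no sequence context, by design.
* The NumPy backend is single-threaded BLAS-bound; full-size (D = 128)
  training is feasible but slow compared to GPU frameworks — the
  package's role is correctness and inspectability, not throughput.
* Attention-map retention is gated by `keep_attention_maps` because a
  full-size map batch is ~16 MB per layer.
* The synthetic generator is not a physiologically validated EEG
  simulator; it is a controlled test bed with the documented spectral
  signatures.
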