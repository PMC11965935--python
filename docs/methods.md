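# Methods

This note documents the models and procedures implemented in `bowelspot`,
the choices made where the design was genuinely open, and what results on
synthetic cohorts do and do not show.

## Analysis chain

Continuous abdominal audio (default fs = 16 kHz) is processed per channel:

1. **Offset removal** — second-order (biquad) Butterworth high-pass, cutoff
   60 Hz, applied causally.
2. **Segmentation** — non-overlapping 10 s clips; a trailing remainder is
   zero-padded to a full clip and flagged so downstream stages can exclude
   the pad.
3. **Log-Mel front-end** — 25 ms Hann window, 10 ms hop, FFT length = window
   length (400 samples), no frame centering: frame *i* covers samples
   `[i*hop, i*hop + win)`, which makes frame↔time conversion exact. 128
   triangular HTK-mel filters (unit peak) between 0 Hz and Nyquist; natural
   log with floor ε = 1e-10. A 10 s clip yields 998 frames and is padded at
   the log floor to the 1,056-frame model input (an architecture constant,
   configurable).
4. **Spotting** — the segmentation model (below) yields per-frame BS
   probabilities; frames with p ≥ 0.5 are positive, maximal positive runs
   `[i, j]` become events `[t0 + i*hop, t0 + j*hop + win]`, events touching
   across clip boundaries are merged, and the event grammar is applied:
   merge chains with inter-event gaps < 100 ms (overlaps count as gap ≤ 0),
   then drop events shorter than 18 ms. The same grammar defines manual
   annotations, so spotted and manual events share one event definition.
   Event times are reported at hop (10 ms) resolution.
5. **Event features** — on audio band-passed with a zero-phase
   (forward–backward) Butterworth band-pass of order 8, 60–5,000 Hz.
   Features are computed over 32 ms frames with 8 ms hop spanning the event
   and averaged across frames; events shorter than one frame are padded
   symmetrically with the surrounding audio. The registry: MFCC_1..MFCC_13
   (1-based; MFCC_1 is the 0th cepstral coefficient of a 40-filter log-Mel
   bank, DCT-II orthonormal), spectral centroid, bandwidth, roll-off (85 %),
   flatness, zero-crossing rate, RMS energy, and event duration.
6. **Classification windows** — the recording timeline is tiled with
   non-overlapping windows of duration δ (default 600 s). Events are
   assigned by start time; each non-empty window contributes per-feature
   mean and population variance (variance 0 for single-event windows).
   Empty windows are omitted, never imputed.
7. **Feature selection** — mutual information between each window-level
   feature and the class label (k-NN estimator for continuous features,
   `mutual_info_classif`). Default mode selects the top-11 features per CV
   training fold (no leakage); a fixed mode selects the 11 MFCC means
   MFCC_3..MFCC_13, dropping the two lowest-quefrency coefficients whose
   band is largely removed by the 60 Hz high-pass.
8. **Classifier** — gradient boosting with exponential loss; presets
   (50 estimators, lr 1e-4) and (100 estimators, lr 1e-3). The tree split
   criterion is Friedman MSE (scikit-learn's internal criterion for this
   model). Per fold: standardisation fitted on the training windows only,
   SMOTE balancing of the training fold only (synthetic minority samples as
   convex combinations of k ≤ 5 nearest minority neighbours; a singleton
   minority falls back to duplication with a warning), fit, then validation
   AUROC plus sensitivity/specificity at the 0.5 probability threshold.
   Folds whose validation set contains one class get no AUROC and are
   excluded from the mean with a warning.
9. **Cross-validation structure** — participants are assigned whole to
   folds (group integrity is asserted on every run) by a seeded greedy
   procedure that balances each class's window counts across folds,
   minority class first. With k = number of patients this reproduces the
   one-patient-per-fold layout; k = number of participants gives
   leave-one-participant-out.
10. **Participant decision** — hard majority voting: IBD iff at least 50 %
    of a participant's windows are called IBD; the tie at exactly 50 % goes
    to IBD by the "at least" rule. The participant-level IBD score is the
    mean window probability; Spearman's r relates it to biomarker levels
    over the patient group.

## Segmentation model

The bundled encoder (`tiny_cnn`) is a 1-D U-Net over the time axis with Mel
bins as input channels: two stride-2 convolutions (kernel 5; 128→32→64
channels) halve the frame axis twice, a kernel-3 bottleneck mixes context,
two nearest-neighbour ×2 upsampling stages with kernel-3 convolutions
restore resolution, the first decoder stage adds the first encoder
activation (skip connection), and a 1×1 head produces one logit per frame —
this collapses the frequency axis before the sigmoid. All weights are
He-initialised; inputs are standardised with training-set mean/SD stored in
the checkpoint. ~51k parameters. It is implemented directly on numpy with
hand-written backprop; the backward pass is verified against numerical
differentiation to ~1e-8 relative error in the test suite's development
history and the loss/gradient path is covered by closed-form tests. An
`efficientnet_b2` encoder name is reserved as a transfer-learning hook and
deliberately not bundled.

**Loss** — sum of mean binary cross-entropy over valid frames and dice loss
`1 − 2Σpt/(Σp + Σt + ε)`, ε = 1e-6, pooled over the batch during training.
Padded frames carry no loss and no gradient.

**Optimisation** — Adam with β₁ = 0.95, β₂ = 0.999, weight decay 5e-7;
25 epochs of random batches of 32; initial learning rate lr₀ held for five
epochs and multiplied by 0.85 each epoch from the sixth
(`lr(e) = lr0 · 0.85^(e−5)` for e ≥ 6). "Imbalanced" batching means plain
random batches without class-balanced sampling. The default lr₀ = 1e-4 is
the recipe appropriate for a pretrained encoder; training
the bundled tiny encoder from scratch at that rate cannot move
He-initialised weights appreciably within ~50 Adam steps, so the training
examples and fixtures use lr₀ = 3e-3, chosen by a pilot run before the
evaluation thresholds were frozen. **Augmentation** (training only):
frequency masking up to 24 contiguous Mel bins, time masking up to 10 % of
frames (input only), additive white noise at uniform 20–40 dB SNR relative
to the spread of spectrogram values, and joint time rolls of spectrogram and
target by up to ±10 frames.

**Spotting evaluation** — frame level: per-frame precision/recall. Event
level: a predicted event is a true positive iff it temporally overlaps a
ground-truth event, matched one-to-one greedily by start time. Undefined
ratios (empty denominator) are reported as undefined, not as 0.

**Inter-rater agreement** — Cohen's κ on binary occupancy sequences obtained
by discretising both tracks at a common resolution (default 1/fs);
κ = (p₀ − pₑ)/(1 − pₑ) from the 2×2 confusion; pₑ = 1 (both tracks constant
and identical) is reported as degenerate rather than 0/0.

## Synthetic cohort simulator

The simulator reproduces the *statistical structure* the analysis assumes,
not peristalsis acoustics:

- **Background**: pink (1/f) noise at a per-participant level
  (N(−40, 2) dB relative to unit burst peak), plus artefacts (broadband
  clicks, 15–35 Hz rumble) at 0.5/min by default.
- **BS bursts**: exponentially damped sinusoids (τ = duration/4, 2 ms
  attack) mixed with band-limited noise at a per-event center frequency;
  durations log-normal (median 80 ms, σ = 0.8 log-units) clipped to
  [18 ms, 3 s]; Poisson placement without overlap (150 ms margin, beyond
  the 100 ms merge gap, so ground truth is stable under the event grammar).
- **Class structure**: per-participant center frequency ~ N(500, 60) Hz and
  event rate ~ N(2.0, 0.4)/min for healthy; IBD means are shifted by
  `class_effect` participant-SDs on both parameters, so `class_effect = 0`
  makes the cohorts statistically identical (verified by KS tests) and
  `class_effect = 2` plants a strong, recoverable difference (realised
  MFCC-mean separation ≥ 1.5 SD at the fixture seed, asserted in the
  suite). These effect sizes are free parameters of the simulator — nothing
  quantitative is known about BS spectra per IBD state — and are not
  calibrated to any clinical cohort.
- **Biomarkers**: class-conditional lognormals (fCP medians 300 vs 30 µg/g,
  CRP 8 vs 1 mg/L) and normal leukocyte counts (8.5 vs 6.0 /nL); disease
  activity is exactly fCP > 250 µg/g. Biomarkers are conditionally
  independent of the acoustic parameters given the class.
- **Determinism**: every output is a pure function of (config, seed);
  per-participant and per-channel streams derive from the master seed.

What passing tests show: the pipeline recovers a planted class difference of
the stated size, stays at chance when none exists, and cannot classify from
BS-free noise when the noise model is class-independent. What they do not
show: performance on clinical recordings — real BS spectra, artefact
structure, inter-patient variability and class differences are unknown here,
so no clinical-scale performance figure is claimed or reproducible from
synthetic data.

## Problem sizes and numerical choices

- Fixtures and the acceptance script use desk-scale conditions chosen as
  realistic for the design: 10 participants per class, 30 min recordings,
  one channel, δ = 600 s (3 windows per participant), k = 5 folds;
  spotter training on ~50 clips from a 500 s high-SNR recording
  (burst SNR ≳ 20 dB), evaluation on a held-out 200 s recording. The full
  2 h, 3-channel, 45-participant protocol is configurable.
- Pink-noise synthesis runs its FFT in single precision (the dominant cost
  at hour scale); everything downstream is float64.
- Probability threshold 0.5 everywhere a binary call is needed (frame
  masks, window calls); no ROC-derived operating points.
- Event-to-window assignment by event start time; windows are anchored at
  t = 0 and fasting/postprandial audio is one timeline per participant.
- Per-fold seeds derive deterministically from the master seed; SMOTE uses
  k = min(5, minority − 1) neighbours.
- δ-sweep grid default {1, 5, 10, 30, 60, 120, 300, 600} s.

## Known limitations

- The tiny encoder is sized for CPU training on synthetic bursts; it is not
  expected to match a pretrained EfficientNet-B2 on real audio.
- The exact per-event feature list of the original study's supplement is
  unavailable; the implemented registry is a superset sufficient to express
  the selected 11 MFCC means, and the registry documents what it contains.
- Mean-of-fold-AUROC on small grouped cohorts is a noisy estimator: null
  cohorts legitimately produce values meaningfully below or above 0.5 at
  single seeds (windows of one participant are correlated, shrinking the
  effective sample size).
- Multi-microphone source localisation and CD-vs-UC discrimination are out
  of scope.
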