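# bowelspot

Bowel-sound event spotting and IBD-vs-healthy classification from continuous
abdominal audio, with a built-in synthetic cohort simulator.

## The problem

Bowel sounds (BS) are short acoustic events (18 ms – 3 s) produced by
gastrointestinal motility and audible on the abdominal wall. Inflammatory
bowel disease (IBD) can alter how often they occur and what they sound like,
which makes wearable abdominal microphones a candidate for cheap,
non-invasive screening — but BS are rare and buried in hours of noisy
recording, so the analysis has to solve two problems in sequence:

1. **Spotting** — find the sparse BS events in continuous audio. Clips of
   10 s are converted to 128-bin log-Mel spectrograms (25 ms Hann window,
   10 ms hop, zero-padded in time to the 1,056-frame model input). An
   encoder–decoder segmentation network predicts, per frame *t*, the
   probability *p(t)* that the frame contains BS. Runs of positive frames
   become events under the annotation grammar: events closer than 100 ms are
   merged, events shorter than 18 ms are dropped.
2. **Classification** — decide IBD vs. healthy per participant. Audio is
   band-passed (zero-phase Butterworth, order 8, 60–5,000 Hz), acoustic
   features (MFCCs, spectral descriptors, ZCR, RMS, duration) are computed
   over 32 ms/8 ms frames around each event and averaged. Events are grouped
   into non-overlapping classification windows *S<sub>i</sub>* of duration
   δ (default 10 min); each window contributes the per-feature mean and
   variance as one classifier sample. A gradient-boosting classifier
   (exponential loss) is evaluated under group-stratified k-fold CV with
   SMOTE balancing of each training fold, and participants are called IBD by
   hard majority voting: IBD iff at least 50 % of their windows are called
   IBD (window call = probability ≥ 0.5).

The clinical recordings this design targets are not public, so the package
ships a **synthetic cohort simulator**: damped-sinusoid BS bursts over pink
noise with artefact transients, two cohorts whose burst spectra and event
rates differ by a configurable class effect, and biomarker panels (faecal
calprotectin with the 250 µg/g activity threshold, CRP, leukocytes). All
tests and the acceptance script run end-to-end on these synthetic cohorts.

## Worked example

`examples/classify_cohort.py` simulates 12 participants (6 IBD, 6 healthy,
20 min each, class effect 2 participant-SDs), extracts event features from
the ground-truth annotations and runs the classification stage:

```
48 classification windows from 12 participants
window-level: mean AUROC 0.812 (SD 0.209) across 5 folds
participant-level (majority vote): accuracy 0.83, sensitivity 0.83, specificity 0.83
  HC01: mean IBD prob 0.45 -> healthy (truth: healthy)
  HC02: mean IBD prob 0.55 -> IBD (truth: healthy)
  ...
```

The window-level AUROC measures how well single 5-minute windows separate
the classes; the majority vote aggregates a participant's windows into one
screening decision. `examples/spot_events.py` trains the bundled tiny
segmentation model on ~40 synthetic clips and reports event-level
precision/recall on a held-out recording (1.00 / 0.89 at the default seed);
`examples/window_sweep.py` shows mean AUROC rising (0.95 → 1.00) and its SD
shrinking as the window duration δ grows from 1 s to 10 min;
`examples/rater_agreement.py` computes sample-resolution Cohen's κ between a
truth track and a simulated imperfect rater; `examples/simulate_cohort.py`
prints what the simulator plants.

A thin CLI wraps the same stages:

```bash
bowelspot simulate --out run/ --seed 7 --n-ibd 4 --n-healthy 4 --duration 600
bowelspot features --audio run/ --manifest run/manifest.csv --delta 600 --out run/windows.csv
bowelspot classify --features run/windows.csv --k 4 --seed 0 --report run/report.json
```

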