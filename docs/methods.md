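# Methods

This note records the modelling assumptions, the defaults that matter,
and the design decisions taken where the architecture left genuine
choices open. It documents what the code computes; every number quoted
elsewhere is produced by the tests or by `scripts/acceptance.py` at run
time.

## Problem and model

The task is single-label classification of a standard 12-lead ECG
record (6–60 s, originally 500 Hz, with age and sex) into nine rhythm
classes in the frozen order N, AF, I-AVB, LBBB, RBBB, PAC, PVC, STD,
STE. Records may carry up to three concurrent diagnoses; training
always uses the first label, and cross-validation scoring credits a
prediction that matches *any* of a record's labels (scored against the
matched label).

The classifier is a two-stage stack:

1. **Twelve per-lead CNN-BiLSTM networks.** Each lead is cut into ten
   6-s segments; a four-layer 1-D convolutional branch (batch-norm,
   ReLU, max-pooling after the first three blocks, global average
   pooling) embeds each segment; the ten embeddings, in time order,
   drive a bidirectional LSTM whose two final hidden states are
   concatenated and classified by a dense softmax layer. Dropout with
   keep probability 0.5 separates the convolutional and recurrent
   stages.
2. **A gradient-boosted-tree fuser.** Per record, the 12 × 9 softmax
   matrix is truncated to its first eight columns (the ninth is
   redundant given rows sum to 1), flattened to 96 values, and extended
   by seven HRV statistics, age, and sex to a 105-vector; a multiclass
   XGBoost model (softprob over the 9 indices) produces the final
   label.

## Tunable parameters

| Parameter | Default | Notes |
|---|---|---|
| analysis rate | 250 Hz | downsampled from the recording rate; polyphase FIR with linear-extension padding |
| wavelet | DB6, 9 levels | sub-bands selected by level index: A9, D1, D2 zeroed, D3–D9 kept |
| segment length / count | 6 s × 10 | starts `round(i·(N−L)/9)`; shorter and longer slices are configurable but untuned |
| z-score | per segment, population SD | constant segments map to zeros (flagged) |
| conv filters / kernel / pool | (16, 32, 32, 64) / 7 / 3 | the published architecture leaves these free; tests and the scaled experiments use the miniature profile (4, 6, 6, 8) with 8 LSTM units |
| branch weights | shared across the 10 segments | `share_branch_weights=False` instantiates ten independent branches |
| optimizer | SGD, lr 0.01, momentum 0.9, batch 32 | conventional defaults; the loss is cross-entropy |
| QRS detector | band-pass 5–15 Hz, 150 ms integration, adaptive dual thresholds, 200 ms refractory | Pan–Tompkins-style; R positions refined on the band-passed signal |
| SampEn | m = 2, r = 0.2·SDRR | both template lengths use n−m templates; all-match ⇒ 0, no-match ⇒ flagged ceiling −ln(2/((n−m−1)(n−m))); series shorter than m+2 intervals ⇒ 0, flagged |
| pNN50 divisor | number of RR intervals | the common elsewhere convention (number of successive differences) is a config switch |
| fusion booster | lr 0.1, depth 5, min-child-weight 4, colsample 0.8/0.2, subsample 0.6, gamma 0.4, 108 rounds | the probability-only variant uses depth 10, min-child-weight 2.6, colsample 0.7/1.0, subsample 0.7, max-delta-step 5, gamma 0.3, 120 rounds |

## Design decisions

* **Slicing rule.** Only the two boundary behaviours are fixed by the
  method (ten copies at 6 s, ten disjoint slices at 60 s); evenly
  spaced starts are the minimal interpolation between them and are what
  `segment_starts` implements.
* **Wavelet sub-band selection by level, not by printed frequency.**
  At a 250 Hz analysis rate the dyadic band edges are 125/2^k Hz; the
  selection is therefore defined by level index (drop A9, D1, D2),
  which is the only internally consistent reading.
* **Oversampling inside cross-validation.** Minority classes are
  replicated *within* each stratified subset (whole-set replication
  when at or below half the reference count, random top-up otherwise),
  and only subsets acting as training folds contribute replicas; the
  held-out fold keeps natural class frequencies, so no record or copy
  of it ever appears on both sides of a split.
* **Out-of-fold stacking.** The fuser is trained on probabilities the
  lead models produce for records they were not trained on (an internal
  80/20 split of each training fold, stratified by class); training the
  fuser in-sample is available as `stack_fraction=0` but optimistic.
* **QRS detection.** A Pan–Tompkins-style detector replaces external
  annotation tooling; its contract (deterministic, 200 ms refractory,
  empty output on flat signals) is what the HRV stage relies on.
  Records where detection fails receive training-set median HRV values
  and a logged flag.
* **Missing demographics.** Age is imputed with the training-fold
  median (never zero — zero is a plausible age only for neonates and
  would silently bias the tree splits); sex is encoded female = 0,
  male = 1, missing = 0.5.
* **Neural layers in numpy.** The per-lead networks are implemented as
  a compact, explicitly differentiated numpy stack (`ecgfusion.nn`),
  sized for CPU-scale experiments; gradients are verified against
  central differences in the test suite. XGBoost, in contrast, is used
  as a dependency — the fusion stage's contribution is the feature
  assembly and stacking protocol, not the boosting algorithm.

## The synthetic generator

`ecgfusion.synth` emulates the *structure* of a 12-lead arrhythmia
dataset, not its clinical appearance. Beats are sums of Gaussian
P/Q/R/S/T bumps plus a smooth ST plateau, projected to the 12 leads by
fixed gains; rhythm is an RR process (truncated normal, per-class mean
and jitter) with optional premature beats and compensatory pauses.
Class caricatures: AF = high RR jitter + absent P; I-AVB = long PR;
LBBB/RBBB = widened QRS with lead-dependent polarity; PAC/PVC = 15 %
early beats (narrow vs wide); STD/STE = ∓ ST offsets on lateral/
anterior leads. Record lengths are offset-exponential (6 s floor,
10 s mean excess, 60 s cap), matching the short-record-dominated length
profile of clinical snapshot archives; ages ~ N(60, 15²) clipped to
[18, 95]; one integer seed with per-record substreams keyed by
`(seed, index)`.

What passing tests therefore show is that the *pipeline mechanics* are
correct and that the fusion design extracts complementary information
when it exists — not that the model reaches clinical accuracy: real
ECGs add inter-subject morphology variation, electrode artefacts,
respiration, and label noise that the generator deliberately omits.

## Problem sizes used by the test suite

The scaled-down cross-validated comparison runs on 400 synthetic
records over four classes (N, AF, PAC, STD) whose identity is partly
RR-borne, conditioned at a 100 Hz analysis rate (600-sample segments),
with the miniature lead-model profile trained for two epochs, in three
seeded repetitions of the full 5-fold ablation (twelve single-lead
models, probability-only fusion, and full fusion from the same fold
fits). These sizes are the package's own scaled experiment design; the
expected orderings (fusion ≥ best single lead; domain-specific features
help) must hold in at least two of the three repetitions.

## Known limitations

* The generator's class separability is optimistic: morphology
  differences are large relative to noise, so absolute scores on
  synthetic data say nothing about clinical datasets.
* The WFDB dialect quantizes on write (documented ADC gain; default
  1000 adu/mV ⇒ ±0.5 µV·mV⁻¹ rounding); round trips are exact only
  after the first write.
* SampEn on short RR series (< 10 intervals) frequently hits the
  no-match ceiling; it is flagged, not an error, and trees tolerate
  the resulting plateau.
* Frequency-domain HRV, multi-label prediction, and attention/residual
  lead-model variants are out of scope.
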