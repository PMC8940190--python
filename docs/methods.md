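# Methods

`voicedx` implements a frame-level classification pipeline for four common
voice disorders — functional dysphonia (FD), glottic neoplasm,
phonotraumatic lesions, and vocal-fold palsy — from either a sustained /a/
or continuous multi-syllable speech, together with a synthetic corpus
generator that stands in for clinical recordings.  This note documents the
models, the numerical choices, and what the synthetic experiments do and do
not show.

## Synthetic voice model

Utterances are produced by a source-filter synthesizer:

* **Glottal source.** A Rosenberg-pulse (flow-derivative) train with 40%
  opening and 16% closing phase per cycle.  Cycle onsets advance by the
  instantaneous period of a per-sample f0 envelope; the pulse shape follows
  the *unperturbed* local period so that jitter enters only through cycle
  spacing.  Aspiration is white noise high-passed at 1 kHz and mixed at a
  linear gain `g` relative to the voiced RMS, giving a harmonics-to-noise
  ratio of `-20 log10 g` dB.
* **Perturbations.** Jitter and shimmer are i.i.d. Gaussian cycle
  perturbations (clipped at 3 sigma).  Because the expected absolute
  difference of two i.i.d. standard normals is `2/sqrt(pi) ~ 1.1284`, the
  drawn sigma is the configured value divided by that constant; the
  *measured local* jitter (mean |dT|/mean T) and shimmer (mean |d 20log10 A|)
  then match the configured percent/dB in expectation.  A peak-picking
  estimator recovers configured jitter within about a quarter point on
  2-second sources.
* **Vocal tract.** A cascade of three 2nd-order resonators (F1-F3) with
  unity DC gain, coefficients updated every 256 samples with carried filter
  state.  The sustained vowel uses the standard /a/ targets 700/1220/2600 Hz
  with 80/100/120 Hz bandwidths; continuous mode moves the targets between
  per-syllable vowels with linear ramps.
* **Continuous mode.** Each script item is a sequence of 7-14 syllable
  vowel targets.  Besides the static source perturbations, each disorder
  class carries *transition dynamics*: syllable-onset formant/f0 transition
  time (50-200 ms across classes), a signed per-syllable f0 onset glide
  (+3 to -6 semitones), syllable duration (0.16-0.22 s), and inter-syllable
  amplitude dip depth.  These class-coded dynamics are what makes the
  continuous condition more informative than the vowel condition — the
  effect the pipeline is designed to demonstrate.
* **Format.** 44.1 kHz mono; in-memory synthesis stays in float64, 16-bit
  PCM quantization happens only on WAV write.  Every utterance begins with
  120 ms at the recording noise floor (-55 dB re voiced RMS) so the VAD's
  noise model can initialize from speech-free frames.

### Disorder profiles

The four default profiles are **invented** acoustic phenotypes (the
diagnoses themselves carry no published acoustic parameterization):

| class        | jitter % | shimmer dB | HNR dB | other                      |
|--------------|----------|------------|--------|----------------------------|
| FD           | 0.5      | 0.4        | 25     | low loudness variation     |
| neoplasm     | 3.0      | 0.8        | 18     | slow falling onsets        |
| phonotrauma  | 1.5      | 1.5        | 15     | deep inter-syllable dips   |
| vocal palsy  | 2.0      | 1.0        | 8      | 4 Hz tremor, slow syllables|

Each speaker draws its values uniformly around the class mean: +/-60%
relative for jitter/shimmer and +/-8 dB for HNR, plus nuisance variation in
base f0 (110-220 Hz) and vocal-tract length (+/-8% formant scaling).  The
spreads were calibrated so that a sustained-vowel classifier lands in the
55-75% UAR range — i.e. the static perturbation cues overlap heavily across
classes, as they do clinically — while the continuous-mode transition cues
remain cleanly class-discriminative.  `profiles_with_separation(scale)`
rescales the transition-parameter differences around their across-class
mean for separation-sensitivity experiments.

## Voice activity detection

Complex-Gaussian speech/noise hypotheses per STFT bin give the likelihood
ratio `Lambda_k = exp(gamma_k xi_k/(1+xi_k))/(1+xi_k)` with a-posteriori
SNR `gamma` and a-priori SNR `xi`.  `xi` follows the decision-directed
recursion (weight 0.98, floor 1e-3) using the MMSE short-time
spectral-amplitude gain for the previous frame's clean-amplitude estimate.
The frame statistic is the mean over bins of `log Lambda` (the log of the
geometric mean), smoothed across frames with coefficient 0.9 and held at
its 4-frame running maximum (a 3-frame hangover).  Frames whose statistic
reaches the threshold — default **0.9 in the log domain** — are speech.
The log domain is a deliberate choice: for speech-absent frames the
geometric-mean LR concentrates at ~1 (its log at ~0 < 0.9), so noise is
rejected, while voiced frames exceed the threshold by orders of magnitude.
The noise model initializes from the first 6 frames and adapts (rate 0.95,
variance floor 1e-12) on frames whose instantaneous statistic is below
threshold.  VAD framing reuses the MFCC geometry (no pre-emphasis), so the
speech mask indexes feature frames one-to-one.

## Feature extraction

Pre-emphasis 0.97; 32 ms Hamming frames at 16 ms hop (1411/706 samples at
44.1 kHz); 2048-point FFT; power spectrum; 26 triangular filters equally
spaced on the mel scale `m(f) = 2595 log10(1 + f/700)` from 0 to fs/2;
natural log floored at 1e-10; orthonormal DCT-II keeping coefficients 0-12
(c0 retained); regression deltas with window N=2 and edge replication.
Non-speech frames are dropped *before* the delta computation so deltas
describe the kept speech stream.  The result is the frames x 26 matrix
(13 static + 13 delta) consumed by every classifier.

## Classifiers and training

* **DNN** — three 200-unit relu layers + softmax head, frame-wise
  (86,604 parameters for K=4).
* **LSTM / GRU** — two 50-cell recurrent layers, dropout 0.2 on layer
  outputs, linear+softmax head over the whole sequence.
* **BiLSTM** — two stacked bidirectional blocks; each block runs a forward
  and a backward 50-cell LSTM over the sequence and **sums** their outputs,
  so the hidden width stays 50.
* **RF** — 26-tree bootstrap ensemble (Gini, unpruned) on single frames,
  via scikit-learn.

The neural stack (layers, BPTT, Adam) is implemented in NumPy (float32).
Every frame inherits its utterance's diagnosis; training minimizes masked
frame-level cross-entropy with Adam at learning rate 0.001 (DNN/GRU) or
0.0005 (LSTM/BiLSTM).  Epochs (default 30; the experiment harnesses use 15
at their corpus sizes, where the loss has plateaued) and batch size (16
utterances, bucketed by length, padding masked out of the loss) are
package choices.  Input features are standardized per dimension with
training-set statistics stored on the model.  Initialization, shuffling and
dropout all flow through seeded generators: a fixed seed reproduces
training bit-for-bit.  Speaker-disjoint k-fold validation (default 5
folds) is available as `crossval_uar`; the experiment harnesses report
held-out-split metrics directly.

## Inference and metrics

Per-frame posteriors are argmax-voted; the most frequent class is the
utterance label (vote tie -> higher mean posterior -> lower class index;
ties are not observed in practice but the rule makes inference total).
From the truth x prediction confusion matrix: accuracy = 100 trace/total;
per-class sensitivity = 100 TP/(TP+FN); UAR = unweighted mean of the K
sensitivities (K=4, or 3 for the challenge-style subset).  The binary
TP+TN accuracy form reduces to trace/total in the multiclass setting;
the TN-inclusive one-vs-rest average is also reported
(`accuracy_macro_ovr`) but not used, since it inflates with K.

## Experiment designs and problem sizes

* **Condition comparison** trains each model kind on matched continuous and
  vowel corpora (same profiles, counts, seed lineage) and tabulates test
  accuracy/UAR.  The package's reference configuration uses 40 utterances
  per class (one speaker each, 80/20 speaker-disjoint split) and 15 epochs;
  the BiLSTM continuous-minus-vowel UAR gap is reported as the median over
  three seeds.
* **Sentence selection** trains one BiLSTM per script item on a fresh
  corpus of single-item utterances and ranks items by UAR, then accuracy,
  then script id.  Item rankings on synthetic scripts reflect syllable
  count and vowel diversity, not any property of real sentences.
* **PCA visualization** mean-pools the last recurrent layer's activations
  per utterance (50-dim), mean-centers, and projects onto the top two
  principal axes (no whitening).  On the reference continuous corpus the
  four classes separate with mean silhouette well above 0.3.

## What the synthetic experiments show — and what they do not

Passing tests demonstrate that the pipeline is implemented correctly and
that, *when class identity rides partly on syllable-transition dynamics*,
sequence models exploit continuous speech far better than sustained vowels
(median UAR gap ~15-30 points at the sizes above).  They do not validate
clinical performance: the disorder profiles are invented, the synthetic
classes are cleaner than clinical populations, channel/recording variation
is absent, and the random forest — which sees transition information
through delta features frame-by-frame — can be unrealistically strong on
synthetic data.  Numbers obtained here are not comparable to results on
clinical corpora.

## Numerical details and edge cases

* Variance floor 1e-12 (VAD noise model), xi floor 1e-3, log-mel floor
  1e-10.
* All-zero input: the VAD returns an empty speech mask; the pipeline
  raises `UnvoicedInputError` rather than guessing.
* A class with no true test examples makes sensitivity undefined; metrics
  raise instead of returning NaN.
* Corpus generation is lazy: replica-size corpora (1,045 / 1,061 / 150
  utterances) can be counted and partitioned without synthesizing audio.
* A split requires at least two speakers per class; the train share is
  `round(split_fraction * n_speakers)` clamped to leave both sides
  non-empty.
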