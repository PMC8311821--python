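# Methods

## Overview

`wristmic` implements an automated speech-detection analysis for wrist-worn
low-fidelity audio recorders used as social-functioning sensors: from mono
8 kHz waveforms to frame-level speech probabilities, minute/day/time-of-day
speech-occupancy summaries, a wearer-attribution measure, classifier
evaluation by leave-one-session-out (LOSO) cross-validation, and the group
statistics layer used to compare a clinical group against controls.

Real recordings of this kind cannot be listened to or shared (the audio is
private by design), so the package is driven end to end by a synthetic
acoustic-cohort generator with exact frame-level ground truth.  Every claim
the test suite makes is therefore a claim about the pipeline's behaviour
under these synthetic study conditions, not about clinical recordings; see
"What the generator does and does not emulate" below.

## The measurement chain

The device contract is mono PCM audio at 8 kHz.  Conditioning follows the
deployment recipe exactly:

1. **Rescale** each recording into (−1, 1) with one global gain
   (`x / (max|x| + ε)`).  Per-recording (not per-frame) scaling preserves the
   within-recording level contrast between near and distant sources, which
   the wearer model later feeds on.
2. **Frame** into non-overlapping 32 ms windows (256 samples); the trailing
   partial frame is dropped.
3. **Standardize** each frame to zero mean and unit sample variance
   (ddof = 1).  Constant frames are mapped to zeros and flagged.  The
   pre-standardization log frame power is kept alongside the frames because
   standardization deliberately erases absolute level; relative level is
   reintroduced as an explicit feature (below), never as raw amplitude.

Two binary frame classifiers sit on top:

* **Model 1 (speech vs non-speech).** Positive class: live human speech
  (wearer or bystander).  Negative class: everything else, including
  device-generated speech (TV/radio) — the model must *reject* loudspeaker
  speech, which is the hard part of the task.
* **Model 2 (wearer vs other).** Applied only to frames Model 1 called
  speech (frame probability > 0.5) inside speech minutes; positive class is
  the wearer's own speech.

Aggregation to behavioural measures:

* a minute *contains speech* iff the mean frame probability over the minute
  is **strictly** above 0.5;
* daily speech % = 100 × speech minutes / epoch minutes, with the epoch
  fixed at the full day (1440 minutes at natural scale) whether or not every
  minute was recorded — unrecorded minutes count as non-speech;
* time-of-day % uses morning [06:00, 12:00), afternoon [12:00, 18:00) and
  evening [18:00, 24:00) bins with half-open boundaries (minute 720 is
  afternoon); 00:00–06:00 lies outside all bins but stays in the 24-h
  denominator;
* the 7-day value is the arithmetic mean of daily values (same for bins);
  fewer than the expected days → computed over what exists, flagged
  incomplete;
* the **wearer measure**: per speech minute, 100 × (frames with wearer
  probability > 0.5) / (speech frames in that minute); the participant value
  is the *unweighted* mean of these per-minute percentages across all speech
  minutes pooled over days.  A participant with no speech minutes gets a
  missing value, not zero.  The two measures are not directly comparable by
  construction: Model 1's denominator is all frames, Model 2's is speech
  frames only.

Evaluation is LOSO: each session is held out once, models are retrained on
the rest, and frame-level confusion counts are pooled across folds
(micro-average), with per-fold metrics retained.  Pooling was chosen because
sessions differ in class balance; a mean-of-folds macro view is recoverable
from the per-fold entries in every report.

## Classifier architecture

The classifiers are compact multilayer perceptrons (scikit-learn
`MLPClassifier`) over engineered frame features, trained per fold in seconds
on one CPU with balanced class subsampling (speech is rare at deployment
scale; unbalanced training collapses to the majority class).  Training is
deterministic given the seed.

Feature modes (selectable on `ModelSpec`):

* `band_energy` (Model 1 default, 14 dims): energy below 300 Hz and above
  3000 Hz relative to the 300–3000 Hz mid band (live speech carries
  fundamental energy below 300 Hz and aspiration noise above 3 kHz; a
  band-limited loudspeaker channel has neither), each at three temporal
  scales, plus the relative-level features below at two scales.
* `level_contour` (Model 2 default, 8 dims): level above the recording's
  quiet floor (10th percentile of log frame power), level relative to the
  local context mean, local level spread (syllabic modulation depth), and
  smoothed level above floor — at a ±3-frame and a ±15-frame (~±0.5 s)
  horizon.  These encode the physics of wrist proximity: the wearer's mouth
  is close, so wearer speech is louder, drier, and keeps deep
  inter-syllable dips, while distant speech is quieter with
  reverberation-filled dips and compressed loudspeaker audio has reduced
  modulation depth.
* `log_spectrogram` (129-bin log-magnitude rFFT per frame + context mean +
  the band/level features) and `raw_frame` are retained as options.

The compact modes are the defaults because session-held-out validation
punishes anything that can memorize speaker identity: with one wearer voice
per session, a 258-dimensional spectral representation lets the network
classify *who* rather than *what*, which collapses on held-out voices.  The
band/level features are speaker-independent by construction and generalize
across sessions.

A training-free **baseline VAD** (logistic squashing of log frame energy
referenced to the recording's quiet floor, discounted by spectral flatness)
is provided for comparison.  It has no concept of device speech — a loud
television scores high — which is precisely the failure mode the trained
detector improves on; the trained model's pooled F1 exceeds the baseline's
by a wide margin on every corpus seed we run.

An **oracle classifier** that emits ground truth as {0, 1} probabilities
feeds the identical aggregation path, so the measurement chain downstream of
the models is tested in isolation: with the oracle plugged in, the pipeline
must reproduce the generator's exactly-counted truth profiles *exactly*
(it does; this identity is asserted without tolerance).

## The synthetic generator

**Speech** is source-filter synthesis: a sawtooth glottal source at the
speaker's fundamental (60–400 Hz) with vibrato and slow pitch drift plus
aspiration noise, pre-emphasized so the formant resonances rather than the
fundamental dominate the envelope, shaped by 2–3 second-order resonators
(formants strictly increasing, < 4 kHz), and amplitude-modulated at a
syllabic 3–6 Hz with dips to 15% amplitude — dips, not silence, so frames
inside an utterance keep voiced content.  Reverberation is an exponentially
decaying noise impulse response whose decay time grows with the wet mix.

**Device speech** reuses the speech synthesizer and applies a fixed
loudspeaker channel: tanh dynamic-range compression, a 300–3000 Hz
band-limit, and one constant room response shared by all device audio.  The
channel is what makes the class learnably distinct — as it must be, since
the deployed classifier demonstrably learned to exclude it.

**Levels** are RMS in dB relative to a bystander reference (REF_RMS = 0.02
full scale): wearer +12 dB with reverb 0.1, bystanders 0 dB with reverb 0.5,
device +3 dB, session noise floor −20 dB.  The +12 dB / dry-vs-wet contrast
encodes wrist proximity and is the physical cue Model 2 exploits.

**Sessions** are event timelines rendered over the noise floor; frame truth
is the majority-occupancy class per 32 ms frame with overlap precedence
wearer > other > device > nonspeech (a deterministic convention: any live
speech in the environment is speech, and the wearer's own voice dominates
attribution).

**Cohorts**: each participant draws a fixed wearer voice, a speech occupancy
and a wearer fraction from their group's normal distribution truncated to
[0, 1] (a warning fires if most of the distribution's mass lies outside).
Packaged group conditions follow the reported clinical contrast: cases
2% ± 1% of minutes with speech and 3% ± 0.3% of speech frames their own;
controls 13% ± 3% and 11% ± 1%.  Speech minutes are placed by diurnal
weights over morning/afternoon/evening (night 00:00–06:00 at weight 0.2 by
default) and filled with 2–7 s utterances to 65–85% coverage, each utterance
wearer-voiced with probability equal to the participant's wearer fraction.
A share (30%) of the rendered silent minutes contains television audio.

**Desk-scale days**: `minutes_per_day` is configurable; simulated minutes
map proportionally onto the 1440-minute clock, so time-of-day semantics and
bin denominators carry over unchanged.  Only minutes containing events plus
a small sample of silent minutes (3 per day by default) are rendered; the
remaining silent minutes are bookkept as non-speech in every denominator.
All randomness flows from one root seed through per-participant/per-day
spawned streams; identical config + seed reproduces bit-identical audio and
truth.

**The training corpus** stands in for an annotated pilot set: 15 sessions of
2 minutes (30 min, ~56k frames), each with its own wearer voice, three
bystander voices and a device voice, mixing all four classes.  Sessions are
the cross-validation unit, so a held-out session is always a cast of unseen
voices.  Session length balances stable per-class frame counts against
per-fold training cost.

### What the generator does and does not emulate

It reproduces the spectro-temporal cues frame-level VADs exploit (harmonic
structure, formant envelopes, syllabic modulation, band-limited loudspeaker
coloration, proximity level/reverb contrasts) and the bookkeeping structure
of multi-day wrist recordings.  It does **not** contain phonetic content,
language, overlapping conversations at realistic turn-taking statistics,
non-stationary real-world noise (traffic, music, wind), device artifacts, or
speaker populations with realistic within-speaker variability.  Passing
tests therefore demonstrate that the pipeline's logic, thresholds,
aggregation arithmetic and evaluation protocol are correct and that the
models can learn class structure from data under controlled conditions —
not that the specific accuracy numbers would transfer to field recordings.
Classifier performance here comfortably exceeds the published field numbers
precisely because the synthetic classes are cleaner than reality; the
published values are used as lower bounds, not as calibration targets.

## Statistics layer

* **Mann–Whitney U** by midrank sums; `statistic` is U of the first group
  (complete separation with the first group lower gives U = 0).  The normal
  approximation uses the tie-corrected variance
  `n1 n2 /12 · ((N+1) − Σ(t³−t)/(N(N−1)))` with **no continuity
  correction**; two groups of 29 in complete separation give
  z = −420.5/√(29·29·59/12) ≈ −6.539.  For n1+n2 ≤ 12 an exact two-tailed
  permutation p (full enumeration, symmetric-deviation definition) is
  computed and reported.
* **Welch t** with Satterthwaite fractional df is the default t test (the
  study context involves unequal variances; fractional df appear in the
  reported results).  Degenerate zero-variance inputs yield t = 0 (equal
  means) or a flagged infinite statistic.
* **Test selection**: a variable is "skewed" when either group's sample
  skewness exceeds 1 in magnitude (configurable; force-override available);
  skewed variables get the U test, others Welch.  The same policy drives
  Pearson-vs-Spearman selection in `correlate` (pairwise missing-data
  removal, n ≥ 3, constant inputs flagged rather than crashing).
* **Cognitive standardization**: per task, z = orientation × (raw − control
  mean)/control SD, so higher always means better; a domain score is the
  mean of member-task z-scores, the Grand score the mean of domains.  The
  task → domain map ships as a user-editable example (see
  `analysis/05_group_statistics.py`), not as a claimed reconstruction of any
  particular battery.  Zero-SD tasks are excluded with a warning.
* No multiple-testing correction by default, matching the analysis style the
  pipeline reproduces; `group_table(..., fdr=True)` adds Benjamini–Hochberg
  adjusted p-values.

Tests cross-check every statistic against scipy reference implementations
(1e-8) and against brute-force enumeration oracles written independently of
the implementation.

## Problem sizes and numerical choices

* Packaged corpus: 15 × 2 min; LOSO of both models ≈ 1.5 min on one CPU.
* Parameter-recovery experiment: the speech model is trained once on the
  corpus (mirroring deployment, where one trained model is applied to all
  participants) and applied to 20 independently seeded cohorts of 5 + 5
  participants × 1 day × 48 simulated minutes; estimated group occupancy
  means must sit within 1 percentage point of exact generator truth with
  complete group separation (U = 0) in ≥ 19 of 20 replicates.
* Demonstration cohort in `analysis/`: 10 + 10 participants × 2 days × 96
  minutes/day.
* Thresholds are strict (`> 0.5`) everywhere a call is made; minute calls at
  a mean probability of exactly 0.5 are non-speech.
* Constant frames are detected by exact peak-to-peak equality (a float std
  of a constant is ~1e-17, not 0).
* Rescale of an all-zero recording is the identity; empty recordings are
  errors; recordings shorter than one frame yield an empty FrameSet with a
  warning.

## Known limitations

* The classifier architectures are explicit stand-ins (compact MLPs over
  engineered features), not reconstructions of any particular deployed
  network; raw-frame and spectrogram modes exist but are not the defaults
  for the reasons above.
* Model 2's level-contour features assume the recording contains some quiet
  frames to estimate the floor; a minute wall-to-wall with speech would bias
  the floor estimate upward (the generator's 65–85% coverage leaves enough
  quiet material).
* The wearer measure is undefined (missing) for participants with no speech
  minutes; downstream group tests drop missing values.
* Device-changeover stitching assumes at most one changeover per day and
  rejects overlapping sessions rather than resolving them.
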