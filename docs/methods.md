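# Methods

`esmlang` reimplements, as a tested pipeline, an experience-sampling (ESM)
analysis of emotion markers in mobile-sensed language: spoken words (speech
content), voice acoustics (speech form), written words (writing content) and
typing dynamics (writing form), related to seven momentary emotion ratings
(valence, arousal, anger, anxiety, sadness, stress, happiness; 0–100 visual
analogue scale) and to trait-level aggregates including the DASS depression
subscale.  Because the underlying participant data are private, the package
ships a synthetic-study generator with known planted effects; every
statistical claim the test suite makes is made against that generator.

## The synthetic study

**Protocol.** 65 enrolled participants, 14 days, 10 beeps/day.  The first
daily beep falls uniformly in [10:00, 11:00); the other nine land one each
in nine equal blocks of [11:00, 22:00).  All timestamps are milliseconds on
a single local clock.

**Emotion dynamics.**  Momentary emotion is a participant trait mean plus a
unit-variance AR(1) deviation at the beep lag (`emotion_ar_coefficient`,
default 0.5).  Cross-emotion structure comes from one shared latent factor
on which valence and happiness load +0.70, the negative emotions −0.50 to
−0.55, arousal +0.10 — the minimal structure reproducing the observed
positive/negative covariance pattern.  Ratings are `trait + within_sd * z`
clipped to [0, 100]; clipping (rather than truncated sampling) is a
deliberate simplification that mildly biases emotions with trait means near
the floor (anger, anxiety, sadness).  Trait means and between-person SDs
default to the published cohort descriptives; within-person SDs (9–14 VAS
units by emotion) are set to typical ESM moment-to-moment variability.

**Compliance.**  A beep is answered with a per-day probability whose
log-odds decline linearly (default 0.03/day) around a participant-specific
engagement offset (SD 0.9); 8% of participants carry an extra −2.8 offset
(a poorly engaged subgroup).  These four numbers were calibrated once, by
numerical integration before any analysis, to the published compliance
statistics: retained-cohort mean 0.78, SD 0.16, range reaching ~0.26, and
roughly 5 of 65 participants below the 30-answer inclusion threshold.
Voice prompts (base 0.223, decay 0.11/day, SD 1.5) and keyboard activity
(base 0.679, decay 0.05/day, SD 1.0) were calibrated the same way to a
~19% voice response rate with a day-correlation near −0.36 and a ~60%
keyboard rate with a day-correlation near −0.23.

**Planted effects.**  Each feature f carries a latent standardized value
`x_f = Σ_e λ_{f,e} z_e + sqrt(1 − Σλ²) ε`.  The default loading matrix
takes its signs from the expected-direction literature (content words,
acoustic arousal effects, typing dynamics) with per-emotion magnitude 0.15.
Loadings are direct coefficients on the standardized emotions, so loadings
on several mutually correlated emotions accumulate; each feature's loading
vector is therefore rescaled so that its largest *implied marginal
correlation* (through the shared-factor correlation matrix) is 0.25,
keeping all realized within-person correlations inside the weak-effect
band (≈0.05–0.25) that the emulated study reports.

**Content rendering.**  Transcript token counts per lexicon category follow
a multinomial whose category weights are `p0 * exp(g · x)` (gain g = 0.9)
around stream-specific baselines (spoken vs written base rates differ, e.g.
swearing is ~100× more frequent in writing).  Multinomial counting
attenuates the correlation between the *extracted* percentage and the
emotion, so the loading vector of each content feature is pre-amplified by
the analytically derived attenuation factor
`g·m / sqrt(m²(e^{g²}−1) + m(1−m)/N)` (m the mean category proportion, N
the typical token count); the planted loading is therefore the target
correlation on the extracted scale.  Rare categories (e.g. sadness words at
0.16% of spoken tokens) cannot be fully compensated and stay attenuated —
as they would be in real data.  Rendered words are drawn only from surface
forms that match exactly one category, so re-extracting a rendered
transcript reproduces the planted counts exactly (a parity test enforces
this).

**Voice rendering.**  Clips (~3 s, 16 kHz mono PCM) alternate voiced
harmonic-pulse segments and silent pauses.  Within a segment the F0 contour
is a slow sinusoidal modulation plus a 0.8 st/s declination; the amplitude
envelope rises, holds and falls; per-period jitter and shimmer perturb
individual pitch periods (planted jitter ≈ 0.03–0.07, shimmer ≈ 1.3 dB);
white noise over the voiced samples sets the harmonics-to-noise ratio
(≈5 dB by default).  The pulse peak sits slightly inside each cycle
(phase π/8) so period peaks are interior samples.  Ground truth returns the
noiseless parameter contours summarized with the same statistics the
extractor uses; for jitter/shimmer/HNR the truth is the planted parameter
itself.

**Keyboard rendering.**  Around each survey with keyboard activity, 1 +
Poisson(4) entries are generated inside the ±30 min window; characters,
backspace rates (~0.17 of keystrokes), typing speed (~2.1 chars/s) and key
press durations (~80 ms) are log-linear in the planted latents, and message
texts reuse the writing-content renderer.  Keystroke events carry
millisecond press/release stamps.

**What the generator does not emulate.**  Linguistically realistic Dutch,
phonetically realistic speech, netspeak/typos (real-world word recognition
of writing was far lower than of transcribed speech), app failures, unequal
time zones, and any between-person coupling between language and traits —
the default generator plants only *within-person* effects, so trait-level
correlation tables are expected to be null, which is also what the emulated
study found.  Passing tests therefore demonstrate that the statistical
machinery is correct and calibrated on data with the stated structure, not
that real speech or typing behaves this way.

## Feature extraction

**Content (LIWC-style).**  Tokens are maximal letter runs of the lowercased
text (apostrophes kept inside); lexicon emojis are counted and removed
first; exclamation marks are counted separately.  Each of the 11 dictionary
categories is scored as 100 × matched tokens / word count; entries are
exact words or trailing-`*` stems matched by prefix; a token may count
toward several categories.  Single-token matching only — "niet blij"
scores one negation and one positive-emotion word, mirroring the stated
limitation of the emulated tool.  Exclamation marks are reported as a
percentage of word count for writing (configurable to raw counts; the
source material does not disambiguate).  Emoji counts stay raw counts.
The shipped demo lexicon (~100 Dutch-flavoured entries) provides the
required category structure; it is not the proprietary dictionary, so
recognized-token fractions are lower than the published 87% (speech) and
54% (writing) and are simply reported.

**Acoustics.**  40 ms frames, 10 ms hop.  Per frame the normalized
autocorrelation is searched over 55–500 Hz; among local maxima within 0.01
— widened to 0.10 for the shortest-lag preference — of the band maximum the
shortest lag wins (on jittered pulse trains the relative period
perturbation shrinks at lag multiples, so a strict argmax halves F0), with
parabolic interpolation.  A frame is voiced iff the peak ≥ 0.45 and its RMS
is within 60 dB of the clip peak.  The voicing mask is cleaned (single-frame
gaps filled, runs < 3 frames dropped) and the contour median-filtered over
5 frames.  The 13 parameters: F0 mean, SD/mean, 20th–80th percentile range
(the eGeMAPS-style percentile range, consistent with published values of a
few semitones), mean rising/falling slopes over maximal monotone contour
runs (≥ 2 consecutive differences beyond ±0.02 st); the same statistics on
the per-frame RMS loudness proxy; jitter as mean |ΔT|/mean T over
peak-picked pitch periods; shimmer as mean |20·log10(A_{k+1}/A_k)| of raw
peak amplitudes; HNR as the mean of 10·log10(r/(1−r)); voiced segments per
second; and the mean internal unvoiced run length.  F0 is always reported
on the semitone scale `12·log2(f/27.5)`.  "F0 SD" is implemented as the
normalized SD/mean — the published value (0.22 against a mean near 30 st)
is only consistent with a normalized variant.  The loudness proxy is linear
in amplitude, not an auditory loudness model; all downstream analyses are
invariant to within-person monotone rescaling because of standardization.
Known limitation: at realistic jitter levels the frame-level F0 slope
estimates are noise-dominated (extracted-vs-truth correlation ≈ 0.2–0.4),
and additive noise inflates measured jitter and shimmer — as it does for
any waveform-based voice-quality measure.

**Typing dynamics.**  Entries are summarized (characters, backspaces,
duration = last release − first press, speed = characters/duration, mean
press duration) and pooled into a closed-left/open-right
[survey − 30 min, survey + 30 min) bin by first press time; counts and
durations are summed, speed and press duration averaged unweighted over
entries; backspaces and typing duration are divided by total keystrokes
(characters + backspaces).

## Assembly

Voice recordings link to the nearest survey of the same participant within
5 minutes, exact matches first, injectively both ways; of two recordings
competing for one survey the nearer wins and the loser is logged.
Participants need ≥ 30 answered surveys and ≥ 1 linked observation of the
relevant stream; voice and keyboard cohorts are retained independently.
The momentary dataset z-scores every variable per participant over that
participant's linked observations (sample n−1 SD; singletons and
zero-variance variables become missing and are logged).  The trait dataset
averages raw (unstandardized) values over the same linked observations and
adds the DASS depression subscale (mean of 7 items scored 0–3).

## Association stage

Momentary: for each emotion × feature cell, the fixed slope of a two-level
regression with a participant random intercept, estimated by REML.  With a
single random intercept the REML criterion profiles down to a 1-D search
over the variance ratio (Woodbury identity per participant), implemented
directly for speed; agreement with the general mixed-model solver in
statsmodels is enforced by test.  Because both variables are standardized
within person, the slope reads as a pooled within-person correlation.
p-values use the large-sample normal approximation of the Wald statistic;
on very small panels (10 participants × 12 beeps) this is mildly
anticonservative (empirically ≈ 0.067 at nominal 0.05), which the
calibration tests bound.  Trait: Spearman rank correlation (mid-ranks,
t-approximation p).  Each displayed table (level × feature family,
including the depression row at trait level) is one multiple-testing
family corrected by Holm's step-down procedure — the procedure the source
material names, although it controls the family-wise error rate rather
than the FDR its label suggests.  Random intercepts only in these pairwise
models; varying slopes appear only in the predictive stage.

## Predictive stage

Candidates: the Holm-flagged features of the association stage for that
emotion; if none, the 3 largest |estimate| (ties by fixed feature order).
Each of the (default 50) resampled splits divides the data 80/20 —
momentary splits at the observation level stratified by participant (every
participant with ≥ 2 rows keeps a training row; the global test fraction is
exact to one row), trait splits at the participant level.  A 10-fold CV on
the training rows fits the full candidate model per fold and keeps
candidates with mean coefficient p < .05; if none qualify, the 2 smallest
mean-p candidates are kept.  CV screening uses OLS p-values — within-person
standardization removes the between-person variance a random intercept
would absorb — while the final momentary model is a mixed model with a
participant random intercept and per-participant random slopes for each
kept predictor (statsmodels MixedLM, REML).  Singular fits drop random
slopes one at a time, last first, down to an intercept-only random
structure.  Test predictions use a participant's estimated effects when the
participant appeared in training and population-level effects otherwise.
The score is the predictive R² = 1 − MSE(test)/Var(test outcomes) with the
population (n) variance convention; the formula is stated in the source as
MSE/Var, but the reported negative values are only possible with the
standard 1 − MSE/Var, which is what is implemented.  Negative values are
preserved.  Global candidates (from the full-data association stage) are
reused across splits rather than refit per split, matching the described
procedure.  Trait models are OLS.

## Numerical and design choices

- Sample (n−1) SD for standardization; population (n) variance in the R²
  denominator (fixed by a worked micro-example in the tests).
- Bin boundaries closed-left/open-right; entries assigned by first press.
- Voicing threshold 0.45, energy floor 60 dB, frame 40 ms/hop 10 ms.
- "2 best" CV fallback ties break by fixed feature order; candidate
  ordering is the declared feature order of each family.
- Whether the 30-response inclusion count refers to answered surveys or
  linked observations is not specified in the source; answered surveys are
  used.  Per-entry typing duration ignores inter-entry pauses.
- All randomness flows from `numpy.random.SeedSequence` chains rooted in a
  single configuration seed; identical configurations produce byte-identical
  artifacts, including WAV files (synthesis is quantized to the int16 grid).

## Problem sizes used by the shipped experiments

The test suite and `scripts/acceptance.py` run the generator at the study's
protocol size (65 × 14 × 10) for cohort statistics and the full-render
pipeline, and at reduced sizes for replicated experiments: parameter
recovery at 60 participants × 80 observations × 20 seeds (through rendered
transcripts), null calibration at 20 × 40 × 200 studies and power checks at
20 × 40 × 10 seeds on latent features (the generator's feature-level ground
truth stands in for rendered streams there, isolating the statistical
machinery from rendering fidelity, which the recovery and parity tests
cover separately).  The acceptance script resamples 20 train/test splits
per reported predictive R².
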