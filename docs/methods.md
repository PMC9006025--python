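# Methods

This note documents the models, algorithms, defaults and design choices
behind `gespeech`, and what the synthetic-data tests do and do not show
about real recordings.

## Data model and conventions

Time is seconds from session start; frame indices are 0-based; pixel
coordinates have the origin top-left with y increasing downward (the
pose-tracker convention).  Keypoints follow the 25-point body map
(0 nose, 1 upper torso/neck, 2/5 shoulders, 4/7 hands, 8 mid-hip) with
five finger-tip ids per hand appended as ids 25–29 (left) and 30–34
(right).  A blur session is `n_grades` (default 10) contiguous windows of
`grade_duration_s` (default 240 s); *grade* always means amount of blur,
so a blur-to-clear session has its labels reversed relative to time.
Gesture events are mapped to grades by their midpoint — an event
straddling a boundary belongs to the grade containing its centre.

Tracker samples with confidence below 0.3 are treated as missing; gaps up
to 0.5 s are bridged by linear interpolation, longer gaps are flagged
unusable.  Neither threshold has an empirical reference for this kind of
data, so both are configuration keys.

## Motion energy

Motion energy of an articulator over a window is Σₜ‖Δp(t)‖ of its
per-frame position, where multi-keypoint articulators (arms = hands 4
and 7, fingers = ten finger tips) are averaged into one position first.
Two choices were genuinely open:

* **Displacement norm.** The per-frame step could be |Δx|+|Δy| or the
  Euclidean norm; we default to Euclidean because it is
  rotation-invariant, with Manhattan available via `metric=`.
* **Reference correction.** "Correcting" head/arm energy for torso
  motion could mean subtracting energies or subtracting positions.  We
  subtract the reference *position* before differencing (relative
  coordinates): this preserves non-negativity and exactly nulls motion
  common to target and reference, so a rigid whole-body translation
  yields zero corrected head/arm/finger energy — an invariant the test
  suite asserts.

No pixel→cm normalisation is applied (all contrasts are within-session);
the image scale can be recorded in the run config for cross-session work.

## Gesture kinematics

Positions are smoothed with a zero-phase 3rd-order Butterworth low-pass
at 10 Hz before differentiation (appropriate for 25–30 fps tracking);
speed is ‖Δp‖·fps.  Per-gesture features:

* **Peak velocity** (px/s): maximum of the two-hand mean speed profile.
* **Submovements**: velocity peaks above 15% of the event peak speed
  that are separated by a valley below 0.5× the smaller adjacent peak;
  unseparated peaks merge into one pulse.  The speed profile receives a
  3-sample moving average and peaks must also be *prominent* by the
  movement threshold; this rejects single-frame tracker-noise spikes
  (which rise from a non-zero noise floor) while genuine ballistic
  pulses, which rise from near zero, are unaffected.  With these
  defaults the detector recovers exact pulse counts on noise-free
  minimum-jerk gestures and ≥95% with 1 px tracker noise at 25 fps.
* **Hold-time** (s): cumulative stillness (speed < 10% of event peak for
  ≥ 0.2 s) strictly between first movement onset and last offset, so
  pre- and post-gesture rest never count.  Hold boundaries are located
  by linear interpolation of the speed profile at the stillness
  threshold, giving sub-frame resolution; the residual bias is the
  sub-threshold deceleration/acceleration tail of the adjacent pulses,
  about 8% of a pulse duration per boundary, i.e. below one frame for
  sub-half-second pulses at 25 fps.
* **Size** (px²): x-extent × y-extent of the union of both hands'
  positions relative to the upper-torso keypoint.
* **McNeillian space**: concentric boxes normalised to body size —
  centre-centre spans the sternum ±0.25 shoulder-width horizontally and
  ±0.25 neck-to-hip vertically; centre is twice that box; periphery is
  bounded by the shoulders (±0.5 shoulder-width), head top and hips;
  beyond is extra-periphery.  Points exactly on a boundary go outward.
  The per-event summary is the most extreme region visited by either
  hand, matching a one-category-per-gesture analysis of peripheral
  space use.  The geometry is our concrete realisation of a schematic
  that has no canonical pixel-level definition.
* **Depth** (px): side-view maximum of the horizontal distance between
  the two-hand mean and the hip keypoint; absent (NaN), not zero, when
  no side view exists — so torso lean and forward reach both count.
* **nPVI**: 100/(m−1) · Σ|dₖ−dₖ₊₁|/((dₖ+dₖ₊₁)/2) over submovement
  durations; undefined for fewer than two submovements.
* **Gesture rate**: events per minute per participant × grade, zeros
  included.

Two-hand handling: features use the two-hand average trajectory except
size (union of both hands) and space (either hand).  The collinearity
screen regresses each feature on the others (OLS) and flags
VIF = 1/(1−R²) above 3.

## Speech acoustics

The amplitude envelope is |analytic signal| low-passed at 8 Hz
(zero-phase) and resampled to 100 Hz.  Intensity is framewise
10·log₁₀(mean-square/ref²) with 30 ms frames, 10 ms hop, ref = 2×10⁻⁵ on
normalised full scale — absolute SPL calibration is irrelevant because
every analysis is a within-recording contrast.  F0 comes from a
normalised autocorrelation tracker (40 ms frames, parabolic peak
interpolation, search band 75–500 Hz, voicing threshold 0.45); on
synthetic glottal-pulse trains it tracks 100–400 Hz with an octave-error
rate below 1%.

The modality split is sample-wise: a voiced sample is
*speech-with-gesture* if it temporally overlaps any gesture event of the
same participant, else *speech-only*; per-grade × modality means feed the
statistics.  Utterance segmentation is out of scope — the sample-wise
split is the direct operationalisation of "speech produced together with
gesture".

## Speech–gesture alignment

Hand speed and the envelope are resampled to a common ≥32 Hz grid
(64 Hz default) and z-scored per event.  The continuous wavelet
transform uses a complex Morlet (ω₀ = 6) on a geometric scale grid of 12
scales/octave whose extreme periods are exactly 125 and 500 ms (2–8 Hz).
Coherence is |S(W₁W₂*)|²/(S|W₁|²·S|W₂|²) with Gaussian time-smoothing of
width ∝ scale and a 3-scale boxcar; phase is the smoothed cross-spectrum
angle.  Phase converts to lag via Δt = φ/(2πf) at each cell's own
frequency; positive asynchrony means speech leads.  Per-event summaries
average coherence over significant cells and aggregate phase by circular
mean per frequency row, convert to ms, then combine across rows weighted
by cell count — the aggregation rule is declared here, as no canonical
one exists.

Significance is cell-wise against surrogates of the speech stream with
the gesture stream fixed: phase randomisation (default, n = 300, seeded)
or AR(1)-matched noise.  The phase-randomised null preserves the
amplitude spectrum, so for a *single-frequency* pair it reproduces the
observed coherence and (correctly) never fires — it targets broadband
temporal coupling, which is what envelope/hand-speed data are.  The AR(1)
null is the right choice when narrowband coupling itself is the question.
Under independence the significant-cell fraction calibrates to the
nominal 0.05 (±0.02 over 200 white-noise pairs), and an injected 50 ms
lead is recovered within ±10 ms on band-limited coupled streams.

## Statistical ladder

Blur grade enters as orthonormal linear/quadratic contrasts (R `poly()`
convention: zero-mean, unit-norm, orthogonal columns), which decorrelates
the two terms.  All LRTs compare maximum-likelihood fits (not REML),
the standard validity condition when fixed effects differ.  The ladder
reports the quadratic-vs-null LRT (df 2) and the quadratic-vs-linear LRT
(df 1) and declares a quadratic effect only when both pass alpha.  Note
the declared two-step rule is conservative: under the null its rejection
probability is ≈0.025 at α = 0.05 (the joint event "χ²₁ component
significant *and* the sum significant"), while each constituent LRT is
calibrated at its nominal level — the calibration tests therefore check
the primary LRT against [0.03, 0.07] and additionally assert the
two-step rule is never more liberal.

Random-effects build-up starts from nested dyad/participant intercepts
and adds a gesture-type intercept when a df-1 LRT supports it (ties keep
the simpler structure); a singular or non-convergent nested fit falls
back to a single global participant factor.  Gaussian models are fitted
with statsmodels `MixedLM`; because optimisers occasionally stop at
different points, each model is fitted with BFGS and Powell and the
better log-likelihood kept.  Crossed gesture-type intercepts are
realised as variance components within a single all-encompassing group.

Poisson (submovements), Gamma-log (strictly positive kinematics) and
cumulative-link ordinal (gesture space) responses use a native mixed GLM
with **one** Gaussian random intercept (participant), integrated by
21-node Gauss–Hermite quadrature and maximised by BFGS with a
Nelder–Mead fallback; standard errors come from a central-difference
Hessian at the optimum.  Restricting non-Gaussian families to the global
participant intercept mirrors the ladder's own fallback structure and
keeps the likelihood exact (1-D quadrature) rather than approximate;
unit tests cross-check the Gaussian path against lme4 and the Gamma path
against glmmTMB on small fixtures.  Ordinal categories with zero
observations are merged off the scale with a warning; the two-category
degenerate case reduces to mixed logistic regression.

Pseudo-R²: conditional R²C = (σ²_f + σ²_r)/(σ²_f + σ²_r + σ²_e) from the
variance-components decomposition (Gaussian fits), ΔR²C against the
null, and R²LR = 1 − exp(−LR/n) for every family.  The adjusted alpha is
α/k^(1−r̄), which reproduces the published worked values 0.025
(k = 2, r̄ = 0.002) and 0.014 (k = 6, r̄ = 0.283) exactly at 3 decimals;
it is monotone decreasing in k and increasing in r̄.

## Synthetic data generator

The generator defines the study conditions: 20 dyads (40 participants),
10 grades × 240 s, 25 fps front and side views, a gesture process of
~2.2 events/min with type-specific mean durations between 1.7 and 2.8 s
(representational 2.8, pragmatic/interactive 1.7, emblem 2.2, deictic
1.9; mixture weights follow the relative prevalence of those types in
conversational corpora).  Every draw derives from one seed;
session-level seeds are a fixed function of (seed, dyad, member), so
studies are reproducible file-by-file.

Gestures are k ∈ {1..5} minimum-jerk pulses (displacement
10τ³−15τ⁴+6τ⁵, peak speed 1.875·A/T) with Dirichlet-distributed
inter-pulse stillness, mirrored across hands, followed by a smooth
retraction to rest *outside* the event window (so event windows never
contain a position discontinuity).  Blur effects are multiplicative,
exp(b₁u + b₂(u²−ū²)) with u the grade mapped to [−1,1] and the ū²
centring keeping the session mean at baseline: defaults b₂ = −0.40
(size), −0.30 (peak velocity), −0.50 (hold-time), −0.35 (rate) give the
inverted-U (mid-blur peak) shape, b₁ = −0.15 the linear depth decrease;
submovements and nPVI carry no effect.  Dyad/participant/gesture-type
random effects are log-normal (SD 0.08/0.12/0.15).

Acoustics: a ~4 Hz syllabic envelope, cross-coupled to hand speed during
gestures with a 50 ms speech lead; intensity 62 dB baseline with the
4.36 dB speech-with-gesture offset, a small shared blur quadratic and a
modality-specific quadratic (both expressed in centred orthonormal
contrasts so the modality *main* effect stays exactly the configured
offset); F0 180 Hz baseline with the 3.71 Hz modality offset and no blur
effect.  Per-(grade × modality) "content variability" draws (0.8 dB /
2.5 Hz) provide the between-cell residual a mixed model of per-grade
means needs.  Audio can be emitted as a true WAV (glottal pulse train
with exactly known F0, for tracker tests) or, at study scale, as direct
envelope/intensity/F0 series.

`simulate_feature_table` samples per-gesture features directly from this
generative model (the fast route for calibration and power studies);
`generate_session` / `generate_study` realise full trajectories and the
on-disk file tree, and the feature-extraction pipeline recovers the
trajectory-level truth (exact submovement counts at zero noise, depth to
±1.5 px, peak velocity to within the smoothing attenuation).

What the generator does **not** emulate: tracker dropout bursts and
identity swaps, camera motion, occlusion-correlated confidence,
conversational turn structure, utterance-level prosody, or correlation
between gesture kinematics and speech content.  Passing tests therefore
demonstrate correctness of the measurement and inference machinery under
the declared generative assumptions, not robustness to every artefact of
real video.

## Problem sizes used in the tests

The acceptance suite runs the calibration studies at sizes chosen to
make the Monte-Carlo error small relative to the tested tolerances:
500 null re-simulations at 10 participants × 10 grades × 2 events for
ladder type-I error; 12 study-scale (20-dyad) replicates for power;
200 five-second white-noise pairs with 100 surrogates for the alignment
false-positive rate; 200 noisy gestures for submovement accuracy.  The
end-to-end modality recovery uses one full 20-dyad study per run.

## Known limitations

* Non-Gaussian families support a single random-intercept factor; nested
  or crossed structures for those families would need an external
  backend (the Gaussian path supports both).
* Random blur slopes are available only with the global participant
  structure.
* The wavelet smoothing constants (Gaussian width ∝ scale, 3-scale
  boxcar) follow common practice conceptually rather than replicating
  any specific package numerically; coherence magnitudes are therefore
  comparable within, not across, implementations.
* The hold-time and submovement thresholds (15% movement, 0.5 valley
  fraction, 10% stillness, 0.2 s minimum hold) are declared defaults,
  all configurable; they are not estimates of any published pipeline's
  internal settings.
* Phase-randomised surrogates cannot flag coupling between two pure
  sinusoids (see above); use the AR(1) null for narrowband questions.
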