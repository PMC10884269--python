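# Methods

This note documents the models, parameter choices and numerical decisions
behind `sispin`, and what the synthetic pipeline does and does not show
about real data.

## Stimulus synthesis

Real CRM recordings are replaced by parametric source–filter synthesis.
Each keyword (call sign, colour, number) is a voiced token: a glottal
impulse train at the voice's F0, with a linear declination of ±2 % across
the token (so the median frame F0 equals the nominal value), per-pulse
timing jitter of 0.2 % of the period (seeded; this is the only thing that
changes between renderings of the same sentence with different seeds), and
an aspiration-noise component at −14 dB relative to the harmonic source.
The source is filtered through a cascade of three second-order formant
resonators; every keyword has a distinct (F1, F2, F3) pattern spanning the
vowel space, so keywords are machine-separable even though the audio is
not human speech.  Carrier words are unvoiced band-limited noise bursts at
lower level: they carry no scoring information and keep the energy-based
segmentation of keywords unambiguous.

The aspiration component is not cosmetic: because it passes through the
same formant filter as the pulse train, the spectral envelope is sampled
*continuously* between harmonics.  The formant estimator in
`sispin.acoustics` exploits this — it masks Welch-spectrum bins within a
guard band of each F0 harmonic and fits a single-resonance magnitude model
(plus log-linear tilt) to the remaining noise-floor bins.  Naive spectral
peak picking on voiced speech is biased toward the nearest harmonic (up to
half the F0 spacing, far outside a 3 % tolerance at F0 = 242 Hz); the
noise-floor fit removes that bias.  F0 itself is estimated by frame-wise
autocorrelation (40 ms frames, parabolic peak interpolation, energy-gated
voicing decision).

Defaults: sample rate 22 050 Hz (adequate for formants below 8 kHz),
keyword tokens 250 ms, carrier tokens 150 ms, 50 ms inter-token gaps,
10 ms raised-cosine token edges.  A sentence is then ≈ 1.85 s, within the
configurable 1.5–2.5 s band.  Sentence durations and carrier timing are
package choices — the originating corpus does not pin them down — and are
exposed in the module constants.

## Voice manipulation

Offsets are expressed in semitones.  `f0_ratio(d) = 2^(d/12)` multiplies
the pulse rate; `vtl_envelope_ratio(d) = 2^(−d/12)` multiplies every
formant frequency.  **Sign convention:** positive ΔVTL means a *longer*
vocal tract (a larger speaker), hence *lower* formants.  The direction is
a documented package decision: the semitone magnitude (+3.8 st) is given
by the design, but its acoustic direction had to be fixed here, and the
"larger speaker" reading matches how VTL is described as a size cue.
Manipulation happens at synthesis-parameter level, not by post-hoc
vocoding: the corpus is parametric, so resynthesis with shifted parameters
is exact.  The zero-offset masker condition still passes through the full
synthesis path, mirroring the resynthesis-parity control of the original
paradigm.

## Masker construction and mixing

Segments of 150–300 ms are drawn uniformly (sentence, length, start
position all random) from eligible masker sentences, ramped with 50 ms
raised-cosine on/off ramps, and butt-joint concatenated (no cross-fade;
the ramps alone prevent splatter) until the masker covers the target plus
750 ms lead and 250 ms tail, then trimmed to that exact sample count.

Keyword exclusion reads "same number and colour keywords" in the stricter
either/or sense: a masker sentence is excluded if it shares *either*
keyword with the target.  The permissive reading (exclude only exact
pairs) is available via `match_mode="both"`.  Masker segments may span
keyword boundaries within their source sentence.

TMR is defined on broadband RMS — target RMS over the target sentence
extent, masker RMS over the full masker extent.  The measurement window is
a package decision (the design does not define one) and is honoured
symmetrically by `Stimulus.measured_tmr_db()`.  If the mixed peak would
clip, both tracks are scaled jointly, which cancels in the ratio.

## Protocol and timing

The trial engine is decoupled from audio rendering: stimulus play time is
taken from token metadata (identical to the rendered duration), so cohort
simulation does not pay the synthesis cost.  Per trial the clock advances
by stimulus duration + listener latency + feedback + any break.  Feedback:
robot 2.5 s (nod) / 3.2 s (shake); computer 0 s / 0.5 s (the brief
negative outline; configurable).  Breaks default to after trials 30 and
60 — the "predefined points" are not specified, so these are package
defaults — with 10 s per robot break prompt and 0 s for the dismissable
computer dialog.  Data-collection duration runs from the first trial's
presentation to the last trial's logged response: it includes in-block
breaks and inter-trial feedback but not the feedback after the final
response, nor training or pre/post interaction.

## Simulated listeners

Accuracy follows a guessing-floor/lapse logistic:

p = 1/48 + (1 − 1/48 − λ) · σ(β₀ + β_tmr·TMR + b_f0·[ΔF0≠0] + b_vtl·[ΔVTL≠0] + b_int·[both] + b_if·[robot])

with defaults β₀ = 1.2, β_tmr = 0.55/dB, b_f0 = 1.5, b_vtl = 1.0,
b_int = 0.5, λ = 0.02, b_if = 0 (no true interface effect).  Voice
benefits are indicator terms, matching the 4-level condition factor of the
analysis; the continuous 9-point training grid reuses the same indicators.
These defaults place accuracy above 95 % at +6 dB for every voice
condition and below 60 % at −6 dB with no voice difference — the
ceiling-at-+6 / degraded-at-−6 pattern the paradigm is built around.
Baseline (no-masker) trials return 1 − λ.  Errors are uniform over the
other 47 matrix cells.  Latency is Normal(3.5 s, 1 s) truncated at zero,
chosen so the computer's inter-response interval lands near 6 s once
stimulus time is included; this is a tuning choice, not data.  Cohorts
draw a per-participant intercept shift (sd 0.35) kept across both
sessions (the repeated-measures structure), with interface order
counterbalanced by seed.

The generator emulates the statistical structure the analyses assume —
repeated measures, near-ceiling and near-floor cells, between-subject
heterogeneity — but not attention drift, fatigue, learning, or real human
latency distributions.  Green tests therefore validate the machinery and
its operating characteristics (type-I error, power at the configured
effect sizes), not claims about human listeners.

NARS questionnaires: 14 five-point Likert items in subscales of 6/5/3
items; the three S3 items are reverse-coded and contribute (6 − rating) to
the subscale total, which reproduces the printed ranges (6–30, 5–25,
3–15) and neutral totals (18, 15, 9).  Item responses are generated to hit
a per-respondent target total (Normal around the subscale target, clipped
to the attainable range) and redistributed randomly across items within
the 1–5 bounds.  Coder tables: a latent Poisson count per
participant × interface × behaviour is shared by both coders, each adding
rounded Normal noise (sd `coder_noise`, clipped at 0), so zero noise gives
perfect agreement and large noise drives ICC toward zero.  Default rates
give robot segments three times the computer's smiling rate.

## Statistics

The three-way within-subjects ANOVA is computed by Möbius-style effect
decomposition on the subject × 2 × 3 × 4 cell array: each effect term
centres along its own factors and averages along the rest; the error
stratum for effect X is the subject × X interaction.  Partial
η² = SS_X / (SS_X + SS_error(X)).  Sphericity per multi-df effect uses
orthonormal (Helmert, Kronecker-product for interactions) contrasts of the
subject × cells collapse; Mauchly's W with the standard chi-square
approximation triggers the Greenhouse–Geisser correction at α = 0.05, and
both corrected and uncorrected p are always reported.  Note a small
mathematical caveat verified by the tests: ε-scaling both dfs raises p in
the rejection-relevant tail but can lower it slightly when F is small, so
"GG is conservative" holds where it matters, not identically.

Bayes factors use the BIC approximation computed within each effect's own
error stratum: the subject × cells collapse is modelled with and without
the effect's (highest-order) term, subject terms in both, and
BF₁₀ = exp((BIC_without − BIC_with)/2).  This is closed-form and
deterministic, avoids per-effect mixed-model fits that can fail to
converge, and keeps the matched-models logic (a reduced model never drops
a main effect's interactions).  It will not numerically reproduce
JASP-style default-prior BFs; direction and ordering of evidence are the
goal.  Evidence labels follow the conventional 1/3–3 / 10 / 30 thresholds,
reported with direction (BF₁₀ < 1 favours the null).

ICC(2,k) is Shrout–Fleiss two-way random effects, absolute agreement,
average measures, from the two-way ANOVA mean squares:
(MSR − MSE) / (MSR + (MSC − MSE)/n).  It is invariant to adding a
constant to all cells and equals 1 for identical coders; at k = 2 the
estimator has a small negative bias under independence, visible in the
simulation tests.  Duration comparisons are paired t-tests with explicit,
reported outlier exclusion.  Percent correct (not rationalized arcsine) is
analysed.

Degrees of freedom follow the standard repeated-measures formulas
throughout; no attempt is made to reproduce anomalous df values that a
specific software configuration might print.

## Calibration

dB SPL exists only under a declared digital convention: a full-scale sine
is defined as 100 dB SPL.  With that anchor, setting a waveform to the
65 dB SPL presentation level is an exact, testable operation.
Third-octave analysis uses the IEC base-2 centre series (1000·2^(k/3) Hz,
nominal 100 Hz–8 kHz); band powers are integrated from the Welch spectrum
between the ±1/6-octave band edges, so the power sum over bands conserves
the broadband level across the covered range.  Speech-shaped noise is
white Gaussian noise multiplied in the frequency domain by the square root
of the target power spectrum.  Hardware measurement chains (mannequin,
sound-level meter, loudspeaker transfer functions) are out of scope; the
band-level comparison is provided as a computation over any two band
spectra.

## Problem sizes and reproducibility

Default study conditions: 27 participants, 91 data trials per session,
two sessions each.  The test suite exercises the statistical operating
characteristics at reduced scale chosen for desk-side runs: type-I error
of the interface effect over 1000 reduced null cohorts (12 participants,
2 trials per cell), and the qualitative equivalence pattern over 50
full-size replicate cohorts.  A single master seed fans out to every
stage through named `SeedSequence` streams (hash of the stage name as
spawn key), so adding a stage never perturbs existing streams and every
artefact is byte-reproducible from the seed.

## Known limitations

- The audio is machine-parsable, not intelligible speech; acoustic
  properties beyond F0, formant structure and timing are not matched to
  any recorded corpus.
- The VTL sign convention is asserted, not derived from data.
- BIC Bayes factors approximate default-prior ANOVA BFs only in direction
  and order of magnitude.
- The listener model is static (no fatigue, learning or attention
  dynamics) and its latency model is a tuning choice.
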