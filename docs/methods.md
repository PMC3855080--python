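# Methods

This note documents the models implemented in `syldiscrim`, the
parameters that matter, and the design decisions taken where the stimulus
and procedure descriptions left room.

## Stimulus synthesis

Each syllable is rendered by a cascade formant synthesizer of the classic
Klatt type, cascade branch only (sufficient for fully voiced CV stimuli;
no nasals or frication bursts are needed):

1. **Voiced source.** An impulse train whose instantaneous rate follows
   the F0 contour, generated by phase accumulation so the declining
   contour is honoured exactly (with a 1e-9 phase tolerance against
   accumulated floating-point error). The contour is linear from 120 Hz
   to 90 Hz over the *voiced* span — from the end of the VOT interval to
   syllable offset — so the first glottal cycle is at 120 Hz regardless
   of VOT. The train is shaped by a zero-frequency second-order resonator
   (bandwidth 100 Hz), giving roughly −12 dB/oct source tilt.
2. **VOT realization.** During the VOT interval the periodic source is
   replaced by Gaussian aspiration noise at −20 dB relative to the shaped
   voiced source RMS, driven through the same formant cascade and drawn
   from a seeded generator (a silent-VOT variant is available). Voicing
   begins at t = VOT.
3. **Formant cascade.** Five second-order digital resonators with unity
   DC gain, coefficients recomputed per sample from piecewise-linear
   frequency tracks: onset → target over the transition, constant to the
   180 ms late-change point, then linear to the late targets where given.
   Bandwidths are constant.
4. **Radiation and offset.** A first difference (+6 dB/oct) models lip
   radiation — the net −6 dB/oct source+radiation tilt is what lets the
   low-F1 transition onsets carry less energy than the open vowel, which
   in turn produces the amplitude-rise behaviour analysed below. Voicing
   is ramped linearly to zero over the final 20 ms, and the syllable is
   peak-normalized to 0.9 full scale (presentation level was adjusted per
   listener in the design being emulated, so absolute level carries no
   information).

Fixed parameters: 200 ms duration, 16 kHz sample rate (covers the highest
formant, 3700 Hz, with margin; configurable).

Two stimulus parameters are not derivable from the printed recipes and
are explicit, documented choices: the /ba/–/da/ F3 *onset* (the printed
500 Hz conflicts with the 2500 Hz target and phonetic plausibility; the
default is 2000 Hz, exposed as `ba_da_f3_onset_hz`) and the /ga/–/ka/
transition duration (not printed; default 40 ms, matching /ba/–/da/,
exposed as `ga_ka_transition_s`).

### Measurement utilities

Pitch is estimated by normalized autocorrelation with parabolic lag
interpolation. Because an autocorrelation window reports the mean period
inside it, the F0 *offset* of a gliding contour is estimated from two
adjacent 25 ms windows with the linear trend extrapolated to the boundary
(the known terminal ramp is divided out first); the onset uses a plain
30 ms window, since the rapid formant transitions there distort short
windows more than the glide does. Formant recovery for validation uses
LPC (autocorrelation method, order 12, 0.97 pre-emphasis) — with the
stated wide F4/F5 bandwidths those two resonances can merge into one
spectral peak that lies within both bandwidths, which the validation
accepts.

## Adaptive procedure

The same/different task is a transformed up-down staircase: the run
starts at the most discriminable pair (full-range limen); after three
consecutive correct responses the test syllable moves toward the
reference, after each error away from it; the step index clamps at the
pair adjacent to the reference and at the far endpoint. Reversals are
logged where the prescribed movement direction flips (clamped moves
count), the run stops at 7 reversals or after 5 consecutive errors on the
easiest pair, and the threshold is the arithmetic mean of the last 4
reversal limens. Catch trials (identical pairs) occur every 5–10 trials,
are scored separately, and never touch the staircase counters.

**Step sizes.** The procedure description prescribes a two-step decrease
after three correct responses and a one-step increase per error. Applied
*throughout*, that 2:1 asymmetry moves the equilibrium of the 3-down/1-up
rule from the 79.4 % point (p = 0.5^(1/3), the standard Levitt result for
equal steps) to the p³ = 1/3 (~69 %) point — Monte-Carlo here shows a
−9 % to −21 % threshold bias. Because the last-4-reversal mean is
interpreted as a 79.4 % threshold, the default reads the two-step
descents as the coarse initial approach: after the first reversal both
directions move one step (`StaircaseConfig.step_down_fine = 1`). Under
this default the mean estimate over 500 seeded runs is within ±3.2 % of
the generating 79.4 % point across nine continuum × level conditions.
The literal 2:1-throughout reading remains available
(`step_down_fine = 2`).

**Degenerate runs.** An error-free responder produces no reversals; the
threshold then falls back to the mean of the 4 hardest limens actually
visited and is flagged partial. The 750 ms inter-stimulus interval is
carried as metadata only — no audio is presented to simulated observers,
which respond to the pair's limen (a waveform-based observer can be
plugged in through the same interface).

## Simulated observers and cohorts

An observer maps a limen Δ to a probability of a correct response:

    p(Δ) = γ + (1 − γ − λ/2) · F(Δ),   γ = 0.5 (same/different guess rate)

where F is a logistic in Δ rescaled so F(0) = 0 and F(∞) = 1, and the
location parameter is solved in closed form so that p equals 0.5^(1/3) ≈
0.794 exactly at `threshold_limen`. λ is a small lapse rate (default
0.02). Steepness defaults to `slope = 6 / threshold` (≈95 % correct near
1.7× threshold), a realistic saturation for syllable discrimination. The
same/different decision is modelled as correct/incorrect Bernoulli draws
(bias-free observer); a Thurstonian differencing model is a noted
extension point.

Cohorts are drawn on the RTI scale: per participant and continuum,
`rti = base + group_shift + training_effect · (years − group mean) +
N(0, σ)`, clipped to (0.02, 0.98) and mapped to a native-unit limen
(clamped to [one step, full range]). Defaults, with their provenance:

| parameter | default | rationale |
|---|---|---|
| n per group | 14 | the emulated design |
| base RTI (ba_da / ba_wa / ga_ka) | 0.60 / 0.50 / 0.58 | /ba/–/wa/ hardest, per the reported difficulty ordering |
| musician shift (ba_da / ba_wa / ga_ka) | 0 / 0.18 / 0.11 | Cohen's d ≈ 0 / 1.30 / 0.74 implied by the reported group statistics, at σ = 0.12 plus staircase noise |
| between-subject σ | 0.12 | keeps thresholds well inside the continua |
| training years (musicians) | truncated normal, mean 12.6, SD 2.96, min 9 | reported cohort moments |
| training years (non-musicians) | mean 1.5, SD 1.57, min 0 | reported cohort moments |
| hours/week (musicians) | mean 10.3, SD 3.97, min 0 | reported cohort moments |
| training_effect | 0.004 RTI/yr | calibrated so the pooled years ↔ /ba/–/wa/ RTI correlation sits near the design's r ≈ 0.5; most of that correlation already comes from the group separation |

What the generator emulates: the group-by-continuum mean structure, the
training covariate, between-subject spread, and psychometric response
noise. What it does not: response bias, attention and memory lapses
beyond a flat lapse rate, learning across the session, or any coupling
between continua within a listener beyond the group structure. Passing
tests therefore validate the pipeline's machinery and calibration — not
claims about human listeners.

## Threshold index and statistics

`RTI = 1 − (x − ref)/range` maps thresholds onto [0, 1] with higher =
better (ba_da: ref 800 Hz, range 800 Hz; ba_wa: 25 ms, 75 ms; ga_ka:
0 ms, 50 ms). Limens are carried in native units everywhere else; the RTI
transform is the only place units are erased. Out-of-range inputs are
clamped with a warning, since the staircase cannot produce them.

The cohort analysis is a 2×3 mixed ANOVA (between: group; within:
continuum; sphericity correction applied automatically when indicated),
one-tailed two-sample t-tests per continuum with the a-priori direction
musicians > non-musicians, paired t-tests between continua, and Pearson
correlations of RTI with years and weekly hours. p-values are
Benjamini–Hochberg corrected at q = 0.05 (the level is configurable, as
is the grouping of tests into correction families; the default corrects
each family separately).

## Envelope rise time

Analysis unit: the pitch period. Periods are delimited either by
integrating the known per-sample F0 track (cycle boundaries at
whole-phase crossings) or by local autocorrelation tracking seeded from a
mid-syllable window; the two methods agree to within one period on these
stimuli. The peak RMS is computed over the five periods centered on the
period containing the global amplitude peak (truncated and flagged near
edges, minimum three periods); scanning from syllable onset, the first
period whose RMS reaches 80 % of that peak value ends the rise, and the
rise time is that period's end time from t = 0. The criterion is a ratio
of RMS values, so it is invariant to amplitude scaling. The VOT continuum
is excluded by construction: its envelope *is* the VOT manipulation, so a
rise-time summary would restate the stimulus dimension.

On the synthesized stimuli the rise time is constant within one pitch
period across all 21 /ba/–/da/ steps and grows monotonically from ~17 ms
to ~52 ms across the /ba/–/wa/ steps — the transition-duration cue
surfaces in the envelope, the spectral cue does not. Rise times quantize
to pitch-period boundaries by definition, hence the one-period tolerance
used in all comparisons.

## Reproducibility and problem sizes

Every stochastic component (aspiration noise, catch spacing,
presentation order, observer responses, cohort draws) is driven by
explicit seeds; the pipeline spawns per-participant child seeds from one
master seed, and identical configurations produce byte-identical result
bundles. The validation suite uses 500 staircase runs per convergence
condition, 200 replicate cohorts for parameter-sign recovery and 1000 for
null calibration of the group test — sizes at which the Monte-Carlo
standard errors are a small fraction of the tolerances being checked.

## Known limitations

- The synthesizer is a minimal cascade implementation: no parallel
  branch, burst transients, jitter/shimmer or breathiness; stimuli are
  cleaner than natural speech.
- The /ba/–/da/ F3 onset and the /ga/–/ka/ transition duration are
  documented assumptions (see above), as is the aspiration (rather than
  silent) VOT default.
- Observers respond to the acoustic difference directly; the link from
  waveform to percept is not modelled.
- Group effect sizes are design parameters calibrated from summary
  statistics, not fitted to individual human data.
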