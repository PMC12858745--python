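# Methods

## Exposure model

All exposure arithmetic follows the equal-energy principle: A-weighted
sound energy is proportional to duration x 10^(L/10). A career is reported
as discrete segments, each with a duration (years), wearing time
(hours/week), the proportion of wearing time at a "loud" volume-control
setting, and the loud and normal settings as % of full volume.

* **Duty cycle 0.2.** Radio ear-pieces carry sound only while speech or
  chatter is transmitted; published channel-activity estimates for UK
  police networks span roughly 15–30 %. Wearing hours are multiplied by
  0.2 to give exposure hours. Constant `DUTY_CYCLE`, single definition.
* **Working year.** 47 weeks x 40 h = 1,880 h. Weeks of use are derived as
  total segment years x 47 unless a reported value is supplied.
* **Noise units.** `device_noise = sum_i h_i 10^((L_i-85)/10) / 1880`: one
  unit is one working year of constant 85 dBA exposure (85 dBA being the UK
  Upper Exposure Action Value). Additive over segments; zero exposure gives
  exactly zero units.
* **Weekly-averaged level.** `85 + 10 log10(noise * 1880 / (40 * weeks))`
  — the constant level that, present 40 h in each working week of use,
  carries the same energy. Depends only on total energy and weeks, not on
  how hours were distributed.
* **Volume average.** The energy-average level over the exposed hours,
  mapped back through the inverse calibration. Being energy-weighted it
  exceeds the duration-weighted mean setting whenever settings vary.
* Zero-exposure careers report these averages as missing, never −inf.
  Levels are carried at full float precision; rounding is a display concern.

### Calibration curve

The volume-to-level mapping is a pluggable CSV of strictly increasing
(volume %, dBA) anchors. Between anchors the package uses shape-preserving
monotone piecewise-cubic (PCHIP) interpolation — exact at anchors, monotone
everywhere, and able to express the mildly nonlinear dial-to-output
relation of real devices; inversion is by bracketed root-finding to 1e-9.
The bundled default spans the full dial, {0 %→58, 25 %→76, 50 %→85,
75 %→93, 100 %→100 dBA}; the 100-dBA top anchor reflects the device class,
the interior anchors are fixture values to be replaced by measured output
levels for a specific device fleet. Every validation property in the test
suite is calibration-agnostic, so swapping the table does not touch the
code. Requests outside the calibrated volume range are domain errors, not
extrapolations.

## Derived variables

* **Shift estimate.** Shifts worked while wearing the device: per segment,
  years x 47 x min(hours_per_week / 8, 5) — an 8-hour shift and at most
  five shifts/week, the standard full-time policing pattern; both
  parameters are overridable. Rounded half-up.
* **TTS count and group.** The five frequency-of-occurrence responses map
  to proportion multipliers {Never 0, Sometimes 0.25, About half the time
  0.5, Most of the time 0.75, Every time 1}; "About half the time" is fixed
  by its wording, the other interior values are interval midpoints and
  overridable. Count = multiplier x shift estimate; groups are none /
  1–100 / >100. Only the group boundaries reach the registered models, so
  sensitivity to the interior multipliers is limited.
* **Side imputation.** Nonusers receive a pseudorandom exposure side for
  the between-ear DIN analysis only: exactly round(0.57 n) right
  (round-half-even), remainder left, assigned by a seeded permutation —
  reproducing the side split observed in users.
* **DIN quality control.** A single pass computes each condition's mean and
  SD over all complete records; any threshold strictly beyond 3 SD excludes
  the whole participant. The rule is deliberately non-iterative (one
  exclusion count, no re-estimation) and per-condition.
* **Ear-wise reshape.** Unilateral users with asymmetric tinnitus
  contribute two rows (ears) with exactly one exposed and one
  tinnitus-predominant ear each; central tinnitus reaching this step is a
  contract violation, not a silent drop.

## Analysis models

RQ1/RQ2 are descriptive. Categorical response tables use Sison–Glaz
simultaneous confidence intervals, implemented from the published
truncated-Poisson/Edgeworth construction: all categories share one
half-width c/N (plus an interpolation term 2δ/N on the upper side), and the
joint level is controlled at 1−α. The implementation is validated against
the large-sample binomial interval in the binary case and by a
10,000-replicate simultaneous-coverage simulation.

RQ3 is a proportional-odds (ordinal logistic) regression of the TTS
response on the energy-weighted volume average; the proportional-odds form
is adopted without a formal test, matching a single-slope report. Unused
response levels are dropped from the cutpoint set. RQ4/RQ5 are ordinary
logistic regressions (TTS group entered as two dummies against "none"),
reported as odds ratios with 95 % Wald intervals on the link scale. RQ7 is
OLS on the exposed-minus-control DIN difference with exposure-side as a
covariate, reported in dB SNR with t-based intervals.

**Covariate rule.** "Include if indicated" is made explicit and symmetric:
a candidate (age for RQ3–RQ5, first-tested ear for RQ7) enters iff it
associates with both the exposure and the outcome at p < .05 on the
analysis sample (Pearson, one-way ANOVA or chi-square as types dictate).
The screening p-values and the decision are logged in every fit result, and
the unadjusted fit is reported alongside the adjusted one. When no
first-tested-ear column is available the RQ7 pretest is logged as not
evaluable and the covariate is omitted.

**RQ6 and within-pair dependence.** The laterality model regresses
"this ear is the predominant tinnitus ear" on "this ear wore the device"
plus an ear (right/left) term. Because each eligible participant has
exactly one tinnitus-predominant ear, a participant's two rows are
perfectly negatively dependent, and a plain logistic regression on stacked
rows understates the exposure SE by about √2 (its Wald test rejects a true
null at ~15 %). The default estimator is therefore a conditional
(matched-pairs) logistic regression, whose exposure coefficient is the
log-odds of within-pair concordance — logit(c) for concordance probability
c — and whose Wald inference is honest (empirically ~5 % under the null).
The pooled-rows fit remains available via `method="pooled"` for comparison
of point estimates (its exposure coefficient is the marginal log-odds
ratio, 2·logit(c)); its p-values should not be trusted.

**No multiplicity correction** is applied across the seven analyses; each
is a separately registered question.

Every fit is a deterministic function of (input CSVs, configuration, seed);
the run manifest records input digests, the seed and stage-by-stage row
counts so that every reported n is auditable.

## DIN simulator

The simulator replaces the human listener, not the test: audio synthesis,
filtering and loudness calibration are out of scope. Per-digit recognition
is a lapse-adjusted logistic in SNR, p = (1−λ) / (1 + exp(−4·s·(snr−θ))),
with per-ear digit thresholds θ (dB SNR), midpoint slope s (probability per
dB; default 0.2) and lapse λ ≤ 0.1. A triplet trial is correct when at
least two of three digits are correct: P = p³ + 3p²(1−p). The antiphasic
(inverted-polarity, diotic-noise) condition is modelled as a scalar
binaural-unmasking advantage subtracted from the better ear's threshold —
deliberately crude, sufficient for pipeline validation.

The adaptive track starts at +2 dB SNR, two-down one-up, 6-dB steps until
the second turnpoint and 2-dB steps thereafter, ending at the sixth
turnpoint; threshold = mean SNR of turnpoints 3–6, the estimator of the
70.7 %-correct point. A turnpoint is logged at each reversal of the SNR
direction, and the step-size change takes effect from the next SNR update.
Tracks carry plumbing bounds absent from the psychophysics: at most 100
trials (otherwise a non-converged signal with no threshold) and SNR clipped
to [−30, +20] dB (pinning for >10 consecutive trials flags a degenerate
listener). All reversals after the second count toward the final four,
including any double-reversal at the step change. A test session runs an
unscored antiphasic practice block, the two monaural blocks in randomised
order, then the scored antiphasic block; practice results are discarded
with no carry-over. Stored tracks are replayable: the (SNR, correct) pairs
deterministically regenerate every turnpoint flag and the threshold.

At the default configuration the threshold estimate is unbiased to well
under 0.5 dB with an SD under 1 dB (Monte-Carlo, 1,000 tracks).

## Synthetic cohort generator

The generator emulates the survey's structure with every effect under
explicit control: group split 48/41/11 (nonuser/unilateral/nonunilateral),
57/43 right/left side, age N(55.6, 8.6) with users two years younger, 66 %
male, 1–4 career segments with total years uniform on [2, 24], wearing
hours/week log-normal (median 25.5, log-SD 1.1, capped at 80 — with the 0.2
duty cycle this gives the ~5 h/week median exposure), loud proportion
Beta(2.4, 2.6), volume settings normal around 81 % (loud) and 51 % (normal)
truncated to [0, 100]. TTS responses are drawn from the same
proportional-odds family RQ3 fits (slope 0.04 per % volume; cutpoints set
so the response marginals sit at roughly 55/40/2/3/1 % at the cohort's mean
energy-weighted volume of ~73 %; this self-consistency is by design).
Tinnitus risk is 13.1 % for nonusers and follows the TTS-mediation
structure for users (never-TTS baseline 13.2 %, odds ratios 2.8 and 3.0 for
the 1–100 and >100 groups, age log-odds 0.022/year), which yields a
~19–20 % user prevalence and a marginal use OR near 1.7 without any direct
use effect; a direct `or_use` parameter exists for recovery studies.
Tinnitus is central with probability 0.6; otherwise the side agrees with
the exposed ear with probability 0.8 in unilateral users and is a fair coin
elsewhere. DIN thresholds come from a personal level N(−10, 1.2) dB SNR,
zero default ear asymmetry and exposure effect, a ~N(6, 1) dB antiphasic
advantage, 0.8 dB measurement noise, 83.4 % task uptake, and a 2.8 %
bad-equipment stratum shifted +8 dB that the 3-SD rule is meant to catch.
`GeneratorConfig.null()` zeroes every effect (ORs 1, slope 0, concordance
0.5, DIN effect 0, equal baselines).

What the generator does **not** emulate: self-selection and recall bias,
nonresponse, correlated reporting errors between exposure and symptoms,
age-related hearing decline in DIN thresholds, and device heterogeneity.
Passing recovery tests therefore show that the pipeline estimates what the
models assume, on data satisfying those assumptions — not that the
assumptions hold in any real cohort.

## Validation design and problem sizes

* Dosimetry agrees with a literal per-hour energy summation to 1e-9
  relative on 1,000 random careers; the defining identity (1,880 h at
  85 dBA → 1 unit) and the 3.01-dB/duration doubling laws hold exactly.
* Staircase: 1,000 seeded tracks; mean estimate within 0.5 dB of the
  root of P(correct) = 2^-1/2; every track replays exactly.
* Recovery: 200 cohorts of n = 4,500; the RQ4/RQ5/RQ6/RQ7 intervals cover
  their generating values (OR 1.7; ORs 2.8/3.0; concordance 0.8 on the
  conditional scale; 0 dB) in ≥ 90 % of replicates. The use-OR and TTS-OR
  scenarios are generated as separate cohorts because a direct use effect
  and TTS-mediated effects are not simultaneously identifiable as stated.
* Type-I: 1,000 null cohorts at n = 4,500 (the scale at which all model
  cells are populated; smaller cohorts can leave the 1–100 TTS cell empty)
  plus 1,000 ear-wise null samples of 150 pairs (the laterality stratum's
  realistic size); every model's rejection rate at α = .05 must lie in
  [3.5 %, 6.5 %].
* Sison–Glaz: binary-case agreement with the binomial interval to
  0.3 percentage points at n = 2,334, and ≥ 94 % simultaneous coverage at
  k = 5, n = 500 over 10,000 replicates (equal cell probabilities 0.2).

## Known limitations

* The default calibration's interior anchors are fixtures; absolute
  exposure summaries (median weekly level, % above 85 dBA) shift with the
  true device table, while all relative and inferential behaviour is
  unaffected.
* The antiphasic listener model is a scalar shift; it cannot express
  frequency-specific binaural unmasking.
* The conditional-logistic RQ6 estimator conditions out ear-pair intercepts
  and so cannot estimate a population baseline rate, only within-pair
  contrasts — exactly the study question, but nothing more.
* Consistency validation implements the career-years cap (25) only; a real
  survey would carry a longer rule set.
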