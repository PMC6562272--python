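# Methods

## The schedule

Blocks are sequences of independent 1-second bins. Bin *t* yields a press
with the probability returned by the agent's policy; the outcome is then
drawn Bernoulli(P(O|A)) if a press occurred and Bernoulli(P(O|~A))
otherwise. Because delivery is conditioned per bin on the agent's own
action, the *experienced* contingency equals the programmed
ΔP = P(O|A) − P(O|~A) in expectation at any press rate — the property
that makes free-operant responding analysable — and the empirical
estimate converges at the binomial 1/√n rate (verified at n = 10⁵ bins).

A session is 12 blocks of 60 bins. Blocks 1–3 are a fixed training
triplet: (0.6, 0) high contingency, (0.6, 0.6) degraded contingency
(P(O|~A) raised with P(O|A) held, the canonical degradation manipulation),
and (0, 0) zero contingency. The degraded block's probabilities are a
package default, configurable via `BlockSpec`/`RunConfig`: only "degraded"
is inherent to the design, not a particular pair. Blocks 4–12 run the nine
experimental conditions — the five analysed pairs
(0,.6),(0,.3),(0,0),(.3,0),(.6,0) plus four simultaneous-variation pairs
(.6,.3),(.3,.6),(.6,.6),(.3,.3), the latter presented but excluded from
analysis — ordered by a row of the cyclic 9×9 Latin square
(r, c) ↦ (r+c) mod 9. A cyclic square is one concrete choice among the
valid counterbalancing schemes; it is reproducible and satisfies the
each-condition-once-per-position property exhaustively checked in the
tests. Cohorts assign rows round-robin across subjects.

Randomness: every session derives three independent child streams from
its seed (policy draws, outcome draws, rating noise) via
`numpy.random.SeedSequence.spawn`, so agent behaviour and schedule noise
are separately reproducible, and per-group sub-seeds isolate cohorts from
one another within a study.

## The agent

Two delta-rule estimators track the conditional probabilities, both
initialised at 0.5 (maximum-uncertainty prior; no pathway favoured) and
carried across blocks so each transition is relearned in place:

    pressed bin:   p̂A  ← p̂A  + α·(o − p̂A)
    unpressed bin: p̂~A ← p̂~A + α·(o − p̂~A)

Exactly one pathway updates per bin, mirroring the fact that a subject
only observes the outcome conditional on what they actually did. The
policy is logistic in the estimated contingency,

    P(press) = logistic(β0 + β1·(p̂A − p̂~A)),

strictly increasing in estimated ΔP for β1 > 0, which yields response
adaptation on both contingency signs for every preset.

The block-end causal rating is a separate read-out of the same estimates:

    rating = clamp(100·g·(wA·p̂A − wNA·p̂~A + wR·r̄) + b + N(0, σ), −100, 100)

with r̄ the block's experienced reward rate. `wA`/`wNA` are
pathway-specific awareness sensitivities; `wR` is an outcome-density
weight capturing misattribution of freely delivered outcomes to one's own
action — a well-documented bias in human causal judgement, and the
mechanism used here for the ageing-related *inversion* of negative-range
ratings (ratings highest at ΔP = −0.6, where non-contingent rewards are
most frequent). A pure two-pathway read-out cannot produce that
inversion: any wNA > 0 makes ratings increase as ΔP rises toward zero on
the negative range, so blunted-awareness profiles here combine a small
wNA with a non-zero wR. Ratings are rounded to integers by default
(visual-analogue scales are recorded coarsely); configurable.

Whether elevated ratings in a clinical group reflect bias (b), gain (g)
or noise (σ) is not identifiable from group-level summary statistics, so
the three are exposed as separate parameters rather than conflated.

### Group presets

All presets share α = 0.15, β0 = −0.5, β1 = 3 (base press rate ≈ 0.38/s,
rising to ≈ 0.79/s at estimated ΔP = 0.6 and falling to ≈ 0.09/s at
−0.6 — rates in the range typical of this task family) and g = 1.

| preset | wA | wNA | wR | b | σ | n |
|---|---|---|---|---|---|---|
| younger_control | 1.0 | 1.0 | 0 | 0 | 12 | 15 |
| older_control | 1.0 | 0.1 | 0.35 | 10 | 12 | 15 |
| age_matched_control | 1.0 | 0.1 | 0.35 | 10 | 12 | 17 |
| latPFC | 1.0 | 0.1 | 0.35 | 10 | 12 | 7 |
| vmPFC | 0.2 | 0.1 | 0.35 | 25 | 15 | 8 |

Cohort sizes are the study's group sizes. The young preset rates both
contingency signs; the older-type presets keep positive-range awareness
(through wA) but lose the negative range; the vmPFC preset additionally
blunts positive-range awareness (wA = 0.2) with elevated ratings overall
(b = 25). These weights are calibration knobs of the synthetic model —
the human study reports effects, not a generative mechanism — and are
declared once here, not fitted.

### What the generator does and does not emulate

It reproduces the statistical structure of the four group-level findings:
response adaptation everywhere, group-specific rating deficits by
contingency sign, elevated ratings in the vmPFC-like and older-type
profiles, and degradation sensitivity across the training transition. It
does **not** model reaction times, fatigue, block-order effects,
individual-difference distributions of the weights, or the (unknown)
cognitive process behind human misattribution — so green tests show the
*pipeline* recovers such patterns when present, not that the human
findings are themselves inevitable.

## Outcome measures

Response rate is pressed-bins/total-bins (presses per second with 1-s
bins); the equivalent complement identity (1 − unpressed/total) is a
tested invariant. Experienced probabilities are the conditional reward
frequencies among pressed and unpressed bins; a zero denominator (an
agent that never or always pressed) produces NaN, which propagates as
missing data and triggers listwise subject dropping (with a count) before
an ANOVA. Analyses select experimental blocks with P(O|~A) = 0 (positive
sign) or P(O|A) = 0 (negative sign); the (0, 0) block is the zero level
of both triplets, and training blocks never enter even though Block 1's
probabilities match a positive-sign condition. The degradation contrast
is response_rate(Block 1) − response_rate(Block 2).

## Statistics

The split-plot ANOVA uses the classical univariate decomposition (group
tested against subjects-within-groups; contingency and the interaction
against the within error). With unequal group sizes the weighted-means
(hierarchical) sums of squares are computed; they are verified to machine
precision against an independent sequential-OLS oracle in the test suite,
and against pingouin on balanced data. SS conservation
(ΣSS = SS_total) holds on every input by construction and is property-
tested.

Sphericity handling: Mauchly's test runs on the *pooled within-group*
covariance with error df N − g (this reduces to the usual single-group
convention at g = 1, where the implementation matches pingouin exactly).
Corrections trigger only when Mauchly rejects at α = 0.05 and the factor
has k > 2 levels — the convention of the R packages this pipeline mirrors
— using Greenhouse–Geisser ε when ε_GG < 0.75 and Huynh–Feldt ε
(capped at 1) otherwise. ε_GG is computed from the eigenvalues of the
double-centred covariance and bounded in [1/(k−1), 1]; a singular
covariance skips the sphericity step with a warning and reports the lower
bound. `sphericity_epsilons` takes the subject/group counts alongside the
covariance because ε_HF depends on the error df, which the matrix alone
does not carry. Effect sizes are generalised η²,
SS_effect / (SS_effect + SS_subjects + SS_error), invariant to affine
rescaling of the measure (property-tested).

FLSD bars: the plotted half-width is 0.5·t₍₁₋α/2, n−1₎·sd(d)/√n where d
are the within-subject condition differences — i.e. the *standard
deviation of the mean difference*. This is the reading under which bar
non-overlap is exactly equivalent to paired-t rejection at α, the
property the bars exist to convey and which the tests check on a
simulated grid; readings using the raw difference SD lack it. Bars are
computed per neighbouring condition pair and averaged for display at
interior conditions. FLSD is unprotected: it is interpreted only after a
significant omnibus effect, and no further multiplicity correction is
applied. Degenerate inputs use explicit conventions: a dependent variable
constant within every subject gives F = 0, and two constant equal samples
give Welch t = 0.

## Problem sizes and numerical choices

The test suite's Monte-Carlo checks use 4–6×10⁴ bins for schedule
fidelity (binomial SE ≈ 0.005 per conditional probability) and 10⁵ bins
in the end-to-end fidelity check. The null-calibration study simulates
1000 two-group cohorts (15 + 15 subjects, full 12-block sessions) with
the rating pathways silenced (wA = wNA = wR = 0, b = 0) and checks that
the contingency main effect on ratings rejects at the nominal α = 0.05
within ±2 binomial SE. Parameter recovery of the rating
weights uses α = 0.01 with 10⁴-bin blocks so the delta-rule estimator's
stationary fluctuation (SD ≈ √(α/(2−α)·p(1−p))) is small enough for 5%
recovery of wA·g and wNA·g by regression on programmed probabilities.

## Known limitations

* The awareness read-out is deliberately minimal; it has no trial-level
  confidence dynamics and cannot distinguish bias/gain/noise accounts of
  rating elevation (the parameters exist but group data do not identify
  them).
* Linear mixed-effects models with maximal random-effect structure are
  not provided; the pipeline reproduces the ANOVA-shaped statistics this
  task family reports.
* Levene's test is computed and reported only; no variance-stabilising
  remediation is applied.
* No subject-exclusion rules are applied by default (none are defined for
  extreme response rates).
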