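# Methods

`dweights` estimates disability weights — the 0 (full health) to 1 (dead)
severity scale used to weight years lived with disability in DALY
calculations — from four health-state valuation instruments, and provides
the comparison layer used to choose among the resulting weight sets. This
note records the models, the simulator that stands in for unreleased survey
data, and the numerical and design choices that were genuinely open.

## The four estimation models

**Model 1 — paired-comparison probit with anchoring.** Respondents choose
the healthier of two health-state descriptions. Choices are modelled
Thurstone-style: `P(a judged healthier than b) = Φ(β_a − β_b)`, one latent
scale value per state, estimated by maximum likelihood with 'being dead' as
the reference (`β_dead = 0`), observed-information covariance, and gradient
tolerance 1e-8. Two pseudo-states, 'full health' and 'being dead', are
valued alongside the substantive states, and the latent scale is anchored by
the affine map that sends them to 0 and 1:

```
dw_h = (z_FH − z_h) / (z_FH − z_dead),   z = Φ⁻¹(p_h) = β_h
```

where `p_h = Φ(β_h)` is the predicted probability that state *h* is judged
healthier than 'being dead'. Anchoring is performed on the latent probit
index rather than on the probability scale. This was a genuinely open design
choice: the two scales give identical orderings but different values. The
latent scale was chosen because the anchoring map is then affine in the
Thurstone index, so a responder population whose choices follow
`Φ((d_b − d_a)/σ)` is recovered with `dw = d` in expectation *for any*
discrimination `σ`; the probability scale compresses severe states whenever
`Φ` saturates (with `σ = 0.25` the index spans 0–4 and probability-scale
anchoring distorts mid-range weights by up to ~0.5, destroying parameter
recovery). Confidence intervals are Wald intervals on `β` pushed through
these monotone maps; anchor values are treated as fixed constants, so anchor
uncertainty is not propagated.

Perfect separation (a state that wins or loses every comparison it appears
in) is a hard error naming the state; an optional ridge penalty (`ridge > 0`,
default off) regularises the likelihood instead. Estimates outside [0, 1]
are emitted unclipped with a warning. Fit quality is assessed by an 80/20
holdout at the individual-comparison level: for every unordered pair in the
holdout, the observed choice frequency is compared with `Φ(β̂_a − β̂_b)`, and
the mean absolute difference over pairs is reported.

**Model 2 — PHE hybrid.** A population-health-equivalence ladder asks
whether averting 1,000 deaths or preventing X cases of a state (X walked
monotonically over {1,500; 2,000; 3,000; 5,000; 10,000}) yields more
population health; under benefit equivalence (one averted death = one unit
of full health), indifference at X implies `dw ≈ 1000/X`, so a completed
ladder brackets the weight between `1000/X_high` and `1000/X_low`.
Open-ended outcomes map to [2/3, 1] (below the bottom rung) and
[0.001, 0.1] (above the top rung); the 0.001 floor exists because the
log-scale likelihood needs a finite positive bound and the data carry no
information below the ladder's resolution. Per-state weights come from
interval regression: an interval-censored normal likelihood with one mean
per state and a common scale, fitted on log(DW). The log scale keeps
estimates positive and matches the multiplicative spacing of the rungs; a
natural-scale variant is available behind a flag for sensitivity analysis.
Standard errors use a finite-difference observed information of the analytic
gradient; per-state CIs are `exp(μ ± 1.96·se)`. The PHE estimates are then
linked to the paired-comparison predicted probabilities by unweighted OLS
(with intercept, probabilities as the regressor), and the fitted line
converts *every* state's probability into a hybrid weight — including
states never seen in a ladder — with CIs from the mean-response prediction
interval.

**Models 3 and 4 — direct disutilities.** Both equate the disability weight
with `1 − utility`. VAS utilities rescale each 0–100 rating against the
respondent's own rating of 'being dead': `u = v/100` if dead was rated 0,
else `u = (v − v_dead)/(100 − v_dead)`; a dead rating of 100 zeroes the
denominator and excludes the block (logged). Ratings below the dead rating
produce disutilities above 1; these are flagged but never clipped, because
clipping would bias the state means. SG utilities are the staircase's
indifference probability; states judged worse than dead are censored at
utility 0. Per-state weights are the coefficients of a no-intercept
regression of disutility on the full state-dummy set — algebraically the
per-state means (an intercept would be unidentifiable with a full dummy
set) — with CIs from the pooled residual variance of that single
regression; a state with one record gets an undefined CI.

## The survey simulator

The raw responses behind the published weights were never deposited, so the
package ships a seeded simulator that generates them from a known latent
scale; every estimator is validated by parameter recovery against that
ground truth. The simulated designs mirror the field designs this package
targets: a registry of `n + 2` states (two anchors), 15 paired comparisons
per respondent drawn uniformly (anchors included), 3 VAS ratings per
respondent (two substantive states plus 'being dead'; anchors excluded from
substantive draws), 3 SG staircases (5% grid starting at 50%), 3 PHE
ladders with a uniformly chosen starting rung.

The paired-comparison responder is probit: a chosen healthier with
probability `Φ((d_b − d_a)/σ_pc)` — chosen to match the analysis model so
that recovery is well-posed; exact ties under `σ_pc = 0` resolve by fair
coin. VAS marks are `100(1 − d)` plus Gaussian noise, clamped to [0, 100]
(the instrument cannot record out-of-range marks). The SG responder is
deterministic given an internal utility `u = (1 − d) + ε`: `u < 0` reports
worse-than-dead at the first question; otherwise the staircase settles on
the grid probability nearest `u` (midpoint ties toward the lower
probability), capped to [0.05, 0.95] since a 5% staircase from 50% cannot
state indifference at 0 or 1. The PHE responder prefers the prevention
programme at rung X iff `X·w ≥ 1000` (a tie counts as preferring it) with
internal weight `w = d + ε` clamped to (0, 1]; the deterministic walk makes
the final bracket independent of the starting rung.

Default noise scales — `σ_pc = 0.25` (latent scale), `σ_vas = 10` VAS
points, `σ_sg = 0.10`, `σ_phe = 0.10` — are moderate values producing
realistic response dispersion (e.g. ~16% discordant choices for states 0.25
apart). Latent weights default to uniform on [0.02, 0.95], keeping
substantive states away from anchor coincidences. The PHE task count per
respondent (3) matches the other instruments; the published design does not
state it. The simulator deliberately omits respondent covariates, quota
sampling, interviewer effects, fatigue/order effects and nonresponse, so
passing recovery tests demonstrate correctness of the estimators under the
stated response model, not robustness to those real-data features. The same
respondent may see the same state in several instruments.

## Evaluation layer

Pearson correlations use pairwise deletion and refuse zero-variance input.
Severity distributions bin weights into deciles with half-open bins
`[lo, hi)` and a closed final bin — the convention that reproduces the
published proportions — with out-of-range values counted in an overflow
bucket. The utility comparison correlates `1 − dw` with externally supplied
utilities (e.g. an EQ-5D-5L tariff) over common states; no tariff is bundled.
The packaged reference table transcribes the published weights of 256 states
(four models, plus GBD 2010 weights for the 220 overlapping states) and is
shape-validated and checksummed on load.

## Problem sizes and numerics

The recovery exercise used throughout (tests and the acceptance script) is
30 substantive states × 500 respondents × 15 comparisons, `σ_pc = 0.25` —
large enough that the probit MLE is well-conditioned and recovery r
exceeds 0.99. Probit fitting runs L-BFGS followed by Newton polishing to a
gradient sup-norm of 1e-8; interval regression uses bounded L-BFGS with a
projected-gradient convergence check (the all-identical-interval case has a
flat likelihood ridge: any mean inside the interval with scale → 0 is
optimal, and the fit reports a point inside with the maximal likelihood).
Grid-search oracles in the test suite (joint grid contraction for the
probit; 2-parameter grid for the censored normal) are derivative-free and
independent of the fitting code.

## Known limitations

- Anchor uncertainty is excluded from Model 1 CIs by construction.
- Model 2's interval regression assumes a common scale across states and
  a log-normal latent weight; severe misfit of either is not diagnosed.
- The SG grid caps non-censored utilities at [0.05, 0.95], bounding Model 4
  estimates away from 0 and 1 except through censored records.
- Holdout mean-absolute-difference depends on the number of replicates per
  holdout pair; sparse designs give noisy observed frequencies even under a
  perfect model.
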