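# Methods

This note documents the models, parameter choices, and numerical decisions
behind `tempotrain`, in the package's own terms. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. The measurement model

### Psychometric function

Keyword-correct probability at time-compression ratio *L* (percent of the
sentence's duration removed, 0 < L < 100) is

p(L) = (1 − λ) · σ(−s·(L − θ)),

a two-parameter decreasing logistic with threshold θ (% compression),
slope *s* (> 0, per %-compression) and a fixed lapse λ ∈ [0, 0.1]
(upper-asymptote shortfall). With λ = 0, p(θ) = 0.5 exactly, so the
threshold parameter *is* the 50%-correct compression ratio being measured.
The functional form is the package's choice — the simplest family whose
50% point equals its location parameter. The guess rate is fixed at 0:
open-set sentence repetition has no meaningful guessing floor. The default
slope 0.15 gives a dynamic range of roughly ±15% compression around
threshold, a realistic span for sentence-level speech tests.

### Adaptive staircase

One block = 30 sentences, each carrying 5 scored keywords. The rule is a
word-majority 1-up/1-down: ≥ 3 of 5 keywords correct → level + step
(faster); otherwise → level − step. Start 20%, initial step 10%, step 5%
after the second reversal; stimuli exist only at 5–95% in 5% steps, so
levels are clamped to that grid. Choices the procedure's description
leaves open, fixed here:

- **Reversal** = a trial whose prescribed direction differs from the
  previous trial's direction; the first trial has no direction. Whether a
  first-trial outcome can count as a reversal is unknowable from the
  procedure's description; with this definition it cannot.
- **Step bookkeeping**: `step_in_force` on trial *t* is the step that set
  trial *t*'s level; the reduced step first applies to the level of the
  trial *after* the second reversal and never reverts.
- **Boundaries**: levels clamp at 5/95; a clamped repeat is not a
  reversal (reversals are defined by response direction only).
- The 30th trial's response moves nothing.
- Sentences are drawn without replacement from the 720-sentence pool
  within a block; an `exhaust_pool` flag extends no-repeat study-wide
  (17 trained-talker blocks × 30 = 510 ≤ 720, so it is satisfiable).

For a Binomial(5, p(L)) responder the chain's equilibrium — the level
where P(≥ 3 of 5 correct) = ½ — equals the level where p = 0.5, because
the binomial median sits at ½ when p = ½ (symmetry). `equilibrium_level`
solves the general case (λ > 0) by root bracketing and is the analytic
oracle for the staircase-convergence tests. The demonstration observer
used in the long-track checks is θ = 40, s = 0.15, λ = 0 (mid-grid, so
boundary effects are negligible).

### Threshold extraction

`fit_block` maximizes the binomial likelihood of the keyword counts over
(θ, s) with λ fixed (L-BFGS-B; start θ₀ = mean visited level, s₀ = 0.1;
bounds θ ∈ [−50, 150] — a plausible range that also clamps runaway fits —
and s ∈ [0.01, 2]). Two scoring conventions are implemented because the
original fitting granularity is not documented: `keyword` (default,
counts of 5 per sentence) and `sentence` (binary, correct iff ≥ 3 of 5;
same logistic family, whose 50% point coincides with the keyword 50%
point under keyword independence). Degenerate blocks are handled
explicitly rather than silently:

- a single visited level raises a degenerate-design error (a 2-parameter
  fit is unidentifiable); the protocol layer catches it and applies the
  fallback;
- responses that never straddle the majority criterion (no 50% crossing)
  or an optimizer failure trigger the **reversal-average fallback** —
  mean of reversal levels, or of all visited levels when < 2 reversals —
  flagged `fallback_used`, never dropped.

Keyword responses are treated as 5 independent Bernoulli draws in the
likelihood; overdispersion (within-sentence keyword correlation) is a
generator-side concern only and is not modeled by default.

## 2. The synthetic listener generator

Block thresholds follow

y = μ + b_i + β_time·[post] + β_talker·[novel] + β_int·[post ∧ novel]
  + β_time·c(session)·[training] + ε

with listener random intercepts b_i ~ N(0, σ²_subject) and block residual
ε ~ N(0, σ²_res). Defaults (all overridable via config):

| parameter | default | units | provenance |
|---|---|---|---|
| μ (pre, trained talker) | 25.8 | % compression | reported intercept |
| β_time (training gain) | 8.2 | % | reported test-time effect |
| β_talker (novel-talker offset) | 5.2 | % | reported talker effect |
| β_int (time × talker) | −1.9 | % | reported interaction |
| σ²_subject | 243.1 | %² | reported random-intercept variance |
| σ_res | 4.4 | % | derived, see below |
| slope s | 0.15 | per % | package choice (see the measurement-model section) |
| learning curve c(k) | k/5 | fraction of β_time | linear; shape configurable |
| AzBio pre mean / SD | 55 / 15 | % | package choice, realistic CI-in-noise spread |
| AzBio change mean | 6.3 | % | reported paired change |
| AzBio change SD | 7.857 | % | derived: 2.1 · √14 (SE → SD at n = 14) |

**Derived σ_res.** The residual variance of the reported model is not
printed. In the balanced 2 × 2 within-listener design with reference
coding, the test-time estimate is a mean of 14 within-listener contrasts,
so Var(β̂_time) = 2σ²_res/14. Inverting the reported SE 1.68 gives
σ_res = 1.68·√7 ≈ 4.44, rounded to 4.4. The test suite verifies this
closed form by brute force: the replicate SD of test-time estimates
across simulated studies reproduces ≈ 1.66–1.68.

**Demographics.** `fixture` mode copies the enrolled cohort's table
verbatim (14 listeners; the table is shipped in-package; note its ages
average 58.9 while the recruitment text says mean 57.4 — the table is
preserved as printed, not reconciled). Listeners with a single
implant-use entry are coded unilateral (3 of 14); per-listener durations
are the mean of the available ears. `parametric` mode draws age uniform
on [30, 82], MoCA ≈ round(N(27.5, 2)) clipped to [0, 30], duration of
deafness Gamma(1.2, 7) years, CI use uniform [1, 25] years, CNC
N(80, 16)% clipped to [0, 100], and redraws until the eligibility screen
(MoCA ≥ 22, CNC ≥ 20%) passes. Number of CIs is Bernoulli(½)+1 with no
effect on thresholds, matching the null device-count finding the
analysis probes.

**What the generator deliberately does not emulate**: audio or electrode
stimulation; correct-answer feedback as a mechanism (learning is indexed
by session count only); per-sentence AzBio scoring (a session-level
percent is drawn directly; the +10 dB SNR babble condition is a label);
any pretest block-order effect (novel-first is scheduled but has no
generative effect — a confound the real design carries); dependence of
the AzBio change on its baseline (independent by construction); dropout;
calendar time. The AzBio posttest score is pre + change without clamping,
so the paired change mean stays exactly recoverable; simulated post
scores can therefore marginally exceed 100%. Consequently, passing
recovery tests demonstrates that the *analysis pipeline* is unbiased for
data following the assumed structure — not that real listeners follow it.

## 3. Protocol

Per listener: pretest (AzBio score; one novel-talker block, then one
trained-talker block, in that order), five training sessions × 3
trained-talker blocks, posttest identical to pretest — 19 threshold
blocks and 2 AzBio scores; a 14-listener study has 266 threshold rows.
Two simulation modes: `trial_level` runs the staircase and psychometric
fit for every block; `threshold_level` draws block thresholds directly
from the generating model (for precise recovery experiments, bypassing
staircase-induced noise). Block RNG streams derive from (study seed,
listener index, phase, session, block), so any block is reproducible in
isolation and identical (config, seed) pairs give bit-identical datasets.

The mixed model uses the pre/post blocks only (4 per listener, 56
observations — consistent with the reported denominator df of 39);
training blocks feed the session summaries (averaging the 3 blocks within
listener first). A config flag can add training rows to the model, coded
with test_time = fraction of training completed (0 at pre, 1 at post);
this is an extrapolation, off by default. The posttest delay and AzBio
list identities (3, 5, 8, 9) are metadata only.

## 4. Analysis

- **Mixed model**: `statsmodels` MixedLM, REML. Design terms (test time,
  talker, interaction) are always retained — the reported final model
  keeps its non-significant interaction, so design terms were evidently
  protected; only the z-scored candidate covariates (age, duration of
  deafness) undergo backward elimination (drop the least significant
  while p > 0.05, ML refits for the comparisons, final model by REML).
  This emulates the *outcome* of hierarchical term selection, not any
  particular selection package's algorithm.
- **Degrees of freedom**: Satterthwaite-type, computed from the observed
  curvature of the REML surface in (σ²_subject, σ²_res): for coefficient
  j, df = 2·f²/(∇f′A∇f) with f = Var(β̂_j) and A the inverse negative
  numeric Hessian of the REML log-likelihood (central differences,
  relative step 10⁻³). Written in-package because the Python mixed-model
  stack does not expose Satterthwaite df; a test validates estimates,
  SEs, df and variance components against an independent lme4 + lmerTest
  fit (agreement ~10⁻³ or better). When the random-intercept variance
  sits on the boundary (detected relatively: σ̂²_subject ≤ 10⁻⁴·σ̂²_res,
  since the optimizer stalls near 10⁻⁶ rather than at 0) the variance is
  floored at 0 with a warning and df fall back to containment
  (between/within) values: N − g − q_within for within-listener terms,
  g − q_between for between terms.
- **Paired test / regression / auxiliaries**: classical paired t on the
  AzBio change; OLS of that change on age, duration of deafness, CNC
  score, and the talker-averaged threshold change; six Pearson
  correlations of age with pre/post thresholds (trained, novel, average)
  and seven equal-variance two-sample t-tests by number of CIs — all
  deliberately uncorrected for multiple comparisons, mirroring the
  analysis being modeled. Groups with < 2 members yield flagged, skipped
  rows (the report always contains 6 + 7 entries). Constant-group
  comparisons are detected by exact range (ptp = 0) because float means
  of identical values differ in the last ulp across group sizes.
- **Missing/degenerate blocks** enter as missing rows (unbalanced fit,
  flagged), never imputed.

## 5. Recovery harness and problem sizes

`run_recovery` simulates replicate studies (fresh parametric cohort each,
n = 14), analyzes each, and reports per-parameter replicate means,
Monte-Carlo SEs (SD/√R), bias, and 95% t-interval coverage; replicate fit
failures are recorded, and > 10% failures invalidate the report. In
`threshold_level` mode the fixed-effect estimators are exactly unbiased
under the generating model; in `trial_level` mode a small
staircase-induced bias is possible (the 30-trial track starts at 20% and
its fit is noisy), which is why precision targets use threshold mode.

Problem sizes used by the shipped experiments, chosen to hold Monte-Carlo
error well below the tolerances they are compared against: 200 replicates
for the headline recovery experiment (≈ 10 s); 1000 replicates in the
test suite where a mean is compared against a 200-replicate-scale
tolerance and for the ≥ 500-replicate coverage check; 500 cohorts for the
AzBio change; 10,000 trials (500 burn-in) for the long staircase track;
200 × 300-trial blocks for fit consistency. Variance-component recovery
at n = 14 is reported but not precision-targeted: REML variance estimates
at 14 groups are noisy and slightly skewed, which the recovery report
shows as a positive mean deviation with a wide Monte-Carlo spread.

## 6. Known limitations

- The logistic form, slope default, and lapse handling are conventions;
  real psychometric functions for time-compressed speech may be
  asymmetric or shallower at high compression.
- The learning curve is linear by default purely for identifiability of
  the session effect's endpoint; only its endpoint (β_time) is
  recovery-targeted.
- Satterthwaite df are approximate near variance boundaries (the code
  falls back to containment df there).
- The change-score regression at n = 14 with 4 predictors has little
  power; the package reproduces the analysis, not its adequacy.
- Re-analysis of real data assumes the documented CSV schema and
  complete pre/post cells per listener.
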