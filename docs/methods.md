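# Methods

## Task and data model

A session is 96 trials in 4 blocks. Each trial offers one high-reward (HR)
and one low-reward (LR) person (from 2 HR + 2 LR task persons; 2 further
baseline persons are rated but never offered). After choosing, the subject
imagines an interaction with the chosen person in a scenario that is pleasant
with probability 0.8 (HR) or 0.3 (LR), and rates its pleasantness on a
continuous scale in [−1, 1] with 0 the neutral midpoint. The binary reward is
`pleasantness > 0`: an exactly-neutral rating counts as non-reward, since the
neutral-to-unpleasant scenario class is the non-rewarding one. Missed trials
carry no outcome, contribute no likelihood term, trigger no value or kernel
update, and are excluded from the `n` in the BIC.

## The five choice models

All models are likelihoods over the per-trial binary choice (HR vs LR
candidate). Free-parameter counts: RW = 2, CK = 2, RWCK = 4, WSLS = 1,
NULL = 1.

- **RW** — Q of the chosen person updated by `Q ← Q + α(r − Q)`; pair
  probabilities via softmax with inverse temperature β. Q is initialized at
  0.5 for every person (approximately neutral before the task), which also
  keeps Q in [0, 1] for 0/1 rewards and α ∈ [0, 1].
- **CK** — a choice kernel per person, initialized at 0, updated every trial
  as `CK ← CK + α_c(chosen − CK)` where `chosen` is 1 for the chosen person
  and 0 for everyone else (including persons not offered); softmax with its
  own inverse temperature β_c. Captures reward-independent perseveration.
- **RWCK** — both updates run in parallel and a single softmax acts on the
  combined logit `β·Q + β_c·CK` (additive combination).
- **WSLS** — noisy win-stay-lose-shift on person identity: after a rewarded
  trial the previously chosen person is re-chosen with probability 1 − ε/2,
  after a non-rewarded trial avoided with probability 1 − ε/2. On the first
  trial, after a missed trial, and whenever the previously chosen person is
  not in the offered pair (pairings vary across trials), both candidates get
  0.5. "Win" means binarized reward 1.
- **NULL** — a constant bias b toward the HR candidate, independent of
  history. It is the chance model at b = 0.5 and absorbs any static
  side/condition preference otherwise.

Numerics: the softmax is computed with max subtraction; choice probabilities
are floored at 1e-12 before logs. Because RWCK nests RW (β_c = 0) and CK
(β = 0), its minimized negative log-likelihood can never exceed theirs
beyond optimizer tolerance — a property the tests assert.

## Fitting and model comparison

Per subject × model, the negative log-likelihood is minimized with L-BFGS-B
from `n_starts = 10` Latin-hypercube start points within bounds α, α_c, ε,
b ∈ [0, 1] and β, β_c ∈ [0, 20] (the softmax over [0, 1]-valued Q saturates
well below 20). Ties between starts go to the lowest start index; everything
is seeded. `BIC = ln(n)·df + 2·NegLL` with n the subject's non-missed trial
count. Fixed-effects comparison uses ΔBIC = BIC_ref − BIC_model and
per-subject best-BIC counts (ties broken by canonical model order RW, CK,
RWCK, WSLS, NULL).

Random-effects Bayesian model selection treats each subject's best model as
drawn from a population distribution with Dirichlet prior (mass 1 per
model). Log model evidence is approximated as −BIC/2 (the standard
Laplace-style surrogate when only BICs are available). The variational
scheme alternates subject responsibilities (softmax of evidence plus
Dirichlet digamma terms) with Dirichlet count updates to a 1e-6 parameter
tolerance. Exceedance probabilities — the posterior probability that a model
is the most frequent in the population — are Monte-Carlo frequencies of the
argmax over 1e6 Dirichlet draws (seeded; stable to about ±0.001), chosen
over pairwise closed forms for K = 5 generality.

## Synthetic cohorts

The generator is first-class, tested code; its defaults are the study
conditions. 49 subjects × 96 trials in 4 blocks; pleasant-scenario
probabilities 0.8/0.3; miss rate 0 by default (settable). Each trial pairs
one random HR with one random LR person, balanced so each of the 4 possible
pairs appears 6 times per 24-trial block; left/right position is
counterbalanced at random. The agent is any of the five models with
parameters drawn per subject from uniform ranges kept 10% inside the fitting
bounds (α ∈ [0.1, 0.9], β ∈ [1, 10], ...), so simulated cohorts are
well-posed for recovery.

Pleasantness ratings are drawn from truncated normals on [−1, 1]: mean +0.5
(sd 0.25) on pleasant trials, mean −0.25 (sd 0.25) on neutral-to-unpleasant
trials. The distributions deliberately straddle the midpoint, so the
binarized reward occasionally disagrees with the scenario valence (about 2%
of pleasant and 16% of unpleasant trials), as with real ratings. These
parameters are plausible stand-ins, not calibrated to any empirical rating
distribution.

Liking structure: post-task liking of each HR person is
`pre + liking_effect·(p(HR) − 0.5) + noise`, with LR and baseline persons
receiving noise only. Defaults `liking_effect = 0.6`,
`liking_noise_sd = 0.08` put the planted preference-liking correlation in a
realistic moderate range (observed skipped Spearman around 0.5–0.8 at
n = 49) so that the pipeline-level tests probe sign and significance rather
than a hairline effect.

Pattern sets for the RSA are `signal_sd · person_component + noise_sd ·
voxel noise` per person × run (4 × 4, 100 voxels by default), with the first
two persons labeled HR and the last two LR. This emulates the *output* of a
condition-congruent pattern-estimation step (HR persons estimated from
pleasant trials only, LR from neutral-to-unpleasant only) — selecting the
congruent trials from raw data is the caller's responsibility.

What the generator does not emulate: BOLD time series or scanner noise,
rating autocorrelation, subject-level lapses/attention drift, or scenario
repetition effects. Passing tests therefore show that the pipeline recovers
the structure it assumes, at the design's sample sizes — not that real data
satisfy those assumptions.

## Recovery studies

Parameter recovery: draw true parameters, simulate a session, refit the
generating model, correlate true with recovered values (Pearson and
Spearman); 100 simulations per condition by default. Recovery of α improves
with larger simulated β, since more deterministic choices are more
informative about values. Model recovery: simulate from each model, fit all
five, record the best-BIC winner; 50 simulations per generating model give a
confusion matrix whose diagonal dominance shows the model space is
discriminable at 96 trials. These sizes are desk-scale defaults chosen for
statistical stability at interactive runtimes.

## Behavioral statistics

- **p(HR)**: fraction of valid trials on which the HR candidate was chosen.
- **Wilcoxon signed-rank** (one-tailed): zero differences dropped, W = rank
  sum of positive differences, z from the normal approximation with a 0.5
  continuity correction and tie-corrected variance, effect size
  r = z/√n. The normal approximation (not exact enumeration) is used
  because it is the standard reporting convention at n ≈ 49; with 49
  distinct values all above the test point it gives W = 1225 and r = 0.87.
- **Liking change**: per condition, mean(post − pre) over its two persons;
  HR and LR changes are corrected by subtracting the baseline change, which
  cancels any generic shift between measurements; the HR-vs-LR contrast is
  ΔHR − ΔLR.
- **Skipped Spearman**: bivariate outliers are flagged by the projection
  method — for every direction from the coordinatewise-median center to a
  data point, a point whose MAD-standardized projected distance exceeds
  √χ²₀.₉₇₅(2) ≈ 2.72 on any direction is skipped — then Spearman on the
  retained pairs with a seeded percentile bootstrap CI (1000 resamples).
  The outlier rule is pluggable (`outlier_fn`) since robust-correlation
  toolboxes differ in the exact variant (e.g. MCD- vs projection-based
  centers); the projection/MAD rule is the default family choice.

## RSA model matrices

The 16 × 16 hypothesis RSM over 4 persons × 4 runs codes same-person,
different-run pairs as +1 and different-person, different-run pairs *within
the same reward condition* as −1. Same-run pairs and cross-condition pairs
are excluded by the mask: the hypothesis is about replicability of person
patterns *across* runs, and cross-condition cells would confound person
identity with condition (value) differences. Of the 120 lower-triangle
cells, 24 are +1, 24 are −1, 72 excluded.

Data RSMs use Kendall τ between pattern vectors. Model-data agreement is
Kendall **τ-a** over the included cells — τ-a rather than τ-b because the
model matrix is almost entirely tied, and τ-b's tie normalization would
inflate the score. A consequence worth knowing: τ-a of the tied model matrix
with itself is not 1 but the tie-limited ceiling 24·24/C(48,2) ≈ 0.51, which
is also the maximum any data RSM can attain. Positive values mean
same-person similarity exceeds different-person similarity; group-level
inference is a one-sample test over per-subject τ values.

## Regressor export

A forward pass of the RW model (single source of truth: the same code path
as the likelihood) yields per-trial Q of the chosen person (pre-update), the
prediction error δ, and the model's choice probability. Group analyses use
the population **median** of the fitted α and β applied uniformly to all
subjects, which is less noisy than per-subject estimates. Events are
exported in BIDS-events dialect (onset, duration, trial_type, modulator):
the 8 s imagination period modulated by δ, choice onsets (stick) modulated
by pre-update Q, rating onsets, and missed-trial onsets. Modulators are
mean-centered within event type — standard parametric-modulation practice,
made explicit here rather than delegated to GLM software defaults.

## Known limitations

- The −BIC/2 evidence surrogate ignores posterior parameter covariance;
  exceedance probabilities on real data would differ from a full
  free-energy-based scheme, typically mildly.
- WSLS is undefined when the previous choice is not re-offered; the 0.5/0.5
  fallback is one reasonable convention among several (e.g. condition-level
  stay/shift) and makes WSLS weakly identified under rapidly changing
  pairings.
- The skipped-correlation CI bootstraps the retained pairs; it does not
  re-run outlier detection inside each bootstrap resample.
- The synthetic liking model is linear in p(HR) with Gaussian noise and
  clipping at the rating bounds; real liking updates are bounded and likely
  heteroskedastic.
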