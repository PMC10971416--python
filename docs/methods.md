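# Methods

`cogmech` re-implements, as a tested and reusable pipeline, the computational
analyses of a class of two-session randomized experiments on brief
cognitive-behavioural intervention components: a reward–effort
decision-making task probing behavioural-activation-like mechanisms, and a
causal-attribution task probing cognitive-restructuring-like mechanisms.
Raw participant data are replaced throughout by a synthetic-cohort generator
with the statistical structure the models assume.

## Behavioural models

### Reward–effort choice

Each trial offers two options; option *i* has value

    V_i = rewSens * reward_i − effSens * effort_i

with reward in coins (3–7) and effort as a fraction of the participant's
calibrated maximal effort (0.25–0.95). The probability of choosing the
higher-reward option is `logistic(V_hi − V_lo)` (Bernoulli likelihood).
Per parameter, the two sessions' subject-level values follow a bivariate
normal with free per-session SDs and a cross-session correlation given a
uniform prior on [−1, 1] (LKJ(1) in the 2×2 case); this correlation is also
the model's test–retest reliability estimate. Allocation to the active
intervention adds a group-level shift `phi_INT` to session-2 parameters
(active arm only), with a standard-normal prior. Subject parameters use the
non-centered parameterization. Catch trials (dominated attention checks)
are excluded from the likelihood by default — they exist to implement the
published exclusion rule, and their dominated structure would otherwise
distort sensitivity estimates; this is configurable.

Priors (the original study's full prior list lives in supplementary
material that is not part of this re-implementation, so these are this
package's documented choices): group means Normal(0, 2) for reward
sensitivity and Normal(0, 5) for effort sensitivity (scales chosen per
predictor range so prior-predictive choice rates are non-degenerate);
subject SDs half-Normal(1); `phi_INT` Normal(0, 1); correlations LKJ(1).
Sensitivities are sign-free, matching the linear value form.

### Causal attribution

Choices among four explanations are coded on two binary dimensions —
internal (vs. external) and global (vs. specific). Each dimension is a
Bernoulli draw with probability `logistic(theta)` for the subject's latent
trait in that (dimension, session, valence) cell. The logit link is this
package's documented reading of the Bernoulli trait model: the trait has
unbounded support under its multivariate-normal population model, so a link
is required to reconcile the two, and the logistic link keeps the trait
interpretable as a log-odds of endorsement. Within each valence, the four
traits (2 dimensions × 2 sessions) share a 4×4 multivariate normal —
half-Normal(1) scales, LKJ(1) correlation (sampled through the C-vine
canonical-partial-correlation construction) — and `phi_INT` shifts
session-2 traits of active-arm subjects per dimension × valence. Group
means have Normal(0, 2) priors.

### Joint symptom–behaviour model

Ordinal item responses are modelled by unidimensional graded response
models: `P(y ≥ k) = logistic(a_j * theta − kappa_jk)` with positive
discriminations and ordered thresholds. Two parallel GRMs are used
(amotivation A: six AMI behavioural-amotivation items plus two PHQ9 items;
negative cognition N: eight DAS short-form items plus two PHQ9 items); the
shipped banks are synthetic, mirroring only the item counts and category
structure. Identification: traits Normal(0, 1), `a_j` log-normal
(log a ~ Normal(0, 0.5)), thresholds Normal(0, 2) on the ordered region via
a first-threshold + log-spacing transform.

In the joint model the trait enters the behavioural hierarchy exactly as a
regression on the target parameter: `beta_BASE * theta` shifts session 1
for everyone, and `beta_INT * theta` adds to the intervention effect for
active-arm subjects at session 2 — and only there, which is how the model
is written; whether a trait–change association should also exist in the
control arm is a sensitivity question the single-stage fit does not answer.
Both betas have Normal(0, 1) priors and are read with the same 90%
credible-interval zero-exclusion rule as the intervention effects.
Default moderated target: effort sensitivity (reward–effort task) and the
internal/positive trait (attribution task); both configurable. A two-step
mode (fit the GRM, plug standardized posterior-mean traits into the
behavioural fit as fixed covariates) is provided for diagnostics; the
single-stage joint fit is the default because it propagates trait
uncertainty.

## Inference

No MCMC framework is pre-installed in the supported environment, so the
package ships its own blocked adaptive Metropolis-within-Gibbs engine,
designed around the structure shared by all models here:

* **Subject blocks.** Non-centered subject offsets are conditionally
  independent across subjects given group-level parameters, so one
  vectorized proposal updates every subject simultaneously with
  per-subject accept/reject. Proposal scales adapt per subject
  (Robbins–Monro toward 0.44 acceptance) with a shared per-dimension shape
  learned from the warmup spread of each coordinate.
* **Group blocks.** Group parameters are transformed to unconstrained
  coordinates (log SDs, atanh canonical partial correlations, ordered
  thresholds via log-spacings) and updated in small multivariate blocks
  whose proposal covariance adapts Haario-style from warmup history.
* **Interweaved recentering moves.** The slow direction of non-centered
  hierarchies — trading group means, intervention effects or scales
  against the sea of subject offsets — is removed by centered moves that
  propose a change to group location/scale parameters while transforming
  the offsets so every subject's natural-scale parameter is exactly
  unchanged. The likelihood is invariant by construction (acceptance
  depends only on priors and the transform Jacobian), making these moves
  essentially free. Without them the intervention-effect posterior can
  remain biased toward its initialization at apparently converged R-hat;
  with them the engine recovers conjugate posteriors exactly (see
  `tests/test_sampling.py`) and passes simulation-based calibration.
* **Preconditioned Crank–Nicolson offset moves.** Each sweep also applies
  a pCN update to the subject offsets (`z' = sqrt(1-beta^2) z + beta eps`),
  which preserves the standard-normal offset prior exactly, so acceptance
  depends on the likelihood alone. Random-walk updates move the overall
  offset *magnitude* very slowly, and the group scales can only mix as
  fast as that magnitude; the pCN move jumps it directly. `beta` adapts
  toward 30% acceptance during warmup.
* All adaptation freezes at the end of warmup, so retained draws come from
  a valid time-homogeneous Markov chain.

Convergence is gated numerically: rank-normalized split-R-hat (the modern
bulk/tail variant, verified against an independent implementation to 1e−6)
computed for every recorded parameter, with fits above 1.05 flagged via a
`ConvergenceWarning` rather than silently returned.

**Sampler profiles.** The published configuration — four chains of 2000
iterations with 1000 discarded as warmup — was designed for a
gradient-based sampler. For this random-walk engine each recorded iteration
spans a configurable number of full Gibbs sweeps (`steps_per_iter`), so the
`full` profile keeps four chains and 1000 retained draws per chain while
spending eight sweeps per retained draw. The `test` profile (two chains,
700 draws, 2000 warmup sweeps, six sweeps per draw) is the default for the
test suite and examples and typically reaches R-hat ≤ 1.1 on the study-size
fits here.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the published design constants: 44 reward–effort
trials in four blocks with two catch trials (highest reward at lowest
effort, in distinct blocks), rewards 3–7 coins, efforts 0.25–0.95 of
calibrated maximum; 32 attribution scenarios (16 per valence) in two
blocks, each offering the 2×2 explanation grid; 1:1 randomization; and the
published exclusion rules with their printed boundary conventions (≥1
correct catch trial retains; median RT must exceed 2 s strictly; a response
position at or above 75% excludes).

**Offer distribution.** The published trial array is not printed, only its
ranges; the original task was explicitly optimized during piloting to
recover its target parameters in a minimal number of trials. The generator
therefore emulates an information-optimized offer mix: about 70%
*effort-decisive* trials (one extra coin against a large effort separation,
placing choices near indifference, where they carry maximal information
about effort sensitivity) and 30% *reward-decisive* trials (two to four
extra coins against a small effort separation, anchoring reward
sensitivity). Mixing the two types anti-correlates reward and effort
differences across trials; a single undifferentiated offer grid leaves the
two sensitivities nearly collinear in the likelihood and inflates
effort-sensitivity uncertainty several-fold, which a Fisher-information
analysis of candidate designs (run before the cohort defaults were frozen)
showed would make session-2 effort-sensitivity shifts of the size studied
here undetectable at N = 100.

**Cohort defaults** (the study conditions for all seeded experiments):
group means rewSens 0.8 per coin and effSens 1.5 per unit effort fraction
(higher-reward choice rates around 0.6–0.75), between-subject SDs 0.4,
cross-session correlation 0.75 — the reliability regime reported for these
tasks. Attribution: trait means internal/positive 0.8, global/positive 0.4,
internal/negative and global/negative −0.2 (endorsement rates ~0.45–0.7),
SDs 1.0, cross-session correlation 0.7, within-session cross-trait
correlation 0.3 (combined separably, which keeps the implied 4×4
correlation positive definite). Response times are log-normal (medians
1.2 s choice, 3.5 s attribution) so the RT exclusion rule can be exercised
in both directions; option positions are uniform.

What the generator does **not** emulate: sequential/block-order effects,
learning or fatigue within session, effort-calibration drift, RT–choice
dependence, item-level response styles, missingness, or model
misspecification of any kind. Passing recovery and calibration tests
therefore shows the inference machinery is correct and well-calibrated
under the model's own assumptions at realistic sizes — not that the model
is true of real participants.

## Validation components

**Simulation-based calibration.** For each replicate: draw all parameters
from the prior, simulate a cohort, refit, and rank each monitored true
value within its thinned posterior draws (ties broken uniformly; default
thinning 4 mitigates autocorrelation, which the rank statistic is otherwise
sensitive to with MCMC draws). Monitored parameters: all group-level
quantities plus five fixed subject-level parameters. Uniformity is tested
by chi-square over equal-width rank bins plus a
Dvoretzky–Kiefer–Wolfowitz ECDF band. SBC priors are the pilot-informed
configuration (narrower, centered at the pilot parameter regime) used for
both simulation and fitting, mirroring the original study's practice of
specifying SBC priors from pilot posterior estimates; with the full
weakly-informative analysis priors most prior draws produce degenerate
(all-same-choice) datasets that say nothing about calibration in the
realistic regime. SBC fits start each chain at the prior draw that
generated the dataset — a stationary start, so short chains remain
unbiased in expectation. Autocorrelation, however, is not harmless here:
mutually correlated draws clump, pushing the true value's rank toward the
extremes and producing spurious U-shaped rank histograms, and the group
*scales* decorrelate slowest. Ranked draws are therefore spaced far apart
(30 sweeps for the reward-effort model, 60 for the attribution model,
whose ten-parameter per-valence scale block mixes slowest; spacings were
increased until the rank diagnostics of the calibrated sampler
stabilized).

Because SBC refits the same small model hundreds of times, the built-in
task models use a *batched* runner (`sbc_run_batched`): all replicate
chains advance in lockstep, with a leading dataset axis on every state
array, which amortizes per-update interpreter overhead and makes generous
spacing affordable. Each replicate remains an independent Markov chain —
no information is shared across datasets — and a test verifies the batched
posterior matches the general-purpose engine on identical data. The
generic per-dataset adapter interface (`sbc_run`) remains for arbitrary
models. The test-scale protocol uses 200 datasets of 20 subjects; the
full-scale protocol (1000 datasets, D = 2000 draws) is available through
the same interfaces.

**Test–retest reliability.** A single hierarchical fit of both sessions
with the intervention term disabled; the posterior of the cross-session
correlation R is the reliability estimate (propagating per-subject
measurement precision, unlike correlating point estimates).

**Fit metrics.** Posterior predictive accuracy replicates choices
stochastically from posterior parameter estimates on the observed trial
arrays (default: posterior-mean subject parameters, 100 replications; a
draws-resampling variant is available since the published computation did
not specify which). The attribution task's two codes are scored as two
separate accuracy streams. Pseudo-r² is `1 − L/C` with `C = t·log(1/2)`,
computed by default at posterior-mean subject parameters (again with a
draws-averaged variant available).

**Heterogeneity of treatment effects.** Change scores are per-subject
differences in posterior-mean parameters between sessions, standardized by
the SD of baseline posterior means (pooled across arms by default, per-arm
optionally — the published text does not say which; pooling uses the
randomization). `SD_IR = sqrt(SD_Act² − SD_Con²)`;
`SD_IRse = sqrt(2(SD_Act⁴/DF_Act + SD_Con⁴/DF_Con))`; 95% CI as
`SD_IR ± 1.96·SD_IRse`; thresholds 0.1/0.3/0.6 classify small, moderate
and large individual-response effects. A negative variance difference is
clamped to 0 and flagged (variances cannot be negative); the signed square
root is available behind a flag. The analytic SE is a variance-scale
approximation: a direct bootstrap of SD_IR is wider by the delta-method
factor `1/(2·SD_IR)` (about 25% at SD_IR = 0.4), which the oracle test
documents.

**Power.** The between-within interaction power uses the noncentral F
distribution with `df1 = (groups−1)(m−1)`, `df2 = N − groups`, and
noncentrality `lambda = f²·N·m/(1−rho)` with `f = d/2` — the convention of
the power software the published analyses used; both published
configurations (d = 0.48, N = 48, ρ = 0.6 and d = 0.47, N = 72, ρ = 0.43)
reproduce ≥ 95% power. The self-consistency simulation in the test suite
uses the generative mapping this convention implies (a group change-score
difference of `d·sqrt(2/(1−rho))` change-score SDs).

## Problem sizes

The test suite runs the recovery protocols at the sizes the package
documents as its standard experiments: ten cohorts of N = 100 (reward–
effort) and ten of N = 200 (attribution) for intervention-effect recovery;
200 SBC datasets of 20 subjects per model; one N = 150 reliability cohort;
one N = 200 joint-model cohort. The acceptance script reruns reduced
versions (three recovery cohorts, 60 SBC datasets, one cohort per remaining
analysis) so a complete from-scratch reproduction stays within a desktop
CPU budget; all sizes are stated in its output.

## Known limitations

* Random-walk MCMC needs many sweeps; the full-scale sampler profile is
  slow (minutes per study-size fit) compared to gradient-based samplers.
* The effort-sensitivity posterior is intrinsically wide at 44 trials; at
  N = 100 an absolute session-2 shift of 0.4 sits near the detection
  boundary (about 75–85% of seeded cohorts exclude zero at 90%), which the
  recovery protocol's 8-of-10 criterion reflects.
* GRM thresholds and discriminations are only weakly identified at 8–10
  items and N ≲ 100; joint-model moderation recovery is correspondingly
  noisy below N ≈ 150.
* The HTE interval is a normal approximation on the variance scale (see
  above); it is reported as published.
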