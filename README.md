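# cogmech

Hierarchical Bayesian modelling of brief-intervention task data in
computational psychiatry: a reusable, fully tested pipeline for two-session
randomized experiments on cognitive-behavioural therapy components.

Researchers studying *which* therapy component moves *which* cognitive
mechanism need more than a group-level p-value: they need task measures
that are reliable enough to carry individual differences, models whose
inference machinery is demonstrably calibrated, and analyses that separate
average treatment effects from individual response heterogeneity. This
package implements that full workflow for two task families, with a seeded
synthetic-cohort generator standing in for participant data:

- **Reward–effort choice** (behavioural-activation mechanisms): option
  values are linear in offered reward and required effort,
  `V = rewSens·reward − effSens·effort`, with Bernoulli-logit choice,
  per-parameter bivariate-normal subject effects across sessions
  (uniform-prior cross-session correlation) and a group-level active-arm
  shift `ϕ_INT` on session-2 parameters.
- **Causal attribution** (cognitive-restructuring mechanisms): each
  scenario choice is coded internal-vs-external and global-vs-specific;
  latent traits θ per subject × session × valence drive both codes through
  a logistic link, with a 4×4 multivariate-normal trait structure per
  valence and the same intervention-shift construction.
- **Joint symptom–behaviour models**: graded-response IRT on ordinal
  symptom items (amotivation and negative-cognition traits), embedded in
  the behavioural hierarchy so traits moderate baseline parameters
  (β_BASE) and intervention effects (β_INT), judged by 90% credible
  intervals excluding zero.
- **Validation and meta-analysis tools**: simulation-based calibration
  (prior draw → simulate → refit → rank uniformity), hierarchical
  test–retest reliability (posterior cross-session correlation R),
  posterior predictive accuracy and pseudo-r² (`1 − L/C`), heterogeneity
  of treatment effects (`SD_IR = √(SD_Act² − SD_Con²)` with its normal CI
  and 0.1/0.3/0.6 thresholds), and repeated-measures interaction power
  (noncentral F, `f = d/2`, `λ = f²·N·m/(1−ρ)`).

Inference runs on a built-in blocked adaptive Metropolis-within-Gibbs
engine with vectorized subject updates and likelihood-invariant
recentering moves (see `docs/methods.md`); convergence is gated by
rank-normalized split-R-hat ≤ 1.05.

## Worked example

```python
from cogmech import (SamplerConfig, default_reward_effort_cohort,
                     fit_reward_effort, generate_task_design,
                     intervention_effect_summary,
                     simulate_reward_effort_cohort)

design = generate_task_design(seed=1)          # 44 trials, 2 catch, 4 blocks
cohort = default_reward_effort_cohort(
    n_subjects=80,
    true_intervention_effect={"rewSens": 0.0, "effSens": -0.5},
    seed=7,
)
data = simulate_reward_effort_cohort(design, cohort)
fit = fit_reward_effort(data, mcmc=SamplerConfig.test_profile(seed=0))
for e in intervention_effect_summary(fit):
    print(e.parameter, round(e.mean, 3),
          [round(e.ci_low, 3), round(e.ci_high, 3)], e.excludes_zero)
```

prints (the simulated truth is a −0.5 shift in effort sensitivity for the
active arm, none for reward sensitivity):

```
phi_int[rewSens] -0.045 [-0.202, 0.102] False
phi_int[effSens] -0.382 [-0.655, -0.139] True
```

The effort-sensitivity effect is negative with a 90% credible interval
excluding zero — active-arm participants became measurably less
effort-averse at session 2 — while the reward-sensitivity interval
straddles zero, matching the simulated ground truth. `examples/` contains
one narrative script per capability (attribution fitting, SBC,
reliability/fit metrics, the joint model, HTE and power).

A thin CLI mirrors the library for scripted runs:
`cogmech simulate|fit|sbc|reliability|metrics|hte|power|report|run`
(see `cogmech --help`; `run` executes a YAML-configured
simulate → fit → validate → report pipeline with a hashed manifest).

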