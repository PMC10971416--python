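"""Fit the causal-attribution latent-trait model to a simulated cohort.

Choices on each of 32 scenarios (16 positive, 16 negative events) are coded
as internal-vs-external and global-vs-specific; the model estimates latent
endorsement tendencies per subject, session and valence, and the effect of
the active intervention on session-2 traits. Here the intervention lowers
internal attributions for negative events (the depressogenic pattern) by
0.5 logits.
"""

import warnings

from cogmech import (
    SamplerConfig,
    attribution_intervention_summary,
    default_attribution_cohort,
    endorsement_summary,
    fit_attribution,
    simulate_attribution_cohort,
)

warnings.filterwarnings("ignore")

cohort = default_attribution_cohort(
    n_subjects=60,
    true_intervention_effect={
        "internal_pos": 0.0, "global_pos": 0.0,
        "internal_neg": -0.5, "global_neg": 0.0,
    },
    seed=11,
)
data = simulate_attribution_cohort(cohort=cohort)
fit = fit_attribution(data, mcmc=SamplerConfig.test_profile(seed=0))
print(f"max R-hat: {fit.max_rhat:.3f}\n")

print("Intervention effects per dimension x valence (90% CI):")
for e in attribution_intervention_summary(fit):
    flag = "excludes 0" if e.excludes_zero else "includes 0"
    print(f"  {e.parameter}: {e.mean:+.3f} "
          f"[{e.ci_low:+.3f}, {e.ci_high:+.3f}] ({flag})")

es = endorsement_summary(fit)
grp = es.groupby(["valence", "dimension", "session"])["p_mean"].mean()
print("\nMean endorsement probabilities (posterior means across subjects):")
print(grp.round(3).to_string())
print(
    "\nA negative internal/negative effect means active-arm participants"
    "\nbecame less likely to blame themselves for negative events."
)
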