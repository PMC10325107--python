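"""Effectiveness of crop-loss mitigation measures.

Mitigation trials report *loss* outcomes (damage with vs without the
measure), so raw effects are computed on the loss scale and sign-aligned:
positive g = the measure reduced crop loss.  The example plants known
effectiveness differences between measure categories and recovers them.
"""

from birdcrop import (
    EffectSimConfig,
    MetaDataset,
    ModeratorSpec,
    compute_effects,
    fit_multilevel,
    simulate_effects,
    subgroup_estimates,
)

cfg = EffectSimConfig(
    n_studies=48,
    comparisons_per_study=(1, 4),
    true_mu=0.0,
    tau2_study=0.2,
    tau2_within=0.1,
    n_range=(3, 20),
    polarity="loss",  # raw outcomes are damage measurements
    moderators=[
        ModeratorSpec(
            "category",
            ["tape/ribbon/flag", "scaring model", "repellent", "sound"],
            [1.76, 1.23, 0.85, 0.98],
        )
    ],
)
effects = compute_effects(simulate_effects(cfg, seed=77))
data = MetaDataset(effects)

fit = fit_multilevel(data)
print(f"k = {fit.k} comparisons from {fit.n_studies} studies")
print(f"overall effectiveness g = {fit.mu:.2f} [{fit.ci_low[0]:.2f}, {fit.ci_high[0]:.2f}]")
print("\nby measure category:")
for level, est in subgroup_estimates(data, "category").items():
    print(
        f"  {level:17s} g = {est.mu:.2f} [{est.ci_low:.2f}, {est.ci_high:.2f}] (k = {est.k})"
    )
print(
    "\nPositive g = the measure reduced crop loss; categories are recovered\n"
    "near their planted effectiveness (1.76, 1.23, 0.98, 0.85)."
)
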