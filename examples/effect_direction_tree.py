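"""Which moderators predict the *direction* of the bird effect?

Fits a conditional inference tree to the sign of each effect size over
categorical moderators.  With a strong woody/herbaceous split planted in
the generator, the root should split on stem type and noise covariates
should be left alone.
"""

from birdcrop import (
    EffectSimConfig,
    ModeratorSpec,
    compute_effects,
    direction_proportions,
    fit_ctree,
    simulate_effects,
)

cfg = EffectSimConfig(
    n_studies=40,
    comparisons_per_study=(2, 6),
    true_mu=0.0,
    tau2_study=0.04,
    moderators=[
        ModeratorSpec("stem_type", ["woody", "herbaceous"], [0.46, -0.48], probs=[0.64, 0.36]),
        ModeratorSpec("climate", ["tropics", "nontropics"], [0.0, 0.0]),
        ModeratorSpec("insecticide", ["yes", "no"], [0.0, 0.0]),
    ],
)
effects = compute_effects(simulate_effects(cfg, seed=99))
responses = [e.g > 0 for e in effects]
covariates = {
    name: [e.moderators[name] for e in effects]
    for name in ("stem_type", "climate", "insecticide")
}

tree = fit_ctree(responses, covariates, alpha=0.05)
print(tree.render())
props = direction_proportions(responses, covariates["stem_type"])
for level, frac in props.items():
    print(f"positive effects among {level}: {100 * frac:.0f}%")
print(
    "\nEach split reports a Bonferroni-adjusted permutation p-value; leaves\n"
    "show the positive/negative counts of effect sizes."
)
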