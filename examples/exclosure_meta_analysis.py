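"""Pooled effect of bird access on crop production, from raw comparisons.

Generates a synthetic exclosure corpus (40 studies, several comparisons
each, with a known woody/herbaceous split), computes Hedges' g for every
treatment/control contrast, and fits the multilevel random-effects model
with stem type as a moderator.
"""

import numpy as np

from birdcrop import (
    EffectSimConfig,
    MetaDataset,
    ModelSpec,
    ModeratorSpec,
    compute_effects,
    fit_multilevel,
    moderator_test,
    simulate_effects,
    subgroup_estimates,
)

cfg = EffectSimConfig(
    n_studies=40,
    comparisons_per_study=(2, 6),
    true_mu=0.0,
    tau2_study=0.04,
    tau2_within=0.02,
    moderators=[
        ModeratorSpec("stem_type", ["woody", "herbaceous"], [0.46, -0.48], probs=[0.64, 0.36])
    ],
)
records = simulate_effects(cfg, seed=20230706)
effects = compute_effects(records)
data = MetaDataset(effects)

fit = fit_multilevel(data)
print(f"k = {fit.k} effect sizes from {fit.n_studies} studies")
print(
    f"overall pooled g = {fit.mu:.3f} "
    f"[{fit.ci_low[0]:.3f}, {fit.ci_high[0]:.3f}]  (p = {fit.p[0]:.3g})"
)
print(
    f"variance components: tau2_study = {fit.tau2_study:.4f}, "
    f"tau2_within = {fit.tau2_within:.4f}"
)
print(f"residual heterogeneity: QE = {fit.QE:.1f} (df {fit.QE_df}, p = {fit.QE_p:.3g})")

qm, df, p = moderator_test(data, ModelSpec(moderators=["stem_type"]))
print(f"stem-type moderator: QM = {qm:.2f} (df {df}, p = {p:.3g})")

for level, est in subgroup_estimates(data, "stem_type").items():
    print(
        f"  {level:11s} g = {est.mu:+.3f} [{est.ci_low:+.3f}, {est.ci_high:+.3f}] "
        f"(k = {est.k})"
    )

print(
    "\nA positive g means birds increased production; the subgroup rows show\n"
    "the woody/herbaceous contrast that drives the overall heterogeneity."
)
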