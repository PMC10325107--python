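"""Publication-bias diagnostics on a censored corpus.

Simulates a set of comparisons in which imprecise experiments are mostly
published only when their evidence looks strong (classic small-study
censoring), then runs the full diagnostic suite: fail-safe number,
rank-correlation and regression asymmetry tests, and trim-and-fill.
"""

from birdcrop import (
    EffectSimConfig,
    MetaDataset,
    bias_report,
    compute_effects,
    simulate_effects,
)

cfg = EffectSimConfig(
    n_studies=200,
    comparisons_per_study=(1, 1),
    true_mu=0.1,
    tau2_study=0.0,
    tau2_within=0.0,
    n_range=(3, 40),
    censor=True,
    censor_strength=1.0,
)
data = MetaDataset(compute_effects(simulate_effects(cfg, seed=12)))
report = bias_report(data)

print(f"k = {data.k} surviving comparisons (true mean effect 0.10)")
print(
    f"fail-safe N = {report.failsafe_n} "
    f"(robust threshold 5k+10 = {report.failsafe_threshold})"
)
print(f"Kendall tau = {report.kendall_tau:+.3f} (p = {report.kendall_p:.3g})")
print(f"Egger-type slope = {report.egger_slope:+.3f} (p = {report.egger_p:.3g})")
print(
    f"trim-and-fill: k0 = {report.trimfill_k0} studies imputed on the "
    f"{report.trimfill_side} side"
)
adj = report.adjusted_fit
print(
    f"adjusted pooled g = {adj.mu:.3f} [{adj.ci_low[0]:.3f}, {adj.ci_high[0]:.3f}]"
)
print(
    "\nSignificant asymmetry tests flag the censoring; the adjusted estimate\n"
    "moves back toward the generating truth of 0.10."
)
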