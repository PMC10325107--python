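# birdcrop

Quantitative synthesis tools for human–bird coexistence in croplands.

Birds in agricultural landscapes both damage crops (direct consumption)
and protect them (predation of herbivorous arthropods). Field evidence on
the *net* effect comes from exclosure experiments — paired plots where
mesh excludes birds but admits arthropods — and from trials of nonlethal
crop-loss mitigation measures; the social side comes from farmer and
resident surveys. `birdcrop` implements the complete analysis chain such
a synthesis needs:

- **Effect sizes** — bias-corrected Hedges' *g* from raw treatment/control
  summaries: *g* = *J·d* with *d* = (X̄_t − X̄_c)/SD_within,
  SD_within the pooled SD, *J* = 1 − 3/(4·df − 1), df = n_t + n_c − 2,
  and V_g = J²·V_d. Loss-scale outcomes are sign-aligned so positive *g*
  always means "birds increase production" or "the measure reduces loss".
- **Multilevel meta-analysis** — random intercepts for study and for
  comparison-within-study, estimated by REML; each effect weighted by the
  inverse of its within-study plus between-study variance; Wald CIs,
  residual-heterogeneity Q tests, omnibus moderator tests (Q_M), and
  subgroup estimates. Matches `metafor::rma.mv` to printed precision.
- **Publication bias** — funnel data, Rosenthal's fail-safe *N* with the
  5k+10 threshold, Begg/Kendall rank correlation (exact small-sample p),
  Egger-type regression on the standard error, and Duval–Tweedie
  trim-and-fill (L0 estimator) with an adjusted single-level fit.
- **Effect direction** — a conditional inference tree: recursive binary
  splits chosen by Bonferroni-adjusted permutation tests of independence
  between moderators and the sign of *g*.
- **Surveys** — binomial GLMMs (logit link, survey-level random
  intercept, Laplace approximation), all-subsets AICc ranking with
  ΔAICc < 2 model averaging, descriptive proportions, and a Spearman
  trend test for study counts over time.
- **Prioritization** — gridded "win-win" mapping: woody-crop share of
  production as a benefit index, min-max standardized richness product as
  a conservation index, 3×3 bivariate tercile classification, and a
  priority mask for cells in the top tercile of both.
- **Synthetic data** — generators for all three input kinds with known
  truths (nested effect structure, censored funnels, logit-scale survey
  effects, co-registered autocorrelated grids), so every stage is
  testable end to end without any external downloads.

## Worked example

```sh
python examples/exclosure_meta_analysis.py
```

```
k = 151 effect sizes from 40 studies
overall pooled g = 0.124 [0.005, 0.244]  (p = 0.0408)
variance components: tau2_study = 0.0701, tau2_within = 0.1236
residual heterogeneity: QE = 358.9 (df 150, p = 3.63e-19)
stem-type moderator: QM = 128.59 (df 1, p = 8.32e-30)
  herbaceous  g = -0.418 [-0.550, -0.286] (k = 49)
  woody       g = +0.384 [+0.283, +0.485] (k = 102)
```

The corpus was generated with woody effects centred at +0.46 and
herbaceous at −0.48: the overall pooled effect is small because the two
subgroups pull in opposite directions, the Q tests flag that
heterogeneity, and the subgroup estimates recover the planted truths.
The other scripts in `examples/` cover mitigation effectiveness,
publication-bias diagnostics, the effect-direction tree, survey model
averaging, and grid prioritization, each printing a short interpretation
of its numbers.

A thin CLI wraps the same library calls:

```sh
birdcrop simulate --what effects --seed 3
birdcrop effects synthetic_comparisons.csv --out effects.csv
birdcrop fit effects.csv --moderator stem_type --out fit.json
birdcrop bias effects.csv --out bias.json
birdcrop reproduce --exclosure data/exclosure.csv --surveys data/surveys.csv --out report.json
```

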