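"""Synthetic inputs with the statistical structure the analyses assume.

Three generators emulate the three kinds of input data:

* ``simulate_effects`` -- nested experimental comparisons: a true effect
  per comparison composed of a grand mean, a study-level random effect, a
  comparison-within-study effect and categorical moderator shifts; raw
  group means/SDs/sample sizes are then drawn so that the *population*
  standardized mean difference equals that true effect.  Raw summaries
  (not effect sizes) are emitted, so the effect-size computation is
  exercised end to end.  An optional censoring rule suppresses
  small/noisy comparisons with unimpressive one-sided evidence, creating
  funnel asymmetry for the publication-bias tests.
* ``simulate_surveys`` -- per-survey binomial proportions with known
  logit-scale covariate effects and a survey-level random intercept.
* ``simulate_grids`` -- co-registered smooth non-negative fields (woody
  production <= total production everywhere) with an optional "hot
  corner" jointly high in woody share and richness, so the priority mask
  has a known answer.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from .effect_sizes import ComparisonRecord, Polarity
from .prioritize import GridLayer
from .surveys import SurveyRecord


@dataclasses.dataclass
class ModeratorSpec:
    """A categorical moderator: levels, sampling probabilities and the true
    additive shift each level applies to the standardized effect."""

    name: str
    levels: Sequence[str]
    shifts: Sequence[float]
    probs: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.shifts):
            raise ValueError("levels and shifts must have equal length")
        if self.probs is not None and not np.isclose(sum(self.probs), 1.0):
            raise ValueError("probs must sum to 1")


@dataclasses.dataclass
class EffectSimConfig:
    """Data-generating settings for nested effect-size data.

    Defaults mirror the exclosure corpus: ~40 studies with 1-6
    comparisons each (~158 comparisons), modest between-study spread, and
    field-trial replication of 2-30 plots per arm.
    """

    n_studies: int = 40
    comparisons_per_study: tuple[int, int] = (1, 6)
    true_mu: float = 0.4
    tau2_study: float = 0.04
    tau2_within: float = 0.02
    n_range: tuple[int, int] = (4, 30)
    moderators: Sequence[ModeratorSpec] = ()
    sd_log_scale: float = 0.3
    censor: bool = False
    censor_strength: float = 0.8
    censor_se_scale: float = 0.25
    polarity: Polarity = Polarity.GAIN
    baseline_mean: float = 10.0

    def __post_init__(self) -> None:
        if self.tau2_study < 0 or self.tau2_within < 0:
            raise ValueError("variance components must be >= 0")
        if not (0.0 <= self.censor_strength <= 1.0):
            raise ValueError("censor_strength must lie in [0, 1]")
        self.polarity = Polarity(self.polarity)


def simulate_effects(
    cfg: EffectSimConfig, seed: int | np.random.Generator = 0
) -> list[ComparisonRecord]:
    """Draw raw comparison records under the nested random-effects model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records: list[ComparisonRecord] = []
    study_effects = rng.normal(0.0, np.sqrt(cfg.tau2_study), cfg.n_studies)
    sign = -1.0 if cfg.polarity is Polarity.LOSS else 1.0
    for s in range(cfg.n_studies):
        n_comp = int(rng.integers(cfg.comparisons_per_study[0], cfg.comparisons_per_study[1] + 1))
        for c in range(n_comp):
            mods: dict[str, object] = {}
            shift = 0.0
            for m in cfg.moderators:
                probs = m.probs if m.probs is not None else [1.0 / len(m.levels)] * len(m.levels)
                j = int(rng.choice(len(m.levels), p=probs))
                mods[m.name] = m.levels[j]
                shift += m.shifts[j]
            theta = cfg.true_mu + study_effects[s] + rng.normal(0.0, np.sqrt(cfg.tau2_within)) + shift
            nt = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
            nc = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
            sigma_t = float(np.exp(rng.normal(0.0, cfg.sd_log_scale)))
            sigma_c = float(np.exp(rng.normal(0.0, cfg.sd_log_scale)))
            # population pooled SD at the drawn group sizes
            pooled = np.sqrt(((nt - 1) * sigma_t**2 + (nc - 1) * sigma_c**2) / (nt + nc - 2))
            mu_c = cfg.baseline_mean
            mu_t = mu_c + sign * theta * pooled
            mean_t = float(rng.normal(mu_t, sigma_t / np.sqrt(nt)))
            mean_c = float(rng.normal(mu_c, sigma_c / np.sqrt(nc)))
            sd_t = float(sigma_t * np.sqrt(rng.chisquare(nt - 1) / (nt - 1)))
            sd_c = float(sigma_c * np.sqrt(rng.chisquare(nc - 1) / (nc - 1)))
            if sd_t <= 0 or sd_c <= 0:  # pathologically small chi-square draw
                continue
            rec = ComparisonRecord(
                study_id=f"study{s + 1:03d}",
                comparison_id=f"c{c + 1}",
                mean_treatment=mean_t,
                mean_control=mean_c,
                sd_treatment=sd_t,
                sd_control=sd_c,
                n_treatment=nt,
                n_control=nc,
                outcome_polarity=cfg.polarity,
                moderators=mods,
            )
            if cfg.censor and _suppressed(rec, cfg, rng):
                continue
            records.append(rec)
    return records


def _suppressed(rec: ComparisonRecord, cfg: EffectSimConfig, rng: np.random.Generator) -> bool:
    """Publication-censoring rule: suppression probability increases with
    the standard error and decreases with the one-sided evidence z = g/se,
    mimicking small noisy studies only being published when their effect
    looks large."""
    from .effect_sizes import hedges_g

    es = hedges_g(rec)
    se = np.sqrt(es.v_g)
    z = es.g / se
    # published with certainty when one-sided significant; otherwise
    # suppression grows with the standard error (precise studies survive)
    p_suppress = (
        cfg.censor_strength
        * float(stats.norm.cdf(stats.norm.isf(0.05) - z))
        * float(1.0 - np.exp(-se / cfg.censor_se_scale))
    )
    return bool(rng.random() < p_suppress)


@dataclasses.dataclass
class SurveySimConfig:
    """Settings for survey proportion data; defaults mirror the attitude
    corpus (tens of surveys, hundreds of respondents each)."""

    n_surveys: int = 39
    respondents_range: tuple[int, int] = (50, 1500)
    intercept: float = 0.0
    coef: Mapping[str, Mapping[str, float]] = dataclasses.field(default_factory=dict)
    # e.g. {"income": {"low": 2.0}} -- shift on the logit scale vs the
    # reference level (lexicographically first)
    sigma_u: float = 0.5
    outcome_kind: str = "perceived_disservice"
    levels: Mapping[str, Sequence[str]] = dataclasses.field(
        default_factory=lambda: {
            "income": ["high", "low"],
            "bird_group": ["general", "granivore", "waterfowl"],
            "stakeholder": ["mixed", "rural", "urban"],
            "climate": ["nontropics", "tropics"],
        }
    )

    def __post_init__(self) -> None:
        if self.respondents_range[0] < 1:
            raise ValueError("respondents must be >= 1")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")


def simulate_surveys(
    cfg: SurveySimConfig, seed: int | np.random.Generator = 0
) -> list[SurveyRecord]:
    """Draw per-survey binomial proportions from the logit mixed model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    for i in range(cfg.n_surveys):
        covs = {name: str(rng.choice(list(levels))) for name, levels in cfg.levels.items()}
        eta = cfg.intercept + float(rng.normal(0.0, cfg.sigma_u))
        for name, val in covs.items():
            eta += float(cfg.coef.get(name, {}).get(val, 0.0))
        n = int(rng.integers(cfg.respondents_range[0], cfg.respondents_range[1] + 1))
        p = 1.0 / (1.0 + np.exp(-eta))
        successes = int(rng.binomial(n, p))
        records.append(
            SurveyRecord(
                survey_id=f"survey{i + 1:03d}",
                n_respondents=n,
                outcome_kind=cfg.outcome_kind,
                proportion=successes / n,
                **covs,
            )
        )
    return records


@dataclasses.dataclass
class GridSimConfig:
    """Settings for co-registered production/richness grids."""

    shape: tuple[int, int] = (40, 60)
    smoothness: float = 2.0
    hot_corner: tuple[int, int, int, int] | None = None  # (row0, row1, col0, col1)
    nodata_border: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] < 3 or self.shape[1] < 3:
            raise ValueError("grid shape must be at least 3x3")


def _smooth_positive(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.normal(size=shape), smoothness)
    return np.exp(field)  # log-normal: positive, spatially autocorrelated


def simulate_grids(
    cfg: GridSimConfig, seed: int | np.random.Generator = 0
) -> tuple[GridLayer, GridLayer, GridLayer, GridLayer]:
    """(woody, total, threatened_richness, total_richness) grid layers.

    Woody production is a smooth share of total production, so woody <=
    total everywhere.  If ``hot_corner`` is set, that block is forced into
    the joint top tercile of woody share and both richness layers.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = cfg.shape
    total = _smooth_positive(rng, shape, cfg.smoothness) * 100.0
    share_logit = ndimage.gaussian_filter(rng.normal(size=shape), cfg.smoothness) * 2.0
    richness = _smooth_positive(rng, shape, cfg.smoothness) * 50.0
    threatened_share = 1.0 / (1.0 + np.exp(-ndimage.gaussian_filter(rng.normal(size=shape), cfg.smoothness)))
    if cfg.hot_corner is not None:
        r0, r1, c0, c1 = cfg.hot_corner
        share_logit[r0:r1, c0:c1] = share_logit.max() + 3.0
        richness[r0:r1, c0:c1] = richness.max() * 2.0
        threatened_share[r0:r1, c0:c1] = 0.95
    share = 1.0 / (1.0 + np.exp(-share_logit))
    woody = total * share
    threatened = richness * threatened_share
    mask = np.zeros(shape, dtype=bool)
    if cfg.nodata_border > 0:
        b = cfg.nodata_border
        mask[:b, :] = mask[-b:, :] = mask[:, :b] = mask[:, -b:] = True
    make = lambda v: GridLayer(v.copy(), mask=mask.copy(), origin=(0.0, 0.0), cellsize=1.0)
    return make(woody), make(total), make(threatened), make(richness)
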