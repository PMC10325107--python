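"""Bias-corrected standardized mean differences (Hedges' g).

The meta-analytic unit is one treatment/control contrast from a field
experiment: an exclosure comparison (open plot = birds present = treatment)
or a crop-loss mitigation trial (measure applied = treatment).  Because
crop production and crop loss are reported in incommensurable units, every
contrast is reduced to a unitless standardized mean difference.

Conventions
-----------
* Cohen's d is the mean difference divided by the pooled within-group
  standard deviation (``(n-1)``-weighted sums of squares, divisor
  ``n_t + n_c - 2``).
* Hedges' correction ``J = 1 - 3 / (4 * df - 1)`` with ``df = n_t + n_c - 2``
  removes the small-sample bias; ``g = J * d`` and ``v_g = J**2 * v_d``.
* After computation, effects measured on a loss scale (e.g. "50% loss vs
  30% loss") are sign-flipped so that positive ``g`` always means "birds
  increase production" (exclosure data) or "the measure reduces loss"
  (mitigation data).
"""

from __future__ import annotations

import dataclasses
import math
from enum import Enum
from typing import Any, Mapping


class Polarity(str, Enum):
    """Direction in which the raw outcome was measured."""

    GAIN = "gain"  # larger value = more production
    LOSS = "loss"  # larger value = more damage/loss


class UndefinedEffectError(ValueError):
    """Raised when an effect size or its variance is not defined."""


@dataclasses.dataclass(frozen=True)
class ComparisonRecord:
    """One treatment/control experimental contrast with summary statistics.

    ``moderators`` carries the categorical/numeric covariates used by the
    moderator models (stem_type, food_type, climate, insecticide, herbicide,
    focal_animal, crop, stage, category, measure, regional_richness, ...).
    """

    study_id: str
    comparison_id: str
    mean_treatment: float
    mean_control: float
    sd_treatment: float
    sd_control: float
    n_treatment: int
    n_control: int
    outcome_polarity: Polarity = Polarity.GAIN
    moderators: Mapping[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_treatment < 2 or self.n_control < 2:
            raise ValueError(
                f"{self.study_id}/{self.comparison_id}: group sizes must be >= 2 "
                f"(got n_treatment={self.n_treatment}, n_control={self.n_control})"
            )
        if not (self.sd_treatment > 0.0) or not (self.sd_control > 0.0):
            raise ValueError(
                f"{self.study_id}/{self.comparison_id}: standard deviations must be "
                f"strictly positive (got {self.sd_treatment}, {self.sd_control})"
            )
        object.__setattr__(self, "outcome_polarity", Polarity(self.outcome_polarity))


@dataclasses.dataclass(frozen=True)
class EffectSize:
    """Hedges' g with its sampling variance, sign-aligned.

    Positive g = birds increase production / the measure reduces loss.
    """

    g: float
    v_g: float
    study_id: str
    comparison_id: str
    moderators: Mapping[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.g):
            raise ValueError("g must be finite")
        if not (self.v_g > 0.0):
            raise ValueError("v_g must be strictly positive")

    @property
    def se(self) -> float:
        return math.sqrt(self.v_g)


def pooled_sd(rec: ComparisonRecord) -> float:
    """Pooled within-group standard deviation of a contrast."""
    nt, nc = rec.n_treatment, rec.n_control
    num = (nt - 1) * rec.sd_treatment**2 + (nc - 1) * rec.sd_control**2
    return math.sqrt(num / (nt + nc - 2))


def cohen_d(rec: ComparisonRecord) -> tuple[float, float]:
    """Cohen's d and its sampling variance for one contrast.

    Raises :class:`UndefinedEffectError` when the pooled SD is zero; with a
    zero pooled SD the sampling variance is undefined even if the means are
    equal, so d = 0 is *not* returned in that case.
    """
    sd_within = pooled_sd(rec)
    if sd_within == 0.0:
        raise UndefinedEffectError(
            f"{rec.study_id}/{rec.comparison_id}: pooled SD is zero; "
            "the standardized effect and its variance are undefined"
        )
    nt, nc = rec.n_treatment, rec.n_control
    d = (rec.mean_treatment - rec.mean_control) / sd_within
    v_d = (nc + nt) / (nc * nt) + d**2 / (2.0 * (nc + nt))
    return d, v_d


def hedges_correction(n_treatment: int, n_control: int) -> float:
    """Small-sample bias-correction factor J in (0, 1).

    J = 1 - 3/(4*df - 1) with df = n_treatment + n_control - 2.
    """
    df = n_treatment + n_control - 2
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1 (got {df})")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def align_direction(es: EffectSize, polarity: Polarity | str) -> EffectSize:
    """Flip the sign of g for loss-scale outcomes; v_g is unchanged.

    An involution: applying the flip twice returns the original effect.
    """
    polarity = Polarity(polarity)
    if polarity is Polarity.GAIN:
        return es
    return dataclasses.replace(es, g=-es.g)


def hedges_g(rec: ComparisonRecord) -> EffectSize:
    """Bias-corrected Hedges' g for one contrast, direction-aligned.

    g = J*d and v_g = J^2 * v_d, then the sign is aligned so positive g is
    "favourable" regardless of whether the outcome was a gain or a loss.
    """
    d, v_d = cohen_d(rec)
    j = hedges_correction(rec.n_treatment, rec.n_control)
    es = EffectSize(
        g=j * d,
        v_g=j * j * v_d,
        study_id=rec.study_id,
        comparison_id=rec.comparison_id,
        moderators=dict(rec.moderators),
    )
    return align_direction(es, rec.outcome_polarity)


def g_from_convertible(
    stat_kind: str,
    values: Mapping[str, float],
    n_treatment: int,
    n_control: int,
    *,
    polarity: Polarity | str = Polarity.GAIN,
    study_id: str = "",
    comparison_id: str = "",
    moderators: Mapping[str, Any] | None = None,
) -> EffectSize:
    """Hedges' g from convertible statistics instead of raw summaries.

    Supported kinds:

    ``t_stat``
        ``values`` holds ``t``, the two-sample t statistic;
        d = t * sqrt(1/n_t + 1/n_c).
    ``mean_se``
        ``values`` holds ``mean_treatment``, ``mean_control``,
        ``se_treatment``, ``se_control``; each SE is converted to an SD via
        SD = SE * sqrt(n) and the record is then processed as raw summaries.
    """
    nt, nc = int(n_treatment), int(n_control)
    if stat_kind == "t_stat":
        t = float(values["t"])
        d = t * math.sqrt(1.0 / nt + 1.0 / nc)
        v_d = (nc + nt) / (nc * nt) + d**2 / (2.0 * (nc + nt))
        j = hedges_correction(nt, nc)
        es = EffectSize(
            g=j * d,
            v_g=j * j * v_d,
            study_id=study_id,
            comparison_id=comparison_id,
            moderators=dict(moderators or {}),
        )
        return align_direction(es, polarity)
    if stat_kind == "mean_se":
        rec = ComparisonRecord(
            study_id=study_id,
            comparison_id=comparison_id,
            mean_treatment=float(values["mean_treatment"]),
            mean_control=float(values["mean_control"]),
            sd_treatment=float(values["se_treatment"]) * math.sqrt(nt),
            sd_control=float(values["se_control"]) * math.sqrt(nc),
            n_treatment=nt,
            n_control=nc,
            outcome_polarity=Polarity(polarity),
            moderators=dict(moderators or {}),
        )
        return hedges_g(rec)
    raise ValueError(
        f"unsupported stat_kind {stat_kind!r}; supported kinds: 't_stat', 'mean_se'"
    )


def compute_effects(records: list[ComparisonRecord]) -> list[EffectSize]:
    """Vector convenience: Hedges' g for every record, in order."""
    return [hedges_g(rec) for rec in records]
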