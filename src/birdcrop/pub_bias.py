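"""Publication-bias diagnostics and sensitivity analysis.

Implements the classic funnel-plot toolkit for a set of effect sizes:
funnel data export, Rosenthal's fail-safe number, the Begg/Kendall rank
correlation between standardized effects and their sampling variances, an
Egger-type weighted regression of effects on their standard errors, and
Duval-Tweedie trim-and-fill with the L0 estimator.

Following the convention of the standard meta-analytic toolchain, the
regression test and
trim-and-fill operate on a *single-level* random-effects model (the
multilevel study structure is collapsed); the Kendall test and fail-safe
number are model-free.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Literal

import numpy as np
from scipy import stats

from .meta_model import MetaDataset, MetaFit, ModelSpec, fit_multilevel

_ONE_SIDED_Z05 = stats.norm.isf(0.05)  # 1.6449, Rosenthal's one-sided alpha


@dataclasses.dataclass
class BiasReport:
    failsafe_n: int
    failsafe_threshold: int
    failsafe_robust: bool
    kendall_tau: float
    kendall_p: float
    egger_slope: float
    egger_p: float
    trimfill_k0: int
    trimfill_side: str
    adjusted_fit: MetaFit | None

    def summary(self) -> dict:
        return {
            "failsafe_n": self.failsafe_n,
            "failsafe_threshold": self.failsafe_threshold,
            "failsafe_robust": self.failsafe_robust,
            "kendall_tau": self.kendall_tau,
            "kendall_p": self.kendall_p,
            "egger_slope": self.egger_slope,
            "egger_p": self.egger_p,
            "trimfill_k0": self.trimfill_k0,
            "trimfill_side": self.trimfill_side,
            "adjusted_mu": None if self.adjusted_fit is None else self.adjusted_fit.mu,
            "adjusted_ci": None
            if self.adjusted_fit is None
            else [float(self.adjusted_fit.ci_low[0]), float(self.adjusted_fit.ci_high[0])],
        }


def funnel_data(data: MetaDataset) -> list[dict]:
    """(g, se) pairs for a funnel plot; data export only, no rendering."""
    return [
        {"study_id": e.study_id, "comparison_id": e.comparison_id,
         "g": e.g, "se": math.sqrt(e.v_g)}
        for e in data.effects
    ]


def failsafe_rosenthal(data: MetaDataset, alpha: float = 0.05) -> tuple[int, int, bool]:
    """Rosenthal's fail-safe number with the 5k+10 robustness threshold.

    N = max(0, floor((sum Z_i)^2 / z_alpha^2 - k)) with Z_i = g_i/se_i and a
    one-sided alpha; the combined result is called robust when N > 5k + 10.
    """
    if data.k < 2:
        raise ValueError("fail-safe number needs k >= 2")
    z = data.g() / np.sqrt(data.v())
    z_alpha = stats.norm.isf(alpha)
    n = max(0, math.floor(float(np.sum(z)) ** 2 / z_alpha**2 - data.k))
    threshold = 5 * data.k + 10
    return n, threshold, n > threshold


def _standardized_deviates(g: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Effects centered at the fixed-effect mean and standardized, the usual
    rank-test transform: (g_i - mu_fe)/sqrt(v_i - 1/sum w)."""
    w = 1.0 / v
    mu_fe = float(np.sum(w * g) / np.sum(w))
    var_star = v - 1.0 / np.sum(w)
    var_star = np.maximum(var_star, 1e-12)
    return (g - mu_fe) / np.sqrt(var_star)


def _kendall_tau_b(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Tau-b and the raw concordant-discordant difference S."""
    n = len(x)
    s = 0
    for i, j in itertools.combinations(range(n), 2):
        s += int(np.sign(x[i] - x[j]) * np.sign(y[i] - y[j]))
    tx = sum(c * (c - 1) // 2 for c in np.unique(x, return_counts=True)[1])
    ty = sum(c * (c - 1) // 2 for c in np.unique(y, return_counts=True)[1])
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    if denom == 0:
        raise ValueError("no rank variation in one of the variables")
    return s / denom, s


def _inversion_counts(n: int) -> np.ndarray:
    """Number of permutations of n items with 0..n(n-1)/2 inversions
    (Mahonian numbers), by polynomial convolution."""
    counts = np.array([1.0])
    for i in range(2, n + 1):
        counts = np.convolve(counts, np.ones(i))
    return counts


def _exact_kendall_p(x: np.ndarray, y: np.ndarray, s_obs: float) -> float:
    """Exact two-sided permutation p for the concordance statistic S.

    Tie-free inputs use the closed permutation distribution of the
    inversion count; tied inputs fall back to full (vectorized) enumeration
    of permutations, feasible for the small k this branch serves.
    """
    n = len(x)
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    n0 = n * (n - 1) // 2
    if not has_ties:
        counts = _inversion_counts(n)  # index = discordant pairs D; S = n0 - 2D
        s_vals = n0 - 2 * np.arange(len(counts))
        return float(np.sum(counts[np.abs(s_vals) >= abs(s_obs) - 1e-9]) / counts.sum())
    pairs = list(itertools.combinations(range(n), 2))
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    sgn_x = np.sign(x[ii] - x[jj])
    sgn_y_mat = np.sign(y[:, None] - y[None, :])
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int8)
    s = (sgn_x[None, :] * sgn_y_mat[perms[:, ii], perms[:, jj]]).sum(axis=1)
    return float(np.mean(np.abs(s) >= abs(s_obs) - 1e-9))


def kendall_bias_test(
    data: MetaDataset, *, rank_by: Literal["variance", "n"] = "variance",
    exact_max_k: int = 10,
) -> tuple[float, float]:
    """Begg-type rank correlation between standardized effects and their
    sampling variances (a monotone surrogate for sample size).

    Exact permutation p for k <= ``exact_max_k``; otherwise the normal
    approximation with tie correction.
    """
    if data.k < 3:
        raise ValueError("rank correlation test needs k >= 3")
    g, v = data.g(), data.v()
    ystar = _standardized_deviates(g, v)
    surrogate = v if rank_by == "variance" else -v
    if np.all(ystar == ystar[0]) or np.all(surrogate == surrogate[0]):
        raise ValueError("no rank variation")
    tau, s_obs = _kendall_tau_b(ystar, surrogate)
    has_ties = len(np.unique(ystar)) < data.k or len(np.unique(surrogate)) < data.k
    if data.k <= exact_max_k and (not has_ties or data.k <= 8):
        p = _exact_kendall_p(ystar, surrogate, s_obs)
    else:
        n = data.k
        # normal approximation for S with tie correction (tau-b flavour)
        tx_counts = np.unique(ystar, return_counts=True)[1]
        ty_counts = np.unique(surrogate, return_counts=True)[1]

        def _v0(counts):
            return sum(c * (c - 1) * (2 * c + 5) for c in counts)

        var_s = (
            n * (n - 1) * (2 * n + 5) - _v0(tx_counts) - _v0(ty_counts)
        ) / 18.0
        var_s += (
            sum(c * (c - 1) * (c - 2) for c in tx_counts)
            * sum(c * (c - 1) * (c - 2) for c in ty_counts)
        ) / (9.0 * n * (n - 1) * (n - 2))
        var_s += (
            sum(c * (c - 1) for c in tx_counts) * sum(c * (c - 1) for c in ty_counts)
        ) / (2.0 * n * (n - 1))
        z = s_obs / math.sqrt(var_s) if var_s > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
    return float(tau), float(min(1.0, p))


def egger_regression_test(data: MetaDataset) -> tuple[float, float]:
    """Egger-type test: single-level random-effects meta-regression of g on
    its standard error; returns the se coefficient and its Wald p."""
    if data.k < 3:
        raise ValueError("regression test needs k >= 3")
    se = np.sqrt(data.v())
    if np.allclose(se, se[0]):
        raise ValueError("regression test degenerate: all standard errors equal")
    effects = [
        dataclasses.replace(e, moderators={**dict(e.moderators), "_se_": float(s)})
        for e, s in zip(data.effects, se)
    ]
    fit = fit_multilevel(
        MetaDataset(effects),
        ModelSpec(moderators=["_se_"], random_structure="none"),
    )
    i = fit.coef_names.index("_se_")
    return float(fit.beta[i]), float(fit.p[i])


def _re_fit(g: np.ndarray, v: np.ndarray) -> MetaFit:
    """Single-level random-effects fit on raw arrays."""
    from .effect_sizes import EffectSize

    effects = [
        EffectSize(g=float(gi), v_g=float(vi), study_id=f"s{i}", comparison_id="c")
        for i, (gi, vi) in enumerate(zip(g, v))
    ]
    return fit_multilevel(MetaDataset(effects), ModelSpec(random_structure="none"))


def trim_and_fill(
    data: MetaDataset,
    *,
    side: Literal["auto", "left", "right"] = "auto",
    max_iter: int = 50,
) -> tuple[int, MetaDataset, MetaFit]:
    """Duval-Tweedie trim-and-fill with the L0 estimator.

    ``side`` is the funnel side on which studies are presumed missing;
    ``auto`` chooses by the sign of the Begg rank-correlation statistic
    (positive correlation between effect and variance = excess of large
    effects on the right = studies missing on the left, and vice versa).
    Missing effects are imputed by mirroring the k0 most extreme observed
    effects about the trimmed centre; the adjusted fit is a single-level
    random-effects model on the augmented set.
    """
    if data.k < 3:
        raise ValueError("trim-and-fill needs k >= 3")
    g, v = data.g(), data.v()

    if side == "auto":
        try:
            tau, _ = _kendall_tau_b(_standardized_deviates(g, v), v)
            stat = tau
        except ValueError:
            # equal variances: no rank signal, fall back to funnel skewness
            # (a truncated left tail leaves a right-skewed funnel)
            stat = float(stats.skew(g))
        side = "left" if stat >= 0 else "right"

    # reduce to the canonical case: studies missing on the LEFT
    # (excess of unmatched extreme effects on the right -> trim from right)
    flip = side == "right"
    y = -g if flip else g

    k = len(y)
    order = np.argsort(y)
    y_sorted, v_sorted = y[order], v[order]

    k0 = 0
    for _ in range(max_iter):
        trimmed = slice(0, k - k0) if k0 > 0 else slice(0, k)
        mu = _re_fit(y_sorted[trimmed], v_sorted[trimmed]).mu
        d = y_sorted - mu
        ad = np.abs(d)
        # quantize so exactly mirrored effects tie despite roundoff
        tol = 1e-8 * max(float(ad.max()), 1e-12)
        ranks = stats.rankdata(np.round(ad / tol) * tol)
        t_n = float(np.sum(ranks[d > 0]))
        l0 = (4.0 * t_n - k * (k + 1)) / (2.0 * k - 1.0)
        k0_new = max(0, int(round(l0)))
        k0_new = min(k0_new, k - 2)  # keep at least 2 effects in the trimmed set
        if k0_new == k0:
            break
        k0 = k0_new
    else:
        raise RuntimeError(
            f"trim-and-fill did not converge after {max_iter} iterations (last k0={k0})"
        )

    if k0 > 0:
        mu = _re_fit(y_sorted[: k - k0], v_sorted[: k - k0]).mu
        y_fill = 2.0 * mu - y_sorted[k - k0 :]
        v_fill = v_sorted[k - k0 :]
        y_aug = np.r_[y, y_fill]
        v_aug = np.r_[v, v_fill]
    else:
        y_aug, v_aug = y, v

    g_aug = -y_aug if flip else y_aug

    from .effect_sizes import EffectSize

    effects = list(data.effects) + [
        EffectSize(
            g=float(gi), v_g=float(vi),
            study_id=f"__filled_{i}", comparison_id="fill",
            moderators={"filled": True},
        )
        for i, (gi, vi) in enumerate(zip(g_aug[k:], v_aug[k:]))
    ]
    augmented = MetaDataset(effects)
    adjusted = _re_fit(g_aug, v_aug)
    return k0, augmented, adjusted


def bias_report(
    data: MetaDataset,
    *,
    trimfill_side: Literal["auto", "left", "right"] = "auto",
) -> BiasReport:
    """Run the full diagnostic suite on one dataset."""
    n, threshold, robust = failsafe_rosenthal(data)
    tau, tau_p = kendall_bias_test(data)
    try:
        slope, egger_p = egger_regression_test(data)
    except ValueError:
        slope, egger_p = float("nan"), float("nan")
    if trimfill_side == "auto":
        resolved_side = "left" if tau >= 0 else "right"
    else:
        resolved_side = trimfill_side
    k0, _, adjusted = trim_and_fill(data, side=resolved_side)
    return BiasReport(
        failsafe_n=n,
        failsafe_threshold=threshold,
        failsafe_robust=robust,
        kendall_tau=tau,
        kendall_p=tau_p,
        egger_slope=slope,
        egger_p=egger_p,
        trimfill_k0=k0,
        trimfill_side=resolved_side,
        adjusted_fit=adjusted,
    )
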