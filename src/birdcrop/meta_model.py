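"""Multilevel random-effects meta-analysis fitted by REML.

The model for k sign-aligned effect sizes g_i with known sampling
variances v_i, grouped into studies s(i) (several comparisons may come
from the same study), is

    g_i = x_i' beta + u_{s(i)} + w_i + e_i,
    u_s ~ N(0, tau2_study),  w_i ~ N(0, tau2_within),  e_i ~ N(0, v_i),

i.e. a random intercept for study and for comparison-within-study.  The
marginal covariance is block diagonal over studies,

    V = diag(v_i + tau2_within) + tau2_study * 1 1'   (within each study),

so each effect is weighted by the inverse of its within-study plus
between-study variance.  Variance components are estimated by restricted
maximum likelihood with a non-negativity constraint; coefficients are the
GLS estimates at the REML variances, with normal (Wald) 95% intervals.

When every study contributes a single comparison the within-study
component is not identified and is dropped automatically.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .effect_sizes import EffectSize

_Z975 = 1.959963984540054


class RankDeficientError(ValueError):
    """Moderator design matrix is not full rank."""


@dataclasses.dataclass
class MetaDataset:
    """Effect sizes plus their study grouping."""

    effects: list[EffectSize]

    def __post_init__(self) -> None:
        if any(not (e.v_g > 0) for e in self.effects):
            raise ValueError("every effect must have v_g > 0")

    @property
    def k(self) -> int:
        return len(self.effects)

    @property
    def grouping(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for e in self.effects:
            out.setdefault(e.study_id, set()).add(e.comparison_id)
        return out

    def g(self) -> np.ndarray:
        return np.array([e.g for e in self.effects], dtype=float)

    def v(self) -> np.ndarray:
        return np.array([e.v_g for e in self.effects], dtype=float)

    def study_index(self) -> np.ndarray:
        labels = {s: j for j, s in enumerate(dict.fromkeys(e.study_id for e in self.effects))}
        return np.array([labels[e.study_id] for e in self.effects], dtype=int)

    def moderator(self, name: str) -> list:
        return [e.moderators.get(name) for e in self.effects]

    def subset(self, mask: Sequence[bool]) -> "MetaDataset":
        return MetaDataset([e for e, m in zip(self.effects, mask) if m])


@dataclasses.dataclass
class ModelSpec:
    """Which moderators enter the mean model and which random levels to use.

    ``random_structure`` is "study/comparison" (nested intercepts, the
    default), "study" (between-study only) or "none" (single-level
    random-effects model: one heterogeneity component shared by all
    comparisons, ignoring the study grouping).
    """

    moderators: list[str] = dataclasses.field(default_factory=list)
    random_structure: str = "study/comparison"
    intercept: bool = True

    def __post_init__(self) -> None:
        if self.random_structure not in ("study/comparison", "study", "none"):
            raise ValueError(f"unknown random structure {self.random_structure!r}")


@dataclasses.dataclass
class MetaFit:
    """A fitted multilevel random-effects model."""

    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    z: np.ndarray
    p: np.ndarray
    coef_names: list[str]
    cov_beta: np.ndarray
    tau2_study: float
    tau2_within: float
    k: int
    n_studies: int
    loglik_reml: float
    QE: float
    QE_df: int
    QE_p: float
    QM: float | None = None
    QM_df: int | None = None
    QM_p: float | None = None

    @property
    def mu(self) -> float:
        """Pooled estimate (first coefficient; the intercept-only pooled mean)."""
        return float(self.beta[0])

    @property
    def tau2_total(self) -> float:
        return self.tau2_study + self.tau2_within

    def summary(self) -> dict:
        return {
            "k": self.k,
            "n_studies": self.n_studies,
            "coefficients": [
                {
                    "name": n,
                    "estimate": float(b),
                    "se": float(s),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "z": float(z),
                    "p": float(p),
                }
                for n, b, s, lo, hi, z, p in zip(
                    self.coef_names, self.beta, self.se, self.ci_low,
                    self.ci_high, self.z, self.p,
                )
            ],
            "tau2_study": self.tau2_study,
            "tau2_within": self.tau2_within,
            "loglik_reml": self.loglik_reml,
            "QE": self.QE, "QE_df": self.QE_df, "QE_p": self.QE_p,
            "QM": self.QM, "QM_df": self.QM_df, "QM_p": self.QM_p,
        }


# ---------------------------------------------------------------------------
# linear algebra on the block-diagonal marginal covariance


def _sorted_blocks(study: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stable sort order by study plus reduceat offsets for the sorted array."""
    order = np.argsort(study, kind="stable")
    s = study[order]
    starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
    return order, starts


class _REMLProblem:
    """REML criterion and GLS solves for V = diag(v + tw) + ts * J_study."""

    def __init__(self, g: np.ndarray, v: np.ndarray, X: np.ndarray, study: np.ndarray):
        order, starts = _sorted_blocks(study)
        self.g = g[order]
        self.v = v[order]
        self.X = X[order]
        self.starts = starts
        self.block_of = np.repeat(
            np.arange(len(starts)), np.diff(np.r_[starts, len(self.g)])
        )
        self.k, self.p = self.X.shape
        # constant term so the criterion matches the usual REML likelihood
        # (which includes +0.5 log|X'X|)
        self.half_logdet_xtx = 0.5 * np.linalg.slogdet(self.X.T @ self.X)[1]

    def _vinv_apply(self, M: np.ndarray, ts: float, tw: float) -> np.ndarray:
        """V^{-1} M column-wise via Sherman-Morrison per study block."""
        d = self.v + tw
        Dinv_M = M / d[:, None]
        if ts == 0.0:
            return Dinv_M
        sinv = np.add.reduceat(1.0 / d, self.starts)  # 1' D^-1 1 per block
        colsum = np.add.reduceat(Dinv_M, self.starts, axis=0)  # 1' D^-1 M
        denom = 1.0 + ts * sinv
        adj = (ts * colsum / denom[:, None])[self.block_of]
        return Dinv_M - adj / d[:, None]

    def _logdet_v(self, ts: float, tw: float) -> float:
        d = self.v + tw
        out = float(np.sum(np.log(d)))
        if ts > 0.0:
            sinv = np.add.reduceat(1.0 / d, self.starts)
            out += float(np.sum(np.log1p(ts * sinv)))
        return out

    def gls(self, ts: float, tw: float):
        """GLS coefficients, their covariance and residuals at (ts, tw)."""
        Vinv_X = self._vinv_apply(self.X, ts, tw)
        XtVinvX = self.X.T @ Vinv_X
        Vinv_g = self._vinv_apply(self.g[:, None], ts, tw)[:, 0]
        beta = np.linalg.solve(XtVinvX, self.X.T @ Vinv_g)
        resid = self.g - self.X @ beta
        return beta, XtVinvX, resid

    def reml_loglik(self, ts: float, tw: float) -> float:
        ts = max(float(ts), 0.0)
        tw = max(float(tw), 0.0)
        beta, XtVinvX, resid = self.gls(ts, tw)
        Vinv_r = self._vinv_apply(resid[:, None], ts, tw)[:, 0]
        quad = float(resid @ Vinv_r)
        sign, logdet_xvx = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            return -np.inf
        return self.half_logdet_xtx - 0.5 * (
            (self.k - self.p) * math.log(2.0 * math.pi)
            + self._logdet_v(ts, tw)
            + logdet_xvx
            + quad
        )


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR-ish greedy scan
        aliased = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            cand = X[:, keep + [j]]
            if np.linalg.matrix_rank(cand) == len(keep) + 1:
                keep.append(j)
            else:
                aliased.append(names[j])
        raise RankDeficientError(f"moderator design is rank deficient; aliased columns: {aliased}")


def build_design(
    data: MetaDataset, spec: ModelSpec
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix for the moderator formula (dummy coding, lexicographic
    reference level), plus a keep-mask after listwise deletion of missing
    moderator values."""
    k = data.k
    keep = np.ones(k, dtype=bool)
    columns: list[tuple[str, np.ndarray]] = []
    for name in spec.moderators:
        vals = data.moderator(name)
        missing = np.array([v is None or (isinstance(v, float) and math.isnan(v)) for v in vals])
        keep &= ~missing
        if all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in vals if v is not None):
            col = np.array([float(v) if v is not None else np.nan for v in vals])
            columns.append((name, col))
        else:
            levels = sorted({str(v) for v, m in zip(vals, missing) if not m})
            ref = levels[0] if spec.intercept else None
            for lev in levels:
                if spec.intercept and lev == ref:
                    continue
                col = np.array([1.0 if str(v) == lev else 0.0 for v in vals])
                columns.append((f"{name}[{lev}]", col))
    n_drop = int(np.sum(~keep))
    if n_drop:
        warnings.warn(
            f"{n_drop} effect(s) dropped listwise for missing moderator values", stacklevel=2
        )
    cols = [c[keep] for _, c in columns]
    names = [n for n, _ in columns]
    if spec.intercept:
        cols = [np.ones(int(keep.sum()))] + cols
        names = ["intercept"] + names
    X = np.column_stack(cols) if cols else np.ones((int(keep.sum()), 1))
    return X, names, keep


def fit_multilevel(
    data: MetaDataset,
    spec: ModelSpec | None = None,
    *,
    tol: float = 1e-8,
) -> MetaFit:
    """Fit the multilevel random-effects model by REML.

    Variance components are profiled numerically (L-BFGS-B with
    non-negativity bounds, several starting points) on the restricted
    log-likelihood; coefficients are GLS at the optimum.
    """
    spec = spec or ModelSpec()
    if data.k < 2:
        raise ValueError("need at least k=2 effects to fit a model")
    X_full, names, keep = build_design(data, spec)
    sub = data.subset(keep) if not keep.all() else data
    g, v = sub.g(), sub.v()
    _check_full_rank(X_full, names)
    if X_full.shape[0] <= X_full.shape[1]:
        raise ValueError("fewer effects than coefficients after listwise deletion")

    if spec.random_structure == "none":
        study = np.arange(sub.k)  # every comparison its own cluster
        two_comp = False
    else:
        study = sub.study_index()
        multi = np.any(np.bincount(study) > 1)
        two_comp = spec.random_structure == "study/comparison" and multi

    prob = _REMLProblem(g, v, X_full, study)

    var_g = float(np.var(g)) if sub.k > 1 else 0.1
    scale = max(var_g, float(np.mean(v)), 1e-4)

    def neg(theta: np.ndarray) -> float:
        if two_comp:
            return -prob.reml_loglik(theta[0], theta[1])
        return -prob.reml_loglik(theta[0], 0.0)

    nparam = 2 if two_comp else 1
    starts = [
        np.full(nparam, scale / (nparam + 1)),
        np.full(nparam, 1e-3 * scale),
        np.full(nparam, 2.0 * scale),
    ]
    if nparam == 2:
        starts += [np.array([scale, 1e-6]), np.array([1e-6, scale])]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg, x0, method="L-BFGS-B",
            bounds=[(0.0, None)] * nparam,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("REML optimization did not converge")
    ts = float(best.x[0])
    tw = float(best.x[1]) if two_comp else 0.0

    beta, XtVinvX, resid = prob.gls(ts, tw)
    cov = np.linalg.inv(XtVinvX)
    se = np.sqrt(np.diag(cov))
    zval = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))

    qe, qe_df, qe_p = _q_residual(g, v, X_full)

    qm = qm_df = qm_p = None
    nonint = [i for i, n in enumerate(names) if n != "intercept"]
    if nonint:
        b = beta[nonint]
        C = cov[np.ix_(nonint, nonint)]
        qm = float(b @ np.linalg.solve(C, b))
        qm_df = len(nonint)
        qm_p = float(stats.chi2.sf(qm, qm_df))

    return MetaFit(
        beta=beta,
        se=se,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        z=zval,
        p=pval,
        coef_names=names,
        cov_beta=cov,
        tau2_study=ts,
        tau2_within=tw,
        k=sub.k,
        n_studies=len(set(e.study_id for e in sub.effects)),
        loglik_reml=float(-best.fun),
        QE=qe, QE_df=qe_df, QE_p=qe_p,
        QM=qm, QM_df=qm_df, QM_p=qm_p,
    )


def _q_residual(g: np.ndarray, v: np.ndarray, X: np.ndarray) -> tuple[float, int, float]:
    """Residual heterogeneity Q at fixed-effects weights w = 1/v."""
    w = 1.0 / v
    WX = X * w[:, None]
    beta_fe = np.linalg.solve(X.T @ WX, WX.T @ g)
    resid = g - X @ beta_fe
    qe = float(np.sum(w * resid**2))
    df = len(g) - X.shape[1]
    p = float(stats.chi2.sf(qe, df)) if df > 0 else float("nan")
    return qe, df, p


def q_test(data: MetaDataset, spec: ModelSpec | None = None) -> tuple[float, int, float]:
    """Chi-square test of residual heterogeneity among comparisons.

    QE = sum_i w_i (g_i - x_i' beta_fe)^2 with fixed-effects weights
    w_i = 1/v_i at the fixed-effect projection; df = k - p.
    """
    spec = spec or ModelSpec()
    X, names, keep = build_design(data, spec)
    sub = data.subset(keep) if not keep.all() else data
    if sub.k <= X.shape[1]:
        raise ValueError("k must exceed the number of coefficients for a Q test")
    return _q_residual(sub.g(), sub.v(), X)


def moderator_test(data: MetaDataset, spec: ModelSpec) -> tuple[float, int, float]:
    """Omnibus Wald chi-square (QM) on all non-intercept coefficients."""
    if not spec.moderators:
        raise ValueError("moderator_test requires at least one moderator in the spec")
    fit = fit_multilevel(data, spec)
    assert fit.QM is not None
    return fit.QM, fit.QM_df, fit.QM_p


@dataclasses.dataclass
class SubgroupEstimate:
    mu: float
    ci_low: float
    ci_high: float
    se: float
    p: float
    k: int


def subgroup_estimates(
    data: MetaDataset,
    moderator_name: str,
    *,
    random_structure: str = "study/comparison",
    order: Sequence[str] | None = None,
) -> dict[str, SubgroupEstimate]:
    """One pooled estimate per moderator level (indicator design, no
    intercept) from a single multilevel fit; empty levels are omitted with a
    warning.  Levels are ordered lexicographically unless ``order`` is given."""
    vals = data.moderator(moderator_name)
    present = [v for v in vals if v is not None]
    levels = sorted({str(v) for v in present})
    if order is not None:
        missing_req = [lev for lev in order if lev not in levels]
        for lev in missing_req:
            warnings.warn(f"subgroup level {lev!r} has no effects; omitted", stacklevel=2)
        levels = [lev for lev in order if lev in levels]
    spec = ModelSpec(
        moderators=[moderator_name], random_structure=random_structure, intercept=False
    )
    fit = fit_multilevel(data, spec)
    counts = {lev: sum(1 for v in vals if v is not None and str(v) == lev) for lev in levels}
    out: dict[str, SubgroupEstimate] = {}
    for lev in levels:
        name = f"{moderator_name}[{lev}]"
        i = fit.coef_names.index(name)
        out[lev] = SubgroupEstimate(
            mu=float(fit.beta[i]),
            ci_low=float(fit.ci_low[i]),
            ci_high=float(fit.ci_high[i]),
            se=float(fit.se[i]),
            p=float(fit.p[i]),
            k=counts[lev],
        )
    return out


def forest_summary(fit: MetaFit, data: MetaDataset) -> list[dict]:
    """Per-effect rows (g, 95% CI from sqrt(v_g)) plus the overall row."""
    rows = []
    for e in data.effects:
        se = math.sqrt(e.v_g)
        rows.append(
            {
                "study_id": e.study_id,
                "comparison_id": e.comparison_id,
                "g": e.g,
                "ci_low": e.g - _Z975 * se,
                "ci_high": e.g + _Z975 * se,
                "kind": "effect",
            }
        )
    rows.append(
        {
            "study_id": "",
            "comparison_id": "overall",
            "g": fit.mu,
            "ci_low": float(fit.ci_low[0]),
            "ci_high": float(fit.ci_high[0]),
            "kind": "overall",
        }
    )
    return rows
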