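"""Social-survey analysis: proportions, binomial mixed models, AICc averaging.

Each survey contributes one observation: the proportion of respondents
giving a particular answer (positive attitude toward birds, perceived
crop service/disservice) together with the number of respondents and
survey-level covariates (country income class, focal bird group,
stakeholder group, climatic region).  Proportions are converted back to
success counts (e.g. 80% of 100 respondents = 80 successes) and modelled
with a logit-link binomial GLMM with a survey-level Gaussian random
intercept, which absorbs the extra-binomial heterogeneity between surveys.

Model selection is all-subsets ("dredge"): every subset of the candidate
terms is fitted and ranked by AICc; models within delta AICc < 2 of the
best are averaged with renormalized Akaike weights (full averaging: a
model that omits a term contributes a zero coefficient).

A nonparametric Spearman trend test for decade-level study counts rounds
out the module.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

_LOG_2PI = math.log(2.0 * math.pi)


@dataclasses.dataclass(frozen=True)
class SurveyRecord:
    """One survey's respondent count, outcome proportion and covariates."""

    survey_id: str
    n_respondents: int
    outcome_kind: str  # positive_attitude, negative_attitude, perceived_service, perceived_disservice
    proportion: float
    income: str | None = None  # high / low
    bird_group: str | None = None
    stakeholder: str | None = None  # rural / urban / mixed
    climate: str | None = None  # tropics / nontropics

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError(f"{self.survey_id}: n_respondents must be >= 1")
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError(f"{self.survey_id}: proportion must lie in [0, 1]")

    @property
    def successes(self) -> int:
        raw = self.proportion * self.n_respondents
        k = int(round(raw))
        if abs(raw - k) > 0.25:
            warnings.warn(
                f"{self.survey_id}: rounding error of {abs(raw - k):.2f} respondents "
                "when reconstructing the success count",
                stacklevel=2,
            )
        return k

    def covariate(self, name: str):
        return getattr(self, name)


def describe_proportions(
    records: Sequence[SurveyRecord], outcome_kind: str
) -> tuple[float, float, int]:
    """Unweighted arithmetic mean and SD of proportions across surveys."""
    props = [r.proportion for r in records if r.outcome_kind == outcome_kind]
    if not props:
        raise ValueError(f"no surveys with outcome {outcome_kind!r}")
    arr = np.asarray(props)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd, len(arr)


# ---------------------------------------------------------------------------
# binomial GLMM with a survey-level random intercept (Laplace approximation)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def _build_design(
    records: Sequence[SurveyRecord], terms: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy columns (lexicographic reference level) per term."""
    cols = [np.ones(len(records))]
    names = ["intercept"]
    for term in terms:
        vals = [r.covariate(term) for r in records]
        if any(v is None for v in vals):
            raise ValueError(f"missing values in covariate {term!r}")
        levels = sorted({str(v) for v in vals})
        for lev in levels[1:]:
            cols.append(np.array([1.0 if str(v) == lev else 0.0 for v in vals]))
            names.append(f"{term}[{lev}]")
    return np.column_stack(cols), names


def _laplace_loglik(
    beta: np.ndarray, log_sigma: float, X: np.ndarray,
    y: np.ndarray, n: np.ndarray,
) -> float:
    """Laplace-approximated marginal log-likelihood.

    Each survey is its own cluster, so the integral over its random
    intercept is one-dimensional: find the conditional mode by Newton
    steps, then apply the Gaussian curvature correction.
    """
    sigma = math.exp(log_sigma)
    eta0 = X @ beta
    u = np.zeros_like(eta0)
    s2 = sigma * sigma
    for _ in range(50):
        p = _expit(eta0 + u)
        grad = y - n * p - u / s2
        hess = -(n * p * (1 - p) + 1.0 / s2)
        step = grad / hess
        u_new = u - step
        if np.max(np.abs(u_new - u)) < 1e-10:
            u = u_new
            break
        u = u_new
    p = _expit(eta0 + u)
    eta = eta0 + u
    from scipy.special import gammaln

    log_choose = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    log_binom = log_choose + y * eta - n * np.log1p(np.exp(np.clip(eta, -700, 700)))
    log_prior = -0.5 * (u / sigma) ** 2 - math.log(sigma) - 0.5 * _LOG_2PI
    curvature = n * p * (1 - p) + 1.0 / s2
    log_laplace = 0.5 * (_LOG_2PI - np.log(curvature))
    return float(np.sum(log_binom + log_prior + log_laplace))


@dataclasses.dataclass
class BinomialMixedFit:
    coef: dict[str, float]
    se: dict[str, float]
    sigma_u: float
    loglik: float
    aicc: float
    aic: float
    n_surveys: int
    terms: tuple[str, ...]
    converged: bool


def fit_binomial_mixed(
    records: Sequence[SurveyRecord],
    terms: Sequence[str] = (),
    *,
    tol: float = 1e-8,
) -> BinomialMixedFit:
    """Fit the logit binomial GLMM with a survey random intercept by
    Laplace-approximated maximum likelihood.

    AICc uses n = number of surveys and p = number of fixed coefficients
    plus one variance parameter.
    """
    X, names = _build_design(records, terms)
    y = np.array([r.successes for r in records], dtype=float)
    n = np.array([r.n_respondents for r in records], dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient; drop aliased terms")
    # separation guard: a dummy column that perfectly predicts all-0/all-1
    for j in range(1, X.shape[1]):
        on = X[:, j] == 1.0
        if on.any() and ((y[on] == 0).all() or (y[on] == n[on]).all()):
            if (n[on] > 1).any():
                warnings.warn(
                    f"possible separation in column {names[j]!r}", stacklevel=2
                )

    p0 = np.clip((y + 0.5) / (n + 1.0), 1e-4, 1 - 1e-4)
    eta0 = np.log(p0 / (1 - p0))
    beta0, *_ = np.linalg.lstsq(X, eta0, rcond=None)
    theta0 = np.r_[beta0, math.log(max(np.std(eta0 - X @ beta0), 0.2))]

    def neg(theta: np.ndarray) -> float:
        return -_laplace_loglik(theta[:-1], theta[-1], X, y, n)

    res = optimize.minimize(
        neg, theta0, method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(-8.0, 5.0)],
        options={"ftol": tol, "gtol": 1e-10, "maxiter": 1000},
    )
    theta = res.x
    ll = -float(res.fun)
    n_surv = len(records)
    p_par = X.shape[1] + 1
    aic = -2.0 * ll + 2.0 * p_par
    denom = n_surv - p_par - 1
    aicc = aic + (2.0 * p_par * (p_par + 1) / denom) if denom > 0 else float("inf")

    # standard errors from the numeric Hessian of the negative log-likelihood
    hess = _numeric_hessian(neg, theta)
    se = np.full(X.shape[1], float("nan"))
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)[: X.shape[1]]
        se = np.sqrt(np.where(diag > 0, diag, float("nan")))
    except np.linalg.LinAlgError:
        pass
    return BinomialMixedFit(
        coef=dict(zip(names, theta[: X.shape[1]].tolist())),
        se=dict(zip(names, se.tolist())),
        sigma_u=float(math.exp(theta[-1])),
        loglik=ll,
        aicc=float(aicc),
        aic=float(aic),
        n_surveys=n_surv,
        terms=tuple(terms),
        converged=bool(res.success),
    )


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.zeros((n, n))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fij = f(x + ei + ej) - f(x + ei) - f(x + ej) + f0
            h[i, j] = h[j, i] = fij / (steps[i] * steps[j])
    return h


# ---------------------------------------------------------------------------
# all-subsets ranking and model averaging


@dataclasses.dataclass
class ModelRanking:
    rows: list[dict]  # term set, aicc, delta, weight (over the full set)
    averaged: dict[str, dict]  # coefficient -> estimate/se/z/p
    delta_threshold: float
    averaging: str

    def top_models(self) -> list[dict]:
        return [r for r in self.rows if r["delta_aicc"] < self.delta_threshold]


def dredge_and_average(
    records: Sequence[SurveyRecord],
    full_terms: Sequence[str],
    *,
    delta: float = 2.0,
    averaging: str = "full",
) -> ModelRanking:
    """Fit every subset of ``full_terms``, rank by AICc, and average the
    coefficients of models within ``delta`` of the best.

    ``averaging="full"`` substitutes zero for a coefficient absent from a
    model (shrinkage toward no effect); ``"conditional"`` averages only
    over the models containing the term.  Averaged standard errors use the
    Burnham-Anderson unconditional form
    se = sum_m w_m * sqrt(se_m^2 + (b_m - b_bar)^2).
    """
    full_terms = list(full_terms)
    if len(full_terms) > 12:
        raise ValueError("exhaustive enumeration limited to <= 12 candidate terms")
    fits: list[BinomialMixedFit] = []
    for r in range(len(full_terms) + 1):
        for subset in itertools.combinations(full_terms, r):
            try:
                fits.append(fit_binomial_mixed(records, subset))
            except Exception as exc:  # noqa: BLE001 - subset skipped, logged
                warnings.warn(f"subset {subset!r} failed: {exc}", stacklevel=2)
    if not fits:
        raise RuntimeError("no candidate model could be fitted")
    aiccs = np.array([f.aicc for f in fits])
    deltas = aiccs - aiccs.min()
    weights = np.exp(-0.5 * deltas)
    weights /= weights.sum()
    order = np.argsort(aiccs, kind="stable")
    rows = [
        {
            "terms": list(fits[i].terms),
            "aicc": float(aiccs[i]),
            "delta_aicc": float(deltas[i]),
            "weight": float(weights[i]),
            "loglik": fits[i].loglik,
        }
        for i in order
    ]
    sel = [i for i in order if deltas[i] < delta]
    w_sel = np.array([weights[i] for i in sel])
    w_sel /= w_sel.sum()
    coef_names: list[str] = []
    for i in sel:
        for name in fits[i].coef:
            if name not in coef_names:
                coef_names.append(name)
    averaged: dict[str, dict] = {}
    for name in coef_names:
        bs, ses, ws = [], [], []
        for i, w in zip(sel, w_sel):
            if name in fits[i].coef:
                bs.append(fits[i].coef[name])
                ses.append(fits[i].se[name])
                ws.append(w)
            elif averaging == "full":
                bs.append(0.0)
                ses.append(0.0)
                ws.append(w)
        bs, ses, ws = np.array(bs), np.array(ses), np.array(ws)
        ws = ws / ws.sum()
        b_bar = float(np.sum(ws * bs))
        se_bar = float(np.sum(ws * np.sqrt(ses**2 + (bs - b_bar) ** 2)))
        z = b_bar / se_bar if se_bar > 0 else float("nan")
        averaged[name] = {
            "estimate": b_bar,
            "se": se_bar,
            "z": z,
            "p": float(2.0 * stats.norm.sf(abs(z))) if se_bar > 0 else float("nan"),
            "approximate": True,
        }
    return ModelRanking(
        rows=rows, averaged=averaged, delta_threshold=delta, averaging=averaging
    )


# ---------------------------------------------------------------------------
# temporal trend of study counts


def spearman_trend(
    counts_by_period: Sequence[float], *, exact_max_n: int = 9
) -> tuple[float, float]:
    """Spearman correlation of counts against the period index.

    Two-sided p; exact by permutation enumeration for <= ``exact_max_n``
    periods, t-approximation otherwise.
    """
    counts = np.asarray(counts_by_period, dtype=float)
    n = len(counts)
    if n < 4:
        raise ValueError("trend test needs at least 4 periods")
    if np.all(counts == counts[0]):
        raise ValueError("constant counts: rank correlation undefined")
    time_idx = np.arange(n, dtype=float)
    rho = float(stats.spearmanr(time_idx, counts).statistic)
    if n <= exact_max_n:
        ranks = stats.rankdata(counts)
        t_ranks = stats.rankdata(time_idx)
        perms = np.array(list(itertools.permutations(range(n))))
        permuted = ranks[perms]
        num = ((t_ranks - t_ranks.mean()) * (permuted - permuted.mean(axis=1, keepdims=True))).sum(axis=1)
        den = math.sqrt(float(np.sum((t_ranks - t_ranks.mean()) ** 2))) * np.sqrt(
            np.sum((permuted - permuted.mean(axis=1, keepdims=True)) ** 2, axis=1)
        )
        rho_perm = num / den
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(time_idx, counts).pvalue)
    return rho, p
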