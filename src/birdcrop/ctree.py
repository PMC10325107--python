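"""Conditional inference tree for a binary response.

Recursive partitioning in the permutation-test framework: at each node the
global null hypothesis of independence between the response (here, the
direction of an effect size) and each covariate is tested; the covariate
with the strongest association (smallest Bonferroni-adjusted permutation
p-value) is selected, and the node is split only if that adjusted p-value
is below alpha.  This gives statistically motivated, multiplicity-aware
stopping without pruning.

Tests:

* categorical covariate x binary response -- Pearson chi-square statistic;
  2x2 tables use the exact conditional (Fisher) distribution, larger
  tables a Monte-Carlo permutation distribution (>= 9,999 permutations).
* numeric covariate -- maximally selected two-sample statistic over
  observed cutpoints, with a Monte-Carlo permutation p-value for the
  maximum.

Splits are binary: exhaustive search over two-set partitions of the
levels (categorical) or over cutpoints (numeric), maximizing the
two-sample chi-square statistic, subject to a minimum node size.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

DEFAULT_SEED = 20230706


@dataclasses.dataclass
class CtreeNode:
    node_id: int
    n: int
    class_counts: tuple[int, int]  # (n_positive, n_negative)
    variable_pvalues: dict[str, float]
    split_variable: str | None = None
    split_partition: tuple[tuple, tuple] | None = None  # level sets, or
    split_cutpoint: float | None = None  # numeric threshold (x <= c goes left)
    children: tuple["CtreeNode", "CtreeNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def proportion_positive(self) -> float:
        return self.class_counts[0] / self.n if self.n else float("nan")

    def to_dict(self) -> dict:
        out = {
            "node_id": self.node_id,
            "n": self.n,
            "n_positive": self.class_counts[0],
            "n_negative": self.class_counts[1],
            "variable_pvalues": self.variable_pvalues,
        }
        if not self.is_leaf:
            out["split_variable"] = self.split_variable
            if self.split_partition is not None:
                out["split_left_levels"] = list(self.split_partition[0])
                out["split_right_levels"] = list(self.split_partition[1])
            if self.split_cutpoint is not None:
                out["split_cutpoint"] = self.split_cutpoint
            out["children"] = [c.to_dict() for c in self.children]
        return out

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        head = (
            f"{pad}[{self.node_id}] n={self.n} "
            f"pos={self.class_counts[0]} neg={self.class_counts[1]}"
        )
        if self.is_leaf:
            return head + " (leaf)\n"
        if self.split_partition is not None:
            rule = f"{self.split_variable} in {sorted(self.split_partition[0])}"
        else:
            rule = f"{self.split_variable} <= {self.split_cutpoint:g}"
        p = self.variable_pvalues.get(self.split_variable, float("nan"))
        s = head + f" split on {rule} (adj p={p:.4g})\n"
        for c in self.children:
            s += c.render(indent + 1)
        return s


def _chisq_stat(table: np.ndarray) -> float:
    """Pearson chi-square statistic of an r x 2 contingency table."""
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def _categorical_test(
    x_codes: np.ndarray, n_levels: int, y: np.ndarray,
    rng: np.random.Generator, n_perm: int,
) -> float:
    """Permutation p-value for independence of a categorical covariate and a
    binary response.  2x2 tables use the exact conditional (hypergeometric)
    distribution of the chi-square statistic; larger ones Monte Carlo."""
    table = np.zeros((n_levels, 2), dtype=float)
    np.add.at(table, (x_codes, y), 1.0)
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        return 1.0
    stat_obs = _chisq_stat(table)
    if n_levels == 2:
        # exact conditional test (Fisher), the permutation distribution of a
        # 2x2 table with fixed margins
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    # Monte-Carlo: permute the response, vectorized over permutations
    n = len(y)
    indicator = np.zeros((n, n_levels))
    indicator[np.arange(n), x_codes] = 1.0
    row_tot = indicator.sum(axis=0)  # per-level n
    n_pos = y.sum()
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    yp = y[perms]  # n_perm x n
    pos_per_level = yp @ indicator  # n_perm x n_levels
    exp_pos = row_tot * n_pos / n
    exp_neg = row_tot * (n - n_pos) / n
    neg_per_level = row_tot[None, :] - pos_per_level
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = ((pos_per_level - exp_pos) ** 2 / exp_pos
               + (neg_per_level - exp_neg) ** 2 / exp_neg).sum(axis=1)
    count = int(np.sum(chi >= stat_obs - 1e-9))
    return (1 + count) / (1 + n_perm)


def _max_rank_stat(x: np.ndarray, y: np.ndarray, min_child: int) -> float:
    """Maximally selected standardized two-sample statistic over cutpoints."""
    order = np.argsort(x, kind="stable")
    ys = y[order].astype(float)
    n = len(ys)
    csum = np.cumsum(ys)
    total = csum[-1]
    ybar = total / n
    var_y = np.mean((ys - ybar) ** 2)
    if var_y == 0:
        return 0.0
    xs = x[order]
    # candidate cut positions: after index m-1 where x changes, respecting size
    stats_at = []
    for m in range(min_child, n - min_child + 1):
        if m < n and xs[m - 1] == xs[m]:
            continue
        mean_left = csum[m - 1] / m
        se = np.sqrt(var_y * (n - m) / (m * n))
        if se == 0:
            continue
        stats_at.append(abs(mean_left - ybar) / se)
    return max(stats_at) if stats_at else 0.0


def _numeric_test(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
    n_perm: int, min_child: int,
) -> float:
    stat_obs = _max_rank_stat(x, y, min_child)
    if stat_obs == 0.0:
        return 1.0
    # vectorized permutation distribution of the maximally selected statistic
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(y)
    cuts = np.array(
        [m for m in range(min_child, n - min_child + 1) if m == n or xs[m - 1] != xs[m]],
        dtype=int,
    )
    if len(cuts) == 0:
        return 1.0
    yf = y.astype(float)
    ybar = yf.mean()
    var_y = np.mean((yf - ybar) ** 2)
    se = np.sqrt(var_y * (n - cuts) / (cuts * n))
    valid = se > 0
    cuts, se = cuts[valid], se[valid]
    if len(cuts) == 0:
        return 1.0
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    yp = yf[perms]
    csum = np.cumsum(yp, axis=1)
    mean_left = csum[:, cuts - 1] / cuts
    stat_perm = (np.abs(mean_left - ybar) / se).max(axis=1)
    count = int(np.sum(stat_perm >= stat_obs - 1e-9))
    return (1 + count) / (1 + n_perm)


def _best_categorical_split(
    x_codes: np.ndarray, levels: Sequence, y: np.ndarray, min_child: int
) -> tuple[tuple, tuple] | None:
    """Binary partition of levels maximizing the collapsed 2x2 chi-square."""
    present = sorted(set(x_codes.tolist()))
    if len(present) < 2:
        return None
    best, best_stat = None, -1.0
    for r in range(1, len(present) // 2 + 1):
        for left in itertools.combinations(present, r):
            left_set = set(left)
            mask = np.isin(x_codes, list(left_set))
            n_l, n_r = int(mask.sum()), int((~mask).sum())
            if n_l < min_child or n_r < min_child:
                continue
            table = np.array(
                [
                    [int(y[mask].sum()), n_l - int(y[mask].sum())],
                    [int(y[~mask].sum()), n_r - int(y[~mask].sum())],
                ],
                dtype=float,
            )
            stat = _chisq_stat(table)
            if stat > best_stat:
                best_stat = stat
                best = (
                    tuple(levels[c] for c in sorted(left_set)),
                    tuple(levels[c] for c in present if c not in left_set),
                )
    return best


def _best_numeric_split(x: np.ndarray, y: np.ndarray, min_child: int) -> float | None:
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order].astype(float)
    n = len(ys)
    best_c, best_stat = None, -1.0
    csum = np.cumsum(ys)
    total = csum[-1]
    for m in range(min_child, n - min_child + 1):
        if m < n and xs[m - 1] == xs[m]:
            continue
        table = np.array(
            [[csum[m - 1], m - csum[m - 1]], [total - csum[m - 1], (n - m) - (total - csum[m - 1])]]
        )
        stat = _chisq_stat(table)
        if stat > best_stat:
            best_stat = stat
            best_c = xs[m - 1] if m == n else (xs[m - 1] + xs[m]) / 2.0
    return best_c


def fit_ctree(
    responses: Sequence[bool] | np.ndarray,
    covariates: Mapping[str, Sequence],
    *,
    alpha: float = 0.05,
    min_split: int = 20,
    min_leaf: int = 7,
    n_perm: int = 9999,
    seed: int = DEFAULT_SEED,
) -> CtreeNode:
    """Grow a conditional inference tree over a binary response.

    ``responses`` is True for a positive effect (g > 0; exactly zero counts
    as non-positive).  ``covariates`` maps names to per-observation values;
    strings are treated as categorical, numbers as numeric.  Per node,
    p-values are Bonferroni-adjusted across covariates and the best
    covariate splits the node iff its adjusted p < alpha.
    """
    y = np.asarray(responses, dtype=bool).astype(int)
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    names = list(covariates)
    if not names:
        raise ValueError("need at least one covariate")
    cols = {}
    for name in names:
        vals = list(covariates[name])
        if len(vals) != len(y):
            raise ValueError(f"covariate {name!r} length mismatch")
        if all(isinstance(v, (int, float, np.integer, np.floating)) and not isinstance(v, bool) for v in vals):
            cols[name] = ("numeric", np.asarray(vals, dtype=float), None)
        else:
            levels = sorted({str(v) for v in vals})
            lookup = {lev: c for c, lev in enumerate(levels)}
            codes = np.array([lookup[str(v)] for v in vals], dtype=int)
            cols[name] = ("categorical", codes, levels)

    rng = np.random.default_rng(seed)
    counter = itertools.count(1)

    def grow(idx: np.ndarray) -> CtreeNode:
        node_id = next(counter)
        yn = y[idx]
        counts = (int(yn.sum()), int(len(yn) - yn.sum()))
        node = CtreeNode(node_id=node_id, n=len(yn), class_counts=counts, variable_pvalues={})
        if len(yn) < min_split or counts[0] == 0 or counts[1] == 0:
            return node
        pvals = {}
        for name in names:
            kind, arr, levels = cols[name]
            if kind == "categorical":
                codes_n = arr[idx]
                if len(set(codes_n.tolist())) < 2:
                    continue
                # re-code to the levels present in this node
                present = sorted(set(codes_n.tolist()))
                remap = {c: j for j, c in enumerate(present)}
                codes_local = np.array([remap[c] for c in codes_n])
                p = _categorical_test(codes_local, len(present), yn, rng, n_perm)
            else:
                xn = arr[idx]
                if len(np.unique(xn)) < 2:
                    continue
                p = _numeric_test(xn, yn, rng, n_perm, min_leaf)
            pvals[name] = min(1.0, p * len(names))  # Bonferroni across covariates
        node.variable_pvalues = pvals
        if not pvals:
            return node
        best_var = min(pvals, key=lambda k: (pvals[k], k))
        if pvals[best_var] >= alpha:
            return node
        kind, arr, levels = cols[best_var]
        if kind == "categorical":
            part = _best_categorical_split(arr[idx], levels, yn, min_leaf)
            if part is None:
                return node
            left_codes = {levels.index(l) for l in part[0]}
            mask = np.isin(arr[idx], list(left_codes))
            node.split_partition = part
        else:
            c = _best_numeric_split(arr[idx], yn, min_leaf)
            if c is None:
                return node
            mask = arr[idx] <= c
            node.split_cutpoint = float(c)
        if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
            return node
        node.split_variable = best_var
        node.children = (grow(idx[mask]), grow(idx[~mask]))
        return node

    return grow(np.arange(len(y)))


def direction_proportions(
    responses: Sequence[bool] | np.ndarray, grouping: Sequence
) -> dict[str, float]:
    """Proportion of positive effects per group level (exact counts)."""
    y = np.asarray(responses, dtype=bool)
    groups = [str(v) for v in grouping]
    if len(groups) != len(y):
        raise ValueError("grouping length mismatch")
    out: dict[str, float] = {}
    for lev in sorted(set(groups)):
        mask = np.array([v == lev for v in groups])
        out[lev] = float(y[mask].mean())
    return out
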