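"""Multilevel REML meta-analysis: closed-form reductions, grid-search and
reference-implementation oracles."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from birdcrop import (
    EffectSimConfig,
    MetaDataset,
    ModelSpec,
    compute_effects,
    fit_multilevel,
    forest_summary,
    moderator_test,
    q_test,
    simulate_effects,
    subgroup_estimates,
)
from birdcrop.meta_model import RankDeficientError

from conftest import make_effects


def dense_reml_loglik(g, v, X, study, ts, tw):
    """Independent dense-matrix REML criterion (slogdet route)."""
    k, p = X.shape
    same = study[:, None] == study[None, :]
    V = np.diag(v + tw) + ts * same
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv @ g)
    r = g - X @ beta
    return float(
        0.5 * np.linalg.slogdet(X.T @ X)[1]
        - 0.5 * (
            (k - p) * np.log(2 * np.pi)
            + np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XtVinvX)[1]
            + r @ Vinv @ r
        )
    )


class TestFitMultilevel:
    def test_identical_effects_zero_heterogeneity(self):
        data = MetaDataset(make_effects([0.5, 0.5], [0.1, 0.1]))
        fit = fit_multilevel(data)
        assert fit.mu == pytest.approx(0.5)
        assert fit.tau2_study == pytest.approx(0.0, abs=1e-6)
        assert fit.tau2_within == pytest.approx(0.0, abs=1e-6)

    def test_equal_variances_zero_tau_reduce_to_mean(self):
        g = [0.1, 0.2, 0.3, 0.6]
        data = MetaDataset(make_effects(g, [0.2] * 4))
        fit = fit_multilevel(data)
        # with equal v the GLS mean equals the arithmetic mean whatever tau2
        assert fit.mu == pytest.approx(np.mean(g))

    def test_reduces_to_closed_form_weighted_mean(self, rng):
        """One comparison per study: mu must equal sum(w g)/sum(w) with
        w = 1/(v + tau2) at the REML tau2."""
        g = rng.normal(0.4, 0.4, 12)
        v = rng.uniform(0.02, 0.3, 12)
        data = MetaDataset(make_effects(g, v))
        fit = fit_multilevel(data)
        w = 1.0 / (v + fit.tau2_study + fit.tau2_within)
        assert fit.mu == pytest.approx(float(np.sum(w * g) / np.sum(w)), rel=1e-6)

    def test_reml_beats_grid_search_k6(self, rng):
        """The optimizer's criterion value dominates a brute-force grid over
        tau2 in [0, 2]^2 (step 0.01) evaluated by an independent dense
        implementation."""
        g = np.array([0.8, 0.1, -0.2, 0.55, 0.3, 0.9])
        v = np.array([0.05, 0.12, 0.2, 0.07, 0.1, 0.15])
        study = np.array([0, 0, 1, 1, 2, 2])
        effects = []
        from birdcrop import EffectSize

        for i, (gi, vi, si) in enumerate(zip(g, v, study)):
            effects.append(
                EffectSize(g=float(gi), v_g=float(vi), study_id=f"s{si}", comparison_id=f"c{i}")
            )
        fit = fit_multilevel(MetaDataset(effects))
        X = np.ones((6, 1))
        grid = np.arange(0.0, 2.0001, 0.01)
        best = -np.inf
        for ts in grid:
            for tw in grid:
                best = max(best, dense_reml_loglik(g, v, X, study, ts, tw))
        assert fit.loglik_reml >= best - 1e-6
        # and the returned optimum matches the dense criterion at (ts, tw)
        assert fit.loglik_reml == pytest.approx(
            dense_reml_loglik(g, v, X, study, fit.tau2_study, fit.tau2_within), abs=1e-8
        )

    def test_rank_deficient_moderator_reported(self):
        effects = make_effects([0.1, 0.2, 0.3, 0.4], [0.1] * 4)
        for e in effects:
            e.moderators["a"] = 1.0  # constant numeric -> aliased with intercept
        with pytest.raises(RankDeficientError, match="a"):
            fit_multilevel(MetaDataset(effects), ModelSpec(moderators=["a"]))

    def test_too_few_effects(self):
        with pytest.raises(ValueError):
            fit_multilevel(MetaDataset(make_effects([0.5], [0.1])))

    def test_matches_metafor_rma_mv(self, tmp_path):
        """Cross-check against the independent reference implementation."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        cfg = EffectSimConfig(n_studies=10, comparisons_per_study=(1, 4))
        data = MetaDataset(compute_effects(simulate_effects(cfg, seed=7)))
        fit = fit_multilevel(data)
        rows = "\n".join(
            f"{e.g},{e.v_g},{e.study_id},{e.comparison_id}" for e in data.effects
        )
        csv = tmp_path / "d.csv"
        csv.write_text("yi,vi,study,comp\n" + rows + "\n")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(metafor))
            d <- read.csv("{csv}")
            m <- rma.mv(yi, vi, random = ~1 | study/comp, data = d, method = "REML")
            cat(coef(m), m$se, m$sigma2[1], m$sigma2[2], logLik(m), sep = ",")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        mu_r, se_r, ts_r, tw_r, ll_r = map(float, out.stdout.strip().split(","))
        assert fit.mu == pytest.approx(mu_r, abs=1e-5)
        assert fit.se[0] == pytest.approx(se_r, abs=1e-5)
        assert fit.tau2_study == pytest.approx(ts_r, abs=1e-5)
        assert fit.tau2_within == pytest.approx(tw_r, abs=1e-5)
        assert fit.loglik_reml == pytest.approx(ll_r, abs=1e-4)


class TestQTest:
    def test_identical_effects_qe_zero(self):
        data = MetaDataset(make_effects([0.4] * 4, [0.1] * 4))
        qe, df, p = q_test(data)
        assert qe == pytest.approx(0.0, abs=1e-12)
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_hand_computed_k5(self, handmade_k5):
        g = np.array([0.1, 0.3, 0.5, 0.7, 0.2])
        v = np.array([0.04, 0.09, 0.16, 0.25, 0.01])
        w = 1 / v
        mu_fe = np.sum(w * g) / np.sum(w)
        expected = float(np.sum(w * (g - mu_fe) ** 2))
        qe, df, _ = q_test(handmade_k5)
        assert qe == pytest.approx(expected, rel=1e-10)
        assert df == 4

    def test_invariant_to_study_relabeling(self, rng):
        g = rng.normal(0, 0.5, 10)
        v = rng.uniform(0.05, 0.2, 10)
        one = MetaDataset(make_effects(g, v, one_per_study=True))
        two = MetaDataset(make_effects(g, v, one_per_study=False))
        assert q_test(one)[0] == pytest.approx(q_test(two)[0])

    def test_k_not_exceeding_p_errors(self):
        data = MetaDataset(make_effects([0.5, 0.6], [0.1, 0.1]))
        effects = data.effects
        for e, lev in zip(effects, ["a", "b"]):
            e.moderators["m"] = lev
        with pytest.raises(ValueError):
            q_test(MetaDataset(effects), ModelSpec(moderators=["m"]))


class TestModeratorTest:
    def test_null_moderator_qm_near_zero(self):
        # identical subgroup means, no heterogeneity
        effects = make_effects([0.5] * 8, [0.1] * 8)
        for i, e in enumerate(effects):
            e.moderators["m"] = "a" if i % 2 == 0 else "b"
        qm, df, p = moderator_test(MetaDataset(effects), ModelSpec(moderators=["m"]))
        assert qm == pytest.approx(0.0, abs=1e-8)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_power_for_strong_subgroup_difference(self):
        """A true 0.8 subgroup shift is detected in >= 80% of replicates."""
        from birdcrop import ModeratorSpec

        cfg = EffectSimConfig(
            n_studies=30,
            comparisons_per_study=(2, 3),
            true_mu=0.0,
            tau2_study=0.02,
            tau2_within=0.01,
            n_range=(10, 30),
            moderators=[ModeratorSpec("grp", ["a", "b"], [0.0, 0.8])],
        )
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            data = MetaDataset(compute_effects(simulate_effects(cfg, rng)))
            _, _, p = moderator_test(data, ModelSpec(moderators=["grp"]))
            hits += p < 0.05
        assert hits / n_rep >= 0.80


class TestSubgroups:
    def test_single_level_equals_overall(self, rng):
        g = rng.normal(0.4, 0.3, 8)
        v = rng.uniform(0.05, 0.2, 8)
        effects = make_effects(g, v)
        for e in effects:
            e.moderators["m"] = "only"
        data = MetaDataset(effects)
        overall = fit_multilevel(data)
        sub = subgroup_estimates(data, "m")
        assert set(sub) == {"only"}
        assert sub["only"].mu == pytest.approx(overall.mu, abs=1e-6)
        assert sub["only"].k == 8

    def test_known_level_means_recovered(self):
        from birdcrop import ModeratorSpec

        cfg = EffectSimConfig(
            n_studies=60,
            comparisons_per_study=(2, 3),
            true_mu=0.0,
            tau2_study=0.01,
            tau2_within=0.01,
            n_range=(20, 40),
            moderators=[ModeratorSpec("grp", ["lo", "hi"], [-0.3, 0.5])],
        )
        rng = np.random.default_rng(5)
        mus = {"lo": [], "hi": []}
        for _ in range(30):
            data = MetaDataset(compute_effects(simulate_effects(cfg, rng)))
            sub = subgroup_estimates(data, "grp")
            for lev in mus:
                mus[lev].append(sub[lev].mu)
        assert np.mean(mus["lo"]) == pytest.approx(-0.3, abs=0.05)
        assert np.mean(mus["hi"]) == pytest.approx(0.5, abs=0.05)


class TestForest:
    def test_overall_row_consistent_with_fit(self, handmade_k5):
        fit = fit_multilevel(handmade_k5)
        rows = forest_summary(fit, handmade_k5)
        assert len(rows) == handmade_k5.k + 1
        overall = rows[-1]
        assert overall["kind"] == "overall"
        assert overall["g"] == pytest.approx(fit.mu)
        assert overall["ci_low"] == pytest.approx(float(fit.ci_low[0]))
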