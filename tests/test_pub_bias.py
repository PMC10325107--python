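"""Publication-bias suite: closed forms, enumeration oracles, reference
implementation cross-checks."""

import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from birdcrop import (
    MetaDataset,
    bias_report,
    egger_regression_test,
    failsafe_rosenthal,
    funnel_data,
    kendall_bias_test,
    trim_and_fill,
)
from birdcrop.pub_bias import _kendall_tau_b, _standardized_deviates

from conftest import make_effects


def symmetric_funnel(rng, k_pairs=10, mu=0.3, se_lo=0.1, se_hi=0.5):
    se = rng.uniform(se_lo, se_hi, k_pairs)
    dev = np.abs(rng.normal(0, se))
    g = np.r_[mu + dev, mu - dev]
    v = np.r_[se, se] ** 2
    return g, v


class TestFunnel:
    def test_se_is_sqrt_variance(self):
        data = MetaDataset(make_effects([0.1, 0.5], [0.25, 0.04]))
        rows = funnel_data(data)
        assert len(rows) == 2
        assert rows[0]["se"] == pytest.approx(0.5)
        assert rows[1]["se"] == pytest.approx(0.2)

    def test_symmetric_funnel_centers_on_mu(self, rng):
        g, v = symmetric_funnel(rng, k_pairs=200)
        rows = funnel_data(MetaDataset(make_effects(g, v)))
        assert np.mean([r["g"] for r in rows]) == pytest.approx(0.3, abs=1e-9)


class TestFailsafe:
    def test_two_z2_effects(self):
        # Z = 2 each: N = floor(16 / 1.6449^2 - 2) = 3
        data = MetaDataset(make_effects([2.0, 2.0], [1.0, 1.0]))
        n, threshold, robust = failsafe_rosenthal(data)
        assert n == 3
        assert threshold == 20
        assert not robust

    def test_all_null_not_robust(self):
        data = MetaDataset(make_effects([0.0, 0.0, 0.0], [0.1, 0.1, 0.1]))
        n, _, robust = failsafe_rosenthal(data)
        assert n == 0 and not robust

    def test_strong_set_exceeds_threshold(self):
        # 20 effects with Z ~= 4 each
        data = MetaDataset(make_effects([0.8] * 20, [0.04] * 20))
        n, threshold, robust = failsafe_rosenthal(data)
        assert threshold == 110
        assert n > 10 * threshold
        assert robust

    @pytest.mark.parametrize("k", [2, 3, 17, 101, 158])
    def test_threshold_is_5k_plus_10(self, k, rng):
        g = rng.normal(0.3, 0.2, k)
        v = rng.uniform(0.05, 0.3, k)
        _, threshold, _ = failsafe_rosenthal(MetaDataset(make_effects(g, v)))
        assert threshold == 5 * k + 10

    def test_scale_invariance(self, rng):
        g = rng.normal(0.4, 0.3, 12)
        v = rng.uniform(0.05, 0.3, 12)
        n1, _, _ = failsafe_rosenthal(MetaDataset(make_effects(g, v)))
        c = 3.7
        n2, _, _ = failsafe_rosenthal(MetaDataset(make_effects(c * g, c * c * v)))
        assert n1 == n2


class TestKendall:
    def test_monotone_tau_one(self):
        # effects increasing with variance, k=6, no ties
        g = np.array([0.0, 0.35, 0.6, 0.8, 1.0, 1.2])
        v = np.array([0.01, 0.04, 0.09, 0.16, 0.25, 0.36])
        ystar = _standardized_deviates(g, v)
        assert all(b > a for a, b in zip(ystar, ystar[1:]))
        tau, p = kendall_bias_test(MetaDataset(make_effects(g, v)))
        assert tau == pytest.approx(1.0)

    def test_tau_equals_pair_enumeration_k5(self, handmade_k5):
        g, v = handmade_k5.g(), handmade_k5.v()
        ystar = _standardized_deviates(g, v)
        s = sum(
            np.sign(ystar[i] - ystar[j]) * np.sign(v[i] - v[j])
            for i, j in itertools.combinations(range(5), 2)
        )
        tau, _ = kendall_bias_test(handmade_k5)
        assert tau == pytest.approx(s / 10.0)

    @pytest.mark.parametrize("k", [4, 5, 6, 7])
    def test_exact_p_equals_full_permutation_enumeration(self, k, rng):
        """The exact branch must equal brute-force enumeration of all k!
        permutations."""
        g = rng.normal(0.3, 0.4, k)
        v = rng.uniform(0.02, 0.4, k)
        data = MetaDataset(make_effects(g, v))
        tau, p = kendall_bias_test(data)
        ystar = _standardized_deviates(g, v)
        _, s_obs = _kendall_tau_b(ystar, v)
        count = 0
        total = 0
        for perm in itertools.permutations(range(k)):
            vp = v[list(perm)]
            s = sum(
                np.sign(ystar[i] - ystar[j]) * np.sign(vp[i] - vp[j])
                for i, j in itertools.combinations(range(k), 2)
            )
            total += 1
            count += abs(s) >= abs(s_obs) - 1e-9
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_all_tied_errors(self):
        data = MetaDataset(make_effects([0.3, 0.3, 0.3], [0.1, 0.1, 0.1]))
        with pytest.raises(ValueError, match="rank"):
            kendall_bias_test(data)


class TestEgger:
    def test_constant_se_degenerate(self):
        data = MetaDataset(make_effects([0.1, 0.5, 0.9], [0.1, 0.1, 0.1]))
        with pytest.raises(ValueError):
            egger_regression_test(data)

    def test_null_type_one_error_near_alpha(self):
        """Symmetric funnels reject at ~5% (500 replicates)."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            se = rng.uniform(0.1, 0.5, 30)
            g = rng.normal(0.3, np.sqrt(se**2 + 0.02))
            _, p = egger_regression_test(MetaDataset(make_effects(g, se**2)))
            rejections += p < 0.05
        assert 0.025 <= rejections / n_rep <= 0.08

    def test_power_grows_with_asymmetry(self):
        """Induced small-study effects raise the rejection rate."""
        rng = np.random.default_rng(7)
        rates = []
        for slope in (0.0, 1.5, 3.0):
            rej = 0
            for _ in range(100):
                se = rng.uniform(0.1, 0.5, 30)
                g = rng.normal(0.1 + slope * se, se)
                _, p = egger_regression_test(MetaDataset(make_effects(g, se**2)))
                rej += p < 0.05
            rates.append(rej / 100)
        assert rates[0] < rates[1] < rates[2]

    def test_matches_metafor_regtest(self, tmp_path, rng):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        se = rng.uniform(0.1, 0.5, 20)
        g = rng.normal(0.3 + se, se)
        slope, p = egger_regression_test(MetaDataset(make_effects(g, se**2)))
        csv = tmp_path / "d.csv"
        csv.write_text(
            "yi,vi\n" + "\n".join(f"{a},{b}" for a, b in zip(g, se**2)) + "\n"
        )
        script = textwrap.dedent(
            f"""
            suppressMessages(library(metafor))
            d <- read.csv("{csv}")
            r <- regtest(rma(d$yi, d$vi, method="REML"), predictor="sei")
            cat(coef(r$fit)[2], r$pval, sep=",")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        slope_r, p_r = map(float, out.stdout.strip().split(","))
        assert slope == pytest.approx(slope_r, abs=1e-4)
        assert p == pytest.approx(p_r, abs=1e-4)


class TestTrimFill:
    def test_perfectly_symmetric_k0_zero(self, rng):
        g, v = symmetric_funnel(rng)
        data = MetaDataset(make_effects(g, v))
        k0, augmented, adjusted = trim_and_fill(data)
        assert k0 == 0
        assert augmented.k == data.k
        from birdcrop import ModelSpec, fit_multilevel

        original = fit_multilevel(data, ModelSpec(random_structure="none"))
        assert adjusted.mu == pytest.approx(original.mu, abs=1e-8)

    def test_idempotent_on_augmented_output(self, rng):
        se = np.geomspace(0.08, 0.6, 10)
        g = np.r_[0.3 + 1.96 * se, 0.3 - 1.96 * se]
        v = np.r_[se, se] ** 2
        order = np.argsort(g)
        keep = order[3:]
        data = MetaDataset(make_effects(g[keep], v[keep]))
        k0, augmented, _ = trim_and_fill(data, side="left")
        assert k0 > 0
        k0_again, _, _ = trim_and_fill(augmented, side="left")
        assert k0_again == 0

    def test_k0_bounded_by_k(self, rng):
        g, v = symmetric_funnel(rng, k_pairs=8)
        k0, _, _ = trim_and_fill(MetaDataset(make_effects(g, v)))
        assert 0 <= k0 <= 16

    def test_matches_metafor_trimfill(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(3)
        se = rng.uniform(0.1, 0.5, 25)
        g = rng.normal(0.2 + 1.2 * se, se)
        data = MetaDataset(make_effects(g, se**2))
        k0, _, adjusted = trim_and_fill(data, side="right")
        csv = tmp_path / "d.csv"
        csv.write_text(
            "yi,vi\n" + "\n".join(f"{a},{b}" for a, b in zip(g, se**2)) + "\n"
        )
        script = textwrap.dedent(
            f"""
            suppressMessages(library(metafor))
            d <- read.csv("{csv}")
            tf <- trimfill(rma(d$yi, d$vi, method="REML"), side="right")
            cat(tf$k0, coef(tf), sep=",")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        k0_r, mu_r = out.stdout.strip().split(",")
        assert k0 == int(k0_r)
        assert adjusted.mu == pytest.approx(float(mu_r), abs=1e-5)


class TestBiasReport:
    def test_report_fields_consistent(self, rng):
        g, v = symmetric_funnel(rng, k_pairs=12)
        data = MetaDataset(make_effects(g, v))
        report = bias_report(data)
        assert report.failsafe_threshold == 5 * data.k + 10
        assert -1.0 <= report.kendall_tau <= 1.0
        assert 0 <= report.trimfill_k0 <= data.k
        assert report.trimfill_side in ("left", "right")
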