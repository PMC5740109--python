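"""Association-scan behavior: PCA bases, the final model, inflation, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import ewaskit as ek

from conftest import nuisance_covariates


def _toy_design(n=150, seed=0):
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame(
        {"age": rng.normal(50, 8, n), "smoker": rng.integers(0, 2, n)},
        index=[f"s{i}" for i in range(n)])
    group = pd.Series(np.where(np.arange(n) < n // 2, "case", "control"),
                      index=cov.index)
    return cov, group, rng


class TestControlProbePcs:
    def test_rank_one_batch_recovered(self, null_cohort):
        basis = ek.control_probe_pcs(null_cohort.control_intensities, k=10)
        r = np.corrcoef(basis.scores["PC1"], null_cohort.truth.batch)[0, 1]
        assert basis.variance_fraction[0] > 0.5 and abs(r) > 0.9

    def test_k_bounds(self, null_cohort):
        with pytest.raises(ValueError):
            ek.control_probe_pcs(null_cohort.control_intensities.iloc[:, :5], k=5)

    def test_identical_samples_error(self):
        X = pd.DataFrame(np.ones((20, 6)) * 100.0)
        with pytest.raises(ValueError):
            ek.control_probe_pcs(X, k=2)

    def test_sign_convention_deterministic(self, null_cohort):
        a = ek.control_probe_pcs(null_cohort.control_intensities, k=5).scores
        b = ek.control_probe_pcs(null_cohort.control_intensities, k=5).scores
        assert a.equals(b)


class TestStage1Residuals:
    def test_orthogonal_to_covariates(self):
        cov, group, rng = _toy_design()
        pcs = pd.DataFrame(rng.normal(size=(len(cov), 2)), index=cov.index,
                           columns=["PC1", "PC2"])
        beta = pd.DataFrame(
            0.3 + 0.004 * cov["age"].to_numpy() + 0.02 * cov["smoker"].to_numpy()
            + rng.normal(0, 0.02, (30, len(cov))),
            columns=cov.index, index=[f"p{i}" for i in range(30)])
        resid = ek.stage1_residuals(beta, cov, pcs)
        assert np.abs(resid.mean(axis=1)).max() < 1e-10
        for col in list(cov.columns) + list(pcs.columns):
            vals = cov[col] if col in cov else pcs[col]
            r = np.corrcoef(resid.to_numpy(), vals.to_numpy()[None, :])[:-1, -1]
            assert np.abs(r).max() < 0.05

    def test_zero_variance_covariate_dropped(self):
        cov, group, rng = _toy_design(seed=1)
        cov["const"] = 1.0
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, (10, len(cov))),
                            columns=cov.index)
        pcs = pd.DataFrame(rng.normal(size=(len(cov), 1)), index=cov.index,
                           columns=["PC1"])
        with pytest.warns(UserWarning, match="aliased"):
            with_const = ek.stage1_residuals(beta, cov, pcs)
        without = ek.stage1_residuals(beta, cov.drop(columns="const"), pcs)
        assert np.allclose(with_const.to_numpy(), without.to_numpy())


class TestResidualPcs:
    def test_hidden_global_confounder_recovered(self):
        cov, group, rng = _toy_design(seed=2)
        hidden = rng.normal(size=len(cov))
        load = rng.normal(0, 0.05, 300)
        beta = expit(rng.normal(0, 1, (300, 1))
                     + load[:, None] * hidden[None, :]
                     + rng.normal(0, 0.1, (300, len(cov))))
        beta = pd.DataFrame(beta, columns=cov.index)
        pcs = pd.DataFrame(rng.normal(size=(len(cov), 1)), index=cov.index,
                           columns=["PC1"])
        resid = ek.stage1_residuals(beta, cov, pcs)
        basis = ek.residual_pcs(resid, k=3)
        r = np.corrcoef(basis.scores["PC1"], hidden)[0, 1]
        assert abs(r) > 0.8


class TestFinalGlm:
    def test_spiked_coefficient_and_sign(self):
        cov, group, rng = _toy_design(n=400, seed=3)
        n = len(cov)
        g = (group == "case").to_numpy(float)
        base = rng.uniform(0.3, 0.7, 200)
        beta = base[:, None] + rng.normal(0, 0.03, (200, n))
        beta[:5] += 0.05 * g[None, :]   # hyper spikes
        beta[5:10] -= 0.05 * g[None, :]  # hypo spikes
        beta = pd.DataFrame(np.clip(beta, 0, 1), columns=cov.index,
                            index=[f"p{i}" for i in range(200)])
        res = ek.fit_final_glm(beta, group, cov)
        hyper = res.table.iloc[:5]
        hypo = res.table.iloc[5:10]
        assert np.abs(hyper["coefficient"] - 0.05).max() < 0.01
        assert np.abs(hypo["coefficient"] + 0.05).max() < 0.01
        assert (hyper["t"] > 0).all() and (hypo["t"] < 0).all()
        assert (hyper["p"] < 5e-7).mean() >= 0.8
        assert np.allclose(res.table["t"],
                           res.table["coefficient"] / res.table["se"], atol=1e-8)

    def test_group_required_in_design(self):
        cov, group, rng = _toy_design(seed=4)
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, (120, len(cov))),
                            columns=cov.index)
        constant_group = pd.Series("case", index=cov.index)
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning, match="aliased"):
                ek.fit_final_glm(beta, constant_group, cov)

    def test_too_few_samples(self):
        cov, group, rng = _toy_design(n=3, seed=5)
        beta = pd.DataFrame(rng.uniform(size=(5, 3)), columns=cov.index)
        with pytest.raises(ValueError):
            ek.fit_final_glm(beta, group, cov)


class TestGenomicInflation:
    def test_all_half_is_one(self):
        assert ek.genomic_inflation(np.full(500, 0.5)) == pytest.approx(1.0)

    def test_uniform_near_one(self):
        rng = np.random.default_rng(6)
        lam = ek.genomic_inflation(rng.uniform(1e-12, 1, 100_000))
        assert abs(lam - 1.0) < 0.02

    def test_inflated_z_scale(self):
        rng = np.random.default_rng(7)
        z = rng.normal(0, 1.2, 100_000)
        p = 2 * stats.norm.sf(np.abs(z))
        lam = ek.genomic_inflation(np.clip(p, 1e-300, 1))
        assert abs(lam - 1.44) < 0.03

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ek.genomic_inflation(np.full(200, 0.0))
        with pytest.raises(ValueError):
            ek.genomic_inflation(np.full(50, 0.5))


class TestFdr:
    def test_hand_example(self):
        q = ek.adjust_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_single_p_passthrough(self):
        assert ek.adjust_fdr(np.array([0.123]))[0] == pytest.approx(0.123)

    def test_order_invariance_and_bruteforce(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1, 500)
        perm = rng.permutation(500)
        q = ek.adjust_fdr(p)
        assert np.allclose(q[perm], ek.adjust_fdr(p[perm]))
        # brute-force BH step-up
        order = np.argsort(p)
        m = len(p)
        raw = p[order] * m / np.arange(1, m + 1)
        stepup = np.minimum.accumulate(raw[::-1])[::-1]
        brute = np.empty(m)
        brute[order] = np.minimum(stepup, 1)
        assert np.allclose(q, brute, atol=1e-12)


class TestPermutationCheck:
    def test_strong_spike_hits_floor_and_is_reproducible(self, spiked_cohort):
        cov = nuisance_covariates(spiked_cohort)
        probes = list(spiked_cohort.truth.spike_probes)[:3]
        a = ek.permutation_check(spiked_cohort.beta, spiked_cohort.samples["group"],
                                 cov, probes, B=100, seed=5)
        b = ek.permutation_check(spiked_cohort.beta, spiked_cohort.samples["group"],
                                 cov, probes, B=100, seed=5)
        assert (a == 1 / 101).all()
        assert a.equals(b)

    def test_null_probes_center_near_half(self, null_cohort):
        cov = nuisance_covariates(null_cohort)
        probes = list(null_cohort.beta.index[:40])
        p = ek.permutation_check(null_cohort.beta, null_cohort.samples["group"],
                                 cov, probes, B=60, seed=6)
        assert 0.35 < p.mean() < 0.65

    def test_small_b_warns(self, null_cohort):
        cov = nuisance_covariates(null_cohort)
        with pytest.warns(UserWarning):
            ek.permutation_check(null_cohort.beta, null_cohort.samples["group"],
                                 cov, [null_cohort.beta.index[0]], B=10, seed=0)


class TestThreeGroupAnova:
    def test_constructed_pattern(self):
        rng = np.random.default_rng(9)
        ids = [f"s{i}" for i in range(90)]
        groups = pd.Series(["current"] * 30 + ["past"] * 30 + ["none"] * 30,
                           index=ids)
        vals = np.concatenate([rng.normal(0.10, 0.01, 30),
                               rng.normal(0.10, 0.01, 30),
                               rng.normal(0.20, 0.01, 30)])
        beta = pd.DataFrame([vals], index=["p1"], columns=ids)
        out = ek.three_group_anova(beta, ["p1"], groups)
        assert out.loc["p1", "p"] < 1e-6
        assert out.loc["p1", "p_current_vs_past"] > 0.05

    def test_two_group_equals_t_squared(self):
        rng = np.random.default_rng(10)
        ids = [f"s{i}" for i in range(40)]
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=ids)
        beta = pd.DataFrame([rng.normal(0.5, 0.05, 40)], index=["p1"], columns=ids)
        out = ek.three_group_anova(beta, ["p1"], groups)
        t = stats.ttest_ind(beta.iloc[0, :20], beta.iloc[0, 20:], equal_var=True)
        assert out.loc["p1", "F"] == pytest.approx(t.statistic**2, rel=1e-9)

    def test_small_group_named(self):
        ids = [f"s{i}" for i in range(5)]
        groups = pd.Series(["a", "a", "b", "b", "tiny"], index=ids)
        beta = pd.DataFrame([[0.1, 0.2, 0.3, 0.4, 0.5]], index=["p1"], columns=ids)
        with pytest.raises(ValueError, match="tiny"):
            ek.three_group_anova(beta, ["p1"], groups)
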