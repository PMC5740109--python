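"""Panel selection, scores, clustering, frailty labels and classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

import ewaskit as ek
from ewaskit.ewas import EwasResult
from ewaskit.frailty import Residualizer, _fixed_svm_auc


def _fake_ewas(probes, ps, coefs):
    table = pd.DataFrame({"coefficient": coefs, "se": 0.01,
                          "t": np.asarray(coefs) / 0.01, "p": ps,
                          "q": ps, "n": 100}, index=probes)
    return EwasResult(table=table, lambda_=1.0, terms=["group"])


class TestSelectPanel:
    def test_p_cut_selection(self):
        res = _fake_ewas(["a", "b", "c"], [1e-5, 5e-4, 0.02], [0.05, -0.03, 0.01])
        panel = ek.select_panel(res, p_cut=1e-3)
        assert panel.probe_ids == ["a", "b"]
        assert panel.weights.loc["b"] == pytest.approx(-0.03)

    def test_p_cut_one_selects_everything(self):
        res = _fake_ewas(["a", "b"], [0.5, 0.99], [0.01, 0.02])
        assert len(ek.select_panel(res, p_cut=1.0 + 1e-12).probe_ids) == 2

    def test_gene_representative_smallest_p(self):
        res = _fake_ewas(["a", "b", "c"], [1e-5, 1e-4, 1e-6], [0.05, 0.03, 0.02])
        man = pd.DataFrame({
            "probe_id": ["a", "b", "c"],
            "gene": ["G1", "G1", "G2"],
        })
        panel = ek.select_panel(res, p_cut=1e-3, manifest=man)
        assert panel.gene_map == {"G1": "a", "G2": "c"}

    def test_empty_selection_error(self):
        res = _fake_ewas(["a"], [0.9], [0.01])
        with pytest.raises(ValueError, match="loosen"):
            ek.select_panel(res, p_cut=1e-6)


class TestResidualizer:
    def _data(self, n=120, m=8, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame({"age": rng.normal(50, 8, n),
                            "smoker": rng.integers(0, 2, n).astype(float)},
                           index=ids)
        beta = pd.DataFrame(
            0.5 + 0.003 * cov["age"].to_numpy() + rng.normal(0, 0.02, (m, n)),
            columns=ids, index=[f"p{i}" for i in range(m)])
        return beta, cov

    def test_residuals_orthogonal_to_nuisance(self):
        beta, cov = self._data()
        rz = Residualizer().fit(beta, cov)
        resid = rz.transform(beta, cov)
        for col in cov.columns:
            r = np.corrcoef(resid.to_numpy(), cov[col].to_numpy()[None, :])[:-1, -1]
            assert np.abs(r).max() < 0.05

    def test_no_leakage_training_coefficients_reused(self):
        beta, cov = self._data()
        train_b, train_c = beta.iloc[:, :80], cov.iloc[:80]
        rz = Residualizer().fit(train_b, train_c)
        held = rz.transform(beta.iloc[:, 80:], cov.iloc[80:])
        # a held-out sample identical to a training sample gets the same residual
        clone_b = beta.iloc[:, [0]].copy()
        clone_b.columns = ["clone"]
        clone_c = cov.iloc[[0]].copy()
        clone_c.index = ["clone"]
        out = rz.transform(clone_b, clone_c)
        train_resid = rz.transform(train_b, train_c)
        assert np.allclose(out["clone"], train_resid.iloc[:, 0])
        assert held.shape == (8, 40)

    def test_zero_covariate_recipe_centers(self):
        beta, cov = self._data()
        empty = cov.iloc[:, :0]
        rz = Residualizer().fit(beta, empty)
        resid = rz.transform(beta, empty)
        assert np.allclose(resid.to_numpy(),
                           beta.to_numpy() - beta.to_numpy().mean(1, keepdims=True))


class TestScore:
    def test_hand_computed(self):
        panel = ek.PanelModel(probe_ids=["a", "b", "c"],
                              weights=pd.Series([1.0, -1.0, 2.0],
                                                index=["a", "b", "c"]),
                              gene_map={})
        vals = pd.DataFrame(0.5, index=["a", "b", "c"], columns=["s1"])
        assert ek.cumulative_score(vals, panel)["s1"] == pytest.approx(1 / 3)

    def test_zero_values_zero_score_and_linearity(self):
        panel = ek.PanelModel(probe_ids=["a", "b"],
                              weights=pd.Series([0.3, -0.2], index=["a", "b"]),
                              gene_map={})
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(2, 5)), index=["a", "b"])
        zeros = pd.DataFrame(0.0, index=["a", "b"], columns=vals.columns)
        assert (ek.cumulative_score(zeros, panel) == 0).all()
        assert np.allclose(ek.cumulative_score(3.0 * vals, panel),
                           3.0 * ek.cumulative_score(vals, panel))

    def test_sign_flip_consistency(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.normal(size=(2, 6)), index=["a", "b"])
        panel = ek.PanelModel(probe_ids=["a", "b"],
                              weights=pd.Series([0.3, -0.2], index=["a", "b"]),
                              gene_map={})
        flipped_panel = ek.PanelModel(probe_ids=["a", "b"],
                                      weights=pd.Series([-0.3, -0.2],
                                                        index=["a", "b"]),
                                      gene_map={})
        flipped_vals = vals.copy()
        flipped_vals.loc["a"] *= -1
        assert np.allclose(ek.cumulative_score(vals, panel),
                           ek.cumulative_score(flipped_vals, flipped_panel))

    def test_missing_probe_listed(self):
        panel = ek.PanelModel(probe_ids=["a", "zz"],
                              weights=pd.Series([1.0, 1.0], index=["a", "zz"]),
                              gene_map={})
        vals = pd.DataFrame(0.5, index=["a"], columns=["s1"])
        with pytest.raises(ValueError, match="zz"):
            ek.cumulative_score(vals, panel)


class TestCorrelation:
    def test_perfect_linear(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        r, p, n = ek.correlate_score_index(s, 10 * s + 5)
        assert r == pytest.approx(1.0) and p < 1e-6 and n == 4

    def test_zero_variance_error(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError):
            ek.correlate_score_index(s, pd.Series([5.0, 5.0, 5.0], index=list("abc")))

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(3)
        rs = []
        for seed in range(20):
            a = pd.Series(rng.normal(size=200))
            b = pd.Series(rng.normal(size=200))
            rs.append(ek.correlate_score_index(a, b)[0])
        assert abs(np.mean(rs)) < 0.05


class TestHierarchicalCluster:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(4)
        X = np.concatenate([rng.normal(0, 0.1, (5, 20)),
                            rng.normal(10, 0.1, (5, 20))], axis=1)
        resid = pd.DataFrame(X, columns=[f"s{i}" for i in range(40)])
        labels, heights = ek.hierarchical_cluster(resid, k=2)
        assert labels.iloc[:20].nunique() == 1
        assert labels.iloc[20:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]
        assert (np.diff(heights) >= -1e-9).all()

    def test_colinear_points_complete_linkage(self):
        resid = pd.DataFrame([[0.0, 1.0, 10.0]], columns=["a", "b", "c"])
        labels, _ = ek.hierarchical_cluster(resid, k=2)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_agrees_with_bruteforce_agglomeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            X = rng.normal(size=(3, n))
            resid = pd.DataFrame(X, columns=[f"s{i}" for i in range(n)])
            labels, _ = ek.hierarchical_cluster(resid, k=2)
            # brute-force complete-linkage agglomeration
            clusters = [{i} for i in range(n)]
            pts = X.T
            while len(clusters) > 2:
                best = None
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        d = max(np.linalg.norm(pts[a] - pts[b])
                                for a in clusters[i] for b in clusters[j])
                        if best is None or d < best[0]:
                            best = (d, i, j)
                _, i, j = best
                clusters[i] |= clusters[j]
                del clusters[j]
            ours = [frozenset(np.flatnonzero(labels.to_numpy() == l))
                    for l in sorted(set(labels))]
            assert set(map(frozenset, clusters)) == set(ours)


class TestClusterPhenotype:
    def test_perfect_contingency_statistic(self):
        ids = [f"s{i}" for i in range(100)]
        labels = pd.Series([1] * 50 + [2] * 50, index=ids)
        samples = pd.DataFrame({"group": ["case"] * 50 + ["control"] * 50,
                                "age": np.r_[np.full(50, 50.0), np.full(50, 51.0)]},
                               index=ids)
        out = ek.cluster_phenotype_association(labels, samples,
                                               categorical=("group",),
                                               continuous=("age",))
        assert out.loc["group", "statistic"] == pytest.approx(100.0)
        assert out.loc["group", "p"] < 1e-20

    def test_independent_covariate_null(self):
        rng = np.random.default_rng(6)
        ps = []
        for seed in range(30):
            ids = [f"s{i}" for i in range(60)]
            labels = pd.Series(rng.permutation([1] * 30 + [2] * 30), index=ids)
            samples = pd.DataFrame({"age": rng.normal(50, 8, 60)}, index=ids)
            out = ek.cluster_phenotype_association(labels, samples,
                                                   categorical=(),
                                                   continuous=("age",))
            ps.append(out.loc["age", "p"])
        assert 0.2 < np.mean(ps) < 0.8  # roughly uniform under the null


class TestFrailtyLabels:
    def test_boundary_conventions(self):
        idx = pd.Series([16, 51, 0, 120, 24, 50], index=list("abcdef"))
        lab = ek.define_frailty_labels(idx)
        assert lab.low["a"] == 0      # 16 is not < 16
        assert lab.high["b"] == 1     # 51 > 50
        assert lab.high["f"] == 0     # 50 is not > 50
        assert lab.band["a"] == 1     # boundary index falls in the lower band
        assert lab.band["e"] == 2

    def test_quantile_cut_derivation(self):
        rng = np.random.default_rng(7)
        idx = pd.Series(rng.integers(0, 121, 2000).astype(float))
        lab = ek.define_frailty_labels(idx, derive_cuts_quantile=True)
        assert lab.high.mean() == pytest.approx(0.2, abs=0.03)
        assert lab.low.mean() == pytest.approx(0.2, abs=0.03)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            ek.define_frailty_labels(pd.Series([10.0, 130.0]))


class TestClassifierAndRoc:
    def _separable(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        y = pd.Series(np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int),
                      index=ids)
        X = pd.DataFrame(rng.normal(size=(5, n)) + 3.0 * y.to_numpy()[None, :],
                         columns=ids)
        return X, y

    def test_separable_training_auc_one(self):
        X, y = self._separable()
        clf = ek.train_frailty_classifier(X, y, folds=5, seed=0)
        auc = roc_auc_score(y, clf.decision_function(X.to_numpy().T))
        assert auc == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(8)
        aucs = []
        for seed in range(5):
            X, y = self._separable(n=120, seed=seed)
            y_shuf = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            Xte, yte = self._separable(n=100, seed=100 + seed)
            yte_shuf = pd.Series(rng.permutation(yte.to_numpy()), index=yte.index)
            clf = ek.train_frailty_classifier(X, y_shuf, folds=5, seed=seed)
            roc = ek.evaluate_roc(clf, Xte, yte_shuf, ci_reps=50, seed=seed)
            aucs.append(roc.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_deterministic_under_seed(self):
        X, y = self._separable(seed=3)
        a = ek.train_frailty_classifier(X, y, folds=5, seed=9)
        b = ek.train_frailty_classifier(X, y, folds=5, seed=9)
        assert np.allclose(a.decision_function(X.to_numpy().T),
                           b.decision_function(X.to_numpy().T))

    def test_perfect_scores_ci_degenerate(self):
        X, y = self._separable(seed=4)
        clf = ek.train_frailty_classifier(X, y, folds=5, seed=0)
        roc = ek.evaluate_roc(clf, X, y, ci_reps=100, seed=0)
        assert roc.auc == 1.0
        assert roc.ci_lower == pytest.approx(1.0) and roc.ci_upper == pytest.approx(1.0)

    def test_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.ones(30), np.zeros(40)].astype(int)
        scores = rng.normal(size=70) + 0.5 * y
        auc = roc_auc_score(y, scores)
        U = stats.mannwhitneyu(scores[y == 1], scores[y == 0],
                               alternative="two-sided").statistic
        assert auc == pytest.approx(U / (30 * 40), abs=1e-12)

    def test_auc_invariant_to_monotone_transform(self):
        X, y = self._separable(seed=5)
        clf = ek.train_frailty_classifier(X, y, folds=5, seed=0)
        s = clf.decision_function(X.to_numpy().T)
        assert roc_auc_score(y, s) == pytest.approx(
            roc_auc_score(y, np.exp(2 * s)), abs=1e-12)

    def test_one_class_test_set_error(self):
        X, y = self._separable(seed=6)
        clf = ek.train_frailty_classifier(X, y, folds=5, seed=0)
        ypos = pd.Series(1, index=y.index)
        with pytest.raises(ValueError):
            ek.evaluate_roc(clf, X, ypos)

    def test_curve_monotone(self):
        X, y = self._separable(n=60, seed=7)
        clf = ek.train_frailty_classifier(X, y, folds=5, seed=0)
        roc = ek.evaluate_roc(clf, X, y, ci_reps=50, seed=0)
        assert (np.diff(roc.tpr) >= 0).all() and (np.diff(roc.fpr) >= 0).all()


class TestPermutationPanelNull:
    def _cohorts(self, seed=0, n=150, m=60, informative=6):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        y = pd.Series((rng.random(n) < 0.3).astype(int), index=ids)
        X = rng.normal(size=(m, n)) * 0.02
        X[:informative] += 0.05 * y.to_numpy()[None, :]
        beta = pd.DataFrame(0.5 + X, index=[f"p{i}" for i in range(m)],
                            columns=ids)
        cov = pd.DataFrame({"age": rng.normal(50, 8, n)}, index=ids)
        return beta, cov, y

    def test_informative_panel_beats_entire_null(self):
        btr, ctr, ytr = self._cohorts(seed=1)
        bte, cte, yte = self._cohorts(seed=2)
        with pytest.warns(UserWarning, match="below 100"):
            out = ek.permutation_panel_null(
                btr, bte, ctr, cte, ytr, yte, panel_size=6,
                observed_panel=[f"p{i}" for i in range(6)], B=60, seed=3)
        assert out.permutation_p == pytest.approx(1 / 61)
        assert out.auc > 0.9

    def test_null_distribution_reproducible(self):
        btr, ctr, ytr = self._cohorts(seed=4)
        bte, cte, yte = self._cohorts(seed=5)
        kw = dict(panel_size=5, B=120, seed=11)
        a = ek.permutation_panel_null(btr, bte, ctr, cte, ytr, yte, **kw)
        b = ek.permutation_panel_null(btr, bte, ctr, cte, ytr, yte, **kw)
        assert np.array_equal(a, b)

    def test_train_test_swap_changes_results(self):
        # weak signal so the two directions give distinguishable AUCs
        btr, ctr, ytr = self._cohorts(seed=6, informative=2)
        bte, cte, yte = self._cohorts(seed=7, informative=2)
        noise = np.random.default_rng(8).normal(0, 0.02, btr.shape)
        btr = btr + noise
        panel = [f"p{i}" for i in range(20)]
        fwd = _fixed_svm_auc(panel, btr, bte, ctr, cte, ytr, yte)
        rev = _fixed_svm_auc(panel, bte, btr, cte, ctr, yte, ytr)
        assert fwd != rev
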