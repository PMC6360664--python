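import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stemsig import (
    CohortClinical,
    GeneSetCollection,
    associate_feature,
    correlate_scores,
    knn_loocv,
    signature_gene_overlap,
)
from stemsig.ssgsea import ScoreMatrix

from conftest import make_matrix


def score_matrix(arr, names=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    names = names or [f"sig{i}" for i in range(arr.shape[0])]
    samples = samples or [f"T{j}" for j in range(arr.shape[1])]
    return ScoreMatrix(pd.DataFrame(arr, index=names, columns=samples))


def clinical_from(d, **kw):
    df = pd.DataFrame(d)
    df.index = [f"T{j}" for j in range(len(df))]
    return CohortClinical(df, **kw)


class TestCorrelateScores:
    def test_unit_diagonal_and_symmetry(self, rng):
        sm = score_matrix(rng.normal(size=(4, 20)))
        corr, _ = correlate_scores(sm)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)

    def test_row_and_negation_correlate_minus_one(self, rng):
        base = rng.normal(size=12)
        sm = score_matrix(np.vstack([base, -base]))
        corr, _ = correlate_scores(sm)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_two_score_families_separate_in_two_cut(self, rng):
        # two positively-linked pairs, mutually anticorrelated through a
        # shared latent factor (the purity mechanism at the score level)
        latent = rng.normal(size=40)
        rows = np.vstack(
            [
                latent + 0.2 * rng.normal(size=40),
                latent + 0.2 * rng.normal(size=40),
                -latent + 0.2 * rng.normal(size=40),
                -latent + 0.2 * rng.normal(size=40),
            ]
        )
        sm = score_matrix(rows, names=["stem_up", "prolif", "stromal", "immune"])
        _, dend = correlate_scores(sm)
        labels = dend.cut(2)
        assert labels["stem_up"] == labels["prolif"]
        assert labels["stromal"] == labels["immune"]
        assert labels["stem_up"] != labels["stromal"]

    def test_zero_variance_row_named_in_error(self, rng):
        sm = score_matrix(np.vstack([np.ones(10), rng.normal(size=10)]),
                          names=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            correlate_scores(sm)


class TestSignatureGeneOverlap:
    def test_identical_lists(self):
        assert signature_gene_overlap(["A", "B"], ["B", "A"]) == (2, 1.0)

    def test_disjoint_lists(self):
        assert signature_gene_overlap(["A"], ["B"]) == (0, 0.0)

    def test_partial_overlap_enumeration(self):
        count, jac = signature_gene_overlap(["A", "B", "C"], ["B", "C", "D", "E"])
        assert (count, jac) == (2, 2 / 5)

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            signature_gene_overlap([], ["A"])


class TestAssociateFeature:
    def test_two_level_dispatches_to_welch_t(self, rng):
        scores = pd.Series(rng.normal(size=40), index=[f"T{j}" for j in range(40)])
        clin = clinical_from({"subtype": ["a"] * 20 + ["b"] * 20})
        res = associate_feature(scores, clin, "subtype")
        assert "Welch" in res.test_name
        g_a = scores[:20].to_numpy()
        g_b = scores[20:].to_numpy()
        stat, p = sps.ttest_ind(g_a, g_b, equal_var=False)
        assert res.statistic == pytest.approx(float(stat))
        assert res.p_value == pytest.approx(float(p))

    def test_multi_level_dispatches_to_anova(self, rng):
        scores = pd.Series(rng.normal(size=30), index=[f"T{j}" for j in range(30)])
        clin = clinical_from({"stage": (["I"] * 10 + ["II"] * 10 + ["III"] * 10)})
        res = associate_feature(scores, clin, "stage")
        assert "ANOVA" in res.test_name

    def test_continuous_dispatches_to_pearson(self, rng):
        scores = pd.Series(rng.normal(size=30), index=[f"T{j}" for j in range(30)])
        clin = clinical_from({"burden": rng.poisson(10, size=30).astype(float)})
        res = associate_feature(scores, clin, "burden")
        assert "Pearson" in res.test_name

    def test_identical_groups_give_zero_statistic(self):
        idx = [f"T{j}" for j in range(8)]
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0], index=idx)
        clin = clinical_from({"g": ["a"] * 4 + ["b"] * 4})
        res = associate_feature(scores, clin, "g")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_constant_feature_is_error(self, rng):
        scores = pd.Series(rng.normal(size=10), index=[f"T{j}" for j in range(10)])
        with pytest.raises(ValueError, match="constant"):
            associate_feature(scores, clinical_from({"g": ["x"] * 10}), "g")

    def test_missing_values_dropped_and_counted(self, rng):
        scores = pd.Series(rng.normal(size=10), index=[f"T{j}" for j in range(10)])
        feat = ["a"] * 4 + ["b"] * 4 + [None, None]
        res = associate_feature(scores, clinical_from({"g": feat}), "g")
        assert res.n == 8 and res.n_missing == 2

    def test_power_at_planted_one_sd_shift(self):
        """A 1-sd group shift at n=100 per arm is detected at p<0.01 in at
        least 99% of 100 seeds."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            idx = [f"T{j}" for j in range(200)]
            scores = pd.Series(
                np.concatenate([r.normal(1.0, 1.0, 100), r.normal(0.0, 1.0, 100)]),
                index=idx,
            )
            clin = clinical_from({"g": ["hi"] * 100 + ["lo"] * 100})
            res = associate_feature(scores, clin, "g")
            hits += res.p_value < 0.01
        assert hits >= 99

    def test_two_level_sign_agrees_with_dummy_correlation(self, rng):
        scores = pd.Series(rng.normal(size=60), index=[f"T{j}" for j in range(60)])
        labels = ["a"] * 30 + ["b"] * 30
        clin = clinical_from({"g": labels, "dummy": [0.0] * 30 + [1.0] * 30})
        t_res = associate_feature(scores, clin, "g")   # a vs b: positive t
        r_res = associate_feature(scores, clin, "dummy")  # corr with 1[b]
        assert np.sign(t_res.statistic) == -np.sign(r_res.statistic)


class TestKnnLoocv:
    @staticmethod
    def separated(rng, n_per=6, delta=5.0, n_genes=20):
        a = rng.normal(0.0, 1.0, size=(n_genes, n_per))
        b = rng.normal(delta, 1.0, size=(n_genes, n_per))
        labels = ["pos"] * n_per + ["neg"] * n_per
        return make_matrix(
            np.hstack([a, b]), annotations={"status": labels}
        )

    def test_well_separated_clusters_perfect_accuracy(self, rng):
        m = self.separated(rng)
        acc, preds = knn_loocv(m, "status", k=3)
        assert acc == 1.0
        assert (preds == m.annotations["status"]).all()

    def test_permuted_labels_near_chance(self):
        """Accuracy over permuted labels centers on 0.5 (permutation
        oracle, 200 permutations of one dataset)."""
        r = np.random.default_rng(5)
        m = self.separated(r, n_per=6)
        accs = []
        labels = m.annotations["status"].to_numpy().copy()
        for _ in range(200):
            r.shuffle(labels)
            m.annotations["status"] = labels
            acc, _ = knn_loocv(m, "status", k=3)
            accs.append(acc)
        mean_acc = np.mean(accs)
        # LOOCV on permuted labels is slightly pessimistic; binomial-ish band
        assert 0.30 < mean_acc < 0.60

    def test_degenerate_identical_samples_follow_tie_break(self):
        m = make_matrix(
            np.ones((4, 4)), annotations={"status": ["a", "b", "a", "b"]}
        )
        acc, preds = knn_loocv(m, "status", k=1)
        # all distances zero: neighbor = smallest other index
        assert preds.tolist() == ["b", "a", "a", "a"]

    def test_sample_order_invariance_without_ties(self, rng):
        m = self.separated(rng, n_per=5)
        acc1, _ = knn_loocv(m, "status", k=3)
        perm = rng.permutation(m.n_samples)
        shuffled = m.values.iloc[:, perm]
        m2 = make_matrix(
            shuffled.to_numpy(),
            gene_ids=m.gene_ids,
            sample_ids=list(shuffled.columns),
            annotations={"status": m.annotations["status"].iloc[perm].tolist()},
        )
        acc2, _ = knn_loocv(m2, "status", k=3)
        assert acc1 == acc2

    def test_k_at_least_n_is_error(self, rng):
        m = self.separated(rng, n_per=2)
        with pytest.raises(ValueError, match="k="):
            knn_loocv(m, "status", k=4)

    def test_single_class_is_error(self, rng):
        m = make_matrix(rng.normal(size=(5, 4)), annotations={"status": ["a"] * 4})
        with pytest.raises(ValueError, match="2 classes"):
            knn_loocv(m, "status", k=1)
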