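import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from stemsig import (
    SortedExperimentTruth,
    build_core_signature,
    compute_snr,
    derive_signature,
    hierarchical_cluster,
    select_top_variable,
    simulate_sorted_experiment,
)
from stemsig.signatures import SignaturePair

from conftest import make_matrix


class TestComputeSnr:
    def test_hand_computed_example(self):
        # A=(1,2,3), B=(4,5,6): sample sds are 1, floors (0.4, 1.0) don't bind
        # snr = (2 - 5) / (1 + 1) = -1.5
        m = make_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        snr = compute_snr(m, ["S1", "S2", "S3"], ["S4", "S5", "S6"])
        assert snr.loc["G1", "snr"] == pytest.approx(-1.5, abs=1e-12)

    def test_constant_equal_gene_has_zero_snr(self):
        m = make_matrix([[5.0, 5.0, 5.0, 5.0]])
        snr = compute_snr(m, ["S1", "S2"], ["S3", "S4"])
        assert snr.loc["G1", "snr"] == 0.0

    def test_sd_floor_binds_at_large_means(self):
        # sds are 1 but floors 0.2*|mean| = 6 and 4 dominate: snr = 10/(6+4)
        m = make_matrix([[29.0, 30.0, 31.0, 19.0, 20.0, 21.0]])
        snr = compute_snr(m, ["S1", "S2", "S3"], ["S4", "S5", "S6"])
        assert snr.loc["G1", "snr"] == pytest.approx(1.0)
        unfloored = compute_snr(
            m, ["S1", "S2", "S3"], ["S4", "S5", "S6"], sd_floor=False
        )
        assert unfloored.loc["G1", "snr"] == pytest.approx(5.0)

    def test_small_group_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match=">= 2 samples"):
            compute_snr(tiny_matrix, ["S1"], ["S2", "S3"])

    def test_unknown_sample_rejected(self, tiny_matrix):
        with pytest.raises(KeyError):
            compute_snr(tiny_matrix, ["S1", "SX"], ["S2", "S3"])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        arrays(
            np.float64,
            (5, 8),
            elements=st.floats(-100, 100, allow_nan=False, width=32),
        )
    )
    def test_antisymmetric_under_group_swap(self, arr):
        m = make_matrix(arr)
        a = [f"S{i}" for i in range(1, 5)]
        b = [f"S{i}" for i in range(5, 9)]
        ab = compute_snr(m, a, b)["snr"].to_numpy()
        ba = compute_snr(m, b, a)["snr"].to_numpy()
        assert (ab == -ba).all()


class TestDeriveSignature:
    @staticmethod
    def _sorted_matrix(values_by_gene):
        """6-sample design: CL1..CL3 x {pos, neg}, one replicate each is too
        few for the pooled sd, so two lines x 3... build explicit layout:
        samples CLi_pos, CLi_neg for i=1..3 plus replicate r2 per arm."""
        samples, ann = [], {"cell_line": [], "cd133_status": []}
        for line in ("CL1", "CL2", "CL3"):
            for status in ("pos", "neg"):
                for rep in ("r1", "r2"):
                    samples.append(f"{line}_{status}_{rep}")
                    ann["cell_line"].append(line)
                    ann["cd133_status"].append(status)
        return make_matrix(values_by_gene, sample_ids=samples, annotations=ann)

    def test_recovers_planted_up_genes_at_large_effect(self):
        # effect 4 sd: per-gene pooled-SNR pass probability ~0.995
        hits_up, hits_down, fp = 0, 0, 0
        for seed in range(10):
            truth = SortedExperimentTruth.default(
                n_genes=500, n_up=30, n_down=30, effect_size=4.0, seed=seed
            )
            m, truth = simulate_sorted_experiment(truth)
            pair = derive_signature(m, name="sig")
            hits_up += len(set(pair.up_genes) & set(truth.planted_up))
            hits_down += len(set(pair.down_genes) & set(truth.planted_down))
            fp += len(set(pair.up_genes) - set(truth.planted_up))
            fp += len(set(pair.down_genes) - set(truth.planted_down))
        assert hits_up / 300 >= 0.95
        assert hits_down / 300 >= 0.95
        assert fp / (2 * 440 * 10) <= 0.01

    def test_vacuous_thresholds_give_empty_signature(self):
        truth = SortedExperimentTruth.default(n_genes=100, seed=1)
        m, _ = simulate_sorted_experiment(truth)
        pair = derive_signature(
            m, up_threshold=np.inf, down_threshold=-np.inf, name="empty"
        )
        assert pair.up_genes == [] and pair.down_genes == []

    def test_sign_inconsistent_gene_excluded(self):
        # G1: strongly up in CL1/CL2 but down in CL3 -> pooled SNR > 1 yet
        # excluded by the per-line consistency rule
        g1 = [4.0, 4.1, -4.0, -4.1, 4.2, 4.3, -3.9, -4.2, -0.5, -0.6, 0.5, 0.6]
        m = self._sorted_matrix([g1])
        pooled = compute_snr(
            m,
            [s for s in m.sample_ids if "_pos_" in s],
            [s for s in m.sample_ids if "_neg_" in s],
        )
        assert pooled.loc["G1", "snr"] > 1.0
        strict = derive_signature(m, name="strict")
        assert "G1" not in strict.up_genes
        lax = derive_signature(m, name="lax", require_sign_consistency=False)
        assert "G1" in lax.up_genes

    def test_missing_arm_names_cell_line(self):
        samples = ["CL1_pos_r1", "CL1_pos_r2", "CL1_neg_r1", "CL1_neg_r2",
                   "CL2_pos_r1", "CL2_pos_r2"]
        ann = {
            "cell_line": ["CL1"] * 4 + ["CL2"] * 2,
            "cd133_status": ["pos", "pos", "neg", "neg", "pos", "pos"],
        }
        m = make_matrix(np.arange(6.0)[None, :], sample_ids=samples, annotations=ann)
        with pytest.raises(ValueError, match="CL2"):
            derive_signature(m)

    def test_up_down_disjoint_by_construction(self):
        with pytest.raises(ValueError, match="disjoint"):
            SignaturePair("bad", ["A", "B"], ["B"])

    def test_stable_under_gene_row_permutation(self):
        truth = SortedExperimentTruth.default(n_genes=300, seed=4)
        m, _ = simulate_sorted_experiment(truth)
        pair1 = derive_signature(m, name="a")
        perm = m.values.sample(frac=1.0, random_state=0)
        m2 = make_matrix(
            perm.to_numpy(), gene_ids=list(perm.index),
            sample_ids=list(perm.columns), annotations=m.annotations.to_dict("list"),
        )
        pair2 = derive_signature(m2, name="b")
        assert set(pair1.up_genes) == set(pair2.up_genes)
        assert set(pair1.down_genes) == set(pair2.down_genes)


class TestSelectTopVariable:
    def test_dominant_gene_selected(self):
        m = make_matrix([[0.0, 100.0, -100.0, 50.0], [1.0, 2.0, 1.5, 1.2],
                         [0.0, 0.1, 0.05, 0.02]])
        assert select_top_variable(m, 1, "mad") == ["G1"]
        assert select_top_variable(m, 1, "variance") == ["G1"]

    def test_constant_matrix_ties_break_lexicographically(self):
        m = make_matrix(np.ones((7, 3)), gene_ids=list("GFEDCBA"))
        assert select_top_variable(m, 5) == ["A", "B", "C", "D", "E"]

    def test_n_equal_gene_count_returns_all(self, tiny_matrix):
        assert len(select_top_variable(tiny_matrix, 3)) == 3

    def test_n_too_large_is_error(self, tiny_matrix):
        with pytest.raises(ValueError, match="exceeds gene count"):
            select_top_variable(tiny_matrix, 4)

    def test_prefix_property(self, rng):
        m = make_matrix(rng.normal(size=(40, 6)))
        for n in range(1, 40):
            assert select_top_variable(m, n) == select_top_variable(m, n + 1)[:n]


class TestBuildCoreSignature:
    def test_exhaustive_enumeration(self):
        assert build_core_signature([["A", "B"], ["B", "C"], ["C", "D"]], 2) == ["B", "C"]

    def test_three_identical_lists(self):
        lists = [["X", "Y"], ["X", "Y"], ["Y", "X"]]
        assert build_core_signature(lists, 2) == ["X", "Y"]
        assert build_core_signature(lists, 3) == ["X", "Y"]

    def test_within_list_duplicates_count_once(self):
        assert build_core_signature([["A", "A"], ["B"]], 2) == []

    def test_min_count_above_list_count_is_error(self):
        with pytest.raises(ValueError, match="min_count"):
            build_core_signature([["A"], ["B"]], 3)


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_zero_height(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0]],
                          index=["a", "b", "c"])
        dend = hierarchical_cluster(df, distance="euclidean")
        assert dend.merge_heights()[0] == 0.0

    def test_anticorrelated_groups_separate_at_two_cut(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame(
            [base, base * 2 + 1, -base, -base * 3 + 5],
            index=["p1", "p2", "n1", "n2"],
        )
        labels = hierarchical_cluster(df, distance="correlation").cut(2)
        assert labels["p1"] == labels["p2"]
        assert labels["n1"] == labels["n2"]
        assert labels["p1"] != labels["n1"]

    def test_sorted_experiment_samples_split_by_status(self):
        truth = SortedExperimentTruth.default(n_genes=500, effect_size=4.0, seed=6)
        m, truth = simulate_sorted_experiment(truth)
        planted = list(truth.planted_up) + list(truth.planted_down)
        df = m.values.loc[planted].T  # samples as items
        labels = hierarchical_cluster(df, distance="correlation").cut(2)
        status = m.annotations["cd133_status"]
        pos_labels = set(labels[status == "pos"])
        neg_labels = set(labels[status == "neg"])
        assert pos_labels.isdisjoint(neg_labels)

    def test_zero_variance_row_rejected_under_correlation(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            hierarchical_cluster(df, distance="correlation")
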