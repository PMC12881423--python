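"""Feature families: omics-derived vectors, assembly, standardization."""

import numpy as np
import pandas as pd
import pytest

from hyperdriver import (
    OmicsTables,
    assemble_core_features,
    combine_features,
    expression_features,
    incidence_features,
    load_comprehensive_features,
    methylation_features,
    mutation_features,
)
from hyperdriver.features import FeatureMatrix, load_feature_matrix, save_feature_matrix


def make_tables(
    mutation=None, lengths=None, tumor=None, normal=None, tb=None, nb=None, genes=("A", "B")
):
    genes = list(genes)
    idx = lambda k: [f"s{i}" for i in range(k)]
    if mutation is None:
        mutation = np.zeros((2, len(genes)), dtype=int)
    if lengths is None:
        lengths = np.full(len(genes), 1000)
    if tumor is None:
        tumor = np.ones((2, len(genes)))
    if normal is None:
        normal = np.ones((2, len(genes)))
    if tb is None:
        tb = np.full((2, len(genes)), 0.5)
    if nb is None:
        nb = np.full((2, len(genes)), 0.5)
    return OmicsTables(
        mutation_counts=pd.DataFrame(mutation, index=idx(len(mutation)), columns=genes),
        gene_lengths=pd.Series(lengths, index=genes),
        tumor_expr=pd.DataFrame(tumor, index=idx(len(tumor)), columns=genes),
        normal_expr=pd.DataFrame(normal, index=idx(len(normal)), columns=genes),
        tumor_beta=pd.DataFrame(tb, index=idx(len(tb)), columns=genes),
        normal_beta=pd.DataFrame(nb, index=idx(len(nb)), columns=genes),
        cancer_type="T",
    )


class TestMutationFeatures:
    def test_fraction_per_kilobase(self):
        # gene A mutated in 2 of 4 samples, length 2000bp -> (2/4)/2 = 0.25
        mut = np.array([[1, 0], [1, 0], [0, 0], [0, 0]])
        t = make_tables(mutation=mut, lengths=[2000, 1000])
        f = mutation_features(t)
        assert f["A"] == pytest.approx(0.25)
        assert f["B"] == 0.0  # never mutated

    def test_ultra_mutated_sample_excluded(self):
        mut = np.array([[1, 0], [0, 0], [0, 0], [600, 600]])
        t = make_tables(mutation=mut)
        f = mutation_features(t, ultra_mut_threshold=1000)
        # the hypermutator (1200 total) is dropped: A mutated in 1 of 3
        assert f["A"] == pytest.approx((1 / 3) / 1.0)

    def test_all_samples_ultra_mutated_is_error(self):
        t = make_tables(mutation=np.full((2, 2), 600))
        with pytest.raises(ValueError, match="retained"):
            mutation_features(t, ultra_mut_threshold=1000)

    def test_sample_size_invariance(self):
        mut = np.array([[1, 0], [0, 1]])
        t1 = make_tables(mutation=mut)
        t2 = make_tables(mutation=np.vstack([mut, mut]))
        pd.testing.assert_series_equal(mutation_features(t1), mutation_features(t2))

    def test_total_count_mode(self):
        mut = np.array([[2, 0], [1, 0]])
        t = make_tables(mutation=mut)
        f = mutation_features(t, per_sample_total=True)
        assert f["A"] == pytest.approx(3.0)  # 3 mutations / 1 kb


class TestExpressionFeatures:
    def test_log2_fold_change(self):
        t = make_tables(tumor=np.full((2, 2), 8.0), normal=np.full((2, 2), 2.0))
        f = expression_features(t)
        assert f["A"] == pytest.approx(np.log2(8.001 / 2.001))
        assert abs(f["A"] - 2.0) < 1e-3

    def test_identical_means_give_zero(self):
        t = make_tables(tumor=np.full((2, 2), 3.0), normal=np.full((2, 2), 3.0))
        assert np.allclose(expression_features(t), 0.0)

    def test_double_zero_cancels_via_pseudocount(self):
        t = make_tables(tumor=np.zeros((2, 2)), normal=np.zeros((2, 2)))
        assert np.allclose(expression_features(t), 0.0)

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(0)
        tum, norm = rng.gamma(2, 3, (3, 2)), rng.gamma(2, 3, (4, 2))
        t = make_tables(tumor=tum, normal=norm)
        t_sw = make_tables(tumor=norm, normal=tum)
        assert np.allclose(expression_features(t), -expression_features(t_sw))

    def test_paired_mode_averages_per_pair_ratios(self):
        tum = np.array([[4.0, 1.0], [16.0, 1.0]])
        norm = np.array([[1.0, 1.0], [4.0, 1.0]])
        t = make_tables(tumor=tum, normal=norm)
        f = expression_features(t, pseudocount=1e-9, pairing={"s0": "s0", "s1": "s1"})
        assert f["A"] == pytest.approx(2.0, abs=1e-6)  # mean(log2 4, log2 4)


class TestMethylationFeatures:
    def test_difference_of_means(self):
        t = make_tables(tb=np.full((2, 2), 0.8), nb=np.full((2, 2), 0.3))
        assert np.allclose(methylation_features(t), 0.5)

    def test_equal_betas_give_zero(self):
        t = make_tables()
        assert np.allclose(methylation_features(t), 0.0)

    def test_bounded_in_unit_interval_difference(self):
        rng = np.random.default_rng(1)
        t = make_tables(tb=rng.random((5, 2)), nb=rng.random((5, 2)))
        f = methylation_features(t)
        assert np.all(f >= -1) and np.all(f <= 1)


def _vectors(ct, genes, base=0.0):
    rng = np.random.default_rng(abs(hash(ct)) % 2**31)
    mk = lambda: pd.Series(base + rng.normal(size=len(genes)), index=genes)
    return ct, (mk(), mk(), mk())


class TestAssembleCoreFeatures:
    def test_sixteen_cancer_types_give_48_columns(self):
        genes = [f"G{i}" for i in range(30)]
        per_cancer = [_vectors(f"CT{i:02d}", genes) for i in range(16)]
        fm, _ = assemble_core_features(per_cancer, genes, mode="pan")
        assert fm.d == 48

    def test_column_order_sorted_by_type_then_omics(self):
        genes = ["G1", "G2"]
        per_cancer = [_vectors("C2", genes), _vectors("C1", genes)]
        fm, _ = assemble_core_features(per_cancer, genes, mode="pan")
        assert fm.column_names == [
            "C1_mut", "C1_expr", "C1_meth", "C2_mut", "C2_expr", "C2_meth",
        ]

    def test_specific_mode_three_columns(self):
        genes = ["G1", "G2"]
        fm, _ = assemble_core_features([_vectors("BRCA", genes)], genes, mode="specific")
        assert fm.d == 3

    def test_specific_mode_rejects_multiple_types(self):
        genes = ["G1"]
        with pytest.raises(ValueError):
            assemble_core_features(
                [_vectors("A", genes), _vectors("B", genes)], genes, mode="specific"
            )

    def test_wrong_vector_count_rejected(self):
        s = pd.Series([1.0], index=["G1"])
        with pytest.raises(ValueError, match="exactly 3"):
            assemble_core_features([("A", (s, s))], ["G1"], mode="pan")

    def test_training_columns_standardized(self):
        genes = [f"G{i}" for i in range(50)]
        per_cancer = [_vectors("A", genes, base=5.0)]
        train_rows = np.arange(30)
        fm, std = assemble_core_features(per_cancer, genes, train_rows=train_rows)
        sub = fm.values[train_rows]
        assert np.max(np.abs(sub.mean(axis=0))) < 1e-8
        assert np.max(np.abs(sub.std(axis=0) - 1)) < 1e-8

    def test_missing_genes_imputed_to_zero(self):
        genes = ["G1", "G2", "G3"]
        s = pd.Series([1.0, 2.0], index=["G1", "G2"])  # G3 missing
        fm, _ = assemble_core_features([("A", (s, s, s))], genes, mode="specific")
        assert np.all(fm.values[2] == 0.0)


class TestIncidenceFeatures:
    def test_equals_incidence_matrix(self, toy_hypergraph):
        fm = incidence_features(toy_hypergraph)
        assert fm.d == toy_hypergraph.n_edges
        assert np.array_equal(
            fm.values, np.asarray(toy_hypergraph.incidence.todense())
        )
        # row sums recover node degrees
        assert fm.values.sum(axis=1).tolist() == [1, 2, 1]


class TestComprehensiveFeatures:
    def _write(self, tmp_path, df):
        p = tmp_path / "comp.tsv"
        df.to_csv(p, sep="\t", index=False)
        return p

    def test_44_column_table(self, tmp_path):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(5, 44)), columns=[f"f{i}" for i in range(44)])
        df.insert(0, "gene", [f"G{i}" for i in range(5)])
        fm, _ = load_comprehensive_features(self._write(tmp_path, df))
        assert fm.d == 44

    def test_missing_value_median_imputed(self, tmp_path):
        df = pd.DataFrame({"gene": ["A", "B", "C"], "f1": [1.0, np.nan, 3.0]})
        fm, _ = load_comprehensive_features(self._write(tmp_path, df), expected_cols=1)
        df2 = pd.DataFrame({"gene": ["A", "B", "C"], "f1": [1.0, 2.0, 3.0]})
        fm2, _ = load_comprehensive_features(self._write(tmp_path, df2), expected_cols=1)
        # median of {1, 3} is 2 -> identical to the explicitly-filled table
        assert np.allclose(fm.values, fm2.values)

    def test_junk_column_dropped_with_warning(self, tmp_path):
        df = pd.DataFrame(
            {"gene": ["A", "B"], "f1": [1.0, 2.0], "junk": ["x", "y"]}
        )
        with pytest.warns(UserWarning, match="junk"):
            fm, _ = load_comprehensive_features(self._write(tmp_path, df), expected_cols=1)
        assert fm.column_names == ["f1"]

    def test_no_gene_column_is_error(self, tmp_path):
        df = pd.DataFrame({"f1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="gene column"):
            load_comprehensive_features(self._write(tmp_path, df))


class TestCombineFeatures:
    def _fm(self, genes, d, tag, offset=0):
        return FeatureMatrix(
            genes=genes,
            values=np.arange(len(genes) * d, dtype=float).reshape(len(genes), d) + offset,
            column_names=[f"{tag}{i}" for i in range(d)],
            family_tag=tag,
        )

    def test_concatenation_width(self):
        genes = ["A", "B"]
        out = combine_features([self._fm(genes, 48, "core"), self._fm(genes, 44, "comp")])
        assert out.d == 92
        assert out.family_tag == "combined"

    def test_single_part_identity_except_tag(self):
        genes = ["A", "B"]
        fm = self._fm(genes, 3, "core")
        out = combine_features([fm])
        assert np.array_equal(out.values, fm.values)
        assert out.family_tag == "combined"

    def test_gene_order_mismatch_is_error(self):
        with pytest.raises(ValueError, match="gene order"):
            combine_features([self._fm(["A", "B"], 2, "x"), self._fm(["B", "A"], 2, "y")])

    def test_name_collision_suffixed(self):
        genes = ["A"]
        a = self._fm(genes, 2, "core")
        b = FeatureMatrix(genes=genes, values=np.ones((1, 2)),
                          column_names=["core0", "other"], family_tag="comp")
        out = combine_features([a, b])
        assert out.column_names == ["core0", "core1", "core0_comp", "other"]


def test_feature_matrix_roundtrip(tmp_path):
    fm = FeatureMatrix(
        genes=["A", "B"], values=np.array([[1.5, 2.0], [3.0, 4.0]]),
        column_names=["x", "y"], family_tag="core",
    )
    save_feature_matrix(fm, tmp_path / "f.tsv")
    fm2 = load_feature_matrix(tmp_path / "f.tsv")
    assert fm2.genes == fm.genes
    assert np.allclose(fm2.values, fm.values)


def test_feature_matrix_rejects_nan():
    with pytest.raises(ValueError, match="NaN"):
        FeatureMatrix(genes=["A"], values=np.array([[np.nan]]), column_names=["x"])
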