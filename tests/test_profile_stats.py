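import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hepatlas.errors import ValidationError
from hepatlas.io_formats import AnnotationDB
from hepatlas.profile_stats import (
    ComplexityClass,
    ComplexityClasses,
    NoAnnotatedGenesError,
    clades_at_root,
    complexity_overrepresentation,
    cv_and_dynamic_range,
    default_classes,
    entropy_null,
    functional_entropy,
    hierarchical_cluster,
    omics_overlap,
    replicate_correlation,
)

from conftest import make_matrix


class TestEntropy:
    def test_uniform_four_categories_gives_ln4(self, disjoint_annotation):
        res = functional_entropy({"g0", "g2", "g4", "g6"}, disjoint_annotation)
        assert res.entropy == pytest.approx(math.log(4), abs=1e-12)
        assert res.n_categories == 4

    def test_single_category_gives_zero(self, disjoint_annotation):
        res = functional_entropy({"g0", "g1"}, disjoint_annotation)
        assert res.entropy == pytest.approx(0.0, abs=1e-12)

    def test_two_one_counts_match_closed_form(self, disjoint_annotation):
        # T = (2, 1): -(2/3 ln 2/3 + 1/3 ln 1/3)
        res = functional_entropy({"g0", "g1", "g2"}, disjoint_annotation)
        expected = -(2 / 3 * math.log(2 / 3) + 1 / 3 * math.log(1 / 3))
        assert res.entropy == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.6365, abs=5e-5)

    def test_multi_category_gene_counts_once_per_category(self):
        db = AnnotationDB({"a": frozenset({"g1", "g2"}), "b": frozenset({"g1"})})
        res = functional_entropy({"g1", "g2"}, db)
        # T = (2, 1) even though only two genes
        assert res.counts.sum() == 3

    def test_unannotated_set_is_an_error_not_zero(self, disjoint_annotation):
        with pytest.raises(NoAnnotatedGenesError):
            functional_entropy({"unknown"}, disjoint_annotation)

    def test_configurable_base(self, disjoint_annotation):
        res = functional_entropy({"g0", "g2"}, disjoint_annotation, base=2)
        assert res.entropy == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_merging_categories_never_increases_entropy(self, a, b, c):
        counts = [x for x in (a + 1, b, c) if x > 0]
        genes = [f"g{i}" for i in range(sum(counts))]
        cats, start = {}, 0
        for ci, n in enumerate(counts):
            cats[f"c{ci}"] = frozenset(genes[start:start + n])
            start += n
        split = functional_entropy(genes, AnnotationDB(cats))
        if len(counts) > 1:
            merged_cats = dict(cats)
            merged_cats["c0"] = cats["c0"] | merged_cats.pop(f"c{len(counts) - 1}")
            merged = functional_entropy(genes, AnnotationDB(merged_cats))
            assert merged.entropy <= split.entropy + 1e-12

    def test_permutation_invariance_in_gene_labels(self, disjoint_annotation):
        s1 = functional_entropy({"g0", "g2", "g3"}, disjoint_annotation).entropy
        # relabeled set with the same category count profile (1, 2)
        s2 = functional_entropy({"g4", "g6", "g7"}, disjoint_annotation).entropy
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestEntropyNull:
    def test_full_universe_draw_is_degenerate(self, disjoint_annotation):
        uni = [f"g{i}" for i in range(8)]
        null = entropy_null(8, disjoint_annotation, uni, draws=1, seed=0)
        assert null.sd == 0.0
        assert null.mean == pytest.approx(
            functional_entropy(uni, disjoint_annotation).entropy
        )

    def test_seed_reproducibility(self, disjoint_annotation):
        uni = [f"g{i}" for i in range(8)]
        n1 = entropy_null(4, disjoint_annotation, uni, draws=25, seed=42)
        n2 = entropy_null(4, disjoint_annotation, uni, draws=25, seed=42)
        np.testing.assert_array_equal(n1.values, n2.values)

    def test_oversized_set_rejected(self, disjoint_annotation):
        with pytest.raises(ValidationError):
            entropy_null(9, disjoint_annotation, [f"g{i}" for i in range(8)], seed=0)

    def test_sampling_mean_matches_enumeration_oracle(self):
        # reduced universe of 12 genes, 4 disjoint categories of 3
        genes = [f"g{i}" for i in range(12)]
        db = AnnotationDB(
            {f"c{c}": frozenset(genes[3 * c:3 * c + 3]) for c in range(4)}
        )
        exact = np.mean([
            functional_entropy(sub, db).entropy
            for sub in itertools.combinations(genes, 5)
        ])
        null = entropy_null(5, db, genes, draws=2000, seed=3)
        se = null.sd / math.sqrt(null.draws)
        assert abs(null.mean - exact) < 3 * se


class TestCVDynamicRange:
    def test_flat_gene_has_zero_cv(self):
        m = make_matrix([[5.0, 5.0, 5.0, 5.0], [1.0, 1.0, 1.0, 3.0]])
        cv, _ = cv_and_dynamic_range(m)
        assert cv["g0"] == pytest.approx(0.0)
        # mean 1.5, population sd sqrt(0.75)
        assert cv["g1"] == pytest.approx(math.sqrt(0.75) / 1.5, abs=1e-12)
        assert cv["g1"] == pytest.approx(0.5774, abs=5e-5)

    def test_dynamic_range_log10_span(self):
        m = make_matrix([[1.0, 2.0], [1e6, 2.0], [0.0, 2.0]], cells=("HC", "KC"))
        _, dr = cv_and_dynamic_range(m)
        assert dr["HC_1"] == pytest.approx(6.0)
        assert dr["KC_1"] == pytest.approx(0.0)

    def test_single_cell_type_rejected(self):
        with pytest.raises(ValidationError):
            cv_and_dynamic_range(make_matrix([[1.0]], cells=("HC",)))


class TestReplicateCorrelation:
    def test_identical_columns_correlate_perfectly(self):
        vals = np.random.default_rng(0).lognormal(size=10)
        m = make_matrix(np.column_stack([vals, vals]), cells=("HC", "KC"))
        df = replicate_correlation(m)
        assert df.rho.iloc[0] == pytest.approx(1.0)

    def test_rank_reversed_pair(self):
        a = np.arange(1.0, 11.0)
        m = make_matrix(np.column_stack([a, a[::-1]]), cells=("HC", "KC"))
        df = replicate_correlation(m)
        assert df.rho.iloc[0] == pytest.approx(-1.0)

    def test_within_and_between_labels(self, cohort_default):
        df = replicate_correlation(cohort_default.proteome)
        assert set(df.kind) == {"within", "between"}
        n = cohort_default.proteome.n_samples
        assert len(df) == n * (n - 1) // 2

    def test_too_few_shared_genes_gives_nan(self):
        m = make_matrix([[1.0, 0.0], [0.0, 2.0], [0.0, 3.0]], cells=("HC", "KC"))
        df = replicate_correlation(m)
        assert np.isnan(df.rho.iloc[0])


class TestHierarchicalCluster:
    def test_identical_triplet_forms_one_clade(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(size=20)
        w = rng.lognormal(size=20)
        m = make_matrix(np.column_stack([v, v, v, w]), cells=("A", "B", "C", "D"))
        res = hierarchical_cluster(m)
        clade_a, clade_b = clades_at_root(res)
        assert min(clade_a, clade_b, key=len) == frozenset({"D_1"})

    def test_column_permutation_leaves_tree_unchanged(self, cohort_default):
        m = cohort_default.proteome
        from hepatlas.io_formats import AbundanceMatrix, SampleInfo

        res1 = hierarchical_cluster(m)
        perm = list(m.data.columns)[::-1]
        samples = [SampleInfo.from_label(c) for c in perm]
        m2 = AbundanceMatrix(m.data[perm], samples, unit="fot")
        res2 = hierarchical_cluster(m2)
        assert res1.leaf_order == res2.leaf_order
        np.testing.assert_allclose(res1.linkage, res2.linkage)

    def test_distance_matrix_symmetric_zero_diagonal(self, cohort_default):
        res = hierarchical_cluster(cohort_default.proteome)
        D = res.distances.to_numpy()
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)

    def test_constant_column_names_sample(self):
        m = make_matrix([[1.0, 2.0, 1.0], [1.0, 3.0, 2.0], [1.0, 4.0, 3.0]],
                        cells=("A", "B", "C"))
        with pytest.raises(ValidationError, match="A_1"):
            hierarchical_cluster(m)


class TestComplexity:
    @pytest.fixture()
    def classes(self):
        genes = [f"g{i}" for i in range(100)]
        attrs = pd.DataFrame(
            {
                "gene_length": [30000 if i < 20 else 1000 for i in range(100)],
                "crm_count": [5 if i < 10 else 1 for i in range(100)],
                "protein_length": [600 if i < 30 else 100 for i in range(100)],
                "domain_repeat_count": [3 if i < 40 else 0 for i in range(100)],
            },
            index=genes,
        )
        return default_classes(attrs), genes

    def test_cell_set_equal_universe_gives_fold_one(self, classes):
        cc, genes = classes
        df = complexity_overrepresentation(genes, genes, cc)
        assert np.allclose(df["fold"], 1.0)

    def test_fold_arithmetic(self, classes):
        cc, genes = classes
        # GL: 20/100 in universe; cell set of 10 with 6 long -> 0.6/0.2 = 3
        cell = genes[:6] + genes[90:94]
        df = complexity_overrepresentation(cell, genes, cc).set_index("class")
        assert df.loc["GL", "fold"] == pytest.approx(3.0)

    def test_empty_intersection_fold_zero_p_one(self, classes):
        cc, genes = classes
        df = complexity_overrepresentation(genes[60:70], genes, cc).set_index("class")
        assert df.loc["GL", "fold"] == 0.0
        assert df.loc["GL", "p"] == pytest.approx(1.0)

    def test_class_absent_from_universe_rejected(self, classes):
        cc, genes = classes
        with pytest.raises(ValidationError, match="GL"):
            complexity_overrepresentation(genes[50:60], genes[50:], cc)

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValidationError):
            ComplexityClass(pd.Series([1.0]), threshold=0.0)


class TestOmicsOverlap:
    def test_identical_sets_all_both(self):
        m = make_matrix([[5.0], [5.0]], genes=["a", "b"], cells=("HC",), unit="fpkm")
        part = omics_overlap({"a", "b"}, m)
        assert part.both == frozenset({"a", "b"})
        assert not part.proteome_only and not part.transcriptome_only

    def test_fpkm_exactly_one_excluded(self):
        m = make_matrix([[1.0], [1.0001]], genes=["a", "b"], cells=("HC",), unit="fpkm")
        part = omics_overlap(set(), m)
        assert part.expressed_transcriptome == frozenset({"b"})

    def test_toy_partition_and_secretome_merge(self):
        m = make_matrix([[0.0], [5.0], [5.0], [5.0]], genes=["a", "b", "c", "d"],
                        cells=("HC",), unit="fpkm")
        part = omics_overlap({"a", "b", "c"}, m)
        assert part.proteome_only == frozenset({"a"})
        assert part.transcriptome_only == frozenset({"d"})
        assert part.both == frozenset({"b", "c"})
        part2 = omics_overlap({"a", "b", "c"}, m, secretome_set={"d"})
        assert part2.both == frozenset({"b", "c", "d"})
        assert part2.transcriptome_only == frozenset()
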