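import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dyadmet.core import DataError
from dyadmet.dyads import (
    DyadFeatureTable,
    assemble_dataset,
    build_random_dyads,
    build_true_dyads,
    grouped_dyad_split,
    pair_dispersion,
    split_train_test,
)

from conftest import make_matrix, scaled_synthetic_pair


class TestPairDispersion:
    def test_equal_values_give_exactly_zero(self):
        assert pair_dispersion(np.array([0.1]), np.array([0.1]))[0] == 0.0

    def test_two_point_sample_std(self):
        # sample std (ddof=1) of {0, 1} is 1/sqrt(2)
        assert pair_dispersion(np.array([0.0]), np.array([1.0]))[0] == pytest.approx(
            1 / np.sqrt(2), abs=1e-15
        )

    def test_identical_vectors_all_zero(self):
        v = np.linspace(0, 1, 9)
        assert np.all(pair_dispersion(v, v) == 0.0)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            pair_dispersion(np.zeros(3), np.zeros(4))

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.floats(0, 1, allow_nan=False),
        b=st.floats(0, 1, allow_nan=False),
        c=st.floats(0, 1, allow_nan=False),
    )
    def test_nonnegative_and_monotone_in_gap(self, a, b, c):
        d_ab = pair_dispersion(np.array([a]), np.array([b]))[0]
        d_ac = pair_dispersion(np.array([a]), np.array([c]))[0]
        assert d_ab >= 0.0
        if abs(a - b) < abs(a - c):
            assert d_ab < d_ac


class TestTrueDyads:
    def test_one_row_per_complete_family(self, small_cohort):
        mothers, children, *_ = small_cohort
        table = build_true_dyads(mothers, children)
        assert len(table) == mothers.n_subjects
        assert set(table.labels) == {1}

    def test_incomplete_family_skipped(self):
        m = make_matrix([[0.1], [0.5], [0.9]], "mother", scaled=True,
                        families=["f1", "f2", "f3"])
        c = make_matrix([[0.2], [0.4]], "child", scaled=True,
                        subjects=["C0", "C1"], families=["f1", "f2"])
        table = build_true_dyads(m, c)
        assert len(table) == 2
        assert table.skipped_families == ["f3"]

    def test_feature_equals_pair_dispersion(self):
        m = make_matrix([[0.3, 1.0]], "mother", scaled=True, families=["f1"])
        c = make_matrix([[0.7, 0.25]], "child", scaled=True, families=["f1"])
        table = build_true_dyads(m, c)
        expected = pair_dispersion(np.array([0.3, 1.0]), np.array([0.7, 0.25]))
        assert np.allclose(table.X[0], expected)

    def test_duplicate_family_member_rejected(self):
        c = make_matrix([[0.2], [0.4]], "child", families=["f1", "f1"], scaled=True)
        m = make_matrix([[0.1]], "mother", families=["f1"], scaled=True)
        with pytest.raises(DataError, match="f1"):
            build_true_dyads(m, c)

    def test_unscaled_rejected(self, tiny_pair):
        m, c = tiny_pair
        with pytest.raises(DataError, match="scaled"):
            build_true_dyads(m, c)


class TestRandomDyads:
    def test_count_follows_shuffles_and_drop(self):
        mothers, children, *_ = scaled_synthetic_pair(
            seed=2, n_families=100, n_metabolites=5, n_heritable=0
        )
        table = build_random_dyads(mothers, children, n_shuffles=2,
                                   drop_fraction=0.30, seed=4)
        assert len(table) == 140  # 2 * 100 * (1 - 0.30)

    def test_deterministic_under_seed(self, small_cohort):
        mothers, children, *_ = small_cohort
        a = build_random_dyads(mothers, children, seed=5)
        b = build_random_dyads(mothers, children, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_no_true_family_contamination(self, small_cohort):
        mothers, children, *_ = small_cohort
        table = build_random_dyads(mothers, children, seed=6)
        fam_m = mothers.family_ids
        fam_c = children.family_ids
        shared_family = [
            fam_m[mo] == fam_c[ch]
            for mo, ch in zip(table.table["mother_id"], table.table["child_id"])
        ]
        assert not any(shared_family)

    def test_too_few_families_rejected(self):
        m = make_matrix([[0.1]], "mother", scaled=True)
        c = make_matrix([[0.2]], "child", scaled=True)
        with pytest.raises(DataError, match="2 complete families"):
            build_random_dyads(m, c)


class TestAssembleAndSplit:
    def test_concatenation_counts(self, small_cohort):
        mothers, children, *_ = small_cohort
        true_d = build_true_dyads(mothers, children)
        rand_d = build_random_dyads(mothers, children, seed=8)
        ds = assemble_dataset(true_d, rand_d)
        assert len(ds) == len(true_d) + len(rand_d)
        assert set(ds.labels) == {0, 1}

    def test_empty_random_rejected(self, small_cohort):
        mothers, children, *_ = small_cohort
        true_d = build_true_dyads(mothers, children)
        empty = DyadFeatureTable(table=true_d.table.iloc[0:0])
        with pytest.raises(DataError, match="non-empty"):
            assemble_dataset(true_d, empty)

    def test_duplicate_pair_across_inputs_rejected(self, small_cohort):
        mothers, children, *_ = small_cohort
        true_d = build_true_dyads(mothers, children)
        dup = DyadFeatureTable(table=true_d.table.copy())
        with pytest.raises(DataError, match="duplicated"):
            assemble_dataset(true_d, dup)

    def test_stratified_split_arithmetic(self, small_dataset):
        n = len(small_dataset)
        train, test = split_train_test(small_dataset, 0.20, seed=1)
        assert len(test) == int(np.ceil(0.20 * n))
        assert len(train) + len(test) == n
        # label proportions preserved within rounding
        p_all = small_dataset.labels.mean()
        assert abs(test.labels.mean() - p_all) < 2 / len(test)

    def test_zero_test_fraction_warns(self, small_dataset):
        train, test = split_train_test(small_dataset, 0.0, seed=1)
        assert len(test) == 0 and len(train) == len(small_dataset)

    def test_split_deterministic(self, small_dataset):
        a = split_train_test(small_dataset, 0.2, seed=3)[0]
        b = split_train_test(small_dataset, 0.2, seed=3)[0]
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_single_class_rejected(self, small_cohort):
        mothers, children, *_ = small_cohort
        true_d = build_true_dyads(mothers, children)
        with pytest.raises(DataError, match="both labels"):
            split_train_test(true_d, 0.2, seed=0)


class TestGroupedSplit:
    def test_no_subject_overlap_between_sides(self, small_split):
        train, test = small_split
        for col in ("mother_id", "child_id"):
            assert not set(train.table[col]) & set(test.table[col])

    def test_both_classes_on_both_sides(self, small_split):
        train, test = small_split
        assert set(train.labels) == {0, 1}
        assert set(test.labels) == {0, 1}

    def test_deterministic(self, small_cohort):
        mothers, children, *_ = small_cohort
        a_tr, _ = grouped_dyad_split(mothers, children, seed=11)
        b_tr, _ = grouped_dyad_split(mothers, children, seed=11)
        pd.testing.assert_frame_equal(a_tr.table, b_tr.table)


def test_heritable_dispersion_separates_true_from_random(small_cohort):
    """Planted heritable metabolites: true-dyad dispersion is stochastically
    smaller than random-dyad dispersion; non-heritable show no such shift."""
    from scipy.stats import mannwhitneyu

    mothers, children, _, _, truth = small_cohort
    true_d = build_true_dyads(mothers, children)
    rand_d = build_random_dyads(mothers, children, seed=17)
    planted = truth.heritable_set
    for met in planted:
        p = mannwhitneyu(true_d.features[met], rand_d.features[met],
                         alternative="less").pvalue
        assert p < 0.01, met
    others = [f for f in true_d.feature_names if f not in planted][:20]
    null_p = [
        mannwhitneyu(true_d.features[f], rand_d.features[f]).pvalue for f in others
    ]
    assert np.mean(np.array(null_p) > 0.05) >= 0.8
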