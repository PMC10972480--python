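import numpy as np
import pandas as pd
import pytest

from dyadmet.core import DataError
from dyadmet.preprocess import (
    PreprocessLog,
    exclude_class,
    filter_intercorrelated,
    filter_low_variance,
    filter_missing,
    impute_detection_limit,
    minmax_scale_within_group,
    preprocess_pipeline,
)

from conftest import make_matrix, scaled_synthetic_pair


def _pair_with(values_m, values_c, **kw):
    return make_matrix(values_m, "mother", **kw), make_matrix(values_c, "child", **kw)


class TestFilterMissing:
    def test_union_rule_over_threshold_in_one_cohort(self):
        nan = np.nan
        # metA missing in 2/5 mothers (40%), complete in children
        m = make_matrix([[nan, 1], [nan, 2], [1, 3], [2, 4], [3, 5]], "mother",
                        names=["metA", "metB"])
        c = make_matrix([[1, 1], [2, 2], [3, 3], [4, 4], [5, 5]], "child",
                        names=["metA", "metB"])
        m2, c2, log = filter_missing(m, c, threshold=0.33)
        assert m2.metabolite_names == ["metB"] == c2.metabolite_names
        assert log.dropped_missing == ["metA"]

    def test_exactly_at_threshold_is_kept(self):
        nan = np.nan
        m = make_matrix([[nan], [1], [2]], "mother")  # exactly 1/3 missing
        c = make_matrix([[nan], [1], [2]], "child")
        m2, _, log = filter_missing(m, c, threshold=1 / 3)
        assert m2.n_metabolites == 1 and log.dropped_missing == []

    def test_complete_matrix_identity(self, tiny_pair):
        m, c = tiny_pair
        m2, c2, log = filter_missing(m, c)
        pd.testing.assert_frame_equal(m2.data, m.data)
        assert log.dropped_missing == []

    def test_mismatched_metabolites_rejected(self):
        m = make_matrix([[1.0]], "mother", names=["a"])
        c = make_matrix([[1.0]], "child", names=["b"])
        with pytest.raises(DataError):
            filter_missing(m, c)


class TestImpute:
    def test_tenth_of_minimum_observed(self):
        m = make_matrix([[0.5], [2.0], [np.nan]], "mother")
        out = impute_detection_limit(m, fraction=0.1)
        assert out.data.iloc[2, 0] == pytest.approx(0.05)
        assert out.data.iloc[0, 0] == 0.5  # observed cells untouched

    def test_no_missing_identity(self):
        m = make_matrix([[1.0], [2.0]], "mother")
        out = impute_detection_limit(m)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_zero_minimum_imputes_zero_with_warning(self):
        m = make_matrix([[0.0], [np.nan], [2.0]], "mother")
        log = PreprocessLog()
        out = impute_detection_limit(m, 0.1, log)
        assert out.data.iloc[1, 0] == 0.0
        assert any("0" in w for w in log.warnings)

    def test_all_missing_column_rejected(self):
        m = make_matrix([[np.nan], [np.nan]], "mother")
        with pytest.raises(DataError, match="no observed"):
            impute_detection_limit(m)


class TestScale:
    def test_minmax_definition(self):
        m = make_matrix([[1.0], [3.0], [5.0]], "mother")
        out = minmax_scale_within_group(m)
        assert out.data.iloc[:, 0].tolist() == [0.0, 0.5, 1.0]
        assert out.scaled

    def test_constant_column_maps_to_zero(self):
        m = make_matrix([[2.0], [2.0], [2.0]], "mother")
        out = minmax_scale_within_group(m)
        assert out.data.iloc[:, 0].tolist() == [0.0, 0.0, 0.0]

    def test_cohorts_scaled_independently(self):
        # the lowest mother maps to 0 in the mothers' scale even though the
        # children span a different concentration range entirely
        m = make_matrix([[0.1], [0.5], [1.0]], "mother")
        c = make_matrix([[100.0], [200.0], [300.0]], "child")
        ms = minmax_scale_within_group(m)
        cs = minmax_scale_within_group(c)
        assert ms.data.iloc[0, 0] == 0.0
        assert cs.data.iloc[0, 0] == 0.0

    def test_missing_values_rejected(self):
        m = make_matrix([[np.nan], [1.0]], "mother")
        with pytest.raises(DataError, match="impute"):
            minmax_scale_within_group(m)

    def test_nonconstant_columns_attain_both_bounds(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.lognormal(size=(20, 8)), "mother")
        out = minmax_scale_within_group(m)
        assert np.allclose(out.values.min(axis=0), 0.0)
        assert np.allclose(out.values.max(axis=0), 1.0)


class TestVarianceFilter:
    def _scaled_pair(self, vm, vc, names=None):
        m, c = _pair_with(vm, vc, names=names)
        return minmax_scale_within_group(m), minmax_scale_within_group(c)

    def test_drops_exactly_floor_fraction(self):
        rng = np.random.default_rng(1)
        vm = rng.random((30, 10))
        vc = rng.random((30, 10))
        vm[:, 4] = 0.5 + 0.001 * rng.random(30)  # smallest pooled variance
        vc[:, 4] = 0.5 + 0.001 * rng.random(30)
        ms = make_matrix(vm, "mother", scaled=True)
        cs = make_matrix(vc, "child", scaled=True)
        m2, c2, log = filter_low_variance(ms, cs, 0.10)
        assert m2.n_metabolites == 9
        assert log.dropped_variance == ["met4"]

    def test_zero_fraction_identity(self, tiny_pair):
        m, c = tiny_pair
        ms, cs = minmax_scale_within_group(m), minmax_scale_within_group(c)
        m2, _, log = filter_low_variance(ms, cs, 0.0)
        assert m2.metabolite_names == ms.metabolite_names
        assert log.dropped_variance == []

    def test_tie_drops_later_column(self):
        base = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [0.5, 0.5, 0.9]])
        m = make_matrix(base, "mother", scaled=True, names=["a", "b", "c"])
        c = make_matrix(base, "child", scaled=True, names=["a", "b", "c"])
        # columns a and b identical -> tied minimal variance; 3*0.34 -> 1 slot
        m2, _, log = filter_low_variance(m, c, 0.34)
        assert log.dropped_variance == ["b"]
        assert m2.metabolite_names == ["a", "c"]


class TestCorrelationFilter:
    def test_perfectly_correlated_second_dropped(self):
        vals = np.array([[0.0, 0.0], [0.5, 0.5], [1.0, 1.0]])
        m = make_matrix(vals, "mother", scaled=True, names=["a", "b"])
        c = make_matrix(vals, "child", scaled=True, names=["a", "b"])
        m2, _, log = filter_intercorrelated(m, c, 0.90)
        assert m2.metabolite_names == ["a"]
        assert log.dropped_correlation[0][:2] == ("a", "b")

    def test_uncorrelated_identity(self):
        rng = np.random.default_rng(3)
        vals = rng.random((50, 5))
        m = make_matrix(vals, "mother", scaled=True)
        c = make_matrix(rng.random((50, 5)), "child", scaled=True)
        m2, _, log = filter_intercorrelated(m, c, 0.90)
        assert m2.n_metabolites == 5 and log.dropped_correlation == []

    def test_greedy_chain_keeps_only_first(self):
        # a, b, c mutually |r| > 0.9: greedy scan drops b and c against a
        base = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        vals = np.column_stack([base, base * 0.99 + 0.005, 1.0 - base])
        m = make_matrix(vals, "mother", scaled=True, names=["a", "b", "c"])
        c = make_matrix(vals, "child", scaled=True, names=["a", "b", "c"])
        m2, _, log = filter_intercorrelated(m, c, 0.90)
        assert m2.metabolite_names == ["a"]
        assert {(k, d) for k, d, _ in log.dropped_correlation} == {("a", "b"), ("a", "c")}

    def test_anticorrelated_duplicates_removed(self):
        base = np.linspace(0, 1, 8)
        vals = np.column_stack([base, 1.0 - base])
        m = make_matrix(vals, "mother", scaled=True, names=["a", "b"])
        c = make_matrix(vals, "child", scaled=True, names=["a", "b"])
        m2, _, _ = filter_intercorrelated(m, c, 0.90)
        assert m2.metabolite_names == ["a"]


class TestExcludeClass:
    def _annotation(self):
        return pd.DataFrame(
            {
                "name": ["met0", "met1", "met2", "met3"],
                "super_class": ["Xenobiotics", "Lipid", "Xenobiotics", "Amino Acid"],
                "annotated": [True] * 4,
            }
        )

    def test_removes_class_members(self, tiny_pair):
        m, c = tiny_pair
        m2, c2, log = exclude_class(m, c, self._annotation(), "Xenobiotics")
        assert m2.metabolite_names == ["met1", "met3"]
        assert log.excluded_class == ["met0", "met2"]

    def test_unknown_class_warns_identity(self, tiny_pair):
        m, c = tiny_pair
        with pytest.warns(UserWarning, match="Nonexistent"):
            m2, _, _ = exclude_class(m, c, self._annotation(), "Nonexistent")
        assert m2.metabolite_names == m.metabolite_names


class TestPipeline:
    def test_order_and_log_partition(self):
        mothers, children, annotation, *_ = scaled_synthetic_pair(seed=3)
        # rebuild from raw (unscaled) data
        from dyadmet.synthetic import SyntheticConfig, generate

        cfg = SyntheticConfig(n_families=60, n_metabolites=30, n_heritable=4,
                              missing_rate=0.1, seed=3)
        m, c, ann, *_ = generate(cfg)
        m2, c2, log = preprocess_pipeline(m, c, annotation=ann)
        survivors = set(m2.metabolite_names)
        dropped = (set(log.dropped_missing) | set(log.dropped_variance)
                   | {d for _, d, _ in log.dropped_correlation})
        assert survivors | dropped == set(m.metabolite_names)
        assert not survivors & dropped
        assert m2.scaled and c2.scaled
        assert m2.metabolite_names == c2.metabolite_names

    def test_deterministic(self):
        from dyadmet.synthetic import SyntheticConfig, generate

        cfg = SyntheticConfig(n_families=40, n_metabolites=25, missing_rate=0.08, seed=9)
        m, c, *_ = generate(cfg)
        a = preprocess_pipeline(m, c)[0]
        b = preprocess_pipeline(m, c)[0]
        pd.testing.assert_frame_equal(a.data, b.data)
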