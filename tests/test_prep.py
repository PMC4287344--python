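import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metaboqtl.errors import InsufficientDataError
from metaboqtl.prep import (
    TraitVector,
    exclude_samples,
    partial_correlation,
    prepare_trait,
    rank_transform,
    remove_outliers,
)


class TestRemoveOutliers:
    def test_gross_outlier_removed(self):
        rng = np.random.default_rng(0)
        vals = np.append(rng.standard_normal(100), 50.0)
        out = remove_outliers(TraitVector.from_values(vals), k=4)
        assert np.isnan(out.values[-1])
        assert np.isfinite(out.values[:-1]).all()

    def test_constant_vector_untouched(self):
        out = remove_outliers(TraitVector.from_values(np.full(10, 3.0)))
        assert np.isfinite(out.values).all()

    def test_missing_passthrough_and_excluded_from_moments(self):
        vals = np.array([0.0, 1.0, np.nan, 0.5, 100.0])
        out = remove_outliers(TraitVector.from_values(vals), k=1)
        assert np.isnan(out.values[2])  # still missing
        assert np.isnan(out.values[4])  # removed
        assert np.isfinite(out.values[[0, 1, 3]]).all()

    def test_single_shot_is_idempotent(self):
        """No re-estimation: a second pass removes nothing new."""
        rng = np.random.default_rng(1)
        vals = np.append(rng.standard_normal(200), [30.0, -25.0])
        once = remove_outliers(TraitVector.from_values(vals), k=4)
        twice = remove_outliers(once, k=4)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_all_missing_rejected(self):
        with pytest.raises(InsufficientDataError):
            remove_outliers(TraitVector.from_values([np.nan, np.nan]))


class TestRankTransform:
    def test_definition_with_missing(self):
        out = rank_transform(TraitVector.from_values([3.1, 2.0, np.nan, 5.5]))
        np.testing.assert_array_equal(out.values[[0, 1, 3]], [2, 1, 3])
        assert np.isnan(out.values[2])

    def test_ties_get_average_rank(self):
        out = rank_transform(TraitVector.from_values([1, 1, 2]))
        np.testing.assert_array_equal(out.values, [1.5, 1.5, 3])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    def test_monotone_transform_invariance(self, vals):
        t = TraitVector.from_values(vals)
        direct = rank_transform(t)
        # multiply by a power of two: exact, strictly monotone, no collisions
        squeezed = rank_transform(TraitVector.from_values(4.0 * t.values))
        np.testing.assert_array_equal(direct.values, squeezed.values)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-100, 100) | st.just(np.nan), min_size=1, max_size=40))
    def test_rank_sum_property(self, vals):
        t = TraitVector.from_values(vals)
        m = int(np.isfinite(t.values).sum())
        if m == 0:
            with pytest.raises(InsufficientDataError):
                rank_transform(t)
            return
        out = rank_transform(t)
        assert np.nansum(out.values) == pytest.approx(m * (m + 1) / 2)


class TestExcludeSamples:
    def test_no_flags_retains_all(self):
        meta = pd.DataFrame({"v": range(5)}, index=list("abcde"))
        flags = pd.DataFrame({"med": [False] * 5}, index=list("abcde"))
        kept, counts = exclude_samples(meta, flags)
        assert kept == list("abcde") and counts == {"med": 0}

    def test_all_flagged_empty(self):
        meta = pd.DataFrame({"v": range(3)}, index=list("abc"))
        flags = pd.DataFrame({"med": [True] * 3}, index=list("abc"))
        kept, counts = exclude_samples(meta, flags)
        assert kept == [] and counts == {"med": 3}

    def test_unknown_id_raises(self):
        meta = pd.DataFrame({"v": [1]}, index=["a"])
        flags = pd.DataFrame({"med": [True]}, index=["zzz"])
        with pytest.raises(KeyError):
            exclude_samples(meta, flags)


class TestPartialCorrelation:
    def test_perfect_correlation(self):
        x = TraitVector.from_values(np.arange(20.0))
        r, p = partial_correlation(x, x)
        assert r == pytest.approx(1.0) and p == 0.0

    def test_independent_series_null(self):
        rng = np.random.default_rng(2)
        rs, ps = [], []
        for _ in range(200):
            x = TraitVector.from_values(rng.standard_normal(200))
            y = TraitVector.from_values(rng.standard_normal(200))
            r, p = partial_correlation(x, y)
            rs.append(r); ps.append(p)
        assert abs(np.mean(rs)) < 0.02
        # p-values uniform under the null
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_adjustment_removes_shared_covariate(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(500)
        x = TraitVector.from_values(z + 0.05 * rng.standard_normal(500))
        y = TraitVector.from_values(z)
        r_adj, _ = partial_correlation(x, y, [TraitVector.from_values(z)])
        assert abs(r_adj) < 0.1

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(80),
                "z": rng.standard_normal(80),
            }
        )
        df["y"] = 0.5 * df.x + 0.3 * df.z + rng.standard_normal(80)
        want = pingouin.partial_corr(df, x="x", y="y", covar="z")
        r, p = partial_correlation(
            TraitVector.from_values(df.x),
            TraitVector.from_values(df.y),
            [TraitVector.from_values(df.z)],
        )
        assert r == pytest.approx(float(want["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(want["p_val"].iloc[0]), rel=1e-6)

    def test_insufficient_cases(self):
        x = TraitVector.from_values([1.0, 2.0, np.nan])
        with pytest.raises(InsufficientDataError):
            partial_correlation(x, x, [x])


class TestPipeline:
    def test_order_and_log(self):
        rng = np.random.default_rng(5)
        meta = pd.DataFrame(
            {
                "trait": np.append(rng.standard_normal(99), 60.0),
                "med": [True] * 10 + [False] * 90,
            },
            index=[f"s{i}" for i in range(100)],
        )
        flags = pd.DataFrame({"medication": meta.pop("med")})
        series, log = prepare_trait(meta, "trait", exclusion_flags=flags)
        assert log["n_retained"] == 90
        assert log["excluded"] == {"medication": 10}
        assert log["history"][0].startswith("remove_outliers")
        assert log["history"][1] == "rank_transform"
        vals = series.dropna()
        assert sorted(vals) == list(np.arange(1.0, len(vals) + 1))
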