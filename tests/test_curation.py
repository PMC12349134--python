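"""Curation protocol: pruning, encoding, winsorization, imputation, ordering."""

import numpy as np
import pandas as pd
import pytest

import phenostrat as ps
from phenostrat.curation import (
    CurationConfig,
    curate,
    drop_near_constant,
    encode_discrete,
    impute_missing,
    prune_missingness,
    retain_events,
    robust_zscore_winsorize,
)
from conftest import make_table


class TestPruneMissingness:
    def test_retained_set_matches_counting_oracle(self):
        rng = np.random.default_rng(0)
        n = 200
        fracs = [0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95]
        cols = []
        for f in fracs:
            col = rng.normal(size=n)
            col[: int(round((1 - f) * n))] = np.nan
            cols.append(col)
        table = make_table(np.column_stack(cols))
        pruned, report = prune_missingness(table, 0.80)
        # oracle: count non-missing per column directly
        keep_oracle = [
            name for name in table.variable_names
            if table.values[name].notna().sum() / n >= 0.80
        ]
        assert pruned.variable_names == keep_oracle
        assert len(report.dropped_missingness) == len(fracs) - len(keep_oracle)

    def test_boundary_79_percent_dropped(self):
        x = np.random.default_rng(1).normal(size=(100, 2))
        x[:21, 0] = np.nan  # populated 79%
        pruned, _ = prune_missingness(make_table(x), 0.80)
        assert pruned.variable_names == ["x001"]

    def test_fully_populated_retained(self):
        x = np.random.default_rng(2).normal(size=(50, 3))
        pruned, report = prune_missingness(make_table(x), 0.80)
        assert pruned.n_variables == 3 and not report.dropped_missingness

    def test_all_dropped_raises_with_threshold(self):
        x = np.full((10, 2), np.nan)
        x[0] = 1.0
        with pytest.raises(ValueError, match="min_populated"):
            prune_missingness(make_table(x), 0.80)


class TestNearConstant:
    def test_995_of_1000_dropped(self):
        col = np.zeros(1000)
        col[:5] = 1.0  # top value fraction 0.995 > 0.99
        out, report = drop_near_constant(make_table(np.column_stack([col, np.arange(1000.0)])))
        assert out.variable_names == ["x001"]
        assert report.dropped_near_constant[0][1] == pytest.approx(0.995)

    def test_balanced_binary_retained(self):
        col = np.repeat([0.0, 1.0], 500)
        out, _ = drop_near_constant(make_table(col[:, None]))
        assert out.n_variables == 1

    def test_constant_dropped(self):
        x = np.column_stack([np.ones(100), np.arange(100.0)])
        out, _ = drop_near_constant(make_table(x))
        assert out.variable_names == ["x001"]


class TestEncodeDiscrete:
    def test_five_levels_give_five_exclusive_indicators(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 5, size=200).astype(float)
        table = make_table(col[:, None], dtypes=["discrete"])
        out, report = encode_discrete(table)
        assert out.n_variables == 5
        assert np.all(out.as_array().sum(axis=1) == 1.0)
        assert report.encoded["x000"] == [f"x000={k}" for k in range(5)]

    def test_binary_row_sums_one(self):
        col = np.repeat([0.0, 1.0], 20)
        out, _ = encode_discrete(make_table(col[:, None], dtypes=["discrete"]))
        assert out.n_variables == 2
        assert np.all(out.as_array().sum(axis=1) == 1.0)

    def test_missing_parent_propagates_to_children(self):
        col = np.array([0.0, 1.0, 2.0, np.nan, 1.0])
        out, _ = encode_discrete(make_table(col[:, None], dtypes=["discrete"]))
        # direct expansion oracle: row 3 missing in all three children
        assert out.values.iloc[3].isna().all()
        assert not out.values.drop(out.values.index[3]).isna().any().any()

    def test_single_level_raises(self):
        col = np.zeros(10)
        with pytest.raises(ValueError, match="near-constant"):
            encode_discrete(make_table(col[:, None], dtypes=["discrete"]))

    def test_children_inherit_category_and_event(self):
        col = np.repeat([0.0, 1.0], 10)
        t = make_table(col[:, None], dtypes=["discrete"],
                       categories=["Socioeconomic"], events=["6_month"])
        out, _ = encode_discrete(t)
        assert all(m.category == "Socioeconomic" and m.event == "6_month" for m in out.meta)


class TestWinsorize:
    def test_extreme_entry_replaced_by_bruteforce_value(self):
        # 100 in-range values plus one detectable extreme (z ~ 9.9); note a
        # lone outlier can mask itself in tiny samples by inflating the SD
        col = np.concatenate([np.arange(1.0, 101.0), [1e4]])
        table = make_table(col[:, None])
        out, report = robust_zscore_winsorize(table)
        # brute-force oracle scan
        mu, sd = col.mean(), col.std()
        in_range = col[np.abs(col - mu) / sd <= 4]
        replacement = in_range[np.argmax(np.abs(in_range))]
        fixed = np.where(np.abs(col - mu) / sd > 4, replacement, col)
        expected = (fixed - fixed.mean()) / fixed.std()
        np.testing.assert_allclose(out.as_array()[:, 0], expected, atol=1e-12)
        assert report.winsorized_counts == {"x000": 1}
        # the replacement itself is in range under pre-replacement statistics
        assert abs(replacement - mu) / sd <= 4

    def test_no_outliers_only_standardized(self):
        rng = np.random.default_rng(4)
        col = rng.uniform(-1, 1, size=100)
        out, report = robust_zscore_winsorize(make_table(col[:, None]))
        np.testing.assert_allclose(out.as_array()[:, 0], (col - col.mean()) / col.std(), atol=1e-12)
        assert not report.winsorized_counts

    def test_zero_sd_column_raises(self):
        with pytest.raises(ValueError, match="zero-SD"):
            robust_zscore_winsorize(make_table(np.ones((10, 1))))

    def test_train_only_statistics_mode(self):
        rng = np.random.default_rng(5)
        col = rng.normal(size=120)
        table = make_table(col[:, None])
        train_ids = table.participant_ids[:80]
        out, _ = robust_zscore_winsorize(table, stats_rows=train_ids)
        ref = col[:80]
        np.testing.assert_allclose(out.as_array()[:80, 0].mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(
            out.as_array()[:, 0], (col - ref.mean()) / ref.std(), atol=1e-12
        )


class TestImpute:
    def test_continuous_median(self):
        col = np.array([1.0, 2.0, np.nan, 3.0])
        out = impute_missing(make_table(col[:, None]))
        assert out.values.iloc[2, 0] == 2.0

    def test_indicator_mode_zero(self):
        col = np.array([0.0, 0.0, 0.0, 1.0, np.nan])
        t = make_table(col[:, None], dtypes=["discrete"])
        out = impute_missing(t)
        assert out.values.iloc[4, 0] == 0.0

    def test_fully_observed_identity(self):
        x = np.random.default_rng(6).normal(size=(30, 4))
        t = make_table(x)
        assert impute_missing(t).values.equals(t.values)


class TestRetainEvents:
    def _with_events(self, coverages):
        rng = np.random.default_rng(7)
        n = 200
        cols, events = [], []
        for i, cov in enumerate(coverages):
            col = rng.normal(size=n)
            miss = rng.choice(n, size=int(round((1 - cov) * n)), replace=False)
            col[miss] = np.nan
            cols.append(col)
            events.append(f"event{i}")
        return make_table(np.column_stack(cols), events=events)

    def test_coverage_threshold(self):
        t = self._with_events([0.80, 0.96, 0.99])
        out, report = retain_events(t, 0.95)
        assert out.variable_names == ["x001", "x002"]
        assert sorted(report.retained_events) == ["event1", "event2"]

    def test_baseline_always_retained(self):
        t = make_table(np.random.default_rng(8).normal(size=(50, 2)))
        out, _ = retain_events(t, 0.95)
        assert out.n_variables == 2

    def test_no_event_qualifies_raises(self):
        t = self._with_events([0.5, 0.6])
        with pytest.raises(ValueError, match="coverage"):
            retain_events(t, 0.95)


class TestCurate:
    def test_conservation_every_variable_accounted_once(self, small_draw):
        _, table, _ = small_draw
        _, report = curate(table)
        assert report.accounted_variables() == set(table.variable_names)

    def test_post_curation_scaling_invariants(self, small_curated):
        curated, _, _ = small_curated
        x = curated.as_array()
        assert not np.isnan(x).any()
        for m, col in zip(curated.meta, x.T):
            if m.dtype == "continuous":
                assert abs(col.mean()) < 1e-8 and abs(col.std() - 1) < 1e-8
            else:
                assert set(np.unique(col)) <= {0.0, 1.0}

    def test_no_entry_violates_four_sd_bound(self, small_curated):
        curated, _, _ = small_curated
        for m, col in zip(curated.meta, curated.as_array().T):
            if m.dtype == "continuous":
                assert np.all(np.abs(col - col.mean()) / col.std() <= 4.0 + 1e-9)

    def test_idempotence_up_to_restandardization(self, small_curated):
        curated, _, _ = small_curated
        again, report2 = curate(curated)
        assert again.variable_names == curated.variable_names
        np.testing.assert_allclose(again.as_array(), curated.as_array(), atol=1e-8)
        assert not report2.encoded and not report2.winsorized_counts

    def test_noncompliance_codes_recoded(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(100, 2))
        x[:3, 0] = 999.0
        _, report = curate(make_table(x), CurationConfig(noncompliance_codes=(999.0,)))
        assert report.noncompliance_counts == {"x000": 3}

    def test_planted_violation_counts_reported(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(300, 3))
        x[:5, 1] = 50.0  # five planted outliers
        _, report = curate(make_table(x))
        assert report.winsorized_counts == {"x001": 5}
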