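"""Selector behaviour and the minimum-votes aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gliovote as gv
from gliovote.errors import SingleClassError
from gliovote.selection import aggregate_to_features, run_selectors


def two_by_two_feature():
    """Binary feature with counts: bin=1 (30 events, 10 non-events),
    bin=0 (20 events, 40 non-events)."""
    feature = np.array([1] * 40 + [0] * 60)
    labels = np.array([1] * 30 + [0] * 10 + [1] * 20 + [0] * 40)
    return feature, labels


class TestWoe:
    def test_hand_computed_two_by_two(self):
        feature, labels = two_by_two_feature()
        bins = gv.woe_bins(feature, labels)
        by_id = {b.bin_id: b for b in bins}
        assert by_id[1].woe == pytest.approx(math.log(1 / 3), abs=1e-12)
        # IV = (0.2-0.6)*ln(1/3) + (0.8-0.4)*ln(2)
        expected_iv = (0.2 - 0.6) * math.log(1 / 3) + 0.4 * math.log(2)
        assert gv.woe_importance(bins) == pytest.approx(expected_iv, abs=1e-12)
        assert expected_iv == pytest.approx(0.7167, abs=5e-4)

    def test_evidence_doubling_odds_gives_ln2(self):
        # a bin where the non-event share is exactly twice the event share
        feature = np.array([1] * 30 + [0] * 70)
        labels = np.array([1] * 10 + [0] * 20 + [1] * 40 + [0] * 30)
        bins = {b.bin_id: b for b in gv.woe_bins(feature, labels)}
        b = bins[1]
        assert b.pct_nonevents == pytest.approx(2 * b.pct_events)
        assert b.woe == pytest.approx(math.log(2), abs=1e-12)

    def test_equal_class_shares_give_zero(self):
        feature = np.array([1, 1, 0, 0] * 10)
        labels = np.array([1, 0] * 20)
        for b in gv.woe_bins(feature, labels):
            assert b.woe == pytest.approx(0.0, abs=1e-12)
        assert gv.woe_importance(gv.woe_bins(feature, labels)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_zero_cell_is_smoothed_to_finite_woe(self):
        feature = np.array([1] * 10 + [0] * 10)
        labels = np.array([1] * 10 + [0] * 10)  # perfectly separating
        bins = gv.woe_bins(feature, labels)
        assert all(np.isfinite(b.woe) for b in bins)
        assert gv.woe_importance(bins) > 0

    def test_percentages_sum_to_one_and_iv_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            feature = rng.normal(size=80)
            labels = rng.integers(0, 2, size=80)
            if len(np.unique(labels)) < 2:
                continue
            bins = gv.woe_bins(feature, labels, n_bins=5)
            assert sum(b.pct_events for b in bins) == pytest.approx(1.0)
            assert sum(b.pct_nonevents for b in bins) == pytest.approx(1.0)
            assert gv.woe_importance(bins) >= 0

    def test_sign_symmetry_under_label_swap(self):
        rng = np.random.default_rng(1)
        feature = rng.integers(0, 2, size=100)
        labels = rng.integers(0, 2, size=100)
        bins = gv.woe_bins(feature, labels)
        flipped = gv.woe_bins(feature, 1 - labels)
        for b, f in zip(bins, flipped):
            assert f.woe == pytest.approx(-b.woe, abs=1e-12)
        assert gv.woe_importance(flipped) == pytest.approx(
            gv.woe_importance(bins), abs=1e-12)

    def test_error_cases(self):
        with pytest.raises(SingleClassError):
            gv.woe_bins([0, 1, 0], [1, 1, 1])
        with pytest.raises(ValueError):
            gv.woe_bins([0.1, 0.5, 0.9], [0, 1, 0], n_bins=1)
        with pytest.raises(ValueError):
            gv.woe_importance([])


class TestRfe:
    def test_n_keep_equal_to_total_selects_all(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, size=40)
        v = gv.select_rfe(X, y, n_keep=4)
        assert v.selected.all()

    def test_identical_columns_keep_exactly_one(self):
        rng = np.random.default_rng(0)
        signal = rng.integers(0, 2, size=60).astype(float)
        y = signal.astype(int)
        X = pd.DataFrame({"dup1": signal, "dup2": signal.copy()})
        v = gv.select_rfe(X, y, n_keep=1)
        assert v.selected.sum() == 1

    def test_noise_eliminated_first_more_often_than_chance(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            y = rng.integers(0, 2, size=n)
            X = pd.DataFrame({
                "s1": y + rng.normal(0, 0.3, n),
                "s2": y + rng.normal(0, 0.3, n),
                "s3": y + rng.normal(0, 0.3, n),
                "s4": y + rng.normal(0, 0.3, n),
                "noise": rng.normal(size=n),
            })
            v = gv.select_rfe(X, y, n_keep=1)
            if v.importance[list(X.columns).index("noise")] == 1:
                hits += 1
        assert hits / 20 > 0.2  # strictly better than 1-in-5 chance

    def test_invalid_n_keep(self):
        X = pd.DataFrame(np.ones((10, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            gv.select_rfe(X, [0, 1] * 5, n_keep=4)


class TestRandomForestSelector:
    def test_importances_normalised_and_constant_column_ignored(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=120)
        X = pd.DataFrame({
            "signal": y + rng.normal(0, 0.5, 120),
            "const": np.zeros(120),
            "noise": rng.normal(size=120),
        })
        v = gv.select_rf(X, y, seed=0)
        assert v.importance.sum() == pytest.approx(1.0, abs=1e-9)
        const_idx = list(X.columns).index("const")
        assert v.importance[const_idx] == 0.0
        assert not v.selected[const_idx]

    def test_planted_strongest_feature_ranks_first(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            y = rng.integers(0, 2, size=n)
            p = np.where(y == 1, 0.9, 0.1)
            X = pd.DataFrame({
                "planted": (rng.random(n) < p).astype(float),
                **{f"null{i}": (rng.random(n) < 0.3).astype(float)
                   for i in range(5)},
            })
            v = gv.select_rf(X, y, seed=seed)
            assert np.argmax(v.importance) == 0

    def test_single_class_raises(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(SingleClassError):
            gv.select_rf(X, np.ones(20, dtype=int))


class TestLasso:
    def test_huge_lambda_selects_nothing(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5))
        y = X[:, 0] * 2 + rng.normal(size=60) * 0.1
        verdict, fit = gv.select_lasso(X, y, lambda_grid=[1e9])
        assert not verdict.selected.any()
        assert (fit.coefficients == 0).all()

    def test_zero_lambda_matches_least_squares(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(size=50) * 0.1
        _, fit = gv.select_lasso(X, y, lambda_grid=[0.0])
        Xs = (X - X.mean(0)) / X.std(0)
        design = np.column_stack([np.ones(50), Xs])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients, beta[1:], atol=1e-6)

    def test_correlated_pair_keeps_at_most_one(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=80)
        X = np.column_stack([base, base, rng.normal(size=80)])
        y = base * 3 + rng.normal(size=80) * 0.1
        verdict, _ = gv.select_lasso(X, y, lambda_grid=[0.5])
        assert verdict.selected[:2].sum() <= 1

    def test_selected_count_non_increasing_in_lambda(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 8))
        beta = np.array([3.0, -2.0, 1.5, 1.0, 0.5, 0.0, 0.0, 0.0])
        y = X @ beta + rng.normal(size=100) * 0.2
        lambdas = np.logspace(-3, 0.5, 12)
        counts = [gv.select_lasso(X, y, lambda_grid=[lam])[0].selected.sum()
                  for lam in lambdas]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cv_choice_recovers_sparse_support(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(120, 6))
        y = X[:, 0] * 2 - X[:, 1] * 1.5 + rng.normal(size=120) * 0.3
        verdict, fit = gv.select_lasso(X, y, seed=0)
        assert fit.lambda_ > 0
        assert verdict.selected[0] and verdict.selected[1]

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            gv.select_lasso(np.ones((10, 2)), np.arange(10), lambda_grid=[])


def make_verdicts(selected_sets, features=("f1", "f2", "f3", "f4")):
    methods = ["WOE", "RFE", "RF", "LASSO"]
    verdicts = []
    for method, sel in zip(methods, selected_sets):
        mask = np.array([f in sel for f in features])
        verdicts.append(gv.SelectorVerdict(
            method, tuple(features), mask.astype(float), mask))
    return verdicts


class TestTally:
    def test_threshold_sweep(self):
        verdicts = make_verdicts([
            {"f1", "f2"}, {"f2"}, {"f2", "f3"}, {"f2"}])
        t0 = gv.tally_votes(verdicts, min_votes=0)
        assert set(t0.selected_features) == {"f1", "f2", "f3", "f4"}
        t1 = gv.tally_votes(verdicts, min_votes=1)
        assert set(t1.selected_features) == {"f1", "f2", "f3"}
        t2 = gv.tally_votes(verdicts, min_votes=2)
        assert set(t2.selected_features) == {"f2"}
        t4 = gv.tally_votes(verdicts, min_votes=4)
        assert set(t4.selected_features) == {"f2"}  # intersection

    def test_woe_only_feature_in_at_one_out_at_two(self):
        verdicts = make_verdicts([{"f1"}, set(), set(), set()])
        assert "f1" in gv.tally_votes(verdicts, 1).selected_features
        assert "f1" not in gv.tally_votes(verdicts, 2).selected_features

    def test_ordering_votes_desc_then_schema_order(self):
        verdicts = make_verdicts([
            {"f3", "f4"}, {"f3", "f1"}, {"f3"}, {"f4"}])
        tally = gv.tally_votes(verdicts, min_votes=1)
        assert tally.selected_features == ["f3", "f4", "f1"]

    def test_mismatched_feature_sets_raise(self):
        a = make_verdicts([{"f1"}] * 4)
        b = make_verdicts([{"g1"}] * 4, features=("g1", "g2", "g3", "g4"))
        with pytest.raises(ValueError, match="differ"):
            gv.tally_votes([a[0], a[1], a[2], b[3]])

    @given(st.lists(st.sets(st.sampled_from(["f1", "f2", "f3", "f4"])),
                    min_size=4, max_size=4))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_monotone_in_min_votes(self, sets):
        verdicts = make_verdicts(sets)
        prev = None
        for k in range(5):
            cur = set(gv.tally_votes(verdicts, min_votes=k).selected_features)
            if prev is not None:
                assert cur.issubset(prev)
            prev = cur

    def test_min_votes_four_is_intersection(self):
        verdicts = make_verdicts([
            {"f1", "f2", "f3"}, {"f2", "f3"}, {"f2", "f3", "f4"}, {"f2"}])
        expected = {"f1", "f2", "f3"} & {"f2", "f3"} & {"f2", "f3", "f4"} & {"f2"}
        assert set(gv.tally_votes(verdicts, 4).selected_features) == expected


class TestAggregation:
    def test_one_hot_columns_fold_back_to_feature(self):
        v = gv.SelectorVerdict(
            "LASSO", ("Race=white", "Race=asian", "IDH1"),
            np.array([0.0, 0.4, 0.7]), np.array([False, True, True]))
        agg = aggregate_to_features(
            v, {"Race=white": "Race", "Race=asian": "Race", "IDH1": "IDH1"},
            ("Race", "IDH1"))
        assert list(agg.feature_names) == ["Race", "IDH1"]
        np.testing.assert_allclose(agg.importance, [0.4, 0.7])
        assert agg.selected.all()


class TestDeterminism:
    def test_selectors_reproducible_at_fixed_seed(self, small_cohort):
        cohort, _ = small_cohort
        X = cohort.X.copy()
        stats = gv.fit_standardization(X["Age_at_diagnosis"])
        X["Age_at_diagnosis"] = gv.standardize_age(
            X["Age_at_diagnosis"], stats)
        runs = [run_selectors(X, cohort.y, cohort.column_map,
                              cohort.feature_names, seed=0)
                for _ in range(2)]
        for v1, v2 in zip(*runs):
            np.testing.assert_array_equal(v1.importance, v2.importance)
            np.testing.assert_array_equal(v1.selected, v2.selected)

    def test_planted_genes_collect_votes(self, small_cohort):
        cohort, truth = small_cohort
        X = cohort.X.copy()
        stats = gv.fit_standardization(X["Age_at_diagnosis"])
        X["Age_at_diagnosis"] = gv.standardize_age(
            X["Age_at_diagnosis"], stats)
        verdicts = run_selectors(X, cohort.y, cohort.column_map,
                                 cohort.feature_names, seed=0)
        tally = gv.tally_votes(verdicts, min_votes=1)
        for gene in truth.informative_features:
            assert tally.votes[gene] >= 1
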