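"""Threshold screening: ranges, AND-rule predictions, metrics, grid search."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from monopred import screen, synthdata
from monopred.screen import (
    DEFAULT_COMBINATIONS,
    ThresholdScreen,
    candidate_range,
    grid_search,
    metrics,
    predict,
    selection_score,
    validate_external,
)


def oracle_best(X, y, score_variant="ratio-sqrt"):
    """Independent brute-force screen: plain loops, no shared helpers."""
    y = np.asarray(y)
    best = None
    for S in DEFAULT_COMBINATIONS:
        point_sets = []
        usable = True
        for k in S:
            xs = X[k].to_numpy(float)
            pos = [v for v, yi in zip(xs, y) if yi == 1 and np.isfinite(v)]
            neg = [v for v, yi in zip(xs, y) if yi == 0 and np.isfinite(v)]
            if not pos or not neg:
                usable = False
                break
            lo, hi = min(pos), max(neg)
            pts = sorted({lo} | {v for v in xs if np.isfinite(v) and lo <= v <= hi})
            point_sets.append(pts)
        if not usable:
            continue
        for taus in product(*point_sets):
            n_pass = tp = n_pos = 0
            for i in range(len(y)):
                vals = [X[k].to_numpy(float)[i] for k in S]
                if any(np.isnan(v) for v in vals):
                    continue
                if y[i] == 1:
                    n_pos += 1
                if all(v >= t for v, t in zip(vals, taus)):
                    n_pass += 1
                    if y[i] == 1:
                        tp += 1
            if n_pass == 0:
                continue
            acc = tp / n_pass
            cov = tp / n_pos if n_pos else float("-inf")
            sc = acc / np.sqrt(n_pass) if score_variant == "ratio-sqrt" else acc * np.sqrt(n_pass)
            key = (-sc, len(S), -acc, -cov, S, taus)
            if best is None or key < best[0]:
                best = (key, S, taus, sc, n_pass, acc)
    return best


class TestCandidateRange:
    def test_direct_definition(self):
        x = [0.3, 0.5, 0.2, 0.4]
        y = [1, 1, 0, 0]
        lo, hi, degenerate = candidate_range(x, y)
        assert (lo, hi) == (0.3, 0.4)
        assert not degenerate

    def test_perfect_separation_degenerate(self):
        lo, hi, degenerate = candidate_range([5, 6, 1, 2], [1, 1, 0, 0])
        assert lo > hi
        assert degenerate

    def test_invariant_to_duplicated_patients(self):
        x, y = [0.3, 0.5, 0.2, 0.4], [1, 1, 0, 0]
        assert candidate_range(x, y) == candidate_range(x * 3, y * 3)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="unavailable"):
            candidate_range([np.nan, np.nan, 1.0], [1, 1, 0])


class TestPredict:
    def _X(self):
        return pd.DataFrame({"A": [0.5, 0.1], "B": [0.2, 0.9]})

    def test_minimum_threshold_passes_everyone(self):
        pred = predict(("A",), {"A": -1e18}, self._X())
        assert (pred == 1).all()

    def test_and_semantics(self):
        pred = predict(("A", "B"), {"A": 0.4, "B": 0.3}, self._X())
        assert pred.tolist() == [0.0, 0.0]  # first fails B, second fails A

    def test_threshold_inclusive(self):
        X = pd.DataFrame({"A": [0.4]})
        assert predict(("A",), {"A": 0.4}, X).item() == 1.0

    def test_missing_indicator_unassigned(self):
        X = pd.DataFrame({"A": [np.nan, 0.5]})
        pred = predict(("A",), {"A": 0.1}, X)
        assert np.isnan(pred.iloc[0]) and pred.iloc[1] == 1.0

    def test_empty_combination_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            predict((), {}, self._X())


class TestMetrics:
    def test_printed_validation_group_sizes(self):
        # all 22 responders pass, none of the 11 non-responders do
        y = np.array([1] * 22 + [0] * 11)
        pred = pd.Series(np.array([1.0] * 22 + [0.0] * 11))
        m = metrics(pred, y)
        assert m["coverage"] == 1.0
        assert m["accuracy"] == 1.0
        assert m["n_pass"] == 22

    def test_nobody_passes(self):
        y = np.array([1, 0, 1])
        m = metrics(pd.Series([0.0, 0.0, 0.0]), y)
        assert m["coverage"] == 0.0
        assert m["accuracy"] is None

    def test_everyone_passes_accuracy_is_prevalence(self):
        y = np.array([1, 1, 0, 0, 1])
        m = metrics(pd.Series([1.0] * 5), y)
        assert m["accuracy"] == pytest.approx(y.mean())

    def test_true_positive_identity(self):
        # accuracy * n_pass = coverage * n_responders = true positives
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 40)
        pred = pd.Series(rng.integers(0, 2, 40).astype(float))
        m = metrics(pred, y)
        assert m["accuracy"] * m["n_pass"] == pytest.approx(m["true_positives"])
        assert m["coverage"] * (y == 1).sum() == pytest.approx(m["true_positives"])


class TestSelectionScore:
    @pytest.mark.parametrize("acc,n,expected", [(1.0, 4, 0.5), (0.8, 16, 0.2)])
    def test_printed_formula(self, acc, n, expected):
        assert selection_score(acc, n) == pytest.approx(expected)

    def test_quadrupling_n_pass_halves_score(self):
        assert selection_score(0.9, 36) == pytest.approx(selection_score(0.9, 9) / 2)

    def test_alternative_variant_behind_flag(self):
        assert selection_score(0.5, 4, "times-sqrt") == pytest.approx(1.0)

    def test_zero_pass_unavailable(self):
        with pytest.raises(ValueError):
            selection_score(1.0, 0)


class TestGridSearch:
    def _random_instance(self, seed, n_missing=0):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 16))
        # discretized values keep observed-value grids small
        X = pd.DataFrame(
            {k: np.round(rng.normal(size=n), 1) for k in ("A", "B", "C")}
        )
        y = rng.integers(0, 2, n)
        if y.sum() == 0:
            y[0] = 1
        if y.sum() == n:
            y[0] = 0
        for _ in range(n_missing):
            X.iloc[int(rng.integers(n)), int(rng.integers(3))] = np.nan
        return X, y

    @pytest.mark.parametrize("seed", range(25))
    def test_best_matches_brute_force_oracle(self, seed):
        X, y = self._random_instance(seed, n_missing=seed % 3)
        res = grid_search(X, y)
        oracle = oracle_best(X, y)
        if oracle is None:
            return
        best = res.best
        assert best.combination == oracle[1]
        assert [best.thresholds[k] for k in best.combination] == pytest.approx(
            list(oracle[2])
        )
        assert best.score == pytest.approx(oracle[3])

    def test_raising_threshold_shrinks_pass_set(self):
        X, y = self._random_instance(99)
        grid = sorted(X["A"].dropna().unique())
        passes = [
            screen.metrics(predict(("A",), {"A": t}, X), y)["n_pass"] for t in grid
        ]
        assert passes == sorted(passes, reverse=True)

    def test_informative_indicator_wins_under_balanced_score(self):
        # the verbatim accuracy/sqrt(n_pass) score is maximized by the
        # smallest pure-responder pass set, so which indicator tops it is
        # decided by single extreme patients; the coverage-rewarding
        # variant recovers the informative indicator
        coh = synthdata.gen_cohort(
            synthdata.CohortSimSpec(
                n_patients=60, prevalence=0.5,
                or_per_sd={"A": 8.0, "B": 1.0, "C": 1.0}, seed=23,
            )
        )
        X = coh.data[["A", "B", "C"]]
        res = grid_search(X, coh.data["y"], score_variant="times-sqrt")
        singles = [r for r in res.ranked if len(r.combination) == 1]
        assert singles[0].combination == ("A",)

    def test_verbatim_score_prefers_small_pass_sets(self):
        coh = synthdata.gen_cohort(
            synthdata.CohortSimSpec(n_patients=60, prevalence=0.5, seed=23)
        )
        X = coh.data[["A", "B", "C"]]
        best = grid_search(X, coh.data["y"], score_variant="ratio-sqrt").best
        assert best.accuracy == 1.0
        assert best.n_pass <= 3

    def test_row_order_invariance(self):
        X, y = self._random_instance(7)
        res1 = grid_search(X, y)
        perm = np.random.default_rng(0).permutation(len(X))
        res2 = grid_search(X.iloc[perm].reset_index(drop=True), y[perm])
        assert res1.best.combination == res2.best.combination
        assert res1.best.thresholds == res2.best.thresholds
        assert res1.best.score == pytest.approx(res2.best.score)

    def test_summary_prints_best(self):
        X, y = self._random_instance(3)
        assert "Best:" in grid_search(X, y).summary()


class TestValidateExternal:
    def test_identical_table_identical_metrics(self):
        X = pd.DataFrame({"A": [0.1, 0.4, 0.6, 0.9], "B": [0.2, 0.3, 0.7, 0.8]})
        y = np.array([0, 0, 1, 1])
        best = grid_search(X, y).best
        val = validate_external(best, X, y)
        assert val.n_pass == best.n_pass
        assert val.accuracy == pytest.approx(best.accuracy)
        assert val.coverage == pytest.approx(best.coverage)

    def test_absent_indicator_skipped_with_warning(self):
        X = pd.DataFrame({"A": [0.1, 0.9], "B": [0.2, 0.8]})
        y = np.array([0, 1])
        best = grid_search(X, y).best
        with pytest.warns(UserWarning, match="absent"):
            out = validate_external(best, X[["A"]].rename(columns={"A": "Z"}), y)
        assert out is None

    def test_label_permutation_null_accuracy_near_prevalence(self):
        coh = synthdata.gen_cohort(
            synthdata.CohortSimSpec(n_patients=80, prevalence=0.5,
                                    or_per_sd={"A": 3.0, "B": 1.0, "C": 1.0}, seed=31)
        )
        X, y = coh.data[["A", "B", "C"]], coh.data["y"].to_numpy()
        best = grid_search(X, y, score_variant="times-sqrt").best
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(200):
            val = validate_external(best, X, rng.permutation(y))
            if val.accuracy is not None:
                accs.append(val.accuracy)
        assert np.mean(accs) == pytest.approx(y.mean(), abs=0.05)

    def test_held_out_validation_beats_prevalence(self):
        coh = synthdata.gen_cohort(
            synthdata.CohortSimSpec(n_patients=400, prevalence=0.65,
                                    or_per_sd={"A": 2.3, "B": 2.3, "C": 2.3}, seed=37)
        )
        X, y = coh.data[["A", "B", "C"]], coh.data["y"].to_numpy()
        train, test = slice(0, 200), slice(200, 400)
        # balanced score: the verbatim ratio-sqrt rule passes ~1 training
        # patient and carries no information to held-out data
        best = grid_search(X.iloc[train], y[train], score_variant="times-sqrt").best
        val = validate_external(best, X.iloc[test].reset_index(drop=True), y[test])
        assert val.accuracy > y[test].mean()
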