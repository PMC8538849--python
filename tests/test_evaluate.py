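"""Metrics, splits, architecture enumeration and grid-search behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from densecg import synthetic
from densecg.errors import InvalidSpecError
from densecg.evaluate import (ConfusionMatrix4, challenge_f1, class_weight_grid,
                              confusion_matrix, enumerate_architectures,
                              grid_search, per_class_metrics, run_cv,
                              stratified_kfold)
from densecg.net import Topology, TrainingConfig

#: published cross-validation confusion matrix of the optimized model
TABLE3 = ConfusionMatrix4([[4603, 14, 433, 26],
                           [16, 615, 111, 16],
                           [657, 101, 1627, 30],
                           [67, 10, 49, 153]])


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = np.array(["N", "AF", "O", "X", "N"], dtype=object)
        cm = confusion_matrix(y, y)
        assert np.array_equal(np.diag(cm.counts), [2, 1, 1, 1])
        assert cm.counts.sum() == 5

    def test_all_predicted_normal(self):
        y = np.array(["N", "AF", "O", "X"], dtype=object)
        cm = confusion_matrix(y, np.array(["N"] * 4, dtype=object))
        assert np.array_equal(cm.counts[:, 0], [1, 1, 1, 1])
        assert cm.counts[:, 1:].sum() == 0

    def test_hand_tally(self):
        t = np.array(["N", "N", "AF", "AF", "O", "O", "X", "X"], dtype=object)
        p = np.array(["N", "AF", "AF", "AF", "O", "N", "X", "O"], dtype=object)
        cm = confusion_matrix(t, p)
        assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1
        assert cm.counts[1, 1] == 2
        assert cm.counts[2, 0] == 1 and cm.counts[2, 2] == 1
        assert cm.counts[3, 2] == 1 and cm.counts[3, 3] == 1

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidSpecError):
            confusion_matrix(np.array(["AFIB"], dtype=object),
                             np.array(["N"], dtype=object))


class TestMetrics:
    def test_published_confusion_matrix_reproduced(self):
        rep = per_class_metrics(TABLE3)
        assert [round(rep.f1[c], 3) for c in ("N", "AF", "O", "X")] == \
            [0.884, 0.821, 0.702, 0.607]
        assert round(rep.precision_pct["N"], 1) == 86.2
        assert round(rep.recall_pct["X"], 1) == 54.8
        assert round(rep.acc_total_pct, 2) == 82.06
        assert round(rep.f1_total, 3) == 0.802

    def test_identity_matrix_perfect_scores(self):
        cm = ConfusionMatrix4(np.diag([10, 20, 30, 40]))
        rep = per_class_metrics(cm)
        assert all(rep.f1[c] == 1.0 for c in rep.f1)
        assert rep.acc_total_pct == 100.0
        assert challenge_f1(cm) == 1.0

    def test_embedded_two_class_f1(self):
        cm = ConfusionMatrix4([[3, 1, 0, 0], [1, 3, 0, 0],
                               [0, 0, 0, 0], [0, 0, 0, 0]])
        rep = per_class_metrics(cm)
        assert rep.f1["N"] == pytest.approx(0.75)
        assert rep.f1["AF"] == pytest.approx(0.75)

    def test_challenge_f1_excludes_noise(self):
        # F1(N)=F1(AF)=1, F1(O)=0 -> 2/3 regardless of X performance
        cm = ConfusionMatrix4([[5, 0, 0, 0], [0, 5, 0, 0],
                               [0, 0, 0, 5], [0, 0, 5, 0]])
        assert challenge_f1(cm) == pytest.approx(2.0 / 3.0)

    def test_micro_identities(self):
        rep = per_class_metrics(TABLE3)
        c = TABLE3.counts
        assert rep.acc_total_pct == pytest.approx(100 * np.trace(c) / c.sum())
        for i, name in enumerate(("N", "AF", "O", "X")):
            support = c[i].sum()
            assert rep.recall_pct[name] * support == pytest.approx(
                100.0 * c[i, i])


class TestStratifiedKFold:
    @pytest.mark.parametrize("n,expected", [
        (5076, [1016, 1015, 1015, 1015, 1015]),
        (758, [152, 152, 152, 151, 151]),
        (2415, [483, 483, 483, 483, 483]),
        (279, [56, 56, 56, 56, 55]),
    ])
    def test_published_per_class_fold_counts(self, n, expected):
        labels = np.array(["AF"] * n, dtype=object)
        split = stratified_kfold(labels, 5, seed=3)
        assert sorted(np.bincount(split.fold, minlength=5), reverse=True) == expected
        # larger folds first
        assert list(np.bincount(split.fold, minlength=5)) == expected

    def test_divisible_case_equal_folds(self):
        split = stratified_kfold(np.array(["N"] * 20, dtype=object), 4, seed=0)
        assert np.bincount(split.fold).tolist() == [5, 5, 5, 5]

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10**6),
           st.lists(st.integers(5, 40), min_size=2, max_size=4))
    def test_stratification_property(self, seed, counts):
        labels = np.concatenate([
            np.array([c] * n, dtype=object)
            for c, n in zip(("N", "AF", "O", "X"), counts)])
        k = 5
        split = stratified_kfold(labels, k, seed=seed)
        for c, n in zip(("N", "AF", "O", "X"), counts):
            per_fold = np.bincount(split.fold[labels == c], minlength=k)
            assert per_fold.max() - per_fold.min() <= 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(InvalidSpecError):
            stratified_kfold(np.array(["N"] * 3, dtype=object), 5)


class TestArchitectureEnumeration:
    def test_full_grid_count(self):
        widths = [1, 2, 4, 8, 16, 32, 64, 128, 256, 512, 1024]
        topos = enumerate_architectures(widths, max_depth=4)
        assert len(topos) == 364  # 1 + 11 + 66 + 286

    def test_counts_by_depth_closed_form(self):
        widths = [1, 2, 4, 8, 16, 32, 64, 128, 256, 512, 1024]
        topos = enumerate_architectures(widths, max_depth=4)
        from math import comb
        by_depth = {d: sum(1 for t in topos if t.depth == d) for d in (1, 2, 3, 4)}
        assert by_depth == {d: comb(11 + d - 2, d - 1) for d in (1, 2, 3, 4)}

    def test_single_width_two_depths(self):
        assert len(enumerate_architectures([7], max_depth=2)) == 2

    def test_two_widths_depth_three(self):
        assert len(enumerate_architectures([4, 8], max_depth=3)) == 6

    def test_hidden_widths_non_increasing(self):
        for t in enumerate_architectures([2, 8, 32], max_depth=4):
            w = t.hidden_widths
            assert all(a >= b for a, b in zip(w, w[1:]))


class TestClassWeightGrid:
    def test_vectors_sum_to_one_and_respect_bounds(self):
        grid = class_weight_grid()
        assert len(grid) > 0
        for v in grid:
            assert sum(v) == pytest.approx(1.0, abs=1e-9)
            assert all(-1e-12 <= w <= 0.5 + 1e-9 for w in v)

    def test_count_matches_brute_force(self):
        grid = class_weight_grid(step=0.05, w_max=0.5)
        count = 0
        for a in range(11):
            for b in range(11):
                for c in range(11):
                    if 10 <= a + b + c <= 20:
                        count += 1
        assert len(grid) == count

    def test_published_optimum_is_off_grid(self):
        # the reported optimum (0.23, 0.25, 0.3, 0.22) is an average of a
        # region, not a grid point
        grid = class_weight_grid()
        assert (0.23, 0.25, 0.3, 0.22) not in grid


def _separable_table(n_per=40, seed=0):
    spec = synthetic.TableSpec(
        n_per_class={"N": n_per, "AF": n_per, "O": n_per, "X": n_per},
        n_features=6,
        informative_features={0: {"N": 5.0}, 1: {"AF": 5.0},
                              2: {"O": 5.0}, 3: {"X": 5.0}},
        seed=seed)
    return synthetic.generate_feature_table(spec)


class TestCrossValidation:
    def test_separable_table_high_f1_and_conservation(self):
        X, y = _separable_table()
        cfg = TrainingConfig(seed=1, max_epochs=60, batch_size=32,
                             dropout_rate=0.1)
        res = run_cv(X, y, Topology(6, (8,)), cfg, k=4)
        assert res.pooled_cm.total == len(y)  # folds partition the data
        assert res.mean_report.f1_total >= 0.95
        assert len(res.models) == 4

    def test_repeat_same_seed_identical(self):
        X, y = _separable_table(n_per=24, seed=3)
        cfg = TrainingConfig(seed=5, max_epochs=20, batch_size=32)
        r1 = run_cv(X, y, Topology(6, (6,)), cfg, k=3)
        r2 = run_cv(X, y, Topology(6, (6,)), cfg, k=3)
        assert np.array_equal(r1.pooled_cm.counts, r2.pooled_cm.counts)
        assert r1.fold_f1 == r2.fold_f1


class TestGridSearch:
    def test_crippled_learning_rate_loses(self):
        X, y = _separable_table(n_per=24, seed=4)
        cfg = TrainingConfig(seed=2, max_epochs=25, batch_size=32)
        res = grid_search(X, y, "learning_rate", [0.005, 1000.0],
                          Topology(6, (6,)), cfg, k=3)
        assert res.best["setting"] == 0.005

    def test_sweep_deterministic(self):
        X, y = _separable_table(n_per=24, seed=4)
        cfg = TrainingConfig(seed=2, max_epochs=15, batch_size=32)
        r1 = grid_search(X, y, "batch_size", [16, 32], Topology(6, (6,)), cfg, k=3)
        r2 = grid_search(X, y, "batch_size", [16, 32], Topology(6, (6,)), cfg, k=3)
        assert [e["mean_f1"] for e in r1.entries] == \
            [e["mean_f1"] for e in r2.entries]

    def test_unknown_axis_rejected(self):
        X, y = _separable_table(n_per=12)
        with pytest.raises(InvalidSpecError):
            grid_search(X, y, "momentum", [0.9], Topology(6, ()),
                        TrainingConfig())
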