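"""Splits, metrics, sleep parameters, agreement statistics, CV, sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchsleep.config import ModelSpec, SplitSpec
from patchsleep.evaluate import (
    compare_parameters,
    confusion_metrics,
    derive_sleep_parameters,
    f1_maximizing_threshold,
    kfold_cv,
    participant_folds,
    split_cohort,
    threshold_sweep,
)

from conftest import make_synthetic_table


class TestSplit:
    def test_sixty_participants_split_42_18(self):
        ids = [f"P{i:03d}" for i in range(60)]
        train, test = split_cohort(ids, SplitSpec(train_fraction=0.7, seed=0))
        assert (len(train), len(test)) == (42, 18)
        assert set(train) | set(test) == set(ids)
        assert not set(train) & set(test)

    def test_ten_participants_split_7_3(self):
        train, test = split_cohort([f"P{i}" for i in range(10)], SplitSpec(seed=1))
        assert (len(train), len(test)) == (7, 3)

    def test_same_seed_same_split(self):
        ids = [f"P{i}" for i in range(20)]
        assert split_cohort(ids, SplitSpec(seed=5)) == split_cohort(ids, SplitSpec(seed=5))

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(["A", "B"], SplitSpec(train_fraction=0.1, seed=0))


def brute_force_auc(p: np.ndarray, y: np.ndarray) -> float:
    """All-pairs AUC: P(sleep score > wake score), ties counting one half."""
    ps, pw = p[y == 1], p[y == 0]
    total = 0.0
    for a in ps:
        for b in pw:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(ps) * len(pw))


class TestConfusionMetrics:
    def test_sensitivity_specificity_from_counts(self):
        y = np.array([1] * 100 + [0] * 50)
        yhat = np.array([1] * 90 + [0] * 10 + [0] * 30 + [1] * 20)
        m = confusion_metrics(yhat, y)
        assert np.isclose(m.sensitivity, 0.9)
        assert np.isclose(m.specificity, 0.6)

    def test_perfect_separation_auc_one(self):
        y = np.array([1, 1, 0, 0])
        m = confusion_metrics(y, y, p_sleep=np.array([0.9, 0.8, 0.2, 0.1]))
        assert m.auc == 1.0

    def test_three_window_auc_half(self):
        # probabilities (0.9, 0.4, 0.6) for truth (S, S, W): pairs (0.9>0.6), (0.4<0.6)
        y = np.array([1, 1, 0])
        p = np.array([0.9, 0.4, 0.6])
        m = confusion_metrics((p >= 0.5).astype(int), y, p)
        assert m.auc == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_matches_all_pairs_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        y = (rng.random(n) < 0.8).astype(int)
        p = np.round(rng.random(n), 1)  # coarse grid forces ties
        m = confusion_metrics((p >= 0.5).astype(int), y, p)
        assert abs(m.auc - brute_force_auc(p, y)) <= 1e-12

    def test_single_class_truth_flags_auc_undefined(self):
        y = np.ones(5, dtype=int)
        m = confusion_metrics(y, y, p_sleep=np.linspace(0, 1, 5))
        assert np.isnan(m.auc)

    def test_f1_is_harmonic_mean_of_precision_and_recall(self):
        y = np.array([1, 1, 1, 0, 0])
        yhat = np.array([1, 1, 0, 1, 0])
        m = confusion_metrics(yhat, y)
        prec, rec = 2 / 3, 2 / 3
        assert np.isclose(m.f1, 2 * prec * rec / (prec + rec))


def rescan_parameters(labels, onset_rule="first"):
    """Independent re-scan of a label sequence (loop-based oracle)."""
    labels = list(labels)
    tst = 5.0 * sum(labels)
    eff = sum(labels) / len(labels)
    onset = None
    for i, v in enumerate(labels):
        if onset_rule == "first" and v == 1:
            onset = i
            break
        if onset_rule == "two_consecutive" and v == 1 and i + 1 < len(labels) and labels[i + 1] == 1:
            onset = i
            break
    if onset is None:
        return tst, float("nan"), float("nan"), eff
    sol = 5.0 * onset
    waso = 5.0 * sum(1 for v in labels[onset:] if v == 0)
    return tst, sol, waso, eff


class TestSleepParameters:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            ([0, 0, 1, 1, 1, 1], (20.0, 10.0, 0.0, 2 / 3)),
            ([1, 1, 1, 1, 1, 1], (30.0, 0.0, 0.0, 1.0)),
            ([1, 0, 1], (10.0, 0.0, 5.0, 2 / 3)),
        ],
    )
    def test_worked_examples(self, labels, expected):
        p = derive_sleep_parameters(np.array(labels))
        assert (p.tst, p.sol, p.waso, p.eff) == expected

    def test_no_sleep_night_flags_onset_undefined(self):
        p = derive_sleep_parameters(np.zeros(6, dtype=int))
        assert p.tst == 0.0 and p.eff == 0.0
        assert np.isnan(p.sol) and np.isnan(p.waso)
        assert not p.onset_defined

    @pytest.mark.parametrize("onset_rule", ["first", "two_consecutive"])
    def test_matches_independent_rescan_on_random_sequences(self, onset_rule):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            labels = (rng.random(rng.integers(1, 30)) < 0.8).astype(int)
            p = derive_sleep_parameters(labels, onset_rule=onset_rule)
            tst, sol, waso, eff = rescan_parameters(labels, onset_rule)
            assert p.tst == tst and p.eff == eff
            assert (np.isnan(p.sol) and np.isnan(sol)) or p.sol == sol
            assert (np.isnan(p.waso) and np.isnan(waso)) or p.waso == waso

    def test_efficiency_identity(self):
        rng = np.random.default_rng(3)
        labels = (rng.random(50) < 0.7).astype(int)
        p = derive_sleep_parameters(labels)
        assert np.isclose(p.eff, p.tst / (5.0 * len(labels)))


def pingouin_style_hedges(x: np.ndarray, y: np.ndarray) -> float:
    """Hand formula for the paired Hedges g convention used in reporting."""
    d = (x.mean() - y.mean()) / np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
    n = len(x)
    return d * (1 - 3 / (4 * 2 * n - 9))


class TestCompareParameters:
    def test_identical_vectors_zero_bias_zero_g(self):
        x = np.array([400.0, 350.0, 420.0, 380.0])
        c = compare_parameters(x, x.copy(), "tst")
        assert c.bias == 0.0 and c.hedges_g == 0.0
        assert c.degenerate

    def test_paired_t_hand_computation(self):
        psg = np.array([10.0, 20.0, 30.0, 40.0])
        device = psg + np.array([2.0, 0.0, 2.0, 0.0])
        c = compare_parameters(device, psg, "tst")
        # t = mean(d) / (SD(d)/sqrt(n)) = 1 / (1.1547/2)
        assert abs(c.t - 1.732) <= 0.001
        assert np.isclose(c.bias, 1.0)

    def test_hedges_g_matches_hand_formula(self):
        rng = np.random.default_rng(1)
        psg = rng.normal(400, 30, size=12)
        device = psg + rng.normal(-10, 15, size=12)
        c = compare_parameters(device, psg, "tst")
        assert np.isclose(c.hedges_g, pingouin_style_hedges(device, psg), atol=1e-10)

    def test_exactly_linear_relation_r2_one(self):
        psg = np.array([100.0, 200.0, 300.0, 400.0])
        c = compare_parameters(2.0 * psg, psg, "tst")
        assert np.isclose(c.r_squared, 1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            compare_parameters(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestThresholdSweep:
    def test_zero_threshold_extremes(self):
        y = np.array([1, 1, 0])
        p = np.array([0.9, 0.4, 0.6])
        sweep = threshold_sweep(p, y, [0.0])
        assert sweep["sensitivity"].iloc[0] == 1.0
        assert sweep["specificity"].iloc[0] == 0.0

    @pytest.mark.parametrize("seed", [0, 7])
    def test_monotonic_tradeoff_over_grid(self, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random(500) < 0.8).astype(int)
        p = np.clip(rng.normal(0.6 + 0.2 * y, 0.2), 0, 1)
        grid = list(np.round(np.arange(0.0, 1.05, 0.05), 2))
        sweep = threshold_sweep(p, y, grid)
        assert np.all(np.diff(sweep["sensitivity"]) <= 1e-12)
        assert np.all(np.diff(sweep["specificity"]) >= -1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0.0, 1.0), st.booleans()), min_size=2, max_size=60
        ).filter(lambda v: len({lab for _, lab in v}) == 2)
    )
    def test_monotonicity_holds_for_arbitrary_series(self, series):
        p = np.array([x for x, _ in series])
        y = np.array([int(lab) for _, lab in series])
        sweep = threshold_sweep(p, y, list(np.linspace(0, 1, 21)))
        assert np.all(np.diff(sweep["sensitivity"]) <= 1e-12)
        assert np.all(np.diff(sweep["specificity"]) >= -1e-12)

    def test_f1_maximizing_threshold_on_grid(self):
        y = np.array([1, 1, 1, 0])
        p = np.array([0.9, 0.8, 0.6, 0.7])
        tau = f1_maximizing_threshold(p, y, [0.5, 0.75])
        assert tau == 0.5  # at 0.75 a sleep window is lost


class TestKfoldCv:
    def test_fold_sizes_for_60_participants(self):
        folds = participant_folds([f"P{i:02d}" for i in range(60)], 10, seed=0)
        assert [len(f) for f in folds] == [6] * 10

    def test_folds_partition_participants(self):
        ids = [f"P{i:02d}" for i in range(23)]
        folds = participant_folds(ids, 10, seed=3)
        flat = [p for f in folds for p in f]
        assert sorted(flat) == sorted(ids)
        assert len(set(flat)) == len(flat)

    def test_cv_report_on_synthetic_cohort(self):
        table = make_synthetic_table(n_participants=9, windows_per_night=40, seed=21)
        report = kfold_cv(
            table,
            ["informative", "noise_0", "noise_1", "noise_2"],
            ModelSpec(kind="gbm", threshold=0.5),
            k=3,
            seed=0,
        )
        assert len(report.folds) == 3
        flat = [p for f in report.fold_participants for p in f]
        assert sorted(flat) == sorted(table["participant"].unique())
        aucs = [f.auc for f in report.folds]
        assert min(aucs) <= report.summary["auc"]["mean"] <= max(aucs)

    def test_k_exceeding_participants_rejected(self):
        with pytest.raises(ValueError):
            participant_folds(["A", "B"], 3)
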