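import numpy as np
import pytest

from cglkit.embeddings import EmbedderSpec
from cglkit.model import ActivityLabel, ModelConfig
from cglkit.simulate import FamilySpec, embed_records, generate_family
from cglkit.training import (HyperparameterSpace, TrainingConfig,
                             compute_metrics, inverse_frequency_weights,
                             rank_correlations, search_hyperparameters,
                             stratified_kfold, train_fold)


class TestStratifiedKFold:
    def test_exact_divisibility(self):
        y = np.array([0] * 20 + [1] * 80)
        folds = stratified_kfold(y, k=5, seed=0)
        for f in range(5):
            sel = y[folds == f]
            assert (sel == 0).sum() == 4 and (sel == 1).sum() == 16

    def test_partition_disjoint_and_exhaustive(self):
        y = np.array([0] * 13 + [1] * 29 + [2] * 8)
        folds = stratified_kfold(y, k=4, seed=1)
        assert set(folds) == {0, 1, 2, 3}
        assert len(folds) == len(y)
        counts = np.bincount(y)
        for c, n in enumerate(counts):
            per_fold = [np.sum((folds == f) & (y == c)) for f in range(4)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_small_class_error_names_class(self):
        y = [ActivityLabel.HIGH] * 3 + [ActivityLabel.LOW] * 20
        with pytest.raises(ValueError, match="HIGH"):
            stratified_kfold(y, k=5)


class TestMetrics:
    def test_perfect_predictions(self):
        y = [0, 1, 2, 1, 0, 2]
        rep = compute_metrics(y, y)
        assert rep.accuracy == rep.macro_f1 == rep.mcc == 1.0

    def test_constant_predictor_on_balanced_binary_has_zero_mcc(self):
        y = [0] * 10 + [1] * 10
        rep = compute_metrics([0] * 20, y)
        assert rep.mcc == 0.0

    def test_three_class_counts_match_brute_force_formulas(self):
        truth = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2, 2])
        pred = np.array([0, 1, 0, 1, 1, 2, 0, 2, 2, 2, 1, 0])
        rep = compute_metrics(pred, truth)
        # independent implementation straight from the definitions
        f1s, tps = [], 0
        for c in (0, 1, 2):
            tp = np.sum((pred == c) & (truth == c))
            fp = np.sum((pred == c) & (truth != c))
            fn = np.sum((pred != c) & (truth == c))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
            tps += tp
        assert rep.macro_f1 == pytest.approx(np.mean(f1s))
        assert rep.accuracy == pytest.approx(tps / len(truth))
        # generalized multiclass correlation form
        n = len(truth)
        cov_xy = tps * n - sum(np.sum(pred == c) * np.sum(truth == c)
                               for c in (0, 1, 2))
        cov_xx = n**2 - sum(np.sum(pred == c)**2 for c in (0, 1, 2))
        cov_yy = n**2 - sum(np.sum(truth == c)**2 for c in (0, 1, 2))
        assert rep.mcc == pytest.approx(cov_xy / np.sqrt(cov_xx * cov_yy))

    def test_rejected_predictions_excluded(self):
        truth = [0, 1, 2, 1]
        pred = [0, -1, 2, 1]
        rep = compute_metrics(pred, truth)
        assert rep.n_rejected == 1
        assert rep.accuracy == 1.0

    def test_rejected_truth_is_an_error(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0, -1])

    def test_invariant_under_class_renaming(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 3, 60)
        pred = rng.integers(0, 3, 60)
        rep = compute_metrics(pred, truth)
        remap = np.array([2, 0, 1])
        rep2 = compute_metrics(remap[pred], remap[truth])
        assert rep.macro_f1 == pytest.approx(rep2.macro_f1)
        assert rep.mcc == pytest.approx(rep2.mcc)


def test_inverse_frequency_weights_normalized_to_mean_one():
    y = [0] * 5 + [1] * 50 + [2] * 10
    w = inverse_frequency_weights(y)
    assert w.mean() == pytest.approx(1.0)
    assert w[0] > w[2] > w[1]


@pytest.fixture(scope="module")
def tiny():
    fix = generate_family(FamilySpec(n_sequences=80, seed=2))
    emb = embed_records(fix.records, EmbedderSpec(dim=16, seed=2))
    y = np.array([int(l) for l in fix.labels])
    return emb, y


class TestTrainFold:

    def test_early_stopping_bound_and_best_checkpoint(self, tiny):
        emb, y = tiny
        mc = ModelConfig(d_model=16, num_blocks=0, n_heads=1, dropout=0.0)
        tc = TrainingConfig(learning_rate=1e-4, max_epochs=50, patience=3,
                            seed=0)
        res = train_fold(emb[:60], y[:60], emb[60:], y[60:], mc, tc)
        f1s = [h["val_macro_f1"] for h in res.history]
        assert res.best_val_macro_f1 == max(f1s)
        best_at = int(np.argmax(f1s))
        assert len(f1s) <= max(best_at + tc.patience + 1, tc.max_epochs)

    def test_non_improving_metric_runs_patience_plus_one_epochs(self, tiny):
        emb, y = tiny
        # learning rate 0 freezes the model, so the metric never improves
        mc = ModelConfig(d_model=16, num_blocks=0, n_heads=1, dropout=0.0)
        tc = TrainingConfig(learning_rate=1e-30, max_epochs=50, patience=5,
                            seed=0)
        res = train_fold(emb[:60], y[:60], emb[60:], y[60:], mc, tc)
        assert len(res.history) == tc.patience + 1

    def test_empty_train_split_is_an_error(self, tiny):
        emb, y = tiny
        mc = ModelConfig(d_model=16, num_blocks=0, n_heads=1)
        with pytest.raises(ValueError):
            train_fold([], y[:0], emb[:5], y[:5], mc, TrainingConfig())


class TestHyperparameterSearch:
    def test_budget_one_returns_single_config(self):
        space = HyperparameterSpace()
        best, log = search_hyperparameters(space, 1, lambda c: 0.5, seed=0)
        assert len(log) == 1 and log[0]["status"] == "ok"

    def test_samples_within_bounds(self):
        space = HyperparameterSpace()
        rng = np.random.default_rng(0)
        for _ in range(100):
            c = space.sample(rng)
            assert 4 <= c["num_blocks"] <= 10
            assert 1e-5 <= c["learning_rate"] <= 5e-3
            assert 0.1 <= c["dropout"] <= 0.7
            assert 1e-6 <= c["weight_decay"] <= 1e-2
            assert c["n_heads"] in (4, 8, 16)
            assert c["optimizer"] in ("adam", "adamw")
            assert 0.3 <= c["tau_high"] <= 0.9

    def test_converges_on_quadratic_objective(self):
        space = HyperparameterSpace()
        opt = np.log(3e-4)

        def objective(c):
            return -(np.log(c["learning_rate"]) - opt) ** 2

        best_small, _ = search_hyperparameters(space, 5, objective, seed=1)
        best_large, _ = search_hyperparameters(space, 200, objective, seed=1)
        assert abs(np.log(best_large["learning_rate"]) - opt) <= \
               abs(np.log(best_small["learning_rate"]) - opt)
        assert abs(np.log(best_large["learning_rate"]) - opt) < 0.3

    def test_failing_trials_are_logged_and_skipped(self):
        calls = {"n": 0}

        def objective(c):
            calls["n"] += 1
            if calls["n"] % 2:
                raise RuntimeError("boom")
            return calls["n"]

        best, log = search_hyperparameters(HyperparameterSpace(), 6,
                                           objective, seed=2)
        assert sum(e["status"] == "ok" for e in log) == 3


class TestRankCorrelations:
    def test_identical_rankings(self):
        assert rank_correlations([1, 2, 3, 4], [10, 20, 30, 40]) == (1.0, 1.0)

    def test_reversed_rankings(self):
        rho, tau = rank_correlations([1, 2, 3, 4], [4, 3, 2, 1])
        assert (rho, tau) == (-1.0, -1.0)

    def test_tau_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal(8)
        g = rng.standard_normal(8)
        _, tau = rank_correlations(s, g)
        conc = disc = 0
        for i in range(8):
            for j in range(i + 1, 8):
                prod = (s[i] - s[j]) * (g[i] - g[j])
                conc += prod > 0
                disc += prod < 0
        assert tau == pytest.approx((conc - disc) / (8 * 7 / 2))

    def test_constant_input_returns_nan(self):
        rho, tau = rank_correlations([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(rho) and np.isnan(tau)
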