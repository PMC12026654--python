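import numpy as np
import pandas as pd
import pytest

from plantlnc import (
    Hyperparameters,
    LabeledDataset,
    ablation_by_category,
    compute_metrics,
    cross_species_eval,
    cross_species_table,
    metrics_from_counts,
    pearson_matrix,
    redundancy_filter,
    reintroduction_experiment,
    simulate_dataset,
)

FAST_HP = Hyperparameters(n_estimators=40, max_depth=3)


class TestMetrics:
    def test_perfect_classifier(self):
        y = np.array([1] * 10 + [0] * 10)
        r = compute_metrics(y, y, y.astype(float))
        assert r.ACC == 100.0 and r.MCC == 1.0 and r.AUC == 1.0

    def test_all_negative_predictor_zero_marginal(self):
        y = np.array([1] * 5 + [0] * 5)
        p = np.zeros(10, dtype=int)
        r = compute_metrics(y, p)
        assert r.SN == 0.0 and r.SP == 100.0
        assert r.MCC == 0.0  # zero-marginal convention
        assert r.F1 == 0.0

    def test_counts_match_direct_arithmetic(self):
        """compute_metrics agrees with hand arithmetic on random matrices."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + tn + fp + fn == 0:
                continue
            r = metrics_from_counts(int(tp), int(tn), int(fp), int(fn))
            n = tp + tn + fp + fn
            assert r.ACC == pytest.approx(100 * (tp + tn) / n)
            if tp + fn:
                assert r.SN == pytest.approx(100 * tp / (tp + fn))
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            if denom:
                assert r.MCC == pytest.approx(
                    (tp * tn - fp * fn) / np.sqrt(denom)
                )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        s = rng.uniform(size=200)
        perm = rng.permutation(200)
        a = compute_metrics(y, p, s)
        b = compute_metrics(y[perm], p[perm], s[perm])
        assert a.to_dict() == b.to_dict()

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(8)
        y = np.concatenate([np.ones(5000, int), np.zeros(5000, int)])
        s = rng.uniform(size=10000)
        r = compute_metrics(y, (s >= 0.5).astype(int), s)
        assert r.AUC == pytest.approx(0.5, abs=0.03)

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 300)
        s = rng.uniform(size=300)
        r = compute_metrics(y, (s >= 0.5).astype(int), s)
        fpr = [p[0] for p in r.roc_points]
        tpr = [p[1] for p in r.roc_points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)
        assert 0 <= r.AUC <= 1

    def test_length_mismatch_and_nonbinary(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 0], [1])
        with pytest.raises(ValueError):
            compute_metrics([1, 2], [1, 0])


class TestPearson:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=500)
        X = np.column_stack([a, a, -a])
        rho = pearson_matrix(X)
        assert rho[0, 1] == pytest.approx(1.0)
        assert rho[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(123)
        X = rng.standard_normal((10000, 2))
        assert abs(pearson_matrix(X)[0, 1]) < 0.05

    def test_zero_variance_column_handled(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.normal(size=50), np.full(50, 3.0)])
        rho = pearson_matrix(X)
        assert rho[0, 1] == 0.0 and rho[1, 1] == 1.0

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            pearson_matrix(np.zeros((1, 3)))


class TestRedundancyFilter:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(0)
        a, c = rng.normal(size=200), rng.normal(size=200)
        X = np.column_stack([a, a, c])
        report = redundancy_filter(X, ["c1", "c2", "c3"], 0.8, seed=0)
        assert len(report.retained) == 2 and len(report.redundant) == 1
        assert report.redundant[0] in ("c1", "c2")
        assert "c3" in report.retained

    def test_threshold_one_removes_nothing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 4)) + 0.2 * rng.normal(size=(100, 1))
        report = redundancy_filter(X, list("abcd"), 1.0, seed=0)
        assert report.redundant == []

    def test_postcondition_no_retained_pair_above_threshold(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(300, 3))
        # correlated copies with noise
        X = np.hstack([base, base + 0.05 * rng.normal(size=(300, 3))])
        names = [f"f{i}" for i in range(6)]
        report = redundancy_filter(X, names, 0.8, seed=4)
        idx = [names.index(n) for n in report.retained]
        sub = np.abs(report.rho[np.ix_(idx, idx)])
        np.fill_diagonal(sub, 0)
        assert (sub <= 0.8).all()
        assert sorted(report.retained + report.redundant) == sorted(names)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=150)
        X = np.column_stack([a, a + 0.01 * rng.normal(size=150), rng.normal(size=150)])
        r1 = redundancy_filter(X, list("xyz"), 0.8, seed=7)
        r2 = redundancy_filter(X, list("xyz"), 0.8, seed=7)
        assert r1.retained == r2.retained


def _split_label_ds(n=240, d=6, seed=0, informative=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = (X[:, informative] > 0).astype(int)
    return LabeledDataset(
        X, y, [f"r{i}" for i in range(n)], [f"f{j}" for j in range(d)]
    )


class TestReintroduction:
    def test_zero_redundant_gives_baseline_only(self):
        tr, te = _split_label_ds(seed=1), _split_label_ds(seed=2)
        table = reintroduction_experiment(tr, te, [], FAST_HP, seed=0)
        assert len(table) == 1
        assert table.iloc[0]["added_feature"] == "(baseline)"

    def test_noise_column_barely_moves_accuracy(self):
        tr, te = _split_label_ds(seed=3), _split_label_ds(seed=4)
        table = reintroduction_experiment(tr, te, ["f5"], FAST_HP, seed=0)
        assert abs(table.iloc[1]["ACC"] - table.iloc[0]["ACC"]) < 2.0

    def test_informative_column_restores_accuracy(self):
        tr = _split_label_ds(seed=5, informative=2)
        te = _split_label_ds(seed=6, informative=2)
        table = reintroduction_experiment(tr, te, ["f2"], FAST_HP, seed=0)
        assert table.iloc[1]["ACC"] > table.iloc[0]["ACC"]

    def test_unknown_feature_rejected(self):
        tr, te = _split_label_ds(), _split_label_ds(seed=9)
        with pytest.raises(KeyError):
            reintroduction_experiment(tr, te, ["ghost"], FAST_HP)


class TestAblation:
    def test_category_sizes_and_fusion(self, pipeline_dataset):
        table = ablation_by_category(pipeline_dataset, hp=FAST_HP, seed=0)
        sizes = dict(zip(table["combination"], table["n_features"]))
        assert sizes == {
            "all": 100, "sequence": 90, "structure": 7, "biological": 3
        }
        accs = dict(zip(table["combination"], table["ACC"]))
        # ORF features alone separate the simulated classes
        assert accs["biological"] > 70.0
        # fusion is not materially worse than any single family
        assert accs["all"] >= max(accs.values()) - 2.0


@pytest.fixture(scope="module")
def two_species():
    a = simulate_dataset(
        80, 80, seed=21, length_range=(200, 350), gc_target=0.35
    )
    b = simulate_dataset(
        80, 80, seed=22, length_range=(200, 350), gc_target=0.55
    )
    b.ids = [f"b_{i}" for i in b.ids]
    return {"low_gc": a, "high_gc": b}


class TestCrossSpecies:
    def test_grid_shape_and_diagonal(self, two_species):
        grid = cross_species_eval(two_species, hp=FAST_HP, seed=0)
        assert set(grid) == {"low_gc", "high_gc"}
        table = cross_species_table(grid, "ACC")
        assert table.shape == (2, 2)
        for name in grid:
            assert grid[name][name].n == 48  # 30% holdout of 160

    def test_distribution_shift_hurts_on_average(self, two_species):
        grid = cross_species_eval(two_species, hp=FAST_HP, seed=0)
        diag = np.mean([grid[g][g].ACC for g in grid])
        off = np.mean(
            [grid[g][h].ACC for g in grid for h in grid if g != h]
        )
        assert off <= diag

    def test_leakage_guard(self, two_species):
        leaky = {
            "a": two_species["low_gc"],
            "b": two_species["low_gc"],  # identical ids
        }
        with pytest.raises(ValueError, match="overlap"):
            cross_species_eval(leaky, hp=FAST_HP, seed=0)
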