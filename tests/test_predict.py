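"""Random-forest CV prediction: metrics arithmetic, sweep, invariances."""

import numpy as np
import pandas as pd
import pytest

from capmech.predict import (
    FEATURE_NAMES,
    FeatureTable,
    assemble_features,
    best_single_and_combination,
    cross_validated_probabilities,
    evaluate_subset,
    improvement_report,
    metrics,
    sweep_combinations,
)


def make_table(n=60, n_pos=12, signal=2.0, seed=0):
    """Synthetic feature table: the two cap features carry the signal."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * n_pos + [-1] * (n - n_pos))
    X = pd.DataFrame(
        rng.normal(size=(n, 9)), columns=list(FEATURE_NAMES),
        index=[f"s{i}" for i in range(n)],
    )
    X["MinCapT"] -= signal * (y == 1)
    X["PB"] += signal * (y == 1)
    return FeatureTable(X, pd.Series(y, index=X.index))


class TestMetrics:
    def test_confusion_arithmetic(self):
        """TP=9, FN=7, TN=94, FP=4 at the Youden cutoff."""
        p = np.concatenate([
            np.full(9, 0.9), np.full(7, 0.01),  # positives
            np.full(94, 0.05), np.full(4, 0.95),  # negatives
        ])
        y = np.concatenate([np.ones(16), -np.ones(98)])
        r = metrics(p, y)
        assert r.acc == pytest.approx(103 / 114)
        assert r.sen == pytest.approx(9 / 16)
        assert r.spe == pytest.approx(94 / 98)

    def test_perfect_prediction(self):
        p = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, -1, -1])
        r = metrics(p, y)
        assert (r.acc, r.sen, r.spe, r.auc) == (1.0, 1.0, 1.0, 1.0)

    def test_constant_probabilities_chance_auc(self):
        r = metrics(np.full(10, 0.4), np.array([1] * 3 + [-1] * 7))
        assert r.auc == 0.5

    def test_acc_decomposition_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.uniform(0, 1, 40)
            y = np.where(rng.uniform(size=40) < 0.3, 1, -1)
            if len(np.unique(y)) < 2:
                continue
            r = metrics(p, y)
            acc = (r.sen * r.n_pos + r.spe * r.n_neg) / (r.n_pos + r.n_neg)
            assert abs(r.acc - acc) < 1e-12

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.01, 0.99, 50)
        y = np.where(rng.uniform(size=50) < 0.4, 1, -1)
        a1 = metrics(p, y).auc
        a2 = metrics(p**3, y).auc  # strictly monotone on [0, 1]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            metrics(np.array([0.5, 0.6]), np.array([1, 1]))


class TestCrossValidation:
    def test_deterministic_given_seed(self):
        t = make_table()
        p1 = cross_validated_probabilities(t, ("MinCapT", "PB"), n_repeats=3, seed=9)
        p2 = cross_validated_probabilities(t, ("MinCapT", "PB"), n_repeats=3, seed=9)
        np.testing.assert_array_equal(p1, p2)

    def test_separable_data_confident_probabilities(self):
        t = make_table(n=60, n_pos=24, signal=6.0)
        p = cross_validated_probabilities(t, ("MinCapT", "PB"), n_repeats=20, seed=1)
        y = t.target.to_numpy()
        assert np.all(p[y == 1] >= 0.9)
        assert np.all(p[y == -1] <= 0.1)

    def test_doubling_trees_changes_little(self):
        t = make_table(signal=3.0)
        r50 = evaluate_subset(t, ("MinCapT", "PB"), n_trees=50, n_repeats=10, seed=3)
        r100 = evaluate_subset(t, ("MinCapT", "PB"), n_trees=100, n_repeats=10, seed=3)
        assert abs(r50.acc - r100.acc) < 0.02
        assert abs(r50.sen - r100.sen) < 0.05
        assert abs(r50.spe - r100.spe) < 0.05

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            cross_validated_probabilities(make_table(), ())


class TestSweep:
    def test_three_feature_debug_sweep(self):
        t = make_table(n=40, n_pos=10)
        res = sweep_combinations(t, n_trees=20, n_repeats=2, seed=0,
                                 features=("MinCapT", "PB", "LA"))
        assert len(res) == 7  # 2^3 - 1
        accs = [r.acc for r in res]
        assert accs == sorted(accs, reverse=True)

    def test_best_combination_not_worse_than_best_single(self):
        t = make_table(n=60, n_pos=15, signal=3.0)
        res = sweep_combinations(t, n_trees=20, n_repeats=3, seed=1,
                                 features=("MinCapT", "PB", "LA"))
        single, combo = best_single_and_combination(res)
        assert combo.acc >= single.acc - 0.02  # CV noise tolerance


class TestAssembleFeatures:
    def _tables(self, n=8):
        idx = [f"s{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        morph = pd.DataFrame(
            rng.normal(size=(n, 5)),
            columns=["LA", "PA", "PB", "MinCapT", "MeanCapT"], index=idx,
        )
        mech = pd.DataFrame(
            rng.normal(size=(n, 4)),
            columns=["MaxCapS", "MeanCapS", "MaxCapSn", "MeanCapSn"], index=idx,
        )
        y = pd.Series([1, 1, -1, -1] * (n // 4), index=idx)
        return morph, mech, y

    def test_joined_shape(self):
        morph, mech, y = self._tables()
        t = assemble_features(morph, mech, y)
        assert t.frame.shape == (8, 9)
        assert list(t.frame.columns) == list(FEATURE_NAMES)

    def test_missing_cap_excluded_with_warning(self):
        morph, mech, y = self._tables()
        morph.loc["s0", "MinCapT"] = np.nan
        with pytest.warns(UserWarning, match="without cap"):
            t = assemble_features(morph, mech, y)
        assert t.n == 7

    def test_duplicate_id_rejected(self):
        morph, mech, y = self._tables()
        morph = pd.concat([morph, morph.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicated"):
            assemble_features(morph, mech, y)

    def test_orphan_ids_rejected(self):
        morph, mech, y = self._tables()
        with pytest.raises(ValueError, match="orphan|both"):
            assemble_features(morph.iloc[:-1], mech, y)


class TestImprovementReport:
    def test_reported_arithmetic(self):
        per_index = {
            "C": (90.3, 83.7, 0.877),
            "MaxS": (77.9, 65.4, 0.776),
            "MeanS": (85.6, 75.6, 0.867),
            "MaxSn": (87.1, 79.8, 0.935),
            "MeanSn": (83.3, 75.3, 0.809),
        }
        rep = improvement_report(per_index)
        assert rep["improvement_points"]["C"] == pytest.approx(6.6)
        assert rep["improvement_points"]["MaxS"] == pytest.approx(12.5)
        assert rep["improvement_points"]["MeanS"] == pytest.approx(10.0)
        assert rep["improvement_points"]["MaxSn"] == pytest.approx(7.3)
        assert rep["improvement_points"]["MeanSn"] == pytest.approx(8.0)
        assert rep["mean_improvement_points"] == pytest.approx(8.9)
        assert rep["mean_auc"] == pytest.approx(0.853)
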