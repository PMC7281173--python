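import numpy as np
import pandas as pd
import pytest

from marrowpet.classify import (
    MLPConfig,
    auc,
    run_experiment,
    stratified_split,
    train_mlp,
)

from oracles import auc_pairs_oracle


class TestStratifiedSplit:
    def test_reference_cohort_split_sizes(self):
        """97 cases with 67 positives at 70/30 -> 68-patient training cohort
        with 47 positives."""
        labels = np.array([True] * 67 + [False] * 30)
        tr, te = stratified_split(labels, 0.70, seed=5)
        assert len(tr) == 68 and len(te) == 29
        assert labels[tr].sum() == 47
        assert labels[te].sum() == 20

    def test_balanced_ten(self):
        labels = np.array([True] * 5 + [False] * 5)
        tr, te = stratified_split(labels, 0.7, seed=1)
        assert len(tr) == 8 and len(te) == 2  # 3.5 rounds half-up to 4 per class
        assert labels[tr].sum() == 4

    def test_disjoint_exhaustive(self, rng):
        labels = rng.random(37) < 0.6
        tr, te = stratified_split(labels, 0.7, seed=3)
        assert sorted(np.concatenate([tr, te]).tolist()) == list(range(37))

    def test_deterministic(self):
        labels = np.array([True, False] * 20)
        a = stratified_split(labels, 0.7, seed=9)
        b = stratified_split(labels, 0.7, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            stratified_split(np.ones(10, dtype=bool), 0.7, seed=0)


class TestTrainMLP:
    def test_separable_blobs_fit_perfectly(self, rng):
        """Well-separated 2D blobs (5 SD apart) are fit to 100% training
        accuracy by the 3-unit tanh network, for every seed."""
        n = 30
        X = np.vstack([rng.standard_normal((n, 2)), rng.standard_normal((n, 2)) + 5.0])
        y = np.array([0] * n + [1] * n)
        Xs = (X - X.mean(0)) / X.std(0)
        for seed in range(5):
            fitted = train_mlp(Xs, y, MLPConfig(), seed=seed)
            acc = np.mean((fitted.predict_proba(Xs) >= 0.5) == y)
            assert acc == 1.0

    def test_deterministic_probabilities(self, rng):
        X = rng.standard_normal((40, 3))
        y = (X[:, 0] > 0).astype(int)
        p1 = train_mlp(X, y, seed=4).predict_proba(X)
        p2 = train_mlp(X, y, seed=4).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_permuted_labels_near_chance(self, rng):
        """With labels shuffled, held-out AUC sits in the permutation-null
        band at n_test = 30."""
        X = rng.standard_normal((100, 4))
        y = rng.permutation([0] * 50 + [1] * 50)
        tr, te = stratified_split(y.astype(bool), 0.7, seed=2)
        fitted = train_mlp(X[tr], y[tr], seed=2)
        a = auc(fitted.predict_proba(X[te]), y[te])
        assert 0.3 <= a <= 0.7

    def test_nonfinite_input_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            train_mlp(X, np.array([0, 1] * 5))

    def test_single_class_training_rejected(self, rng):
        with pytest.raises(ValueError, match="single-class"):
            train_mlp(rng.standard_normal((6, 2)), np.zeros(6))

    def test_config_minima_enforced(self):
        with pytest.raises(ValueError):
            MLPConfig(units_per_layer=2)
        with pytest.raises(ValueError):
            MLPConfig(n_hidden_layers=0)


class TestAUC:
    def test_perfect_ordering(self):
        assert auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_tied_scores(self):
        assert auc(np.full(6, 0.5), np.array([0, 1, 0, 1, 0, 1])) == 0.5

    def test_worked_example_with_tie(self):
        scores = np.array([0.1, 0.4, 0.4, 0.6, 0.7, 0.2])
        labels = np.array([0, 0, 1, 1, 1, 0])
        assert auc(scores, labels) == pytest.approx(auc_pairs_oracle(scores, labels))

    def test_matches_pair_enumeration_small_instances(self, rng):
        """Rank-sum AUC equals exhaustive pair counting on every random
        instance up to n = 12, ties included."""
        for n in range(2, 13):
            for _ in range(20):
                labels = np.zeros(n, dtype=bool)
                k = rng.integers(1, n)
                labels[rng.permutation(n)[:k]] = True
                scores = rng.integers(0, 4, size=n) / 3.0  # coarse grid forces ties
                assert auc(scores, labels) == pytest.approx(
                    auc_pairs_oracle(scores, labels), abs=1e-12
                )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))


def _toy_cohort(rng, n=80):
    involved = rng.random(n) < 0.65
    rel = np.where(involved, rng.uniform(1, 80, n), 0.0)
    cell = rng.uniform(30, 90, n)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "scanner_id": rng.choice(["S1", "S2"], n),
            "involved": involved.astype(int),
            "rel": rel,
            "cellularity": cell,
            "abs": cell * rel / 100,
            "wbc": rng.uniform(4, 20, n) + 3 * involved,
            "ldh": rng.uniform(150, 350, n),
            "ki67": rng.uniform(5, 80, n),
        }
    )


class TestRunExperiment:
    def test_report_schema_and_run_counts(self, rng):
        cohort = _toy_cohort(rng)
        n = len(cohort)
        suv = pd.DataFrame(rng.standard_normal((n, 3)), columns=["suv_max", "suv_mean", "suv_peak"])
        scores = pd.DataFrame(rng.standard_normal((n, 4)), columns=[f"PC{i+1}" for i in range(4)])
        scores["PC1"] += cohort["involved"]
        report = run_experiment(cohort, suv, scores, master_seed=3)
        frame = report.frame()
        # labs variant exists for every endpoint except the Ki-67 task
        expected_cells = 6 * 3 - 1
        assert len(frame) == expected_cells * 5
        assert (frame.groupby(["endpoint", "feature_set"]).size() == 5).all()
        assert not (
            (frame["endpoint"] == "ki67") & (frame["feature_set"] == "signature+labs")
        ).any()
        summary = report.summary()
        for m in ("train_accuracy", "test_accuracy", "auc"):
            assert (summary[f"{m}_min"] <= summary[f"{m}_median"]).all()
            assert (summary[f"{m}_median"] <= summary[f"{m}_max"]).all()
        assert frame["train_accuracy"].between(0, 100).all()
        assert frame["auc"].between(0, 1).all()

    def test_ki67_task_restricted_to_involved(self, rng):
        cohort = _toy_cohort(rng)
        n = len(cohort)
        suv = pd.DataFrame(rng.standard_normal((n, 3)), columns=["suv_max", "suv_mean", "suv_peak"])
        scores = pd.DataFrame(rng.standard_normal((n, 2)), columns=["PC1", "PC2"])
        from marrowpet.classify import endpoint_labels
        from marrowpet.cohort import ENDPOINTS

        pos, labels = endpoint_labels(cohort, ENDPOINTS["ki67"])
        assert len(pos) == int(cohort["involved"].sum())
        assert len(labels) == len(pos)

    def test_determinism_of_full_experiment(self, rng):
        cohort = _toy_cohort(rng, n=50)
        n = len(cohort)
        suv = pd.DataFrame(rng.standard_normal((n, 3)), columns=["suv_max", "suv_mean", "suv_peak"])
        scores = pd.DataFrame(rng.standard_normal((n, 2)), columns=["PC1", "PC2"])
        r1 = run_experiment(cohort, suv, scores, endpoints=("involved",), master_seed=8)
        r2 = run_experiment(cohort, suv, scores, endpoints=("involved",), master_seed=8)
        assert r1.frame().equals(r2.frame())

    def test_suv_feature_set_has_three_inputs(self, rng):
        from marrowpet.classify import feature_matrix

        cohort = _toy_cohort(rng, n=20)
        suv = pd.DataFrame(rng.standard_normal((20, 3)), columns=["suv_max", "suv_mean", "suv_peak"])
        scores = pd.DataFrame(rng.standard_normal((20, 5)), columns=[f"PC{i+1}" for i in range(5)])
        assert feature_matrix("suv", suv, scores, cohort).shape[1] == 3
        assert feature_matrix("signature", suv, scores, cohort).shape[1] == 5
        assert feature_matrix("signature+labs", suv, scores, cohort).shape[1] == 7
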