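"""Feature assembly, MDA/EM, discrimination strings, trees, jackknife."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from surfionomics.discriminant import (
    assemble_features,
    build_tree,
    discriminate,
    jackknife_importance,
    mda_fit,
)


def gaussian_classes(rng, means, n_per, scale=1.0):
    means = np.asarray(means, float)
    X = np.vstack([rng.normal(m, scale, (n_per, means.shape[1])) for m in means])
    y = np.repeat(np.arange(len(means)), n_per)
    return X, y


class TestAssemble:
    def test_shape_and_blocks(self):
        idx = [f"{t}__f{i}" for t in ("A", "B") for i in range(3)]
        ionic = pd.DataFrame({"Li_count": np.arange(6.0)}, index=idx)
        anat = pd.DataFrame({"entropy": np.linspace(0, 1, 6)}, index=idx)
        fm = assemble_features(ionic, anat)
        assert fm.X.shape == (6, 2)
        assert fm.blocks == {"ion__Li_count": "ionic", "anat__entropy": "anatomical"}
        # standardized columns
        assert np.allclose(fm.X.mean(), 0.0) and np.allclose(fm.X.std(ddof=0), 1.0)

    def test_constant_column_dropped_with_warning(self):
        idx = list("abcdef")
        ionic = pd.DataFrame({"x": np.arange(6.0), "flat": 1.0}, index=idx)
        with pytest.warns(UserWarning, match="zero-variance"):
            fm = assemble_features(ionic)
        assert fm.columns == ["ion__x"]

    def test_observation_mismatch_rejected(self):
        ionic = pd.DataFrame({"x": [1.0, 2.0]}, index=["a", "b"])
        anat = pd.DataFrame({"y": [1.0, 2.0]}, index=["a", "c"])
        with pytest.raises(ValueError):
            assemble_features(ionic, anat)

    def test_missing_values_rejected(self):
        ionic = pd.DataFrame({"x": [1.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError):
            assemble_features(ionic)


class TestMDA:
    @pytest.mark.parametrize("trial", range(5))
    def test_single_subclass_matches_lda(self, trial):
        rng = np.random.default_rng(500 + trial)
        K = int(rng.integers(2, 5))
        p = int(rng.integers(2, 6))
        X, y = gaussian_classes(rng, rng.normal(0, 2, (K, p)), n_per=20)
        model = mda_fit(X, y, n_subclasses=1, seed=trial)
        lda = LinearDiscriminantAnalysis().fit(X, y)
        assert np.array_equal(model.predict(X).astype(int), lda.predict(X))

    def test_loglik_monotone(self, rng):
        X, y = gaussian_classes(rng, [[0, 0], [1.5, 0], [0, 1.5]], n_per=25)
        model = mda_fit(X, y, n_subclasses=3, seed=0)
        trace = np.asarray(model.loglik_trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) >= -1e-7)

    def test_separated_classes_perfect_training_accuracy(self, rng):
        X, y = gaussian_classes(rng, [[-10, -10], [10, 10]], n_per=25)
        model = mda_fit(X, y, n_subclasses=2, seed=0)
        assert model.score() == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(77)
        X = rng.normal(0, 1, (300, 2))
        y = rng.permutation(np.repeat(np.arange(3), 100))
        model = mda_fit(X, y, n_subclasses=1, seed=0)
        assert model.score() == pytest.approx(1 / 3, abs=0.10)

    def test_weights_simplex_and_spd_covariance(self, rng):
        X, y = gaussian_classes(rng, [[0, 0, 0], [3, 0, 0]], n_per=30)
        model = mda_fit(X, y, n_subclasses=3, seed=1)
        for w in model.weights:
            assert w.sum() == pytest.approx(1.0)
            assert (w >= 0).all()
        evals = np.linalg.eigvalsh(model.cov)
        assert (evals > 0).all()
        assert np.allclose(model.cov, model.cov.T)

    def test_more_parameters_than_rows_is_reduced_not_fatal(self, rng):
        X = rng.normal(0, 1, (12, 40))
        X[:6] += 4.0
        y = np.repeat([0, 1], 6)
        model = mda_fit(X, y, n_subclasses=2, seed=0)
        assert model.projection is not None
        assert model.score() == 1.0

    def test_small_class_caps_subclass_count(self, rng):
        # a class with fewer rows than subclasses gets one subclass per row
        X = np.vstack([rng.normal(0, 1, (2, 3)), rng.normal(5, 1, (30, 3))])
        y = np.array(["small"] * 2 + ["big"] * 30)
        model = mda_fit(X, y, n_subclasses=3, seed=0)
        k_small = model.classes_.index("small")
        assert len(model.weights[k_small]) <= 2
        assert model.score() == 1.0


class TestDiscriminate:
    def collinear_model(self, centers=(0.0, 1.0, 10.0), n_per=20, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal([c, 0], 0.3, (n_per, 2)) for c in centers])
        y = np.array([t for t in "ABC" for _ in range(n_per)])
        return mda_fit(X, y, n_subclasses=1, seed=seed)

    def test_string_and_neighbor_matrix(self):
        res = discriminate(self.collinear_model())
        assert res.string in (["A", "B", "C"], ["C", "B", "A"])
        M = res.binary_matrix
        assert M.loc["A", "B"] == 1 and M.loc["B", "C"] == 1 and M.loc["A", "C"] == 0

    def test_collinear_centroids_keep_near_pair_adjacent(self):
        res = discriminate(self.collinear_model())
        s = res.string
        assert abs(s.index("A") - s.index("B")) == 1

    def test_two_treatments_always_neighbors(self, rng):
        X = np.vstack([rng.normal(-2, 1, (10, 3)), rng.normal(2, 1, (10, 3))])
        y = np.array(["A"] * 10 + ["B"] * 10)
        res = discriminate(mda_fit(X, y, n_subclasses=1, seed=0))
        assert res.binary_matrix.to_numpy().tolist() == [[0, 1], [1, 0]]

    def test_matrix_invariants_on_random_data(self, rng):
        X = rng.normal(0, 1, (40, 4))
        y = np.array([t for t in "ABCDE" for _ in range(8)])
        res = discriminate(mda_fit(X, y, n_subclasses=1, seed=3))
        M = res.binary_matrix.to_numpy()
        assert np.array_equal(M, M.T)
        assert not np.diag(M).any()
        assert (M.sum(axis=1) <= 2).all()
        assert sorted(res.string) == list("ABCDE")

    def test_string_canonicalized_lexicographically(self, rng):
        res = discriminate(self.collinear_model())
        assert list(res.string) <= list(reversed(res.string))

    def test_gate_merges_identical_treatments(self, rng):
        # A and B drawn from one distribution, C far away
        X = np.vstack([rng.normal(0, 1, (16, 3)), rng.normal(0, 1, (16, 3)),
                       rng.normal(8, 1, (16, 3))])
        y = np.array(["A"] * 16 + ["B"] * 16 + ["C"] * 16)
        model = mda_fit(X, y, n_subclasses=1, seed=0)
        res = discriminate(model, n_permutations=499, alpha=0.05, seed=0)
        groups = sorted(map(sorted, res.groups))
        assert ["A", "B"] in groups and ["C"] in groups
        assert res.binary_matrix.loc["A", "C"] == 0
        assert res.binary_matrix.loc["B", "C"] == 0


class TestTree:
    def matrix(self, data, labels):
        return pd.DataFrame(data, index=labels, columns=labels)

    def test_single_matrix_first_merge(self):
        M = self.matrix([[0, 1, 0], [1, 0, 0], [0, 0, 0]], list("ABC"))
        tree = build_tree([M])
        first = sorted(tree.clusters_at(0.5), key=len)[-1]
        assert first == {"A", "B"}
        assert tree.merge_heights()[0] == pytest.approx(0.0)

    def test_repeated_matrix_idempotent(self):
        M = self.matrix([[0, 1, 0], [1, 0, 0], [0, 0, 0]], list("ABC"))
        t1 = build_tree([M])
        t3 = build_tree([M, M.copy(), M.copy()])
        assert np.allclose(t1.linkage_matrix, t3.linkage_matrix)
        assert t1.newick() == t3.newick()

    def test_consistent_pairing_isolates_last_label(self):
        labels = ["Control", "EtOH", "Steam", "Microwave", "NaOH"]
        M = pd.DataFrame(0, index=labels, columns=labels)
        M.loc["Control", "EtOH"] = M.loc["EtOH", "Control"] = 1
        M.loc["Steam", "Microwave"] = M.loc["Microwave", "Steam"] = 1
        tree = build_tree([M])
        clusters = tree.clusters_at(0.5)
        assert {"Steam", "Microwave"} in clusters
        assert {"Control", "EtOH"} in clusters
        assert {"NaOH"} in clusters

    def test_label_mismatch_rejected(self):
        A = self.matrix(np.zeros((2, 2)), list("AB"))
        B = self.matrix(np.zeros((2, 2)), list("AC"))
        with pytest.raises(ValueError):
            build_tree([A, B])

    def test_newick_contains_all_labels(self):
        M = self.matrix([[0, 1, 0], [1, 0, 0], [0, 0, 0]], list("ABC"))
        nwk = build_tree([M]).newick()
        assert nwk.endswith(";")
        for lab in "ABC":
            assert lab in nwk


class TestJackknife:
    def planted_matrix(self, seed, p_noise=5, effect=2.5, n_per=10):
        rng = np.random.default_rng(seed)
        y = np.repeat(np.arange(3), n_per)
        planted = (y - 1) * effect + rng.normal(0, 1, y.size)
        X = np.column_stack([planted] + [rng.normal(0, 1, y.size) for _ in range(p_noise)])
        return X, y

    def test_pure_noise_importances_near_zero(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            y = np.repeat(np.arange(3), 80)
            X = rng.normal(0, 1, (240, 5))
            report = jackknife_importance(X, y, n_subclasses=1, seed=seed)
            drop_points = report["misclass_increase"].abs().max() / len(y) * 100
            assert drop_points < 10.0

    def test_planted_column_ranks_first(self):
        X, y = self.planted_matrix(seed=42)
        report = jackknife_importance(X, y, n_subclasses=2, seed=0)
        assert report.iloc[0]["group"] == "x0"
        assert sorted(report["rank"]) == list(range(1, 7))

    def test_duplicated_planted_column_loses_importance(self):
        X, y = self.planted_matrix(seed=7)
        solo = jackknife_importance(X, y, n_subclasses=1, seed=0)
        imp_solo = float(solo.set_index("group").loc["x0", "importance_pct"])
        Xdup = np.column_stack([X, X[:, 0]])
        dup = jackknife_importance(Xdup, y, n_subclasses=1, seed=0).set_index("group")
        assert dup.loc["x0", "importance_pct"] < imp_solo
        assert dup.loc["x6", "importance_pct"] < imp_solo

    def test_group_removal_and_errors(self):
        X, y = self.planted_matrix(seed=3, p_noise=2)
        names = ["x0", "x1", "x2"]
        report = jackknife_importance(
            pd.DataFrame(X, columns=names), y,
            groups={"signal": ["x0"], "noise": ["x1", "x2"]},
            n_subclasses=1, seed=0,
        )
        assert report.iloc[0]["group"] == "signal"
        with pytest.raises(ValueError):
            jackknife_importance(
                pd.DataFrame(X, columns=names), y,
                groups={"all": names}, n_subclasses=1, seed=0,
            )
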