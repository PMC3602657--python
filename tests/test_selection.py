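import itertools

import numpy as np
import pandas as pd
import pytest

import dbpred.modeling
from dbpred.selection import (
    _discretize_matrix,
    discretize,
    ifs,
    mrmr_rank,
    mutual_information,
)
from oracles import greedy_mid_oracle, mi_oracle, mi_table_oracle


class TestDiscretize:
    def test_boundary_arithmetic(self):
        # mean 2, population std 4 -> boundaries [-2, 6]
        np.testing.assert_array_equal(
            discretize(np.array([0, 0, 0, 0, 10.0])), [1, 1, 1, 1, 2]
        )

    def test_constant_feature_all_mid(self):
        np.testing.assert_array_equal(discretize(np.full(6, 3.3)), [1] * 6)

    def test_t_zero_limit(self):
        states = discretize(np.array([1.0, 2.0, 3.0]), t=0.0)
        np.testing.assert_array_equal(states, [0, 1, 2])  # only the mean is mid

    def test_low_state_reachable(self):
        np.testing.assert_array_equal(
            discretize(np.array([-10.0, 0, 0, 0, 0])), [0, 1, 1, 1, 1]
        )


class TestMutualInformation:
    def test_identical_balanced_binaries(self):
        x = np.array([0, 0, 1, 1])
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_constant_gives_zero(self):
        assert mutual_information(np.zeros(8), np.array([0, 1] * 4)) == 0.0

    def test_symmetry(self, rng):
        for _ in range(20):
            x = rng.integers(0, 3, 30)
            y = rng.integers(0, 2, 30)
            assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))

    def test_matches_oracle_on_exhaustive_small_tables(self):
        """Plug-in MI agrees with scikit-learn on every 2x2 table with cell
        counts <= 6 and every 3x2 table with cell counts <= 3."""
        checked = 0
        for cells in itertools.product(range(7), repeat=4):
            table = np.array(cells).reshape(2, 2)
            if table.sum() < 2:
                continue
            x = np.repeat([0, 0, 1, 1], cells)
            y = np.repeat([0, 1, 0, 1], cells)
            assert mutual_information(x, y) == pytest.approx(
                mi_table_oracle(table), abs=1e-10
            )
            checked += 1
        for cells in itertools.product(range(4), repeat=6):
            table = np.array(cells).reshape(3, 2)
            if table.sum() < 2:
                continue
            x = np.repeat([0, 0, 1, 1, 2, 2], cells)
            y = np.repeat([0, 1, 0, 1, 0, 1], cells)
            assert mutual_information(x, y) == pytest.approx(
                mi_table_oracle(table), abs=1e-10
            )
            checked += 1
        assert checked > 6000


class TestMRMRRank:
    def test_label_aligned_feature_ranked_first(self, rng):
        """The feature carrying the class signal has maximal relevance.

        (A literal 0/1 copy of a balanced label is invisible to the
        mean +/- std discretization — both values fall in the mid band — so
        the signal feature is continuous and class-shifted.)
        """
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 30))
        X[:, 13] = y * 5.0 + rng.normal(size=n)
        ranking = mrmr_rank(X, y, top_k=5)
        assert ranking.indices[0] == 13
        assert ranking.redundancy[0] == 0.0

    def test_duplicate_of_signal_feature_penalized(self, rng):
        """A verbatim copy of the already-selected signal feature is beaten by
        a weakly relevant but independent feature (MID redundancy term)."""
        n = 60
        y = np.repeat([0, 1], n // 2)
        strong = y * 5.0 + rng.normal(size=n)
        weak = y * 1.5 + rng.normal(size=n) * 1.5
        X = np.column_stack([strong, strong, weak])
        ranking = mrmr_rank(X, y, top_k=3)
        assert ranking.indices[0] == 0
        assert ranking.indices[1] == 2  # the copy (index 1) is not second

    def test_matches_exhaustive_mid_oracle(self, rng):
        """Full greedy ranking equals a brute-force MID search on 8 features."""
        for trial in range(5):
            X = rng.normal(size=(40, 8))
            y = (X[:, trial % 8] + 0.5 * rng.normal(size=40) > 0).astype(int)
            states = _discretize_matrix(X, t=1.0)
            expected = greedy_mid_oracle(states, y, top_k=8)
            got = mrmr_rank(X, y, top_k=8).indices.tolist()
            assert got == expected

    def test_scale_invariance(self, rng):
        X = rng.normal(size=(50, 12))
        y = (X[:, 3] > 0).astype(int)
        scales = rng.uniform(0.1, 50, size=12)
        offsets = rng.normal(0, 10, size=12)
        a = mrmr_rank(X, y, top_k=12).indices
        b = mrmr_rank(X * scales + offsets, y, top_k=12).indices
        np.testing.assert_array_equal(a, b)

    def test_top_k_truncated_with_warning(self, rng, caplog):
        X = rng.normal(size=(20, 5))
        y = np.repeat([0, 1], 10)
        with caplog.at_level("WARNING"):
            ranking = mrmr_rank(X, y, top_k=50)
        assert len(ranking) == 5
        assert "truncating" in caplog.text


class TestIFS:
    @pytest.fixture()
    def canned_curve(self, monkeypatch, rng):
        """Replace the SVM evaluation with a canned MCC per prefix size."""
        calls = []
        curve = {1: 0.5, 2: 0.9, 3: 0.7}

        def fake_grid_search(X, y, grid=None, cv_folds=5, seed=0):
            calls.append(X.shape[1])
            return dbpred.modeling.GridSearchResult(1.0, 1.0, {"MCC": curve[X.shape[1]]})

        monkeypatch.setattr(dbpred.modeling, "grid_search_svm", fake_grid_search)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        y = np.repeat([0, 1], 10)
        ranking = mrmr_rank(X, y, top_k=3)
        return X, y, ranking, calls, curve

    def test_peak_selection(self, canned_curve):
        X, y, ranking, calls, _ = canned_curve
        result = ifs(X, y, ranking, step=1, seed=0)
        assert result.optimal_count == 2
        assert calls == [1, 2, 3]

    def test_tie_breaks_to_smaller_count(self, canned_curve):
        X, y, ranking, _, curve = canned_curve
        curve[3] = 0.9
        result = ifs(X, y, ranking, step=1, seed=0)
        assert result.optimal_count == 2
        assert len(result.optimal_features) == 2

    def test_planted_signal_recovers_small_model(self, rng):
        """Only features 0-4 carry signal: the IFS peak stays small and its
        CV MCC is close to the 5-feature reference model."""
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 30))
        X[:, :5] += 1.6 * y[:, None]
        frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(30)])
        grid = [(1.0, 0.125)]
        ranking = mrmr_rank(frame, y, top_k=15)
        result = ifs(frame, y, ranking, step=1, seed=7, grid=grid, max_features=15)
        assert result.optimal_count <= 10
        oracle = dbpred.modeling.grid_search_svm(
            frame[[f"f{i}" for i in range(5)]], y, grid=grid, seed=7
        )
        assert result.mcc_curve.max() >= oracle.cv_report["MCC"] - 0.05

    def test_curve_reproducible(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 10)))
        X.columns = [f"f{i}" for i in range(10)]
        y = (X["f2"].to_numpy() > 0).astype(int)
        ranking = mrmr_rank(X, y, top_k=6)
        grid = [(1.0, 0.25)]
        a = ifs(X, y, ranking, step=2, seed=3, grid=grid)
        b = ifs(X, y, ranking, step=2, seed=3, grid=grid)
        np.testing.assert_array_equal(a.mcc_curve, b.mcc_curve)
        assert len(a.counts) == len(a.mcc_curve) == 4  # sizes 1,3,5,6
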