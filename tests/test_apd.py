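"""Applicability-domain thresholding and the Gower distance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoqstr.apd import APDModel, fit_apd, gower_distance, _gower_matrix
from nanoqstr.errors import ValidationError


class TestEuclideanAPD:
    def test_hand_computed_example(self):
        """Points {0,1,2,10}: retained {1,2,1} -> threshold 1.6220 at Z=0.5."""
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0]})
        m = fit_apd(df, metric="euclidean", Z=0.5, scale_numeric=False)
        assert m.mean_retained == pytest.approx(4 / 3, abs=1e-10)
        assert m.sd_retained == pytest.approx(np.sqrt(1 / 3), abs=1e-10)
        assert m.threshold == pytest.approx(1.6220, abs=1e-4)

    def test_zero_z_threshold_equals_mean(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0]})
        m = fit_apd(df, metric="euclidean", Z=0.0, scale_numeric=False)
        assert m.threshold == m.mean_retained

    def test_two_rows_cannot_retain_below_mean(self):
        with pytest.raises(ValidationError):
            fit_apd(pd.DataFrame({"x": [0.0, 1.0]}), metric="euclidean")

    def test_equal_distances_give_guidance_error(self):
        # one-hot rows: every pairwise distance is bit-identical sqrt(2)
        df = pd.DataFrame(np.eye(3), columns=list("xyz"))
        with pytest.raises(ValidationError, match="retain-below-mean"):
            fit_apd(df, metric="euclidean", scale_numeric=False)

    def test_matches_brute_force_oracle(self):
        """Threshold recomputed with an explicit double loop, to 1e-10."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 5))
        df = pd.DataFrame(X, columns=list("abcde"))
        m = fit_apd(df, metric="euclidean", Z=0.5, scale_numeric=False)
        dists = [
            np.sqrt(((X[i] - X[j]) ** 2).sum())
            for i in range(80) for j in range(i + 1, 80)
        ]
        dists = np.array(dists)
        retained = dists[dists < dists.mean()]
        expected = retained.mean() + 0.5 * retained.std(ddof=1)
        assert m.threshold == pytest.approx(expected, abs=1e-10)

    def test_categorical_columns_excluded(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0], "cat": [0, 1, 0, 1]})
        m = fit_apd(df, metric="euclidean", Z=0.5, scale_numeric=False,
                    categorical_columns=["cat"])
        assert m.columns == ["x"]


class TestInDomain:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        return df, fit_apd(df, metric="euclidean", Z=0.5, scale_numeric=False)

    def test_training_row_is_reliable(self, fitted):
        df, m = fitted
        out = m.in_domain(df.iloc[[0]])
        assert out["nearest_distance"].iloc[0] == pytest.approx(0.0)
        assert bool(out["reliable"].iloc[0])

    def test_far_query_is_unreliable(self, fitted):
        df, m = fitted
        far = df.iloc[[0]] + 100.0
        out = m.in_domain(far)
        assert not bool(out["reliable"].iloc[0])

    def test_boundary_is_inclusive(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0]})
        m = fit_apd(df, metric="euclidean", Z=0.5, scale_numeric=False)
        query = pd.DataFrame({"x": [10.0 + m.threshold]})
        assert bool(m.in_domain(query)["reliable"].iloc[0])

    def test_missing_columns_listed(self, fitted):
        _, m = fitted
        with pytest.raises(ValidationError, match="b"):
            m.in_domain(pd.DataFrame({"a": [0.0], "c": [0.0]}))


class TestGower:
    W1 = np.array([1.0, 1.0])

    def test_identical_rows_are_zero(self):
        d = gower_distance([1.0, 2.0], [1.0, 2.0], self.W1, [4.0, 1.0], [False, True])
        assert d == 0.0

    def test_maximal_mixed_distance_is_one(self):
        # numeric a full range apart, categorical mismatch, equal weights
        d = gower_distance([0.0, 0.0], [4.0, 1.0], self.W1, [4.0, 1.0], [False, True])
        assert d == 1.0

    def test_half_range_with_matching_category(self):
        d = gower_distance([0.0, 1.0], [2.0, 1.0], self.W1, [4.0, 1.0], [False, True])
        assert d == pytest.approx(0.25)

    def test_numeric_overshoot_clipped_at_one(self):
        d = gower_distance([0.0], [9.0], [1.0], [3.0], [False])
        assert d == 1.0

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError):
            gower_distance([0.0], [1.0], [0.0], [1.0], [False])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.floats(-5, 5), min_size=4, max_size=4),
        y=st.lists(st.floats(-5, 5), min_size=4, max_size=4),
        c1=st.integers(0, 3),
        c2=st.integers(0, 3),
    )
    def test_metric_properties_on_random_mixed_rows(self, x, y, c1, c2):
        """Symmetry, identity of indiscernibles, [0,1] range."""
        w = np.array([0.5, 1.0, 2.0, 1.5, 1.0])
        ranges = np.array([10.0, 10.0, 10.0, 10.0, 1.0])
        cat = np.array([False, False, False, False, True])
        a = np.array(x + [c1], dtype=float)
        b = np.array(y + [c2], dtype=float)
        dab = gower_distance(a, b, w, ranges, cat)
        dba = gower_distance(b, a, w, ranges, cat)
        assert dab == pytest.approx(dba, abs=1e-12)
        assert 0.0 <= dab <= 1.0 + 1e-12
        assert gower_distance(a, a, w, ranges, cat) == 0.0

    def test_matrix_matches_scalar_function(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 3, size=(12, 4))
        X[:, 3] = rng.integers(0, 3, 12)
        w = np.array([1.0, 2.0, 0.5, 1.0])
        ranges = np.array([3.0, 3.0, 3.0, 1.0])
        cat = np.array([False, False, False, True])
        M = _gower_matrix(X, X, w, ranges, cat)
        for i in range(12):
            for j in range(12):
                assert M[i, j] == pytest.approx(
                    gower_distance(X[i], X[j], w, ranges, cat), abs=1e-10)


class TestGowerAPD:
    def test_fit_and_gate_mixed_table(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "num1": rng.uniform(0, 10, 25),
            "num2": rng.normal(size=25),
            "cat": rng.integers(0, 3, 25).astype(float),
        })
        m = fit_apd(df, metric="gower", Z=0.5, categorical_columns=["cat"])
        assert 0 < m.threshold < 1
        out = m.in_domain(df)
        assert out["reliable"].mean() > 0.9  # training rows are in-domain

    def test_shap_style_weights_accepted(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        m = fit_apd(df, metric="gower", Z=0.5, weights={"a": 0.8, "b": 0.2})
        assert m.weights.tolist() == [0.8, 0.2]

    def test_zero_range_feature_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=15), "const": np.full(15, 2.0)})
        with pytest.warns(UserWarning, match="zero-range"):
            m = fit_apd(df, metric="gower", Z=0.5)
        assert np.isfinite(m.threshold)
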