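"""Pearson/cosine metrics: hand values, independent oracles, invariants."""

import numpy as np
import pytest
import scipy.spatial.distance
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from msstab import (
    BinConfig,
    block_summary,
    cosine,
    normalize_tic,
    pearson_r,
    similarity_matrix,
)

from conftest import make_series, make_spectrum, random_sparse_rows


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3], [2, 4, 6], 1.0),  # exact linear relation
        ([1, 0], [0, 1], -1.0),  # two-point anti-correlation
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # direct evaluation by hand
    ],
)
def test_pearson_hand_values(x, y, expected):
    assert pearson_r(make_spectrum(x), make_spectrum(y)) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([2, 5, 1], [2, 5, 1], 1.0),  # identical direction
        ([1, 0], [0, 1], 0.0),  # orthogonal
        ([3, 4], [4, 3], 0.96),  # 24/(5*5) by hand
    ],
)
def test_cosine_hand_values(x, y, expected):
    assert cosine(make_spectrum(x), make_spectrum(y)) == pytest.approx(expected, abs=1e-12)


def test_metrics_require_shared_config():
    with pytest.raises(ValueError, match="BinConfig"):
        cosine(make_spectrum([1, 2]), make_spectrum([1, 2, 3]))


@pytest.mark.parametrize("n_bins", [10, 200, 1000])
def test_pair_metrics_match_scipy_on_random_sparse_vectors(n_bins):
    """scipy.stats.pearsonr and scipy cosine distance are the independent
    oracle for the sparse implementations (densified input)."""
    rng = np.random.default_rng(n_bins)
    cfg = BinConfig(0.0, float(n_bins), 1.0)
    for _ in range(20):
        a, b = random_sparse_rows(rng, 2, n_bins)
        x, y = make_spectrum(a, cfg), make_spectrum(b, cfg)
        assert pearson_r(x, y) == pytest.approx(scipy.stats.pearsonr(a, b).statistic, abs=1e-12)
        assert cosine(x, y) == pytest.approx(
            1.0 - scipy.spatial.distance.cosine(a, b), abs=1e-12
        )


class TestDegenerateConventions:
    def test_all_zero_vector_scores_zero(self):
        cfg = BinConfig(0, 4, 1.0)
        z = make_spectrum([0, 0, 0, 0], cfg)
        x = make_spectrum([1, 2, 0, 0], cfg)
        assert cosine(z, x) == 0.0
        assert pearson_r(z, x) == 0.0

    def test_constant_dense_vector_has_zero_pearson(self):
        cfg = BinConfig(0, 3, 1.0)
        const = make_spectrum([2, 2, 2], cfg)
        x = make_spectrum([1, 2, 3], cfg)
        assert pearson_r(const, x) == 0.0
        assert cosine(const, x) > 0  # cosine is still defined

    def test_degenerate_rows_zeroed_in_matrix(self):
        series = make_series([[1, 2, 0], [0, 0, 0], [1, 2, 0]])
        m = similarity_matrix(series, metric="cosine")
        assert m.degenerate.tolist() == [False, True, False]
        assert m.values[1].tolist() == [0.0, 0.0, 0.0]
        assert m.values[0, 0] == 1.0


class TestSimilarityMatrix:
    def test_identical_spectra_give_all_ones(self):
        m = similarity_matrix(make_series([[1, 2, 3]] * 3), metric="cosine")
        np.testing.assert_allclose(m.values, np.ones((3, 3)), atol=1e-12)

    def test_orthogonal_groups_block_diagonal(self):
        cfg = BinConfig(0, 4, 1.0)
        a = make_series([[1, 2, 0, 0]] * 2, cfg, label="A")
        b = make_series([[0, 0, 3, 1]] * 2, cfg, label="B")
        m = similarity_matrix([a, b], metric="cosine")
        assert m.group_labels == [("A", 0, 2), ("B", 2, 4)]
        np.testing.assert_allclose(m.values[:2, :2], 1.0, atol=1e-12)
        np.testing.assert_allclose(m.values[:2, 2:], 0.0, atol=1e-12)

    @pytest.mark.parametrize("metric", ["pearson", "cosine"])
    def test_matches_brute_force_double_loop(self, metric):
        rng = np.random.default_rng(11)
        rows = random_sparse_rows(rng, 6, 40)
        series = make_series(rows)
        m = similarity_matrix(series, metric=metric)
        n = rows.shape[0]
        for i in range(n):
            for j in range(n):
                if metric == "cosine":
                    expect = rows[i] @ rows[j] / (
                        np.linalg.norm(rows[i]) * np.linalg.norm(rows[j])
                    )
                else:
                    xc = rows[i] - rows[i].mean()
                    yc = rows[j] - rows[j].mean()
                    expect = xc @ yc / (np.linalg.norm(xc) * np.linalg.norm(yc))
                assert m.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(5)
        series = make_series(random_sparse_rows(rng, 8, 30))
        for metric in ("pearson", "cosine"):
            m = similarity_matrix(series, metric=metric)
            np.testing.assert_array_equal(m.values, m.values.T)
            np.testing.assert_array_equal(np.diag(m.values), np.ones(8))
            assert np.all(m.values >= -1) and np.all(m.values <= 1)

    def test_mixed_configs_rejected(self):
        a = make_series([[1, 2]], BinConfig(0, 2, 1.0))
        b = make_series([[1, 2, 3]], BinConfig(0, 3, 1.0))
        with pytest.raises(ValueError, match="BinConfig"):
            similarity_matrix([a, b])

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            similarity_matrix(make_series([[1, 2]]), metric="euclid")

    def test_write_matrix_and_sidecar(self, tmp_path):
        m = similarity_matrix(make_series([[1, 2], [2, 4]]), metric="cosine")
        m.write(tmp_path / "m.csv")
        loaded = np.loadtxt(tmp_path / "m.csv", delimiter=",")
        np.testing.assert_allclose(loaded, m.values, atol=1e-12)
        import json

        side = json.loads((tmp_path / "m.json").read_text())
        assert side["metric"] == "cosine"
        assert side["groups"][0]["end"] == 2


@st.composite
def sparse_vector_pairs(draw):
    n = draw(st.integers(4, 60))
    density = draw(st.floats(0.1, 0.9))
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    return random_sparse_rows(rng, 2, n, density), n


class TestMetricIdentities:
    """The structural facts that make cosine a usable stand-in for Pearson
    on high-dimensional nonnegative spectra."""

    @given(sparse_vector_pairs())
    @settings(max_examples=60, deadline=None)
    def test_pearson_equals_cosine_at_zero_mean(self, pair):
        (a, b), n = pair
        ac, bc = a - a.mean(), b - b.mean()
        # mean-zero vectors live outside BinnedSpectrum (nonnegative), so
        # evaluate both formulas directly on dense data
        pear = scipy.stats.pearsonr(a, b).statistic
        cos_centered = ac @ bc / (np.linalg.norm(ac) * np.linalg.norm(bc))
        assert pear == pytest.approx(cos_centered, abs=1e-12)

    @given(sparse_vector_pairs(), st.floats(1e-3, 1e3))
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance(self, pair, c):
        (a, b), n = pair
        cfg = BinConfig(0.0, float(n), 1.0)
        x, y, ys = make_spectrum(a, cfg), make_spectrum(b, cfg), make_spectrum(c * b, cfg)
        assert cosine(x, ys) == pytest.approx(cosine(x, y), abs=1e-12)
        assert pearson_r(x, ys) == pytest.approx(pearson_r(x, y), abs=1e-12)

    @given(sparse_vector_pairs())
    @settings(max_examples=60, deadline=None)
    def test_tic_normalization_invariance(self, pair):
        (a, b), n = pair
        cfg = BinConfig(0.0, float(n), 1.0)
        x, y = make_spectrum(a, cfg), make_spectrum(b, cfg)
        xn, yn = normalize_tic(x), normalize_tic(y)
        assert cosine(xn, yn) == pytest.approx(cosine(x, y), abs=1e-9)
        assert pearson_r(xn, yn) == pytest.approx(pearson_r(x, y), abs=1e-9)

    @given(sparse_vector_pairs())
    @settings(max_examples=60, deadline=None)
    def test_cosine_nonnegative_and_symmetric(self, pair):
        (a, b), n = pair
        cfg = BinConfig(0.0, float(n), 1.0)
        x, y = make_spectrum(a, cfg), make_spectrum(b, cfg)
        c = cosine(x, y)
        assert 0.0 <= c <= 1.0
        assert c == cosine(y, x)
        assert pearson_r(x, y) == pearson_r(y, x)


class TestBlockSummary:
    def test_identical_group_within_mean_is_one(self):
        m = similarity_matrix(make_series([[1, 2, 3]] * 3, label="A"))
        df = block_summary(m)
        row = df[(df.group_row == "A") & (df.group_col == "A")].iloc[0]
        assert row["mean"] == pytest.approx(1.0, abs=1e-12)
        assert row["n_pairs"] == 6  # off-diagonal entries only

    def test_orthogonal_groups_between_mean_zero(self):
        cfg = BinConfig(0, 4, 1.0)
        a = make_series([[1, 1, 0, 0]] * 2, cfg, label="A")
        b = make_series([[0, 0, 1, 2]] * 2, cfg, label="B")
        df = block_summary(similarity_matrix([a, b]))
        row = df[(df.group_row == "A") & (df.group_col == "B")].iloc[0]
        assert row["mean"] == pytest.approx(0.0, abs=1e-12)

    def test_means_match_direct_block_averages(self):
        rng = np.random.default_rng(2)
        cfg = BinConfig(0, 10, 1.0)
        a = make_series(random_sparse_rows(rng, 2, 10), cfg, label="A")
        b = make_series(random_sparse_rows(rng, 2, 10), cfg, label="B")
        m = similarity_matrix([a, b])
        df = block_summary(m).set_index(["group_row", "group_col"])
        v = m.values
        assert df.loc[("A", "A"), "mean"] == pytest.approx((v[0, 1] + v[1, 0]) / 2)
        assert df.loc[("A", "B"), "mean"] == pytest.approx(v[:2, 2:].mean())
        assert df.loc[("B", "A"), "min"] == pytest.approx(v[2:, :2].min())
        assert df.loc[("B", "B"), "max"] == pytest.approx(max(v[2, 3], v[3, 2]))

    def test_overlapping_groups_rejected(self):
        m = similarity_matrix(make_series([[1, 2]] * 3))
        m.group_labels = [("A", 0, 2), ("B", 1, 3)]
        with pytest.raises(ValueError, match="overlap|partition"):
            block_summary(m)

    def test_single_scan_group_has_no_within_row(self):
        m = similarity_matrix(make_series([[1, 2]], label="solo"))
        df = block_summary(m)
        assert df.empty
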