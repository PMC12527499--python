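import math

import numpy as np
import pytest

from netatrophy import (
    build_morphological_network,
    correlate_maps,
    neighbor_atrophy,
    network_weighted_wscores,
    weighted_degree,
)
from conftest import random_graph_and_map


def brute_force_neighbor(t, sc, weights=None, normalization="weight_sum",
                         clamp=True):
    """Independent double-loop oracle for the neighbor-aggregation rules."""
    n = len(t)
    out = np.full(n, np.nan)
    for i in range(n):
        num = den = 0.0
        cnt = 0
        for j in range(n):
            if i == j or sc[i, j] <= 0:
                continue
            w = 1.0 if weights is None else weights[i, j]
            if weights is not None and clamp and w < 0:
                w = 0.0
            num += w * t[j]
            den += w
            cnt += 1
        if normalization == "count":
            den = cnt
        if den > 0:
            out[i] = num / den
    return out


class TestMorphologicalNetwork:
    def test_fisher_z_values(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 200)
        # construct two columns with known population correlation 0.5
        col2 = 0.5 * base + np.sqrt(1 - 0.25) * rng.normal(0, 1, 200)
        ct = np.column_stack([base, col2, rng.normal(0, 1, 200)]) * 0.1 + 2.5
        smn = build_morphological_network(ct)
        r = np.corrcoef(ct[:, 0], ct[:, 1])[0, 1]
        assert smn[0, 1] == pytest.approx(math.atanh(r), abs=1e-12)
        assert np.all(np.diag(smn) == 0)

    def test_identical_columns_capped_not_infinite(self):
        rng = np.random.default_rng(1)
        col = rng.normal(2.5, 0.1, 50)
        ct = np.column_stack([col, col, rng.normal(2.5, 0.1, 50)])
        smn = build_morphological_network(ct)
        assert np.isfinite(smn[0, 1])
        assert smn[0, 1] == pytest.approx(math.atanh(0.999999), rel=1e-9)

    def test_constant_column_error(self):
        ct = np.ones((30, 4)) * 2.5
        ct[:, 1:] += np.random.default_rng(2).normal(0, 0.1, (30, 3))
        with pytest.raises(ValueError, match="constant"):
            build_morphological_network(ct)

    def test_too_few_subjects_error(self):
        with pytest.raises(ValueError, match="10"):
            build_morphological_network(np.random.default_rng(3).random((5, 4)))


class TestWeightedDegree:
    def test_hand_example(self):
        m = np.array([[0, 1, 2], [1, 0, 0], [2, 0, 0]], dtype=float)
        np.testing.assert_array_equal(weighted_degree(m), [3, 1, 2])

    def test_all_zero(self):
        np.testing.assert_array_equal(weighted_degree(np.zeros((4, 4))), 0.0)

    def test_row_sums_equal_column_sums(self, study):
        sc = study["connectomes"].sc
        np.testing.assert_allclose(weighted_degree(sc, "sc"), sc.sum(axis=0),
                                   atol=1e-12)

    def test_asymmetric_error(self):
        m = np.zeros((3, 3))
        m[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            weighted_degree(m)


class TestNeighborAtrophy:
    def test_unweighted_hand_example(self):
        # node 0 has neighbors {1, 2} with thinning 1 and 3 -> mean 2
        sc = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        t = np.array([9.0, 1.0, 3.0])
        out = neighbor_atrophy(t, sc)
        assert out[0] == pytest.approx(2.0)

    def test_weighted_both_normalizations(self):
        sc = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        w = np.array([[0, 1, 3], [1, 0, 0], [3, 0, 0]], dtype=float)
        t = np.array([0.0, 1.0, 3.0])
        assert neighbor_atrophy(t, sc, w)[0] == pytest.approx(2.5)      # (1+9)/4
        assert neighbor_atrophy(t, sc, w, "count")[0] == pytest.approx(5.0)  # (1+9)/2

    def test_constant_map_identity(self, study):
        sc = study["connectomes"].sc
        out = neighbor_atrophy(np.full(68, 3.7), sc)
        np.testing.assert_allclose(out, 3.7, atol=1e-10)

    def test_equal_weights_reduce_to_unweighted(self):
        rng = np.random.default_rng(4)
        sc, _, t = random_graph_and_map(rng)
        ones = (sc > 0).astype(float)
        base = neighbor_atrophy(t, sc)
        np.testing.assert_allclose(neighbor_atrophy(t, sc, ones), base, atol=1e-12)
        np.testing.assert_allclose(neighbor_atrophy(t, sc, ones, "count"), base,
                                   atol=1e-12)

    @pytest.mark.parametrize("normalization", ["weight_sum", "count"])
    @pytest.mark.parametrize("use_weights", [False, True])
    def test_matches_brute_force(self, normalization, use_weights):
        rng = np.random.default_rng(5)
        for _ in range(50):
            sc, w, t = random_graph_and_map(rng)
            weights = w if use_weights else None
            with np.errstate(invalid="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    got = neighbor_atrophy(t, sc, weights, normalization)
            want = brute_force_neighbor(t, sc, weights, normalization)
            np.testing.assert_allclose(got, want, atol=1e-10, equal_nan=True)

    def test_isolated_node_warns_and_nans(self):
        sc = np.zeros((4, 4))
        sc[0, 1] = sc[1, 0] = 1.0
        sc[2, 3] = sc[3, 2] = 0.0
        sc[1, 2] = sc[2, 1] = 1.0
        t = np.arange(4.0)
        with pytest.warns(UserWarning, match="isolated|neighbors"):
            out = neighbor_atrophy(t, sc)
        assert np.isnan(out[3])

    def test_all_isolated_error(self):
        with pytest.raises(ValueError, match="isolated"):
            neighbor_atrophy(np.zeros(3), np.zeros((3, 3)))


class TestNetworkWeightedWScores:
    def test_constant_w_row(self, study, smn):
        sc = study["connectomes"].sc
        out = network_weighted_wscores(np.ones((1, 68)), sc, smn)
        np.testing.assert_allclose(out, 1.0, atol=1e-10)

    def test_support_is_structural_neighborhood(self, study, smn):
        sc = study["connectomes"].sc
        w = np.zeros((1, 68))
        j = 17
        w[0, j] = 1.0
        out = network_weighted_wscores(w, sc, smn)[0]
        neighbors = np.flatnonzero(sc[j] > 0)
        nonzero = np.flatnonzero(np.abs(out) > 1e-15)
        assert set(nonzero) <= set(neighbors)

    def test_single_row_equals_neighbor_atrophy(self, study, smn):
        rng = np.random.default_rng(6)
        sc = study["connectomes"].sc
        row = rng.normal(0, 1, 68)
        a = network_weighted_wscores(row[None, :], sc, smn)[0]
        b = neighbor_atrophy(row, sc, smn)
        np.testing.assert_allclose(a, b, atol=1e-12, equal_nan=True)

    def test_identical_rows_identical_output(self, study, smn):
        rng = np.random.default_rng(7)
        sc = study["connectomes"].sc
        row = rng.normal(0, 1, 68)
        out = network_weighted_wscores(np.vstack([row, row]), sc, smn)
        np.testing.assert_array_equal(out[0], out[1])


class TestCorrelateMaps:
    def test_affine_and_negation(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 30)
        assert correlate_maps(a, 2 * a + 1) == pytest.approx(1.0)
        assert correlate_maps(a, -a) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 4.0, 3.5, 0.5])
        b = np.array([2.0, 1.0, 3.0, 5.0, 1.5])
        n = 5
        num = n * (a * b).sum() - a.sum() * b.sum()
        den = np.sqrt(n * (a**2).sum() - a.sum()**2) \
            * np.sqrt(n * (b**2).sum() - b.sum()**2)
        assert correlate_maps(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_pairwise_complete(self):
        a = np.array([1.0, np.nan, 2.0, 3.0, 4.0])
        b = np.array([2.0, 5.0, 4.0, np.nan, 8.0])
        assert correlate_maps(a, b) == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="3"):
            correlate_maps(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        with pytest.raises(ValueError, match="variance"):
            correlate_maps(np.ones(5), np.arange(5.0))
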