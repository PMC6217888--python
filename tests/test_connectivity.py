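"""Unit and property tests for the edge estimators.

The grid-maximised MI path is checked against a deliberately slow
brute-force evaluator that rebins every enumerated grid with plain Python
loops, independent of the vectorised implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from miconn import (
    LN3,
    ConnectivityMatrix,
    DegenerateSeriesError,
    GridSpec,
    MiConfig,
    TimeSeriesMatrix,
    axis_boundary_pairs,
    connectivity_matrix,
    contingency_counts,
    enumerate_grids,
    gaussian_reference,
    grid_mi,
    mi_from_counts,
    pearson_edge,
    read_connectivity,
    write_connectivity,
)

SIX = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])


def brute_force_grid_mi(x, y, config=None):
    """Independent oracle: rebin every enumerated grid with Python loops."""
    best = -np.inf
    for grid in enumerate_grids(x, y, config):
        counts = [[0] * 3 for _ in range(3)]
        for xv, yv in zip(x, y):
            bx = grid.x_bounds
            by = grid.y_bounds
            i = 0 + (xv >= bx[1]) + (xv >= bx[2])
            j = 0 + (yv >= by[1]) + (yv >= by[2])
            counts[i][j] += 1
        n = len(x)
        mi = 0.0
        for i in range(3):
            for j in range(3):
                pij = counts[i][j] / n
                if pij > 0:
                    pi = sum(counts[i]) / n
                    pj = sum(row[j] for row in counts) / n
                    mi += pij * math.log(pij / (pi * pj))
        best = max(best, mi)
    return best


class TestPearsonEdge:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1.0, 2.0, 5.0, 3.0], [1.0, 2.0, 5.0, 3.0], 1.0),
            ([1.0, 2.0, 5.0, 3.0], [-1.0, -2.0, -5.0, -3.0], 1.0),
            ([1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0], 0.8),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_edge(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            pearson_edge([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    @given(
        hnp.arrays(
            np.float64,
            20,
            elements=st.floats(-50, 50, allow_nan=False),
        ).filter(lambda a: a.std() > 1e-6)
    )
    def test_bounded_and_sign_symmetric(self, x):
        y = np.linspace(-1, 1, 20) + 0.5 * x
        if y.std() <= 1e-12:
            return
        w = pearson_edge(x, y)
        assert 0.0 <= w <= 1.0
        assert pearson_edge(x, -y) == pytest.approx(w, abs=1e-12)


class TestGridEnumeration:
    def test_default_counts(self):
        config = MiConfig()
        assert len(axis_boundary_pairs(SIX, config)) == 25
        assert config.n_candidate_grids == 125
        assert len(enumerate_grids(SIX, SIX, config)) == 125

    def test_small_family_counts(self):
        config = MiConfig(multiples=(0.5, 1.0))
        assert len(enumerate_grids(SIX, SIX, config)) == 8
        assert config.n_axis_boundary_pairs == 4

    def test_full_mode_count(self):
        config = MiConfig(multiples=(0.5, 1.0), enumeration_mode="full")
        assert len(enumerate_grids(SIX, SIX, config)) == 16

    def test_closed_under_axis_swap(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        grids = {(g.x_bounds, g.y_bounds) for g in enumerate_grids(x, y)}
        swapped = {(g.y_bounds, g.x_bounds) for g in enumerate_grids(y, x)}
        assert grids == swapped

    def test_degenerate_grids_dropped(self):
        # one extreme outlier pulls mean +/- 1.25 SD outside the data range
        x = np.array([0.0, 0.01, 0.02, 0.03, 100.0])
        grids = enumerate_grids(x, x, MiConfig())
        assert 0 < len(grids) < 125
        for g in grids:
            assert g.x_bounds[0] < g.x_bounds[1] < g.x_bounds[2] < g.x_bounds[3]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MiConfig(multiples=(1.0, 0.5))
        with pytest.raises(ValueError):
            MiConfig(resolution=4)


class TestContingencyAndMi:
    def test_hand_binned_diagonal(self):
        grid = GridSpec((1.0, 2.565, 4.435, 6.0), (1.0, 2.565, 4.435, 6.0))
        table = contingency_counts(SIX, SIX, grid)
        assert np.diagonal(table.counts).tolist() == [2, 2, 2]
        assert table.counts.sum() == table.n == 6
        assert mi_from_counts(table) == pytest.approx(LN3, abs=1e-12)

    def test_boundary_value_goes_to_upper_bin(self):
        # half-open [b0,b1), [b1,b2), [b2,b3]: a value on b1 lands in bin 1
        grid = GridSpec((0.0, 2.0, 4.0, 6.0), (0.0, 2.0, 4.0, 6.0))
        x = np.array([2.0, 2.0, 2.0, 6.0, 0.0, 4.0])
        table = contingency_counts(x, x, grid)
        assert table.counts[1, 1] == 3  # the three values exactly on b1
        assert table.counts[2, 2] == 2  # max lands in the right-closed last bin

    def test_uniform_table_and_degenerate_marginal(self):
        from miconn.connectivity import ContingencyTable

        uniform = ContingencyTable(np.full((3, 3), 4), 36)
        assert mi_from_counts(uniform) == pytest.approx(0.0, abs=1e-15)
        single = ContingencyTable(np.array([[9, 0, 0], [0, 0, 0], [0, 0, 0]]), 9)
        assert mi_from_counts(single) == pytest.approx(0.0, abs=1e-15)

    @given(st.lists(st.integers(0, 20), min_size=9, max_size=9).filter(sum))
    def test_mi_bounds(self, flat):
        from miconn.connectivity import ContingencyTable

        counts = np.array(flat).reshape(3, 3)
        table = ContingencyTable(counts, int(counts.sum()))
        assert 0.0 <= mi_from_counts(table) <= LN3 + 1e-12


class TestGridMi:
    def test_perfect_diagonal(self):
        assert grid_mi(SIX, SIX) == pytest.approx(LN3, abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(25):
            x = rng.standard_normal(50)
            y = rng.standard_normal(50) + 0.5 * x
            v = grid_mi(x, y)
            assert 0.0 <= v <= LN3
            assert grid_mi(y, x) == pytest.approx(v, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal(12)
            y = 0.7 * x + 0.5 * rng.standard_normal(12)
            assert grid_mi(x, y) == pytest.approx(brute_force_grid_mi(x, y), abs=1e-12)

    def test_max_dominates_single_grids(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        v = grid_mi(x, y)
        for grid in enumerate_grids(x, y):
            assert v >= mi_from_counts(contingency_counts(x, y, grid)) - 1e-12

    def test_full_mode_at_least_paper125(self, rng):
        x = rng.standard_normal(40)
        y = x**2 + 0.1 * rng.standard_normal(40)
        assert grid_mi(x, y, MiConfig(enumeration_mode="full")) >= grid_mi(x, y) - 1e-12

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            grid_mi(np.ones(20), np.arange(20.0))


class TestGaussianReference:
    def test_known_values(self):
        assert gaussian_reference(0.0) == 0.0
        assert gaussian_reference(0.8) == pytest.approx(0.5108256237659907, abs=1e-12)

    @given(st.floats(-0.999, 0.999))
    def test_even_and_nonnegative(self, r):
        assert gaussian_reference(r) == gaussian_reference(-r)
        assert gaussian_reference(r) >= 0.0

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_domain_error(self, r):
        with pytest.raises(ValueError):
            gaussian_reference(r)


class TestConnectivityMatrix:
    def test_contract_and_duplicate_node(self, rng):
        base = rng.standard_normal(60)
        vals = np.vstack([base, base + 0.0, rng.standard_normal(60)])
        ts = TimeSeriesMatrix(vals, node_ids=("a", "b", "c"))
        cm = connectivity_matrix(ts, "pearson_abs")
        assert cm.weights.shape == (3, 3)
        assert np.allclose(cm.weights, cm.weights.T)
        assert np.diagonal(cm.weights).sum() == 0.0
        assert cm.weights[0, 1] == pytest.approx(1.0)

    def test_constant_node_names_offender(self, rng):
        vals = np.vstack([rng.standard_normal(30), np.zeros(30)])
        ts = TimeSeriesMatrix(vals, node_ids=("good", "flat"))
        with pytest.raises(DegenerateSeriesError, match="flat"):
            connectivity_matrix(ts, "grid_mi")

    def test_matrix_matches_scalar_grid_mi(self, rng):
        ts = TimeSeriesMatrix(rng.standard_normal((4, 60)))
        cm = connectivity_matrix(ts, "grid_mi")
        for i in range(4):
            for j in range(i + 1, 4):
                assert cm.weights[i, j] == pytest.approx(
                    grid_mi(ts.values[i], ts.values[j]), abs=1e-12
                )

    def test_roundtrip_io(self, tmp_path, rng):
        ts = TimeSeriesMatrix(rng.standard_normal((5, 40)))
        cm = connectivity_matrix(ts, "pearson_abs")
        path = tmp_path / "conn.tsv"
        write_connectivity(cm, path)
        back = read_connectivity(path)
        assert back.method == cm.method
        assert back.node_ids == cm.node_ids
        np.testing.assert_array_equal(back.weights, cm.weights)

    def test_validation(self):
        with pytest.raises(ValueError):
            ConnectivityMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]), "pearson_abs", ("a", "b"))
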