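"""Coordinate system and semi-local sampling contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from owsr.grid import (FeatureMap, build_sample_grid, extract_semi_local,
                       hr_to_feature_coord, nearest_cell_lookup,
                       semi_local_indices)


def brute_force_lookup(coord, grid_shape):
    """Exhaustive Euclidean scan over all cell centers; first minimum wins."""
    p_n, q_n = grid_shape
    u = min(max(coord[0], 0.0), 1.0)
    v = min(max(coord[1], 0.0), 1.0)
    centers_u = (np.arange(p_n) + 0.5) / p_n
    centers_v = (np.arange(q_n) + 0.5) / q_n
    d2 = (centers_u[:, None] - u) ** 2 + (centers_v[None, :] - v) ** 2
    flat = int(np.argmin(d2))  # row-major argmin -> smaller index on ties
    return flat // q_n, flat % q_n


@pytest.mark.parametrize("index,shape,expected", [
    ((0, 0), (2, 2), (0.25, 0.25)),
    ((1, 1), (3, 3), (0.5, 0.5)),
    ((10, 20), (96, 96), (10.5 / 96, 20.5 / 96)),
])
def test_pixel_centers_map_to_unit_square(index, shape, expected):
    assert hr_to_feature_coord(index, shape) == pytest.approx(expected)


def test_out_of_range_pixel_index_rejected():
    with pytest.raises(ValueError):
        hr_to_feature_coord((2, 0), (2, 2))


def test_sample_grid_half_integer_offsets():
    g = build_sample_grid((0.5, 0.5), 4, (0.1, 0.1))
    assert np.allclose(g[:, 0, 0], [0.35, 0.45, 0.55, 0.65])
    assert np.allclose(g[0, :, 1], [0.35, 0.45, 0.55, 0.65])


def test_sample_grid_spacing_is_one_cell():
    g = build_sample_grid((0.51, 0.49), 6, (1 / 48, 1 / 48))
    assert np.allclose(np.diff(g[:, 0, 0]), 1 / 48)
    assert np.allclose(np.diff(g[0, :, 1]), 1 / 48)


@given(u=st.floats(0.01, 0.99), v=st.floats(0.01, 0.99),
       m=st.sampled_from([4, 6, 8]))
@settings(max_examples=50, derandomize=True, deadline=None)
def test_sample_grid_mean_is_center(u, v, m):
    g = build_sample_grid((u, v), m, (0.02, 0.03))
    assert np.allclose(g.reshape(-1, 2).mean(axis=0), (u, v))


@pytest.mark.parametrize("m", [3, 5, 2, 0])
def test_odd_or_small_region_size_rejected(m):
    with pytest.raises(ValueError):
        build_sample_grid((0.5, 0.5), m, (0.1, 0.1))


@pytest.mark.parametrize("coord,shape,expected", [
    ((0.4, 0.4), (3, 3), (1, 1)),
    ((0.5 / 3, 2.5 / 3), (3, 3), (0, 2)),   # exactly at a cell center
    ((-0.1, 0.5), (3, 3), (0, 1)),          # clamped then nearest
    ((1.0 / 3, 0.5), (3, 3), (0, 1)),       # boundary tie -> smaller index
])
def test_nearest_cell_examples(coord, shape, expected):
    assert nearest_cell_lookup(coord, shape) == expected
    assert brute_force_lookup(coord, shape) == expected


def test_nearest_cell_rejects_non_finite():
    with pytest.raises(ValueError):
        nearest_cell_lookup((np.nan, 0.5), (3, 3))


def test_nearest_cell_matches_bruteforce_on_random_queries(rng):
    for _ in range(5):
        shape = tuple(rng.integers(2, 30, size=2))
        for coord in rng.uniform(-0.2, 1.2, size=(50, 2)):
            assert nearest_cell_lookup(tuple(coord), shape) == \
                brute_force_lookup(coord, shape)


def test_extract_constant_field(rng):
    c = rng.normal(size=5)
    psi = FeatureMap(np.tile(c, (7, 9, 1)))
    s = extract_semi_local(psi, (0.31, 0.77), 4)
    assert np.allclose(s.values, c)


def test_extract_center_equals_direct_slice(rng):
    psi = FeatureMap(rng.normal(size=(48, 48, 3)))
    s = extract_semi_local(psi, (0.5, 0.5), 6)
    assert np.array_equal(s.values, psi.values[21:27, 21:27])
    assert s.offset == (0.5, 0.5)  # boundary point, tie to the smaller cell


def test_extract_corner_replicates_border(rng):
    psi = FeatureMap(rng.normal(size=(48, 48, 2)))
    s = extract_semi_local(psi, (0.0, 0.0), 6)
    # the first three grid rows fall off the grid -> all clamp to row 0
    assert np.array_equal(s.values[0], s.values[1])
    assert np.array_equal(s.values[1], s.values[2])
    assert np.array_equal(s.values[:, 0], s.values[:, 1])


def test_translation_by_one_cell_shifts_block(rng):
    psi = FeatureMap(rng.normal(size=(32, 32, 2)))
    c = (0.4, 0.6)
    a = extract_semi_local(psi, c, 6)
    b = extract_semi_local(psi, (c[0] + 1 / 32, c[1]), 6)
    assert np.array_equal(a.values[1:], b.values[:-1])


def test_extraction_is_deterministic(rng):
    psi = FeatureMap(rng.normal(size=(20, 20, 4)))
    a = extract_semi_local(psi, (0.123, 0.456), 6)
    b = extract_semi_local(psi, (0.123, 0.456), 6)
    assert np.array_equal(a.values, b.values) and a.offset == b.offset


@given(u=st.floats(1e-9, 1, exclude_max=True), v=st.floats(1e-9, 1, exclude_max=True),
       p=st.integers(2, 40), q=st.integers(2, 40))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_offsets_live_in_half_open_cell(u, v, p, q):
    # pixel-center queries are strictly interior; only the degenerate clamped
    # coordinate u == 0 itself would sit at exactly -0.5
    _, off = semi_local_indices(np.array([[u, v]]), (p, q), 4)
    assert np.all(off > -0.5) and np.all(off <= 0.5)
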