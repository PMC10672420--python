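"""Overlapping-window cascade and decoder contracts."""

import numpy as np
import pytest

from owsr import autodiff as ad
from owsr.autodiff import Tensor
from owsr.owindow import (decode_rgb, init_ow_params, ow_reduce, ow_step,
                          select_center_window, window_sizes)


def loop_ow_step(t, w):
    """Crop-multiply-accumulate reference, one corner at a time."""
    m, d = t.shape[0], t.shape[2]
    s = m - 1
    out = np.zeros((s, s, d))
    crops = [t[:s, :s], t[:s, 1:], t[1:, :s], t[1:, 1:]]
    for ci in range(4):
        for i in range(s):
            for j in range(s):
                out[i, j] += crops[ci][i, j] * w[ci, i, j]
    return out


def loop_ow_reduce(region, weights):
    t = region
    for w in weights:
        t = loop_ow_step(t, w)
    return t


def test_window_size_schedule():
    assert window_sizes(6) == [5, 4, 3]
    assert window_sizes(4) == [3, 2]
    assert window_sizes(8) == [7, 6, 5, 4]
    with pytest.raises(ValueError):
        window_sizes(5)


def test_ow_step_all_ones_sums_four_corners():
    out = ow_step(np.ones((3, 3, 2)), np.ones((4, 2, 2, 2)))
    assert out.data.shape == (2, 2, 2)
    assert np.allclose(out.data, 4.0)


def test_ow_step_selector_weights_pick_one_corner(rng):
    t = rng.normal(size=(5, 5, 3))
    w = np.zeros((4, 4, 4, 3))
    w[0] = 1.0  # top-left only
    out = ow_step(t, w)
    assert np.allclose(out.data, t[:4, :4])


def test_ow_step_shape_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        ow_step(rng.normal(size=(4, 4, 2)), rng.normal(size=(4, 2, 2, 2)))


@pytest.mark.parametrize("m", [4, 6, 8])
@pytest.mark.parametrize("d", [1, 3])
def test_cascade_matches_loop_oracle(m, d):
    rng = np.random.default_rng(100 * m + d)
    region = rng.normal(size=(m, m, d))
    weights = [rng.normal(size=(4, s, s, d)) for s in window_sizes(m)]
    params = init_ow_params(m, d, mlp_hidden=(8,), rng=rng)
    for wt, warr in zip(params.window_weights, weights):
        wt.data[:] = warr
    got = ow_reduce(region, params)
    want = loop_ow_reduce(region, weights)
    assert got.data.shape == (m // 2, m // 2, d)
    assert np.abs(got.data - want).max() < 1e-6


def test_iteration_count_is_half_m():
    for m in (4, 6, 8):
        assert len(window_sizes(m)) == m // 2


def test_zero_weights_annihilate(rng):
    params = init_ow_params(6, 2, mlp_hidden=(8,), rng=rng)
    for w in params.window_weights:
        w.data[:] = 0.0
    out = ow_reduce(rng.normal(size=(6, 6, 2)), params)
    assert np.allclose(out.data, 0.0)


def test_average_init_preserves_constant(rng):
    c = rng.normal(size=4)
    params = init_ow_params(6, 4, mlp_hidden=(8,), rng=rng)  # weights 1/4
    out = ow_reduce(np.tile(c, (6, 6, 1)), params)
    assert np.abs(out.data - c).max() < 1e-6


def test_region_params_mismatch_rejected(rng):
    params = init_ow_params(6, 2, mlp_hidden=(8,), rng=rng)
    with pytest.raises(ValueError):
        ow_reduce(rng.normal(size=(4, 4, 2)), params)


@pytest.mark.parametrize("offset,origin", [
    ((0.3, 0.3), (1, 1)),
    ((0.0, 0.0), (0, 0)),      # not > 0 -> stay top-left of center
    ((-0.2, 0.4), (0, 1)),
])
def test_center_window_steering_in_3x3(offset, origin, rng):
    t = rng.normal(size=(3, 3, 2))
    win = select_center_window(t, offset)
    i, j = origin
    assert np.array_equal(win.data, t[i:i + 2, j:j + 2])


def test_center_window_identity_for_2x2(rng):
    t = rng.normal(size=(2, 2, 5))
    assert np.array_equal(select_center_window(t, (0.49, -0.3)).data, t)


def test_decoder_output_contract(rng):
    params = init_ow_params(4, 7, mlp_hidden=(16, 16), rng=rng)
    out = decode_rgb(rng.normal(size=(2, 2, 7)), (0.1, -0.2), params.mlp)
    assert out.data.shape == (3,)
    # zero weights and biases -> exactly zero output
    for w, b in params.mlp:
        w.data[:] = 0; b.data[:] = 0
    out = decode_rgb(rng.normal(size=(2, 2, 7)), (0.1, -0.2), params.mlp)
    assert np.allclose(out.data, 0.0)


def test_decoder_is_deterministic(rng):
    params = init_ow_params(4, 3, mlp_hidden=(16,), rng=rng)
    win = rng.normal(size=(2, 2, 3))
    a = decode_rgb(win, (0.2, 0.2), params.mlp).data
    b = decode_rgb(win, (0.2, 0.2), params.mlp).data
    assert np.array_equal(a, b)


def test_decoder_rejects_non_finite(rng):
    params = init_ow_params(4, 3, mlp_hidden=(8,), rng=rng)
    bad = np.full((2, 2, 3), np.nan)
    with pytest.raises(ValueError):
        decode_rgb(bad, (0.0, 0.0), params.mlp)


def test_l1_gradient_reaches_all_window_and_mlp_parameters(rng):
    m, d = 6, 3
    params = init_ow_params(m, d, mlp_hidden=(16, 16), rng=rng)
    region = Tensor(rng.normal(size=(5, m, m, d)), requires_grad=True)
    offsets = rng.uniform(-0.5, 0.5, size=(5, 2))
    t = ow_reduce(region, params)
    win = select_center_window(t, offsets)
    pred = decode_rgb(win, offsets, params.mlp)
    loss = ad.mean(ad.absolute(pred - Tensor(rng.random((5, 3)))))
    loss.backward()
    for p in params.parameters() + [region]:
        assert p.grad is not None and np.all(np.isfinite(p.grad))
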