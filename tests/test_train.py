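"""Training-loop contracts: schedule, sampling, optimization."""

import numpy as np
import pytest

from owsr.phantom import gen_analytic_image
from owsr.train import (Adam, ImageTooSmall, TrainConfig, evaluate,
                        lr_at_epoch, make_training_sample, tiny_config, train)
from owsr.autodiff import Tensor


def test_lr_schedule_closed_form():
    cfg = TrainConfig()
    assert lr_at_epoch(1, cfg) == pytest.approx(1e-4)
    assert lr_at_epoch(40, cfg) == pytest.approx(1e-4)
    assert lr_at_epoch(41, cfg) == pytest.approx(3e-5)
    assert lr_at_epoch(61, cfg) == pytest.approx(9e-6)
    assert lr_at_epoch(71, cfg) == pytest.approx(2.7e-6)
    for e in range(1, 101):
        passed = sum(1 for ms in (40, 60, 70) if e > ms)
        assert lr_at_epoch(e, cfg) == pytest.approx(1e-4 * 0.3 ** passed)


def test_training_sample_constant_image(rng):
    img = gen_analytic_image("constant", (120, 120), value=0.7)
    cfg = tiny_config(points_per_image=50, scale_range=(1.0, 2.0))
    s = make_training_sample(img, cfg, rng)
    assert np.allclose(s.targets, 0.7)
    assert np.allclose(s.lr_patch, 0.7, atol=1e-12)


def test_training_sample_scale_one_is_verbatim_crop(rng):
    img = np.random.default_rng(5).random((60, 60, 3))
    cfg = tiny_config(scale_range=(1.0, 1.0), points_per_image=20)
    s = make_training_sample(img, cfg, rng)
    assert s.lr_patch.shape == (48, 48, 3)
    # the patch is an exact sub-array of the source
    found = any(np.array_equal(s.lr_patch, img[i:i + 48, j:j + 48])
                for i in range(13) for j in range(13))
    assert found


def test_training_sample_determinism_and_interior_coords():
    img = np.random.default_rng(5).random((96, 96, 3))
    cfg = tiny_config(scale_range=(1.0, 2.0), points_per_image=64)
    a = make_training_sample(img, cfg, np.random.default_rng(42))
    b = make_training_sample(img, cfg, np.random.default_rng(42))
    assert np.array_equal(a.lr_patch, b.lr_patch)
    assert np.array_equal(a.query_coords, b.query_coords)
    assert np.array_equal(a.targets, b.targets)
    assert np.all(a.query_coords > 0) and np.all(a.query_coords < 1)
    # distinct points
    assert len({(r, c) for r, c in map(tuple, a.query_coords)}) == 64


def test_too_small_image_raises(rng):
    cfg = tiny_config(scale_range=(2.0, 2.0))
    with pytest.raises(ImageTooSmall):
        make_training_sample(np.zeros((50, 50, 3)), cfg, rng)


def test_adam_descends_a_quadratic():
    p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([p])
    for _ in range(300):
        opt.zero_grad()
        p.grad = 2 * p.data  # d/dp sum(p^2)
        opt.step(0.05)
    assert np.abs(p.data).max() < 1e-2


def test_short_training_reduces_loss_and_is_reproducible(phantom_image, tmp_path):
    cfg = tiny_config(epochs=30, seed=9, scale_range=(1.0, 2.0),
                      points_per_image=128)
    _, log_a = train(cfg, [phantom_image], out_dir=tmp_path)
    _, log_b = train(cfg, [phantom_image])
    assert [r[3] for r in log_a] == [r[3] for r in log_b]  # seeded determinism
    assert log_a[-1][3] < log_a[0][3]
    assert (tmp_path / "model.npz").exists()
    assert (tmp_path / "train_log.csv").exists()


def test_evaluate_reports_both_reconstructions(tiny_model, phantom_image):
    records = evaluate(tiny_model, [phantom_image], [2.0, 3.0])
    assert len(records) == 2
    for r in records:
        assert 0.0 <= r.psnr_model <= 100.0
        assert 0.0 <= r.psnr_bicubic <= 100.0
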