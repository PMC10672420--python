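"""Synthetic vessel phantoms and analytic fixtures."""

import numpy as np
import pytest

from owsr.phantom import (PhantomSpec, gen_analytic_image, gen_vessel_phantom,
                          make_fixture_dataset, render_vessel_phantom)


def test_same_seed_bit_identical():
    spec = PhantomSpec(seed=11)
    assert np.array_equal(gen_vessel_phantom(spec), gen_vessel_phantom(spec))


def test_values_bounded_and_finite():
    r = render_vessel_phantom(PhantomSpec(seed=2))
    for arr in (r.image, r.clean):
        assert np.all(np.isfinite(arr))
        assert arr.min() >= 0.0 and arr.max() <= 1.0
    assert r.image.shape == (96, 96, 3)


def test_vessel_centerlines_brighter_than_background():
    r = render_vessel_phantom(PhantomSpec(seed=4))
    assert r.mask.sum() > 20
    assert r.clean[r.mask].mean() > r.clean[~r.mask].mean() + 0.1


def test_zero_gain_leaves_background_only():
    spec = PhantomSpec(seed=6, vessel_gain=0.0)
    r = render_vessel_phantom(spec)
    assert r.clean.max() <= spec.background_level + spec.background_texture + 1e-12


def test_speckle_vanishes_in_large_shape_limit():
    base = PhantomSpec(seed=8, speckle_shape=1e6)
    r = render_vessel_phantom(base)
    assert np.abs(r.image - r.clean).max() < 0.01 * max(1e-3, r.clean.max())


def test_analytic_constant_and_gradient():
    c = gen_analytic_image("constant", (8, 8), value=0.7)
    assert c.shape == (8, 8, 3) and np.all(c == 0.7)
    g = gen_analytic_image("gradient", (5, 3))
    col_means = g[:, :, 0].mean(axis=0)
    assert np.all(np.diff(col_means) > 0)


def test_analytic_sinusoid_degenerate_frequency():
    s = gen_analytic_image("sinusoid", (6, 6), fx=0.0, fy=0.0)
    assert np.allclose(s, 0.5)
    with pytest.raises(ValueError):
        gen_analytic_image("plaid", (4, 4))


def test_fixture_dataset_idempotent(tmp_path):
    d1 = tmp_path / "a"
    d2 = tmp_path / "b"
    make_fixture_dataset(3, (32, 32), seed=5, out_dir=d1)
    make_fixture_dataset(3, (32, 32), seed=5, out_dir=d2)
    pngs = sorted(p.name for p in d1.glob("*.png"))
    assert len(pngs) == 3
    for name in pngs + ["manifest.json"]:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_fixture_dataset_empty(tmp_path):
    manifest = make_fixture_dataset(0, (16, 16), seed=0, out_dir=tmp_path)
    assert manifest["images"] == []
    assert list(tmp_path.glob("*.png")) == []
    assert (tmp_path / "manifest.json").exists()


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(width_range=(0.0, 2.0))
    with pytest.raises(ValueError):
        PhantomSpec(size=(4, 4))
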