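"""DIP components: forward model, networks, loss plumbing, training loop."""

import numpy as np
import pytest

from cmrf.dip import (DIPTrainConfig, IRNConfig, PENConfig, _Loss1,
                      _loss1_and_grad, build_irn, build_pen,
                      forward_model_frame)
from cmrf.epg import Subspace


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def _random_subspace(rng, t, k):
    A = rng.standard_normal((t, k)) + 1j * rng.standard_normal((t, k))
    return Subspace(V_k=np.linalg.qr(A)[0], k=k, energy_fraction=1.0)


def test_forward_model_frame_matches_loop_oracle(rng):
    """Vectorized forward model vs explicit loops (8x8, k=3, 4 coils)."""
    ny = nx = 8
    k, c, t = 3, 4, 6
    xk = rng.standard_normal((k, ny, nx)) + 1j * rng.standard_normal((k, ny, nx))
    csm = rng.standard_normal((c, ny, nx)) + 1j * rng.standard_normal((c, ny, nx))
    S = _random_subspace(rng, t, k)
    P = rng.random((ny, nx)) > 0.5
    W = rng.random((ny, nx))
    i = 2
    out = forward_model_frame(xk, csm, S, P, W, i)

    def fft2c(a):
        return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a), norm="ortho"))

    brute = np.zeros((c, ny, nx), complex)
    for cc in range(c):
        for kk in range(k):
            brute[cc] += fft2c(csm[cc] * xk[kk]) * np.conj(S.V_k[i, kk])
        brute[cc] *= P * W
    assert np.abs(out - brute).max() / np.abs(brute).max() < 1e-6


def test_forward_model_frame_reduction_and_linearity(rng):
    """With V = identity, one uniform coil and trivial masks the model
    reduces to the FFT of frame i; and it is linear in x_k."""
    ny = nx = 8
    t = k = 4
    S = Subspace(V_k=np.eye(t).astype(complex), k=k, energy_fraction=1.0)
    xk = rng.standard_normal((k, ny, nx)) + 1j * rng.standard_normal((k, ny, nx))
    csm1 = np.ones((1, ny, nx), complex)
    ones = np.ones((ny, nx))
    out = forward_model_frame(xk, csm1, S, ones.astype(bool), ones, 1)
    ref = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(xk[1]), norm="ortho"))
    assert np.abs(out[0] - ref).max() < 1e-10
    out2 = forward_model_frame(3.0 * xk, csm1, S, ones.astype(bool), ones, 1)
    np.testing.assert_allclose(out2, 3.0 * out, rtol=1e-12)
    with pytest.raises(IndexError):
        forward_model_frame(xk, csm1, S, ones.astype(bool), ones, 99)


def test_sparse_loss1_matches_dense_reference(rng):
    t, c, k, ny, nx = 10, 4, 3, 16, 16
    csm = (rng.standard_normal((c, ny, nx))
           + 1j * rng.standard_normal((c, ny, nx))).astype(np.complex64)
    V = (rng.standard_normal((t, k))
         + 1j * rng.standard_normal((t, k))).astype(np.complex64)
    P = rng.random((t, ny, nx)) > 0.7
    W = rng.random((ny, nx)).astype(np.float32)
    y = (rng.standard_normal((t, c, ny, nx))
         + 1j * rng.standard_normal((t, c, ny, nx))).astype(np.complex64)
    y *= P[:, None] * W[None, None]
    out = rng.standard_normal((2 * k, ny, nx)).astype(np.float32)
    frames = np.array([1, 4, 7])
    l_dense, g_dense = _loss1_and_grad(out, csm, V, P, W, y, frames)
    loss1 = _Loss1(csm, V, P, W, y)
    l_sparse, g_sparse = loss1(out, frames)
    assert abs(l_dense - l_sparse) / l_dense < 1e-6
    assert np.abs(g_dense - g_sparse).max() / np.abs(g_dense).max() < 1e-5


def test_loss1_gradient_against_finite_differences(rng):
    t, c, k, ny, nx = 8, 2, 2, 8, 8
    csm = (rng.standard_normal((c, ny, nx))
           + 1j * rng.standard_normal((c, ny, nx))).astype(np.complex64)
    V = (rng.standard_normal((t, k))
         + 1j * rng.standard_normal((t, k))).astype(np.complex64)
    P = rng.random((t, ny, nx)) > 0.4
    W = rng.random((ny, nx)).astype(np.float32)
    y = (rng.standard_normal((t, c, ny, nx))
         + 1j * rng.standard_normal((t, c, ny, nx))).astype(np.complex64)
    y *= P[:, None] * W[None, None]
    out = rng.standard_normal((2 * k, ny, nx)).astype(np.float32)
    frames = np.array([0, 3, 5])
    _, g = _loss1_and_grad(out, csm, V, P, W, y, frames)
    d = rng.standard_normal(g.shape).astype(np.float32)
    eps = 1e-3
    lp, _ = _loss1_and_grad(out + eps * d, csm, V, P, W, y, frames)
    lm, _ = _loss1_and_grad(out - eps * d, csm, V, P, W, y, frames)
    num = (lp - lm) / (2 * eps)
    an = float(np.sum(g * d))
    assert abs(num - an) / abs(num) < 5e-3


def test_irn_output_shape_and_determinism():
    cfg = IRNConfig(d=8, filters=(8, 8, 8, 8, 8), dropout_rate=0.1, seed=3)
    irn = build_irn(64, 64, 5, cfg)
    out = irn.forward(train=False)
    assert out.shape == (10, 64, 64)         # 2k channels for k = 5
    irn2 = build_irn(64, 64, 5, cfg)
    np.testing.assert_array_equal(out, irn2.forward(train=False))
    # dropout disabled => evaluation deterministic
    np.testing.assert_array_equal(irn.forward(train=False),
                                  irn.forward(train=False))


def test_irn_input_is_fixed_and_size_validated():
    cfg = IRNConfig(d=4, filters=(4, 4, 4, 4, 4), seed=0)
    irn = build_irn(32, 32, 2, cfg)
    z0 = irn.z.copy()
    assert np.abs(irn.z).max() <= 0.1
    irn.forward(train=True)
    irn.backward(np.zeros((4, 32, 32), np.float32))
    np.testing.assert_array_equal(irn.z, z0)
    with pytest.raises(ValueError):
        build_irn(48, 48, 2, cfg)             # not divisible by 2^5


def test_pen_output_shape_and_bounds(rng):
    pen = build_pen(5, PENConfig(seed=1))
    xv = rng.standard_normal((257, 10)).astype(np.float32) * 5
    t1, t2, m0r, m0i = pen.forward(xv, train=False)
    assert t1.shape == (257,)
    assert np.all((t1 >= 50.0) & (t1 <= 3000.0))
    assert np.all((t2 >= 5.0) & (t2 <= 1000.0))
    z = pen.forward(np.zeros((1, 10), np.float32), train=False)
    assert all(np.isfinite(v).all() for v in z)
    with pytest.raises(ValueError):
        build_pen(0)


@pytest.fixture(scope="module")
def tiny_dip_inputs():
    """A miniature Cartesian dataset + frozen FGN for fast loop tests."""
    from cmrf.fgn import FGNModel
    from cmrf.grog import CartesianMRFData
    from cmrf.phantom import CoilMaps
    from cmrf.sequence import SequenceParams, build_schedule

    rng = np.random.default_rng(42)
    ny = nx = 32
    t, c, k = 20, 2, 3
    sch = build_schedule(SequenceParams(n_heartbeats=5, window_ms=21.6))
    assert sch.total_trs == t
    V = np.linalg.qr(rng.standard_normal((t, k))
                     + 1j * rng.standard_normal((t, k)))[0]
    S = Subspace(V_k=V, k=k, energy_fraction=1.0)
    P = rng.random((t, ny, nx)) > 0.8
    W = np.where(P.any(0), rng.random((ny, nx)) * 0.9 + 0.1, 0.0)
    csm = CoilMaps(S=(rng.standard_normal((c, ny, nx))
                      + 1j * rng.standard_normal((c, ny, nx))))
    y = (rng.standard_normal((t, c, ny, nx))
         + 1j * rng.standard_normal((t, c, ny, nx))) * 0.1
    y *= P[:, None] * W[None, None]
    cart = CartesianMRFData(y_cart=y, P=P, W=W, csm=csm, schedule=sch)
    fgn = FGNModel(n_rr=4, t=t, hidden=32, rng=np.random.default_rng(5))
    fgn.schedule_hash = sch.schedule_hash()
    return cart, S, fgn, sch


def _run_tiny(tiny_dip_inputs, seed=9, n_iters=30):
    from cmrf.dip import dip_reconstruct

    cart, S, fgn, sch = tiny_dip_inputs
    cfg = DIPTrainConfig(n_iters=n_iters, minibatch_frames=8, voxel_batch=64,
                         dropout_rate=0.1, seed=seed)
    irn_cfg = IRNConfig(d=4, filters=(4, 4, 8, 8, 8),
                        dropout_rate=0.1, seed=seed)
    return dip_reconstruct(cart, S, fgn, sch.rhythm, cfg, irn_cfg=irn_cfg)


def test_dip_loop_losses_fall_and_are_reproducible(tiny_dip_inputs):
    maps, bis, tr1 = _run_tiny(tiny_dip_inputs, seed=9, n_iters=40)
    assert len(tr1["loss1"]) == 40
    assert tr1["loss1"][-10:].mean() < tr1["loss1"][:10].mean()
    assert np.isfinite(tr1["loss2"]).all()
    _, _, tr2 = _run_tiny(tiny_dip_inputs, seed=9, n_iters=40)
    np.testing.assert_array_equal(tr1["loss1"], tr2["loss1"])
    np.testing.assert_array_equal(tr1["loss2"], tr2["loss2"])
    assert maps.t1_map.shape == (32, 32)
    assert np.all((maps.t1_map >= 0) & (maps.t1_map <= 3000))


def test_dip_gradient_isolation(tiny_dip_inputs):
    """FGN weights receive no updates; PEN updates do not change the IRN
    and vice versa (parameter hashes before/after)."""
    cart, S, fgn, sch = tiny_dip_inputs
    before = [p.value.copy() for p in fgn.params()]
    _run_tiny(tiny_dip_inputs, seed=11, n_iters=15)
    for p, b in zip(fgn.params(), before):
        np.testing.assert_array_equal(p.value, b)
        assert np.all(p.grad == 0)


def test_dip_schedule_mismatch_raises(tiny_dip_inputs):
    from cmrf.dip import dip_reconstruct
    from cmrf.sequence import CardiacRhythm

    cart, S, fgn, sch = tiny_dip_inputs
    bad = CardiacRhythm((700.0, 700.0))       # wrong number of RR gaps
    with pytest.raises(ValueError):
        dip_reconstruct(cart, S, fgn, bad, DIPTrainConfig(n_iters=2,
                                                          minibatch_frames=4))
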