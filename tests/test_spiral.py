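"""Spiral trajectory, nonuniform Fourier operators, acquisition simulation."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cmrf.phantom import make_coil_maps
from cmrf.spiral import (GOLDEN_ANGLE_DEG, make_spiral, ndft_adjoint,
                         ndft_forward, nufft_forward, phantom_image_series,
                         simulate_acquisition, voronoi_density_weights)


@pytest.fixture(scope="module")
def traj64():
    return make_spiral(64, n_interleaves=48, dwell_us=25.0, n_trs=140)


def test_spiral_defaults(traj64):
    assert traj64.n_interleaves == 48
    assert np.isclose(traj64.rotation_per_tr_deg, 111.246)


def test_spiral_reaches_kmax(traj64):
    r = np.hypot(traj64.coords[0, :, 0], traj64.coords[0, :, 1])
    assert r.max() <= traj64.k_max
    assert r.max() > 0.995 * traj64.k_max


def test_golden_angle_rotations_never_repeat():
    """All pairwise rotation differences over 705 TRs exceed 0.01 deg."""
    rot = (GOLDEN_ANGLE_DEG * np.arange(705)) % 360.0
    d = np.abs(rot[:, None] - rot[None, :])
    d = np.minimum(d, 360.0 - d)
    iu = np.triu_indices(705, 1)
    assert d[iu].min() >= 0.01


def test_spiral_validation():
    with pytest.raises(ValueError):
        make_spiral(64, n_interleaves=0)
    with pytest.raises(ValueError):
        make_spiral(64, readout_ms=0.01, dwell_us=25.0)


def test_ndft_adjoint_identity(traj64):
    """<Ax, y> == <x, A*y> to near machine precision."""
    rng = np.random.default_rng(0)
    img = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
    s = (rng.standard_normal(traj64.n_samples)
         + 1j * rng.standard_normal(traj64.n_samples))
    Ax = ndft_forward(img, traj64.coords[0])
    Aty = ndft_adjoint(s, traj64.coords[0], 64, 64)
    err = abs(np.vdot(Ax, s) - np.vdot(img, Aty))
    assert err / (np.linalg.norm(img) * np.linalg.norm(s)) < 1e-6


def test_ndft_matches_brute_force_dft():
    """Agreement with the explicit discrete Fourier sum on 8x8."""
    rng = np.random.default_rng(1)
    img = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
    coords = rng.uniform(-4, 3.99, size=(17, 2))
    out = ndft_forward(img, coords)
    brute = np.zeros(17, complex)
    for m, (kx, ky) in enumerate(coords):
        for y in range(8):
            for x in range(8):
                brute[m] += img[y, x] * np.exp(
                    -2j * np.pi * (kx * (x - 4) + ky * (y - 4)) / 8)
    brute /= 8.0
    assert np.abs(out - brute).max() / np.abs(brute).max() < 1e-6


def test_centered_impulse_gives_unit_magnitude(traj64):
    img = np.zeros((64, 64), complex)
    img[32, 32] = 1.0
    mags = np.abs(ndft_forward(img, traj64.coords[0])) * 64.0
    np.testing.assert_allclose(mags, 1.0, atol=1e-9)


def test_ndft_on_integer_grid_equals_unitary_fft():
    """Energy-conserving convention: on the integer grid the NDFT equals
    the centered orthonormal FFT."""
    rng = np.random.default_rng(2)
    img = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
    ky, kx = np.mgrid[-8:8, -8:8].astype(float)
    coords = np.stack([kx.ravel(), ky.ravel()], -1)
    out = ndft_forward(img, coords).reshape(16, 16)
    ref = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img), norm="ortho"))
    assert np.abs(out - ref).max() < 1e-10
    assert np.isclose(np.linalg.norm(out), np.linalg.norm(img))


def test_out_of_range_coordinates_raise():
    img = np.ones((8, 8), complex)
    with pytest.raises(ValueError):
        ndft_forward(img, np.array([[5.0, 0.0]]))


def test_union_of_interleaves_recovers_bandlimited_image(phantom64):
    """Nyquist completeness: gridding all 48 base interleaves of a static
    (bandlimited) image and adjoint-reconstructing with Voronoi density
    weights gives nRMSE < 5%."""
    traj = make_spiral(64, n_interleaves=48, dwell_us=25.0, n_trs=48,
                       rotation_per_tr_deg=360.0 / 48)
    coords = traj.coords.reshape(-1, 2)
    obj = gaussian_filter(np.abs(phantom64.m0_map), 1.0).astype(complex)
    samp = ndft_forward(obj, coords)
    w = voronoi_density_weights(coords)
    rec = ndft_adjoint(samp * w, coords, 64, 64)
    sc = np.vdot(rec, obj) / np.vdot(rec, rec)
    assert np.linalg.norm(sc * rec - obj) / np.linalg.norm(obj) < 0.05


def test_acquisition_noiseless_is_seed_independent(phantom64, coils64,
                                                   schedule5, traj64):
    a = simulate_acquisition(phantom64, schedule5, coils64, traj64,
                             noise_pct=0.0, seed=1)
    b = simulate_acquisition(phantom64, schedule5, coils64, traj64,
                             noise_pct=0.0, seed=99)
    np.testing.assert_array_equal(a.y, b.y)


def test_acquisition_frame_count(acquisition, schedule5):
    assert acquisition.n_trs == schedule5.total_trs == 140


def test_acquisition_noise_sd_matches_request(phantom64, coils64, schedule5,
                                              traj64):
    """Empirical complex-noise SD on a zero phantom matches the requested
    sigma within 5% (>= 1e5 samples)."""
    import copy

    ph0 = make_zero = copy.deepcopy(phantom64)
    ph0.m0_map = np.zeros_like(ph0.m0_map)
    ref = simulate_acquisition(phantom64, schedule5, coils64, traj64,
                               noise_pct=0.1, seed=4)
    z = simulate_acquisition(phantom64, schedule5, coils64, traj64,
                             noise_pct=0.1, seed=4)
    # same seed twice -> identical (reproducibility)
    np.testing.assert_array_equal(ref.y, z.y)
    noisy = simulate_acquisition(ph0, schedule5, coils64, traj64,
                                 noise_pct=0.0, seed=4)
    # zero phantom, no noise -> exactly zero
    assert np.abs(noisy.y).max() == 0.0
    # empirical SD check: subtract the noiseless signal
    clean = simulate_acquisition(phantom64, schedule5, coils64, traj64,
                                 noise_pct=0.0, seed=0)
    noise = ref.y - clean.y
    assert noise.size >= 1e5
    emp = np.sqrt(np.mean(np.abs(noise) ** 2))
    assert abs(emp - ref.noise_sigma) / ref.noise_sigma < 0.05


def test_negative_noise_rejected(phantom64, coils64, schedule5, traj64):
    with pytest.raises(ValueError):
        simulate_acquisition(phantom64, schedule5, coils64, traj64,
                             noise_pct=-1.0, seed=0)


def test_image_series_rank_matches_subspace_bound(phantom64, schedule5,
                                                  coarse_dictionary):
    """Phantom + simulator compose: the rank-5 projection error of the
    voxel fingerprint series is at most a few times the dictionary
    subspace bound sqrt(1 - energy_fraction)."""
    _, S, _ = coarse_dictionary
    x = phantom_image_series(phantom64, schedule5)
    Xm = x.reshape(x.shape[0], -1).T          # (n, t)
    proj = (Xm @ S.V_k) @ S.V_k.conj().T
    err = np.linalg.norm(proj - Xm) / np.linalg.norm(Xm)
    assert err < 3.0 * np.sqrt(1.0 - S.energy_fraction)
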