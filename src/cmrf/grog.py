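"""GRAPPA operator gridding (GROG) and coil-sensitivity self-calibration.

GROG shifts each spiral k-space sample onto its nearest Cartesian grid cell
by applying fractional powers of coil-coupling "unit shift" matrices G_x
and G_y (one n_coils x n_coils matrix per axis).  The operators are
calibrated from a fully-sampled central Cartesian block obtained
self-consistently: the temporal average of the spiral data is gridded with
the nonuniform Fourier adjoint, Fourier transformed, and the central
``calib_region`` square is used as calibration data.  Coil sensitivity
maps are estimated from the same time-averaged coil images with the
adaptive combination (local-covariance eigenvector) method.

The gridded dataset carries the per-frame binary sampling masks P_i and
the density compensation map W (per-cell spiral hit counts over the union
of all frames, normalized to a maximum of one); each frame of the output
is pre-multiplied by W, matching the weighting used by the reconstruction
losses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .phantom import CoilMaps
from .sequence import CardiacSchedule
from .spiral import SpiralMRFData, ndft_adjoint, voronoi_density_weights

__all__ = [
    "GrogOperators",
    "CartesianMRFData",
    "walsh_coil_maps",
    "self_calibration",
    "calibrate_grog",
    "fractional_shift",
    "grog_grid",
]

DEFAULT_CALIB_REGION = 48


@dataclass
class GrogOperators:
    """Unit-shift GRAPPA operator matrices along k_x and k_y."""

    G_x: np.ndarray
    G_y: np.ndarray
    calib_region: int


@dataclass
class CartesianMRFData:
    """GROG-gridded multicoil Cartesian MRF k-space time series.

    y_cart : (t, n_coils, n_y, n_x), zero off the per-frame masks and
             pre-multiplied by W
    P      : (t, n_y, n_x) boolean sampling masks
    W      : (n_y, n_x) density weights in [0, 1]
    """

    y_cart: np.ndarray
    P: np.ndarray
    W: np.ndarray
    csm: CoilMaps
    schedule: CardiacSchedule

    @property
    def n_trs(self) -> int:
        return self.y_cart.shape[0]

    @property
    def shape(self):
        return self.y_cart.shape[-2:]


def walsh_coil_maps(coil_images: np.ndarray, block: int = 7,
                    phase_reference_coil: int = 0) -> CoilMaps:
    """Adaptive-combination coil map estimate from coil images.

    Per voxel, the leading eigenvector of the local (block x block)
    sample covariance across coils gives the relative sensitivity vector;
    maps are unit-norm per voxel and phase-referenced to one coil.
    """
    n_c, n_y, n_x = coil_images.shape
    R = np.empty((n_y, n_x, n_c, n_c), dtype=np.complex128)
    for i in range(n_c):
        for j in range(i, n_c):
            prod = coil_images[i] * np.conj(coil_images[j])
            sm = uniform_filter(prod.real, block) + 1j * uniform_filter(prod.imag, block)
            R[..., i, j] = sm
            if i != j:
                R[..., j, i] = np.conj(sm)
    w, v = np.linalg.eigh(R.reshape(-1, n_c, n_c))
    lead = v[:, :, -1]                       # (n, n_c) leading eigenvector
    ref = lead[:, phase_reference_coil]
    ph = np.where(np.abs(ref) > 0, ref / np.maximum(np.abs(ref), 1e-30), 1.0)
    lead = lead * np.conj(ph)[:, None]
    S = lead.T.reshape(n_c, n_y, n_x)
    return CoilMaps(S=S)


def _fft2c(x):
    """Centered orthonormal 2-D FFT over the last two axes."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)),
                                       norm="ortho"), axes=(-2, -1))


def _ifft2c(x):
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)),
                                        norm="ortho"), axes=(-2, -1))


def time_averaged_coil_images(data: SpiralMRFData, matrix: int | None = None) -> np.ndarray:
    """Grid the temporal average of the spiral data into coil images.

    All frames' samples are pooled into one cloud (golden-angle rotation
    makes the union well-sampled), density-compensated with Voronoi cell
    areas, and gridded per coil with the nonuniform Fourier adjoint.
    """
    matrix = data.trajectory.matrix if matrix is None else matrix
    t, n_c, m = data.y.shape
    coords = data.trajectory.coords[:t].reshape(-1, 2)
    w = voronoi_density_weights(coords)
    samples = data.y.transpose(1, 0, 2).reshape(n_c, -1) * w[None] / t
    return ndft_adjoint(samples, coords, matrix, matrix)


def self_calibration(data: SpiralMRFData, calib_region: int = DEFAULT_CALIB_REGION):
    """Cartesian calibration block and coil maps from the data itself.

    Returns ``(calib, csm)`` where ``calib`` is the central
    ``calib_region x calib_region`` multicoil Cartesian k-space of the
    time-averaged images and ``csm`` the adaptive-combination coil maps.
    """
    if data.n_trs < data.trajectory.n_interleaves:
        warnings.warn(
            "fewer frames than interleaves: time-averaged calibration may be aliased",
            stacklevel=2,
        )
    matrix = data.trajectory.matrix
    if calib_region > matrix:
        raise ValueError("calib_region exceeds matrix size")
    imgs = time_averaged_coil_images(data)
    csm = walsh_coil_maps(imgs)
    ksp = _fft2c(imgs)
    lo = matrix // 2 - calib_region // 2
    calib = ksp[:, lo:lo + calib_region, lo:lo + calib_region]
    return calib, csm


def _unit_shift_lsq(src: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    """Least-squares G with G @ src ~= tgt (both n_coils x N)."""
    SS = src @ src.conj().T
    TS = tgt @ src.conj().T
    lam = 1e-9 * np.trace(SS).real / SS.shape[0]
    cond = np.linalg.cond(SS)
    if cond > 1e12:
        warnings.warn("rank-deficient GROG calibration; regularized solve",
                      stacklevel=3)
        lam = 1e-6 * np.trace(SS).real / SS.shape[0]
    return TS @ np.linalg.inv(SS + lam * np.eye(SS.shape[0]))


def _normalize_eigenvalues(G: np.ndarray) -> np.ndarray:
    """Project the eigenvalues of G onto the unit circle (phase only).

    An ideal unit shift is norm-preserving; least-squares calibration on
    noisy data shrinks eigenvalues (occasionally close to zero), which
    makes fractional powers G**delta with delta < 0 amplify noise
    unboundedly.  Keeping only the eigenvalue phases removes that failure
    mode at negligible cost in shift accuracy.
    """
    w, Q = np.linalg.eig(G)
    w = w / np.maximum(np.abs(w), 1e-12)
    return (Q * w[None, :]) @ np.linalg.inv(Q)


def calibrate_grog(calib: np.ndarray, calib_region: int | None = None,
                   normalize: bool = True) -> GrogOperators:
    """Calibrate unit-shift matrices from a fully-sampled Cartesian block.

    ``calib`` has shape (n_coils, n_ky, n_kx); G_x maps each multicoil
    k-space vector to its +1 neighbor along k_x (last axis), G_y along k_y.
    By default the eigenvalues are normalized to unit modulus (see
    :func:`_normalize_eigenvalues`).
    """
    n_c, n_ky, n_kx = calib.shape
    src_x = calib[:, :, :-1].reshape(n_c, -1)
    tgt_x = calib[:, :, 1:].reshape(n_c, -1)
    G_x = _unit_shift_lsq(src_x, tgt_x)
    src_y = calib[:, :-1, :].reshape(n_c, -1)
    tgt_y = calib[:, 1:, :].reshape(n_c, -1)
    G_y = _unit_shift_lsq(src_y, tgt_y)
    if normalize:
        G_x = _normalize_eigenvalues(G_x)
        G_y = _normalize_eigenvalues(G_y)
    return GrogOperators(G_x=G_x, G_y=G_y,
                         calib_region=calib_region or n_kx)


def fractional_shift(G: np.ndarray, delta: float) -> np.ndarray:
    """Fractional power G**delta via eigendecomposition (principal branch).

    Used to shift a sample by a sub-cell distance ``delta`` (in cells,
    |delta| <= 1).  Falls back to the matrix logarithm if G is defective.
    """
    if abs(delta) > 1.0 + 1e-12:
        raise ValueError("|delta| must be <= 1")
    w, Q = np.linalg.eig(G)
    try:
        Qinv = np.linalg.inv(Q)
    except np.linalg.LinAlgError:
        Qinv = None
    if Qinv is None or np.linalg.cond(Q) > 1e10:
        warnings.warn("defective GROG operator; using matrix-log power",
                      stacklevel=2)
        from scipy.linalg import expm, logm
        return expm(delta * logm(G))
    return (Q * (w[None, :] ** delta)) @ Qinv


def _eig_factors(G):
    w, Q = np.linalg.eig(G)
    return w, Q, np.linalg.inv(Q)


def grog_grid(data: SpiralMRFData, ops: GrogOperators,
              csm: CoilMaps | None = None) -> CartesianMRFData:
    """Shift every spiral sample to its nearest Cartesian cell.

    Nearest-cell rounding is half-toward-negative for determinism; samples
    landing in one cell within a frame are averaged; W counts total hits
    per cell over all frames (normalized to max 1) and each output frame
    is pre-multiplied by it.  Samples whose target cell falls outside the
    grid are dropped.
    """
    matrix = data.trajectory.matrix
    t, n_c, m = data.y.shape
    half = matrix // 2
    wx, Qx, Qxi = _eig_factors(ops.G_x)
    wy, Qy, Qyi = _eig_factors(ops.G_y)

    sums = np.zeros((t, n_c, matrix * matrix), dtype=np.complex128)
    counts = np.zeros((t, matrix * matrix), dtype=np.int64)
    for i in range(t):
        k = data.trajectory.coords[i]
        tx = np.ceil(k[:, 0] - 0.5)
        ty = np.ceil(k[:, 1] - 0.5)
        dx = tx - k[:, 0]
        dy = ty - k[:, 1]
        valid = (tx >= -half) & (tx < half) & (ty >= -half) & (ty < half)
        tx, ty, dx, dy = tx[valid], ty[valid], dx[valid], dy[valid]
        ys = data.y[i][:, valid]                              # (c, mv)
        # per-sample shift operators G_x^dx @ G_y^dy
        px = wx[None, :] ** dx[:, None]                       # (mv, c)
        py = wy[None, :] ** dy[:, None]
        Mx = np.einsum("ab,mb,bc->mac", Qx, px, Qxi)
        My = np.einsum("ab,mb,bc->mac", Qy, py, Qyi)
        shifted = np.einsum("mab,mbc,cm->am", Mx, My, ys)     # (c, mv)
        flat = ((ty + half) * matrix + (tx + half)).astype(np.int64)
        counts[i] = np.bincount(flat, minlength=matrix * matrix)
        for c in range(n_c):
            sums[i, c] = (np.bincount(flat, weights=shifted[c].real, minlength=matrix * matrix)
                          + 1j * np.bincount(flat, weights=shifted[c].imag, minlength=matrix * matrix))

    nz = counts > 0
    y_cart = sums
    y_cart[nz[:, None, :].repeat(n_c, 1)] /= counts[:, None, :].repeat(n_c, 1)[nz[:, None, :].repeat(n_c, 1)]
    union = counts.sum(axis=0).astype(float)
    W = (union / union.max()).reshape(matrix, matrix)
    P = nz.reshape(t, matrix, matrix)
    y_cart = y_cart.reshape(t, n_c, matrix, matrix) * W[None, None]
    if csm is None:
        _, csm = self_calibration(data, min(ops.calib_region, matrix))
    return CartesianMRFData(y_cart=y_cart, P=P, W=W, csm=csm,
                            schedule=data.schedule)
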