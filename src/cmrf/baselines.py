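"""Reference reconstructions: direct dictionary matching and SLLR.

*Direct matching* grids one undersampled image per TR with the nonuniform
Fourier adjoint and matches each voxel's time signal to the dictionary by
maximum normalized inner product, with M0 the complex least-squares scale
between the winning atom and the signal.

*SLLR* solves the subspace reconstruction

    min_xk  ||A(xk) - y||^2 + lambda_llr * sum_b ||P_b(xk)||_*
                            + lambda_wav * ||Psi(xk)||_1

with A the frame-wise (mask o FFT o coils o V_i,k^*) encoding operator on
GROG-gridded Cartesian data, P_b non-overlapping 8x8 spatial patches
reshaped to (patch-pixels x k) matrices, and Psi an orthogonal Daubechies-4
wavelet per basis image.  Both nonsmooth terms are Charbonnier-smoothed and
the problem is solved with nonlinear conjugate gradient (Polak-Ribiere,
Armijo backtracking) for a fixed iteration budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .epg import Dictionary, Subspace
from .grog import CartesianMRFData, _fft2c, _ifft2c
from .phantom import CoilMaps
from .spiral import SpiralMRFData, ndft_adjoint, radial_density_weights

__all__ = [
    "BasisImageSet",
    "ParameterMaps",
    "SLLRConfig",
    "gridded_image_series",
    "direct_match",
    "match_signals",
    "match_compressed",
    "sllr_reconstruct",
    "nufft_basis_images",
]


@dataclass
class BasisImageSet:
    """Complex spatial basis images x_k, shape (n_y, n_x, k)."""

    x_k: np.ndarray
    subspace: Subspace


@dataclass
class ParameterMaps:
    """Quantitative maps: T1/T2 in ms, complex M0, background flags."""

    t1_map: np.ndarray
    t2_map: np.ndarray
    m0_map: np.ndarray
    background: np.ndarray


@dataclass
class SLLRConfig:
    lambda_llr: float = 0.02
    lambda_wav: float = 0.005
    patch: int = 8
    n_iters: int = 25
    smoothing_eps: float = 1e-6
    wavelet: str = "db4"
    wavelet_levels: int = 3


def match_signals(signals: np.ndarray, D: Dictionary) -> ParameterMaps:
    """Dot-product matching of per-voxel signals (n_vox, t) to a dictionary.

    Matching maximizes |<d, s>| / ||d||; M0 = <d, s> / <d, d> for the
    winning atom.  All-zero signals are flagged background.  Works in any
    coefficient domain as long as ``signals`` and ``D.D`` live in the same
    one (full time series or compressed subspace).
    """
    sig = signals.reshape(-1, signals.shape[-1])
    norms = np.linalg.norm(D.D, axis=1)
    Dn = (D.D / norms[:, None]).astype(np.complex64)
    n_vox = sig.shape[0]
    best = np.empty(n_vox, dtype=np.int64)
    chunk = max(1, int(2e7 // max(D.p, 1)))
    sc = sig.astype(np.complex64)
    for lo in range(0, n_vox, chunk):
        hi = min(lo + chunk, n_vox)
        scores = np.abs(sc[lo:hi] @ Dn.conj().T)
        best[lo:hi] = np.argmax(scores, axis=1)
    d_win = D.D[best]
    m0 = np.einsum("vt,vt->v", np.conj(d_win), sig) / (norms[best] ** 2)
    background = np.all(sig == 0, axis=1)
    t1 = D.entries[best, 0].copy()
    t2 = D.entries[best, 1].copy()
    t1[background] = 0.0
    t2[background] = 0.0
    m0[background] = 0.0
    shape = signals.shape[:-1]
    return ParameterMaps(
        t1_map=t1.reshape(shape),
        t2_map=t2.reshape(shape),
        m0_map=m0.reshape(shape),
        background=background.reshape(shape),
    )


def gridded_image_series(data: SpiralMRFData, csm: CoilMaps) -> np.ndarray:
    """One coil-combined image per TR via the nonuniform Fourier adjoint
    with ramp density compensation.  Returns (t, n_y, n_x) complex."""
    t, n_c, m = data.y.shape
    n_y, n_x = csm.S.shape[1:]
    out = np.empty((t, n_y, n_x), dtype=np.complex128)
    ss = np.sum(np.abs(csm.S) ** 2, axis=0)
    ss = np.maximum(ss, 1e-6 * ss.max())
    for i in range(t):
        w = radial_density_weights(data.trajectory.coords[i])
        imgs = ndft_adjoint(data.y[i] * w[None], data.trajectory.coords[i], n_y, n_x)
        out[i] = np.sum(np.conj(csm.S) * imgs, axis=0) / ss
    return out


def direct_match(data: SpiralMRFData, D: Dictionary, csm: CoilMaps) -> ParameterMaps:
    """Per-TR gridding followed by dictionary matching (the conventional
    MRF reconstruction)."""
    if data.schedule.schedule_hash() != D.schedule_hash:
        raise ValueError("dictionary was simulated for a different schedule")
    series = gridded_image_series(data, csm)           # (t, ny, nx)
    signals = np.moveaxis(series, 0, -1)               # (ny, nx, t)
    return match_signals(signals, D)


def match_compressed(x_k: BasisImageSet | np.ndarray, D_k: np.ndarray,
                     entries: np.ndarray, schedule_hash: str = "") -> ParameterMaps:
    """Match spatial basis images to the SVD-compressed dictionary."""
    xk = x_k.x_k if isinstance(x_k, BasisImageSet) else np.asarray(x_k)
    Dk = Dictionary(entries=entries, D=np.asarray(D_k), schedule_hash=schedule_hash)
    return match_signals(xk, Dk)


# ---------------------------------------------------------------------------
# SLLR


class _CartesianSubspaceOp:
    """Frame-wise encoding  y_i = Wt P_i ((F S x_k) V_i,k^*)  and adjoint.

    ``Wt`` is an arbitrary nonnegative residual weight map; the DIP loss
    uses the hit-count map W itself while SLLR uses sqrt(W) (a
    density-compensated least-squares weighting).
    """

    def __init__(self, data: CartesianMRFData, S: Subspace,
                 weight: np.ndarray | None = None):
        self.P = data.P
        self.Wt = data.W if weight is None else weight
        self.csm = data.csm.S
        self.V = S.V_k                      # (t, k)
        self.t = data.n_trs
        self.k = S.k
        self.shape = data.shape

    def forward(self, x_k: np.ndarray) -> np.ndarray:
        """x_k (k, ny, nx) -> (t, c, ny, nx), masked and weighted."""
        G = _fft2c(self.csm[:, None] * x_k[None])       # (c, k, ny, nx)
        y = np.einsum("tk,ckyx->tcyx", np.conj(self.V), G)
        return y * (self.P[:, None] * self.Wt[None, None])

    def adjoint(self, r: np.ndarray) -> np.ndarray:
        rw = r * (self.P[:, None] * self.Wt[None, None])
        B = np.einsum("tk,tcyx->ckyx", self.V, rw)
        imgs = _ifft2c(B)
        return np.einsum("cyx,ckyx->kyx", np.conj(self.csm), imgs)

    def spectral_norm(self, n_iters: int = 8, seed: int = 0) -> float:
        rng = np.random.default_rng(seed)
        x = (rng.standard_normal((self.k, *self.shape))
             + 1j * rng.standard_normal((self.k, *self.shape)))
        s = 1.0
        for _ in range(n_iters):
            x = self.adjoint(self.forward(x))
            s = np.linalg.norm(x)
            x /= s
        return float(np.sqrt(s))


def _charbonnier_l1(x, eps):
    v = np.sqrt(np.abs(x) ** 2 + eps ** 2)
    return np.sum(v - eps), x / v


def _llr_value_grad(x_k: np.ndarray, patch: int, eps: float):
    """Charbonnier-smoothed nuclear norm over non-overlapping patches."""
    k, ny, nx = x_k.shape
    py, px = ny // patch, nx // patch
    # (py, px, patch*patch, k) patch matrices
    Xp = (x_k.reshape(k, py, patch, px, patch)
          .transpose(1, 3, 2, 4, 0)
          .reshape(py, px, patch * patch, k))
    U, s, Vh = np.linalg.svd(Xp, full_matrices=False)
    sv = np.sqrt(s ** 2 + eps ** 2)
    value = float(np.sum(sv - eps))
    gs = s / sv
    G = np.einsum("...ij,...j,...jk->...ik", U, gs, Vh)
    grad = (G.reshape(py, px, patch, patch, k)
            .transpose(4, 0, 2, 1, 3)
            .reshape(k, ny, nx))
    return value, grad


def _wav_value_grad(x_k: np.ndarray, cfg: SLLRConfig, eps: float):
    value = 0.0
    grad = np.empty_like(x_k)
    for j in range(x_k.shape[0]):
        coeffs = pywt.wavedec2(x_k[j], cfg.wavelet, level=cfg.wavelet_levels,
                               mode="periodization")
        arr, slices = pywt.coeffs_to_array(coeffs)
        v, g = _charbonnier_l1(arr, eps)
        value += v
        gc = pywt.array_to_coeffs(g, slices, output_format="wavedec2")
        grad[j] = pywt.waverec2(gc, cfg.wavelet, mode="periodization")
    return value, grad


def sllr_reconstruct(
    data: CartesianMRFData,
    S: Subspace,
    cfg: SLLRConfig | None = None,
    verbose: bool = False,
) -> BasisImageSet:
    """Sparse + locally-low-rank subspace reconstruction (nonlinear CG).

    Regularization weights are relative to the maximum magnitude of the
    initial adjoint basis images, matching the convention of quoting
    lambdas against the maximum basis-image intensity.  Aborts if the cost
    increases over five consecutive failed line searches.
    """
    cfg = cfg or SLLRConfig()
    # plain masked least squares on the gridded cells: the stored data
    # carry the density weight W, which is divided out so that every
    # sampled cell contributes with equal weight (best conditioning for a
    # fixed CG budget); the operator is normalized to unit spectral norm
    # so the relative regularization weights have their conventional
    # meaning
    with np.errstate(divide="ignore", invalid="ignore"):
        y_avg = np.where(data.W[None, None] > 0,
                         data.y_cart / data.W[None, None], 0.0)
    Wh = (data.W > 0).astype(float)
    op = _CartesianSubspaceOp(data, S, weight=Wh)
    L = op.spectral_norm()
    op.Wt = Wh / L
    y = y_avg * (Wh / L)[None, None]
    x = op.adjoint(y)
    scale = np.abs(x).max()
    if scale == 0:
        raise ValueError("all-zero input data")
    lam_llr = cfg.lambda_llr * scale
    lam_wav = cfg.lambda_wav * scale
    eps = cfg.smoothing_eps * scale

    def cost_grad(x):
        r = op.forward(x) - y
        dc = float(np.sum(np.abs(r) ** 2))
        g = 2.0 * op.adjoint(r)
        total = dc
        if lam_llr > 0:
            v, gl = _llr_value_grad(x, cfg.patch, eps)
            total += lam_llr * v
            g += lam_llr * gl
        if lam_wav > 0:
            v, gw = _wav_value_grad(x, cfg, eps)
            total += lam_wav * v
            g += lam_wav * gw
        return total, g

    f, g = cost_grad(x)
    d = -g
    history = [f]
    fails = 0
    for it in range(cfg.n_iters):
        gd = float(np.real(np.vdot(g, d)))
        if gd >= 0:           # restart on non-descent direction
            d = -g
            gd = float(np.real(np.vdot(g, d)))
        alpha = 1.0
        # scale initial step to the operator
        denom = float(np.sum(np.abs(op.forward(d)) ** 2))
        if denom > 0:
            alpha = -0.5 * gd / denom
        ok = False
        for _ in range(20):
            f_new, g_new = cost_grad(x + alpha * d)
            if f_new <= f + 1e-4 * alpha * gd:
                ok = True
                break
            alpha *= 0.5
        if not ok:
            fails += 1
            if fails >= 5:
                raise RuntimeError("SLLR diverged: 5 consecutive failed line searches")
            d = -g
            continue
        fails = 0
        x = x + alpha * d
        beta = max(0.0, float(np.real(np.vdot(g_new, g_new - g))
                              / np.real(np.vdot(g, g))))
        d = -g_new + beta * d
        g, f = g_new, f_new
        history.append(f)
        if verbose:
            print(f"  sllr iter {it + 1}: cost {f:.6g}")
    xk = np.moveaxis(x, 0, -1)                # (ny, nx, k)
    bis = BasisImageSet(x_k=xk, subspace=S)
    bis.cost_history = history
    return bis


def nufft_basis_images(data: SpiralMRFData, S: Subspace, csm: CoilMaps) -> BasisImageSet:
    """Gridding (adjoint) estimate of the basis images from spiral data:
    project the per-TR gridded image series onto the subspace."""
    series = gridded_image_series(data, csm)           # (t, ny, nx)
    xk = np.einsum("tyx,tk->yxk", series, np.conj(S.V_k))
    return BasisImageSet(x_k=xk, subspace=S)
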