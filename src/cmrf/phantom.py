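"""Numerical cardiac phantom and synthetic coil sensitivity maps.

Emulates an MRXCAT-style short-axis cardiac slice: an elliptical thorax
containing lungs, liver, a left-ventricular blood pool surrounded by a
myocardial annulus, a right-ventricular blood pool, and a subcutaneous fat
rim.  Each tissue carries 1.5T-like T1/T2 values with a small per-seed
jitter, and a complex M0 with a smooth low-order phase ramp so that
complex-M0 estimation is exercised.  Acceptance metrics are always computed
against the phantom's own ground truth, so the exact tissue constants do
not bias correctness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TissuePhantom", "CoilMaps", "make_cardiac_phantom", "make_coil_maps",
           "TISSUES", "LABELS"]

# label -> (T1 ms, T2 ms, M0 magnitude); 1.5T-like design constants
TISSUES = {
    "background": (0.0, 0.0, 0.0),
    "lv_blood": (1550.0, 240.0, 1.0),
    "rv_blood": (1550.0, 240.0, 1.0),
    "myocardium": (1000.0, 45.0, 0.8),
    "liver": (590.0, 46.0, 0.7),
    "fat": (260.0, 60.0, 0.9),
    # lung parenchyma carries negligible proton density at 1.5T and is
    # treated as signal-free (background for metric purposes)
    "lung": (1200.0, 80.0, 0.0),
}
LABELS = {name: i for i, name in enumerate(TISSUES)}


@dataclass
class TissuePhantom:
    """Quantitative tissue phantom: T1/T2 maps (ms), complex M0, labels."""

    t1_map: np.ndarray
    t2_map: np.ndarray
    m0_map: np.ndarray
    labels: np.ndarray
    tissue_values: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def shape(self):
        return self.t1_map.shape

    @property
    def foreground(self) -> np.ndarray:
        """Non-background mask (ground-truth M0 != 0)."""
        return np.abs(self.m0_map) > 0


@dataclass
class CoilMaps:
    """Complex coil sensitivities, shape (n_coils, n_y, n_x)."""

    S: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.S.shape[0]


def _ellipse(yy, xx, cy, cx, ry, rx, angle_deg=0.0):
    a = np.deg2rad(angle_deg)
    dy, dx = yy - cy, xx - cx
    u = np.cos(a) * dx + np.sin(a) * dy
    v = -np.sin(a) * dx + np.cos(a) * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_cardiac_phantom(n_y: int, n_x: int, seed: int = 0) -> TissuePhantom:
    """Generate a deterministic short-axis cardiac phantom.

    Geometry is ellipse-based and scales with the matrix size; tissue T1/T2
    get a per-seed +/-3% jitter around the design constants.  Requires
    n_y, n_x >= 32.
    """
    if n_y < 32 or n_x < 32:
        raise ValueError("matrix must be at least 32 x 32")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:n_y, 0:n_x].astype(float)
    cy, cx = (n_y - 1) / 2.0, (n_x - 1) / 2.0
    ry, rx = 0.46 * n_y, 0.48 * n_x

    labels = np.zeros((n_y, n_x), dtype=np.int32)
    thorax = _ellipse(yy, xx, cy, cx, ry, rx)
    fat = thorax & ~_ellipse(yy, xx, cy, cx, 0.92 * ry, 0.93 * rx)
    body = thorax & ~fat

    # lungs: two lateral ellipses
    lung_l = _ellipse(yy, xx, cy - 0.08 * n_y, cx - 0.30 * n_x, 0.26 * n_y, 0.16 * n_x, 15)
    lung_r = _ellipse(yy, xx, cy - 0.08 * n_y, cx + 0.30 * n_x, 0.26 * n_y, 0.16 * n_x, -15)
    # liver: lower-right quadrant ellipse
    liver = _ellipse(yy, xx, cy + 0.28 * n_y, cx + 0.18 * n_x, 0.14 * n_y, 0.22 * n_x, -10)
    # heart: LV blood pool + myocardial annulus, slightly left of center
    hy, hx = cy - 0.02 * n_y, cx - 0.06 * n_x
    lv_out = _ellipse(yy, xx, hy, hx, 0.17 * n_y, 0.17 * n_x)
    lv_in = _ellipse(yy, xx, hy, hx, 0.10 * n_y, 0.10 * n_x)
    myo = lv_out & ~lv_in
    # RV: crescent hugging the LV on the septal side
    rv = (_ellipse(yy, xx, hy - 0.01 * n_y, hx - 0.16 * n_x, 0.15 * n_y, 0.14 * n_x)
          & ~_ellipse(yy, xx, hy, hx, 0.18 * n_y, 0.18 * n_x))

    labels[body] = LABELS["liver"]  # placeholder soft tissue -> refined below
    labels[body] = 0
    for name, mask in [("liver", liver & body), ("lung", (lung_l | lung_r) & body)]:
        labels[mask] = LABELS[name]
    # soft tissue elsewhere inside the body treated as liver-like parenchyma
    soft = body & (labels == 0)
    labels[soft] = LABELS["liver"]
    labels[fat] = LABELS["fat"]
    # heart drawn last so it overrides lung/liver overlap
    labels[rv & body] = LABELS["rv_blood"]
    labels[myo & body] = LABELS["myocardium"]
    labels[lv_in & body] = LABELS["lv_blood"]

    t1 = np.zeros((n_y, n_x))
    t2 = np.zeros((n_y, n_x))
    m0_mag = np.zeros((n_y, n_x))
    values = {}
    for name, (T1, T2, M0) in TISSUES.items():
        if name == "background":
            continue
        jitter = 1.0 + 0.03 * rng.uniform(-1, 1, size=2)
        T1j, T2j = T1 * jitter[0], min(T2 * jitter[1], 0.95 * T1 * jitter[0])
        mask = labels == LABELS[name]
        t1[mask], t2[mask], m0_mag[mask] = T1j, T2j, M0
        values[name] = {"t1_ms": float(T1j), "t2_ms": float(T2j), "m0": float(M0)}

    # smooth low-order phase ramp over the FOV
    phase = (0.8 * np.pi * (xx - cx) / n_x + 0.5 * np.pi * (yy - cy) / n_y
             + 0.3 * np.pi * ((xx - cx) / n_x) * ((yy - cy) / n_y))
    m0 = m0_mag * np.exp(1j * phase)
    m0[labels == 0] = 0.0
    return TissuePhantom(t1_map=t1, t2_map=t2, m0_map=m0, labels=labels,
                         tissue_values=values, seed=seed)


def make_coil_maps(n_y: int, n_x: int, n_coils: int = 8, seed: int = 0,
                   flat: bool = False) -> CoilMaps:
    """Smooth synthetic coil sensitivities.

    Coils are placed around the FOV perimeter with Gaussian-lobe magnitude
    profiles and a smooth linear phase per coil.  ``flat=True`` returns
    unit sensitivities (single-channel sanity checks).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if flat:
        return CoilMaps(S=np.ones((n_coils, n_y, n_x), dtype=np.complex128))
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:n_y, 0:n_x].astype(float)
    cy, cx = (n_y - 1) / 2.0, (n_x - 1) / 2.0
    S = np.empty((n_coils, n_y, n_x), dtype=np.complex128)
    radius = 0.55 * max(n_y, n_x)
    sigma = 0.55 * max(n_y, n_x)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.1, 0.1)
        py, px = cy + radius * np.sin(ang), cx + radius * np.cos(ang)
        d2 = (yy - py) ** 2 + (xx - px) ** 2
        mag = np.exp(-d2 / (2 * sigma ** 2))
        ph = (2 * np.pi / max(n_y, n_x)) * (
            0.3 * np.cos(ang) * (xx - cx) + 0.3 * np.sin(ang) * (yy - cy)
        ) + rng.uniform(0, 2 * np.pi)
        S[c] = mag * np.exp(1j * ph)
    # guarantee nonzero root-sum-of-squares everywhere
    rss = np.sqrt(np.sum(np.abs(S) ** 2, axis=0))
    assert rss.min() > 0
    return CoilMaps(S=S)
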