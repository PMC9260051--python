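"""Fingerprint Generator Network: a learned surrogate for the EPG simulator.

A small fully-connected network (two hidden layers, 300 units, leaky-ReLU)
maps (T1, T2, RR_1..RR_{HB-1}) to the interleaved real/imaginary parts of a
unit-l2-normalized fingerprint of length t.  It is pre-trained once per
schedule on EPG-simulated fingerprints over random tissue values and
cardiac rhythms, after which it replaces the simulator inside the
self-supervised reconstruction loop - crucially, it is differentiable with
respect to its (T1, T2) inputs, which the parameter-estimation network
needs for backpropagation.

Inputs are normalized by fixed constants (T1, T2 by 3000 ms; RR by
2000 ms); targets are l2-normalized so the complex M0 scale is absorbed
by the reconstruction's M0 map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Dense, LeakyReLU, Adam, DTYPE
from .sequence import CardiacSchedule, CardiacRhythm
from .epg import simulate_fingerprints, DEFAULT_N_STATES

__all__ = ["FGNConfig", "FGNModel", "pretrain_fgn", "fgn_forward"]

T_NORM = 3000.0   # ms, T1/T2 input normalization
RR_NORM = 2000.0  # ms, RR input normalization


@dataclass
class FGNConfig:
    n_samples: int = 50_000
    epochs: int = 80
    batch_size: int = 128
    lr: float = 2e-3
    hidden: int = 300
    validation_frac: float = 0.1
    patience: int = 10
    lr_decay: bool = True   # cosine decay of the learning rate to lr/100
    rr_range_ms: tuple = (500.0, 1500.0)
    t1_range_ms: tuple = (50.0, 3000.0)
    t2_range_ms: tuple = (5.0, 1000.0)
    seed: int = 0
    n_states: int = DEFAULT_N_STATES
    convergence_threshold: float = 0.25  # max acceptable validation loss


class FGNModel:
    """Trained fingerprint generator for one fixed schedule."""

    def __init__(self, n_rr: int, t: int, hidden: int, rng: np.random.Generator):
        self.n_rr = n_rr
        self.t = t
        self.layers = [
            Dense(2 + n_rr, hidden, rng),
            LeakyReLU(),
            Dense(hidden, hidden, rng),
            LeakyReLU(),
            Dense(hidden, 2 * t, rng),
        ]
        self.schedule_hash = ""
        self.validation_loss = np.nan

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    # -- raw (normalized-input) passes -----------------------------------
    def forward(self, xin: np.ndarray) -> np.ndarray:
        h = xin
        for lay in self.layers:
            h = lay.forward(h, train=True)
        return h

    def backward(self, g: np.ndarray) -> np.ndarray:
        """Backpropagate to the inputs, accumulating weight grads."""
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g

    def input_gradient(self, g: np.ndarray) -> np.ndarray:
        """Backpropagate to the inputs with frozen weights (no grad
        accumulation on the parameters)."""
        for lay in reversed(self.layers):
            if isinstance(lay, Dense):
                g = g @ lay.W.value.T
            else:
                g = lay.backward(g)
        return g

    # -- user-facing evaluation ------------------------------------------
    def normalize_inputs(self, t1_ms, t2_ms, rr_ms) -> np.ndarray:
        t1 = np.atleast_1d(np.asarray(t1_ms, dtype=DTYPE)) / DTYPE(T_NORM)
        t2 = np.atleast_1d(np.asarray(t2_ms, dtype=DTYPE)) / DTYPE(T_NORM)
        rr = np.asarray(rr_ms, dtype=DTYPE) / DTYPE(RR_NORM)
        if rr.ndim == 1:
            rr = np.broadcast_to(rr, (t1.size, rr.size))
        return np.concatenate([t1[:, None], t2[:, None], rr], axis=1)

    def predict(self, t1_ms, t2_ms, rr_ms) -> np.ndarray:
        """Batched fingerprints, complex (m, t)."""
        xin = self.normalize_inputs(t1_ms, t2_ms, rr_ms)
        out = self.forward(xin)
        return deinterleave(out)


def interleave(fp: np.ndarray) -> np.ndarray:
    """Complex (m, t) -> real (m, 2t) with interleaved re/im."""
    out = np.empty((fp.shape[0], 2 * fp.shape[1]), dtype=DTYPE)
    out[:, 0::2] = fp.real
    out[:, 1::2] = fp.imag
    return out


def deinterleave(v: np.ndarray) -> np.ndarray:
    """Real (m, 2t) interleaved -> complex (m, t)."""
    return v[:, 0::2] + 1j * v[:, 1::2]


def _sample_training_set(schedule: CardiacSchedule, cfg: FGNConfig,
                         rng: np.random.Generator):
    n = cfg.n_samples
    t1 = rng.uniform(*cfg.t1_range_ms, size=n)
    t2 = rng.uniform(*cfg.t2_range_ms, size=n)
    # enforce T2 < T1 by resampling T2 below min(T1, T2max)
    hi = np.minimum(t1, cfg.t2_range_ms[1])
    bad = t2 >= hi
    t2[bad] = cfg.t2_range_ms[0] + rng.random(bad.sum()) * (
        hi[bad] - cfg.t2_range_ms[0])
    n_rr = schedule.n_heartbeats - 1
    rr = rng.uniform(*cfg.rr_range_ms, size=(n, n_rr))
    fps = simulate_fingerprints(t1, t2, schedule, cfg.n_states, rr_override=rr)
    norms = np.linalg.norm(fps, axis=1, keepdims=True)
    fps = fps / np.maximum(norms, 1e-30)
    X = np.concatenate(
        [t1[:, None] / T_NORM, t2[:, None] / T_NORM, rr / RR_NORM], axis=1
    ).astype(DTYPE)
    Y = interleave(fps)
    return X, Y


def pretrain_fgn(schedule: CardiacSchedule, cfg: FGNConfig | None = None,
                 verbose: bool = False) -> FGNModel:
    """One-time supervised pre-training against the EPG simulator.

    Mean-squared-error loss on l2-normalized fingerprints, Adam, early
    stopping on a held-out validation split.  Deterministic under
    ``cfg.seed``.  Raises if the validation loss fails to fall below
    ``cfg.convergence_threshold``.
    """
    cfg = cfg or FGNConfig()
    rng = np.random.default_rng(cfg.seed)
    X, Y = _sample_training_set(schedule, cfg, rng)
    n_val = max(1, int(cfg.validation_frac * len(X)))
    Xv, Yv = X[:n_val], Y[:n_val]
    Xt, Yt = X[n_val:], Y[n_val:]

    model = FGNModel(schedule.n_heartbeats - 1, schedule.total_trs,
                     cfg.hidden, rng)
    model.schedule_hash = schedule.schedule_hash()
    opt = Adam(model.params(), lr=cfg.lr)
    n = len(Xt)
    best_val = np.inf
    best_state = None
    stale = 0
    for epoch in range(cfg.epochs):
        if cfg.lr_decay:
            frac = epoch / max(cfg.epochs - 1, 1)
            opt.lr = cfg.lr * (0.01 + 0.99 * 0.5 * (1 + np.cos(np.pi * frac)))
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            pred = model.forward(Xt[idx])
            r = pred - Yt[idx]
            model.backward((2.0 / r.size) * r)
            opt.step()
        val = float(np.mean((model.forward(Xv) - Yv) ** 2))
        if verbose:
            print(f"  fgn epoch {epoch + 1}: val mse {val:.3e}")
        if val < best_val - 1e-12:
            best_val = val
            best_state = [p.value.copy() for p in model.params()]
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.value = v
    model.validation_loss = best_val
    # scale-aware convergence check: mse per fingerprint / unit norm
    rel = np.sqrt(best_val * Y.shape[1])
    if rel > cfg.convergence_threshold:
        raise RuntimeError(
            f"FGN pre-training failed to converge: held-out relative error "
            f"{rel:.3f} exceeds {cfg.convergence_threshold}")
    return model


def fgn_forward(model: FGNModel, t1_ms, t2_ms, rhythm: CardiacRhythm) -> np.ndarray:
    """Fingerprints for (T1, T2) arrays under one cardiac rhythm.

    Returns complex (m, t).  Warns outside the training range; raises on a
    schedule-length mismatch.
    """
    rr = rhythm.as_array()
    if rr.size != model.n_rr:
        raise ValueError(
            f"rhythm has {rr.size} RR intervals; model expects {model.n_rr}")
    t1 = np.atleast_1d(np.asarray(t1_ms, float))
    t2 = np.atleast_1d(np.asarray(t2_ms, float))
    if np.any(t1 < 50) or np.any(t1 > 3000) or np.any(t2 < 5) or np.any(t2 > 1000):
        import warnings
        warnings.warn("inputs outside the FGN training range", stacklevel=2)
    return model.predict(t1, t2, rr)
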