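"""ECG-triggered cardiac MRF sequence model.

The sequence plays an acquisition window of identical TRs in diastole of
every heartbeat.  Magnetization preparation pulses (an adiabatic inversion
or a T2 preparation) precede the window following a fixed five-beat cycle,
and variable flip angles are applied within each window.  Everything here
is pure combinatorics/timing: given the sequence parameters and the
subject's RR intervals, a deterministic per-TR event list (schedule) is
produced that the signal simulators consume.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence as Seq

import numpy as np

__all__ = [
    "SequenceParams",
    "CardiacRhythm",
    "PrepEvent",
    "CardiacSchedule",
    "images_per_heartbeat",
    "flip_angle_series",
    "constant_rhythm",
    "build_schedule",
]

#: Length of the reference per-heartbeat flip-angle pattern (the number of
#: TRs that fit in the full 254 ms acquisition window).
BASE_PATTERN_LENGTH = 47


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition parameters of the cardiac MRF sequence.

    Defaults correspond to the FISP cardiac MRF protocol: constant
    TR/TE of 5.4/1.4 ms, flip angles swept between 4 and 25 degrees,
    a 21 ms inversion delay, T2 preparations of 30/50/80 ms, and a
    five-heartbeat preparation cycle.
    """

    n_heartbeats: int = 15
    window_ms: float = 254.0
    tr_ms: float = 5.4
    te_ms: float = 1.4
    flip_min_deg: float = 4.0
    flip_max_deg: float = 25.0
    inversion_delay_ms: float = 21.0
    t2prep_times_ms: tuple = (30.0, 50.0, 80.0)
    prep_cycle_length: int = 5

    def __post_init__(self):
        if self.n_heartbeats < 1:
            raise ValueError("n_heartbeats must be >= 1")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if not (0 < self.te_ms < self.tr_ms):
            raise ValueError("te_ms must lie in (0, tr_ms)")
        if self.flip_min_deg > self.flip_max_deg:
            raise ValueError("flip_min_deg must be <= flip_max_deg")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")


@dataclass(frozen=True)
class CardiacRhythm:
    """RR-interval timing from the ECG.

    ``rr_intervals_ms[i]`` is the elapsed time between the end of the
    acquisition window in heartbeat ``i`` and the beginning of the window
    in heartbeat ``i + 1`` (length ``n_heartbeats - 1``).
    """

    rr_intervals_ms: tuple

    def __post_init__(self):
        rr = np.asarray(self.rr_intervals_ms, dtype=float)
        if rr.ndim != 1:
            raise ValueError("rr_intervals_ms must be a 1-D sequence")
        if np.any(rr <= 0):
            raise ValueError("all RR intervals must be positive")
        object.__setattr__(self, "rr_intervals_ms", tuple(float(x) for x in rr))

    def __len__(self):
        return len(self.rr_intervals_ms)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rr_intervals_ms, dtype=float)


@dataclass(frozen=True)
class PrepEvent:
    """A magnetization preparation applied before one heartbeat's window."""

    heartbeat: int
    kind: str          # "inversion" | "none" | "t2prep"
    duration_ms: float


@dataclass(frozen=True)
class CardiacSchedule:
    """Deterministic per-TR event list for one cardiac MRF scan."""

    params: SequenceParams
    rhythm: CardiacRhythm
    n_per_heartbeat: int
    total_trs: int
    flip_deg: tuple
    prep_events: tuple

    @property
    def tr_ms(self) -> float:
        return self.params.tr_ms

    @property
    def te_ms(self) -> float:
        return self.params.te_ms

    @property
    def n_heartbeats(self) -> int:
        return self.params.n_heartbeats

    def flip_array(self) -> np.ndarray:
        return np.asarray(self.flip_deg, dtype=float)

    def prep_for_heartbeat(self, h: int) -> PrepEvent:
        return self.prep_events[h]

    def schedule_hash(self) -> str:
        """Stable hash identifying (params, rhythm, flips); used to key
        dictionaries and fingerprint-generator checkpoints."""
        payload = {
            "params": asdict(self.params),
            "rr": list(self.rhythm.rr_intervals_ms),
            "flip": list(self.flip_deg),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_dict(self) -> dict:
        params = {k: (list(map(float, v)) if isinstance(v, tuple) else
                      (int(v) if isinstance(v, (int, np.integer)) else float(v)))
                  for k, v in asdict(self.params).items()}
        return {
            "params": params,
            "rr_intervals_ms": [float(x) for x in self.rhythm.rr_intervals_ms],
            "n_per_heartbeat": int(self.n_per_heartbeat),
            "total_trs": int(self.total_trs),
            "flip_deg": [float(x) for x in self.flip_deg],
            "prep_events": [
                {"heartbeat": p.heartbeat, "kind": p.kind, "duration_ms": p.duration_ms}
                for p in self.prep_events
            ],
        }


def images_per_heartbeat(window_ms: float, tr_ms: float) -> int:
    """Number of TRs (one image each) fitting in the acquisition window.

    Round-to-nearest with ties rounding up; this is the only rule
    consistent with all published window/TR-count variants
    (254 ms -> 47, 200 -> 37, 150 -> 28, 100 -> 19, 50 -> 9).
    """
    if window_ms <= 0 or tr_ms <= 0:
        raise ValueError("window_ms and tr_ms must be positive")
    return int(np.floor(window_ms / tr_ms + 0.5))


def flip_angle_series(
    n_per_heartbeat: int,
    params: SequenceParams = SequenceParams(),
    pattern: Seq | None = None,
) -> np.ndarray:
    """Per-heartbeat flip-angle pattern, truncated to ``n_per_heartbeat``.

    The default waveform is a sinusoidal ramp from ``flip_min_deg`` up to
    ``flip_max_deg`` and back over the reference 47-TR window; shortened
    windows use the first ``n`` entries of that pattern.  A user-supplied
    ``pattern`` (for example the measured scanner waveform) overrides the
    default; all downstream logic is independent of the waveform choice.
    """
    if n_per_heartbeat < 1:
        raise ValueError("n_per_heartbeat must be >= 1")
    if pattern is not None:
        base = np.asarray(pattern, dtype=float)
        if len(base) < n_per_heartbeat:
            raise ValueError("supplied flip pattern is shorter than the window")
        return base[:n_per_heartbeat].copy()
    length = max(n_per_heartbeat, BASE_PATTERN_LENGTH)
    j = np.arange(length)
    base = params.flip_min_deg + (params.flip_max_deg - params.flip_min_deg) * np.sin(
        np.pi * j / (length - 1)
    )
    return base[:n_per_heartbeat]


def constant_rhythm(params: SequenceParams, bpm: float = 60.0) -> CardiacRhythm:
    """Regular rhythm at ``bpm``: every RR gap equals the heartbeat period
    minus the acquisition window (the simulated-scanner default)."""
    period = 60000.0 / bpm
    gap = period - params.window_ms
    if gap <= 0:
        raise ValueError("acquisition window does not fit in the heartbeat period")
    return CardiacRhythm(tuple([gap] * (params.n_heartbeats - 1)))


def _prep_cycle(params: SequenceParams):
    """One period of the preparation cycle as (kind, duration) pairs."""
    cycle = [("inversion", params.inversion_delay_ms), ("none", 0.0)]
    cycle += [("t2prep", float(tau)) for tau in params.t2prep_times_ms]
    return cycle[: params.prep_cycle_length]


def build_schedule(
    params: SequenceParams,
    rhythm: CardiacRhythm | None = None,
    flip_pattern: Seq | None = None,
) -> CardiacSchedule:
    """Assemble the deterministic per-TR schedule for one scan.

    The preparation schedule cycles with period ``prep_cycle_length``
    (inversion / none / T2-prep 30, 50, 80 ms by default) and the flip-angle
    pattern repeats every heartbeat.  If ``rhythm`` is None a regular
    60 bpm rhythm is assumed.
    """
    if rhythm is None:
        rhythm = constant_rhythm(params)
    if len(rhythm) != params.n_heartbeats - 1:
        raise ValueError(
            f"rhythm has {len(rhythm)} RR intervals; expected "
            f"{params.n_heartbeats - 1} for {params.n_heartbeats} heartbeats"
        )
    n_per = images_per_heartbeat(params.window_ms, params.tr_ms)
    flips_hb = flip_angle_series(n_per, params, pattern=flip_pattern)
    flip_deg = tuple(np.tile(flips_hb, params.n_heartbeats))
    cycle = _prep_cycle(params)
    prep_events = tuple(
        PrepEvent(h, *cycle[h % len(cycle)]) for h in range(params.n_heartbeats)
    )
    return CardiacSchedule(
        params=params,
        rhythm=rhythm,
        n_per_heartbeat=n_per,
        total_trs=n_per * params.n_heartbeats,
        flip_deg=flip_deg,
        prep_events=prep_events,
    )
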