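"""Shared fixtures: one small desk-scale dataset reused across the suite."""

import numpy as np
import pytest

from cmrf.epg import build_dictionary, compress_dictionary, compute_subspace
from cmrf.phantom import make_cardiac_phantom, make_coil_maps
from cmrf.sequence import SequenceParams, build_schedule
from cmrf.spiral import make_spiral, simulate_acquisition


@pytest.fixture(scope="session")
def schedule5():
    """5-heartbeat / 150 ms acquisition window (140 TRs), 60 bpm."""
    return build_schedule(SequenceParams(n_heartbeats=5, window_ms=150.0))


@pytest.fixture(scope="session")
def phantom64():
    return make_cardiac_phantom(64, 64, seed=1)


@pytest.fixture(scope="session")
def coils64():
    return make_coil_maps(64, 64, 8, seed=2)


@pytest.fixture(scope="session")
def coarse_dictionary(schedule5):
    """Coarse (fast) dictionary + rank-5 subspace for the 140-TR schedule."""
    t1_grid = np.concatenate([np.arange(50.0, 2000.0, 40.0),
                              np.arange(2000.0, 3000.1, 100.0)])
    t2_grid = np.concatenate([np.arange(5.0, 100.0, 5.0),
                              np.arange(100.0, 200.0, 20.0),
                              np.arange(200.0, 1000.1, 50.0)])
    D = build_dictionary(schedule5, t1_grid, t2_grid)
    S = compute_subspace(D, 5)
    return D, S, compress_dictionary(D, S)


@pytest.fixture(scope="session")
def acquisition(phantom64, coils64, schedule5):
    """Simulated 140-frame spiral acquisition at 0.1% DC noise."""
    traj = make_spiral(64, n_interleaves=48, dwell_us=12.5,
                       n_trs=schedule5.total_trs)
    return simulate_acquisition(phantom64, schedule5, coils64, traj,
                                noise_pct=0.1, seed=3)


@pytest.fixture(scope="session")
def gridded(acquisition):
    from cmrf.grog import calibrate_grog, grog_grid, self_calibration

    calib, csm_est = self_calibration(acquisition)
    return grog_grid(acquisition, calibrate_grog(calib), csm=csm_est), csm_est
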