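"""Shared constructors for acceptance tests: hand-built place maps and
theta-comodulated unit pairs."""

import numpy as np

from thetapop import (GroundTruthUnit, LaserEvents, SimConfig, simulate_lfp,
                      simulate_spikes, simulate_trajectory)
from thetapop.lfp import segment_theta
from thetapop.tuning import PlaceMap


def _map(rate, occ):
    rate = np.asarray(rate, dtype=float)
    occ = np.asarray(occ, dtype=float)
    return PlaceMap(spike_map=rate * occ, occupancy=occ, rate_map=rate,
                    raw_rate_map=rate, bin_size=1.0, smoothing_sd=0.0,
                    arena_side=float(rate.shape[0]))


def uniform_map():
    return _map(np.full((5, 5), 3.0), np.ones((5, 5)))


def two_bin_map():
    return _map(np.array([[2.0, 0.0]]), np.array([[1.0, 1.0]]))


def comod_pair(seed, duration=120.0, motif=False):
    """Two theta-locked units that are conditionally independent unless the
    tagged-cell -> interneuron motif is enabled."""
    cfg = SimConfig(duration=duration, common_gain_sd=0.0, noise_amp=0.0,
                    theta_jitter=0.2, rng_seed=seed,
                    motif_gain=25.0 if motif else 0.0,
                    suppression_fast_gain=0.0, suppression_gain=0.0)
    ref = GroundTruthUnit("ref", "DG", "principal", tag="chr2_abdgc",
                          base_rate=3.0, theta_kappa=1.5, theta_mu=160.0)
    tgt = GroundTruthUnit("tgt", "CA3",
                          "interneuron" if motif else "principal",
                          base_rate=8.0, theta_kappa=1.5, theta_mu=120.0)
    pos = simulate_trajectory(cfg)
    lfp, phase = simulate_lfp(cfg)
    laser = LaserEvents(np.empty(0), np.empty(0), 0.0, "none")
    table = simulate_spikes([ref, tgt], pos, phase, laser, cfg)
    return table.times("ref"), table.times("tgt"), segment_theta(lfp)
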