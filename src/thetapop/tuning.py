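"""Single-unit tuning: place maps, spatial information and coherence,
oscillatory phase coupling, and rate-matched control selection.

Place maps divide the arena into square bins (default 1.4 cm, i.e. a
30 × 30 grid over the 41-cm box); spike-count and occupancy maps are
smoothed separately with a 2-D Gaussian kernel (s.d. 1.2 bin widths) before
division.  Spatial information per spike follows Skaggs:

    I = Σ_i P_i (λ_i/λ) log2(λ_i/λ),   λ = Σ_i P_i λ_i

with P_i the occupancy probability of bin i and λ_i its firing rate.
Phase coupling is summarised by the circular mean direction (preferred
phase) and the mean resultant length (MRL) of spike-phase unit phasors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import pearsonr

from .core import ValidationError

__all__ = [
    "PlaceMap",
    "PhaseCoupling",
    "make_place_map",
    "spatial_information",
    "spatial_information_null",
    "spatial_coherence",
    "phase_coupling",
    "rate_match",
    "GAMMA_MIN_SPIKES",
]

DEFAULT_BIN_CM = 41.0 / 30.0  # ≈1.37 cm: 30 × 30 bins over the 41-cm arena
DEFAULT_SMOOTH_SD = 1.2  # bin widths
OCCUPANCY_MIN_S = 0.1  # below this a bin counts as unvisited
GAMMA_MIN_SPIKES = 200  # inclusion threshold for slow-gamma coupling
MIN_NULL_SHIFT_S = 20.0


@dataclass
class PlaceMap:
    """Spike, occupancy and rate maps over a square arena.

    ``rate_map`` divides the smoothed maps; ``raw_rate_map`` divides the
    unsmoothed maps (used for spatial coherence).  Unvisited bins
    (occupancy < 0.1 s) are NaN in both rate maps.
    """

    spike_map: np.ndarray  # counts/bin, unsmoothed
    occupancy: np.ndarray  # s/bin, unsmoothed
    rate_map: np.ndarray  # events/s, smoothed
    raw_rate_map: np.ndarray
    bin_size: float  # cm
    smoothing_sd: float  # bin widths
    arena_side: float  # cm

    @property
    def visited(self) -> np.ndarray:
        return self.occupancy >= OCCUPANCY_MIN_S


def _interp_positions(spike_times: np.ndarray, position: pd.DataFrame):
    """Linear position at spike times; spikes outside the track are dropped."""
    t = position["time_s"].to_numpy()
    inside = (spike_times >= t[0]) & (spike_times <= t[-1])
    st = spike_times[inside]
    return (np.interp(st, t, position["x_cm"].to_numpy()),
            np.interp(st, t, position["y_cm"].to_numpy()))


def make_place_map(spike_times: np.ndarray, position: pd.DataFrame, arena_side: float = 41.0,
                   bin_size: float = DEFAULT_BIN_CM,
                   smoothing_sd: float = DEFAULT_SMOOTH_SD) -> PlaceMap:
    """Build a smoothed firing-rate map.

    Spike and occupancy maps are smoothed separately, then divided; bins
    with < 0.1 s raw occupancy are marked unvisited (NaN).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    n_bins = int(round(arena_side / bin_size))
    edges = np.linspace(0.0, arena_side, n_bins + 1)
    t = position["time_s"].to_numpy()
    if t.size < 2:
        raise ValidationError("position track too short for a place map")
    dt = float(np.median(np.diff(t)))
    occ, _, _ = np.histogram2d(position["x_cm"], position["y_cm"], bins=[edges, edges])
    occ *= dt
    if occ.sum() <= 0:
        raise ValidationError("zero total occupancy")
    sx, sy = _interp_positions(spike_times, position)
    spk, _, _ = np.histogram2d(sx, sy, bins=[edges, edges])

    visited = occ >= OCCUPANCY_MIN_S
    if smoothing_sd > 0:
        spk_s = gaussian_filter(spk, sigma=smoothing_sd, mode="constant")
        occ_s = gaussian_filter(occ, sigma=smoothing_sd, mode="constant")
    else:
        spk_s, occ_s = spk, occ
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ_s > 0, spk_s / np.where(occ_s > 0, occ_s, 1.0), np.nan)
        raw = np.where(occ > 0, spk / np.where(occ > 0, occ, 1.0), np.nan)
    rate[~visited] = np.nan
    raw[~visited] = np.nan
    return PlaceMap(spike_map=spk, occupancy=occ, rate_map=rate, raw_rate_map=raw,
                    bin_size=arena_side / n_bins, smoothing_sd=smoothing_sd,
                    arena_side=arena_side)


def spatial_information(place_map: PlaceMap, smoothed: bool = True) -> float:
    """Skaggs information per spike (bits/spike) over visited bins."""
    v = place_map.visited
    occ = place_map.occupancy[v]
    lam = (place_map.rate_map if smoothed else place_map.raw_rate_map)[v]
    p = occ / occ.sum()
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        warnings.warn("mean rate is zero; spatial information undefined")
        return np.nan
    ratio = lam / lam_bar
    nz = ratio > 0
    return float(np.sum(p[nz] * ratio[nz] * np.log2(ratio[nz])))


def spatial_information_null(spike_times: np.ndarray, position: pd.DataFrame,
                             n_shuffles: int = 100, arena_side: float = 41.0,
                             bin_size: float = DEFAULT_BIN_CM,
                             rng: np.random.Generator | None = None) -> np.ndarray:
    """Null spatial information by circularly shifting spikes vs location.

    Each shuffle shifts all spike times by a uniform offset of at least
    20 s (wrapping within the tracked interval), decoupling spikes from
    position while preserving the train's temporal structure.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    t = position["time_s"].to_numpy()
    duration = float(t[-1] - t[0])
    if duration <= 2 * MIN_NULL_SHIFT_S:
        raise ValidationError(
            f"session of {duration:.1f} s too short for >= {MIN_NULL_SHIFT_S:g}-s shifts"
        )
    spike_times = np.asarray(spike_times, dtype=float)
    out = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shift = rng.uniform(MIN_NULL_SHIFT_S, duration - MIN_NULL_SHIFT_S)
        shifted = t[0] + (spike_times - t[0] + shift) % duration
        pm = make_place_map(np.sort(shifted), position, arena_side=arena_side, bin_size=bin_size)
        out[k] = spatial_information(pm)
    return out


def spatial_coherence(place_map: PlaceMap) -> float:
    """Pearson r between each bin's rate and its 8-neighbour mean rate.

    Computed from the unsmoothed rate map over visited bins with at least
    one visited neighbour; NaN when either side has zero variance.
    """
    raw = place_map.raw_rate_map
    v = place_map.visited
    if int(v.sum()) < 9:
        raise ValidationError("spatial coherence needs at least 9 visited bins")
    n0, n1 = raw.shape
    center, neigh = [], []
    # interior bins only: a full 3x3 neighbourhood must lie inside the grid
    for i in range(1, n0 - 1):
        for j in range(1, n1 - 1):
            if not v[i, j]:
                continue
            vals = [raw[a, b]
                    for a in range(max(i - 1, 0), min(i + 2, n0))
                    for b in range(max(j - 1, 0), min(j + 2, n1))
                    if (a, b) != (i, j) and v[a, b]]
            if vals:
                center.append(raw[i, j])
                neigh.append(float(np.mean(vals)))
    center = np.asarray(center)
    neigh = np.asarray(neigh)
    if np.std(center) == 0 or np.std(neigh) == 0:
        warnings.warn("zero variance in rate map; coherence undefined")
        return np.nan
    return float(pearsonr(center, neigh)[0])


@dataclass
class PhaseCoupling:
    """Circular summary of spike phases: preferred phase and MRL."""

    preferred_phase: float  # deg in [-180, 180)
    mrl: float  # in [0, 1]
    n_spikes: int


def phase_coupling(phases_deg: np.ndarray, min_spikes: int = 1) -> PhaseCoupling:
    """Mean direction and resultant length of spike phases (degrees).

    NaN phases (spikes outside accepted theta cycles) are dropped.  For
    slow-gamma coupling call with ``min_spikes=GAMMA_MIN_SPIKES``.
    """
    phases = np.asarray(phases_deg, dtype=float)
    phases = phases[np.isfinite(phases)]
    if phases.size < max(min_spikes, 1):
        raise ValidationError(
            f"phase coupling needs >= {max(min_spikes, 1)} spikes with defined phase, "
            f"got {phases.size}"
        )
    z = np.exp(1j * np.radians(phases)).mean()
    pref = float(np.degrees(np.angle(z)))
    if pref >= 180.0:
        pref -= 360.0
    return PhaseCoupling(preferred_phase=pref, mrl=float(np.abs(z)), n_spikes=phases.size)


def rate_match(reference_rates: dict, candidate_rates: dict) -> dict:
    """Greedy nearest-rate matching of candidates to references.

    Pairs are formed in ascending order of |log-rate difference|, without
    replacement (each reference and candidate used at most once).  Returns
    ``{reference_id: (candidate_id, abs_log_ratio)}``; references left
    unmatched (fewer candidates) are reported with value None.
    """
    pairs = []
    for r_id, r in reference_rates.items():
        for c_id, c in candidate_rates.items():
            if r <= 0 or c <= 0:
                raise ValidationError("rates must be positive for log-rate matching")
            pairs.append((abs(np.log(c) - np.log(r)), r_id, c_id))
    pairs.sort(key=lambda p: (p[0], str(p[1]), str(p[2])))
    matched: dict = {}
    used_c = set()
    for d, r_id, c_id in pairs:
        if r_id in matched or c_id in used_c:
            continue
        matched[r_id] = (c_id, float(d))
        used_c.add(c_id)
    unmatched = [r for r in reference_rates if r not in matched]
    if unmatched:
        warnings.warn(f"{len(unmatched)} reference unit(s) left unmatched")
        for r in unmatched:
            matched[r] = None
    return matched
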