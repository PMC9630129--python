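"""Seeded generator of ground-truth hippocampal recording sessions.

Emulates the statistical structure the downstream analyses assume:

* open-field exploration of a square arena (smoothed reflective random walk
  at the 25 frames/s tracking rate);
* a theta-dominated LFP (frequency-jittered 5–12-Hz sinusoid + 1/f noise,
  optional slow-gamma bursts) with the generating phase retained as ground
  truth (peak = 0°);
* heterogeneous log-normal unit firing rates with a high-rate tagged
  (adult-born granule cell) subpopulation, Gaussian place fields, von-Mises
  theta-phase locking, and light modulation (ms-latency evoked spiking under
  473-nm pulses, multiplicative suppression under 30-s 561-nm pulses);
* a feed-forward motif: spikes of tagged cells elevate interneuron rates in
  a 20–40-ms lag window, and pooled interneuron spiking divisively
  suppresses principal cells (fast phasic + slow normalising components);
* a slow shared log-normal excitability gain carried by all units.

Spikes are drawn from the resulting inhomogeneous rate by thinning, so
empirical rates can be checked against the analytic intensity.  All
randomness flows from one session seed; per-unit sub-streams are derived
deterministically so single units are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import i0

from .core import LaserEvents, LfpSignal, SpikeTable, ValidationError

__all__ = [
    "GroundTruthUnit",
    "SimConfig",
    "SyntheticSession",
    "simulate_trajectory",
    "simulate_lfp",
    "simulate_laser",
    "simulate_spikes",
    "default_units",
    "make_session",
]


# ------------------------------------------------------------------- types

@dataclass
class GroundTruthUnit:
    """Generating parameters of one simulated unit."""

    unit_id: str
    region: str  # DG | CA3 | CA1
    cell_class: str  # principal | interneuron
    tag: str = "none"  # none | chr2_abdgc | archt_abdgc
    base_rate: float = 1.0  # events/s (long-run mean in the absence of opto)
    place_center: tuple | None = None  # cm; None = untuned
    place_width: float = np.inf  # cm, s.d. of the Gaussian field
    theta_kappa: float = 0.0  # von-Mises concentration
    theta_mu: float = 0.0  # preferred phase, deg, peak = 0°
    opto_gain: float = 1.0  # multiplicative rate factor during light
    opto_latency: float = 0.0  # s

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValidationError(f"{self.unit_id}: base_rate must be > 0")
        if self.place_width <= 0:
            raise ValidationError(f"{self.unit_id}: place_width must be > 0")
        if self.theta_kappa < 0 or self.opto_gain < 0 or self.opto_latency < 0:
            raise ValidationError(f"{self.unit_id}: negative modulation parameter")


@dataclass
class SimConfig:
    """Session-level generator configuration (defaults = study conditions)."""

    duration: float = 600.0  # s
    arena_side: float = 41.0  # cm, square box
    tracking_rate: float = 25.0  # frames/s
    lfp_rate: float = 1250.0  # samples/s (the analysis rate)
    theta_freq: float = 8.0  # Hz, mean theta frequency
    theta_jitter: float = 0.4  # Hz, s.d. of the slow frequency wander
    theta_amp: float = 200.0  # µV
    gamma_band: tuple = (30.0, 55.0)  # Hz
    gamma_amp: float = 0.0  # µV; 0 disables gamma bursts
    gamma_burst_rate: float = 0.5  # bursts/s when enabled
    noise_amp: float = 40.0  # µV RMS of the 1/f background
    noise_exponent: float = 1.0  # 1/f^exponent
    # unit counts per region/class
    n_ca1: int = 14
    n_ca3: int = 10
    n_dg: int = 8
    n_abdgc: int = 1
    n_interneurons: int = 6  # spread across regions
    # slow shared excitability (log-normal, mean 1)
    common_gain_sd: float = 1.2  # s.d. of log gain
    common_gain_tau: float = 10.0  # s, correlation time (behavioral-state scale)
    # laser protocol: None | "activation" (5-ms, 473 nm) | "silencing" (30-s, 561 nm)
    protocol: str | None = None
    pulse_width: float = 0.005  # s (activation)
    activation_isi: tuple = (0.5, 2.5)  # s, uniform inter-stimulus interval
    silencing_width: float = 30.0  # s
    silencing_isi: tuple = (5.0, 22.0)  # s, uniform inter-stimulus interval
    evoked_prob: float = 1.0  # per-pulse evoked-spike probability (ChR2)
    # motif parameters
    motif_lag: tuple = (0.02, 0.04)  # s, tagged-spike -> interneuron window
    motif_gain: float = 25.0  # interneuron rate gain per tagged spike in window
    # divisive inhibition of principal cells by pooled interneuron spiking:
    # a fast component (phasic feed-forward suppression) plus a slow
    # component (tonic normalisation tracking shared excitability)
    suppression_fast_gain: float = 0.15  # weight per spike, fast window
    suppression_fast_window: float = 0.08  # s
    suppression_gain: float = 0.05  # weight per spike, slow window
    suppression_window: float = 0.30  # s
    # low-rate principal cells are under proportionally stronger inhibitory
    # control: per-cell inhibition scales as (1.5 Hz / base_rate)^exponent
    suppression_rate_exponent: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.arena_side <= 0:
            raise ValidationError("arena_side must be > 0")
        top = max(self.theta_freq, self.gamma_band[1] if self.gamma_amp > 0 else 0.0)
        if self.lfp_rate < 2.0 * top:
            raise ValidationError(
                f"lfp_rate {self.lfp_rate:g} below Nyquist for {top:g} Hz content"
            )

    def rng(self, *key: int) -> np.random.Generator:
        """Deterministic sub-stream keyed on (seed, *key)."""
        return np.random.default_rng(np.random.SeedSequence((self.rng_seed,) + key))


# stream keys (stable across versions)
_K_TRAJ, _K_LFP, _K_LASER, _K_UNITS, _K_SPIKE, _K_GAIN = 1, 2, 3, 4, 5, 6


@dataclass
class SyntheticSession:
    """A complete generated session plus its generating truth."""

    spikes: SpikeTable
    lfp: LfpSignal
    position: pd.DataFrame  # time_s, x_cm, y_cm
    laser: LaserEvents
    truth: list
    phase_truth: np.ndarray  # deg in [-180, 180), aligned to lfp samples
    config: SimConfig


# -------------------------------------------------------------- trajectory

def simulate_trajectory(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Smoothed reflective random walk in the square arena.

    Velocity follows an Ornstein–Uhlenbeck process (mean speed a few cm/s,
    clipped at ``v_max`` = 30 cm/s); positions reflect off the walls.
    """
    if rng is None:
        rng = config.rng(_K_TRAJ)
    rate = config.tracking_rate
    n = int(round(config.duration * rate))
    n = max(n, 1)
    dt = 1.0 / rate
    side = config.arena_side
    v_max = 30.0  # cm/s
    tau = 1.0  # s, velocity correlation time
    sigma_v = 8.0  # cm/s, stationary speed scale

    xy = np.empty((n, 2))
    xy[0] = rng.uniform(0.2 * side, 0.8 * side, size=2)
    v = rng.normal(0.0, sigma_v, size=2)
    a = np.exp(-dt / tau)
    b = sigma_v * np.sqrt(1.0 - a * a)
    for i in range(1, n):
        v = a * v + b * rng.normal(size=2)
        speed = np.hypot(*v)
        if speed > v_max:
            v *= v_max / speed
        p = xy[i - 1] + v * dt
        # reflect at the walls
        for d in range(2):
            if p[d] < 0:
                p[d] = -p[d]
                v[d] = -v[d]
            elif p[d] > side:
                p[d] = 2 * side - p[d]
                v[d] = -v[d]
        xy[i] = np.clip(p, 0.0, side)
    t = np.arange(n) * dt
    return pd.DataFrame({"time_s": t, "x_cm": xy[:, 0], "y_cm": xy[:, 1]})


# --------------------------------------------------------------------- LFP

def _one_over_f_noise(n: int, rate: float, exponent: float, amp_rms: float,
                      rng: np.random.Generator) -> np.ndarray:
    if amp_rms <= 0:
        return np.zeros(n)
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(x**2))
    return x * (amp_rms / rms) if rms > 0 else x


def simulate_lfp(config: SimConfig, rng: np.random.Generator | None = None):
    """Generate the LFP and the ground-truth theta phase (deg, peak = 0°).

    The theta component is ``theta_amp·cos(φ(t))`` where the instantaneous
    frequency wanders slowly (s.d. ``theta_jitter`` Hz, ~1-s correlation)
    around ``theta_freq``.  1/f background noise and optional slow-gamma
    bursts are added on top.
    """
    if rng is None:
        rng = config.rng(_K_LFP)
    rate = config.lfp_rate
    if rate < 250.0:
        raise ValidationError("lfp_rate must be at least 250 samples/s")
    n = int(round(config.duration * rate))
    dt = 1.0 / rate

    if config.theta_jitter > 0:
        # slow frequency wander: Gaussian noise smoothed over ~1 s
        w = rng.normal(size=n)
        k = int(rate)  # 1-s boxcar
        kern = np.ones(k) / k
        slow = np.convolve(w, kern, mode="same")
        slow = slow / max(np.std(slow), 1e-12) * config.theta_jitter
        freq = config.theta_freq + slow
    else:
        freq = np.full(n, config.theta_freq)
    phase_rad = 2.0 * np.pi * np.cumsum(freq) * dt
    phase_rad -= phase_rad[0]  # start at the peak
    theta = config.theta_amp * np.cos(phase_rad)
    phase_deg = (np.degrees(phase_rad) + 180.0) % 360.0 - 180.0

    samples = theta + _one_over_f_noise(n, rate, config.noise_exponent, config.noise_amp, rng)

    if config.gamma_amp > 0:
        f_g = 0.5 * (config.gamma_band[0] + config.gamma_band[1])
        t = np.arange(n) * dt
        carrier = np.sin(2 * np.pi * f_g * t + rng.uniform(0, 2 * np.pi))
        envelope = np.zeros(n)
        n_bursts = rng.poisson(config.gamma_burst_rate * config.duration)
        centers = rng.uniform(0, config.duration, size=n_bursts)
        for c in centers:
            envelope += np.exp(-0.5 * ((t - c) / 0.05) ** 2)
        samples = samples + config.gamma_amp * envelope * carrier

    return LfpSignal(samples=samples, rate=rate, t0=0.0), phase_deg


# ------------------------------------------------------------------- laser

def simulate_laser(config: SimConfig, rng: np.random.Generator | None = None) -> LaserEvents:
    """Pulse schedule for the configured protocol.

    Activation: 5-ms 473-nm pulses, uniform 0.5–2.5-s inter-stimulus
    intervals.  Silencing: 30-s 561-nm pulses, uniform 5–22-s intervals.
    Pulses that would overrun the session are dropped.
    """
    if rng is None:
        rng = config.rng(_K_LASER)
    if config.protocol is None:
        return LaserEvents(onsets=np.empty(0), durations=np.empty(0),
                           wavelength_nm=0.0, protocol="none")
    if config.protocol == "activation":
        width, isi, wl = config.pulse_width, config.activation_isi, 473.0
    elif config.protocol == "silencing":
        width, isi, wl = config.silencing_width, config.silencing_isi, 561.0
    else:
        raise ValidationError(f"unknown protocol {config.protocol!r}")
    onsets = []
    t = rng.uniform(*isi)
    while t + width <= config.duration:
        onsets.append(t)
        t += width + rng.uniform(*isi)
    onsets = np.asarray(onsets)
    return LaserEvents(onsets=onsets, durations=np.full(onsets.size, width),
                       wavelength_nm=wl, protocol=config.protocol)


# ------------------------------------------------------------------ spikes

def _thin_spikes(rate_grid: np.ndarray, grid_rate: float, duration: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous-Poisson sampling by thinning against a piecewise-
    constant intensity defined on the LFP time grid."""
    lam_max = float(np.max(rate_grid)) if rate_grid.size else 0.0
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * duration)
    t_cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    idx = np.minimum((t_cand * grid_rate).astype(int), rate_grid.size - 1)
    keep = rng.uniform(size=n_cand) < rate_grid[idx] / lam_max
    return t_cand[keep]


def _lagged_drive(spike_times: np.ndarray, n: int, grid_rate: float,
                  lag_lo: float, lag_hi: float) -> np.ndarray:
    """Per-grid-sample count of source spikes lagging by [lag_lo, lag_hi)."""
    drive = np.zeros(n)
    if spike_times.size == 0:
        return drive
    counts = np.bincount(np.minimum((spike_times * grid_rate).astype(int), n - 1),
                         minlength=n).astype(float)
    k_lo = int(round(lag_lo * grid_rate))
    k_hi = max(int(round(lag_hi * grid_rate)), k_lo + 1)
    kernel = np.zeros(k_hi)
    kernel[k_lo:k_hi] = 1.0
    return np.convolve(counts, kernel)[:n]


def simulate_spikes(units: list, position: pd.DataFrame, phase_truth: np.ndarray,
                    laser: LaserEvents, config: SimConfig) -> SpikeTable:
    """Draw spike trains for all units by thinning an inhomogeneous rate.

    Per unit, ``rate(t) = base_rate × place(x,y) × theta(φ) × opto(t)``:

    * the Gaussian place factor is normalised by its mean over the actual
      trajectory, so the long-run mean rate stays ``base_rate``;
    * the von-Mises theta factor ``exp(κ·cos(φ−µ))/I₀(κ)`` integrates to 1
      over a cycle by construction (rate-preserving);
    * the opto factor is ``opto_gain`` from ``opto_latency`` after each
      matching pulse onset until pulse offset; ChR2-tagged units
      additionally emit a near-deterministic evoked spike within 10 ms of
      each 473-nm pulse.

    All units additionally share a slow log-normal excitability gain
    (mean 1, log-s.d. ``common_gain_sd``, ~1-s correlation), emulating the
    common state fluctuations that correlate simultaneously recorded cells.

    Motif: tagged-cell spikes elevate every interneuron's rate by
    ``motif_gain`` per tagged spike lagged 20–40 ms; principal cells are
    divisively suppressed by the pooled interneuron spiking integrated
    over ``suppression_window``.  Because interneurons also carry the
    shared gain, this
    feed-forward inhibition divisively normalises common fluctuations:
    silencing the tagged drive both disinhibits principal cells and lets
    the shared gain express more fully (higher co-firing, lower
    dimensionality), while activating it transiently suppresses the
    population (sparser post-pulse vectors).  Tagged cells are generated
    first, then interneurons, then the remaining principal cells.
    """
    grid_rate = config.lfp_rate
    n = phase_truth.size
    if abs(n / grid_rate - config.duration) > 1.0 / grid_rate + 1e-9:
        raise ValidationError("phase_truth length does not match session duration")
    duration = n / grid_rate
    t_grid = np.arange(n) / grid_rate

    pos_t = position["time_s"].to_numpy()
    if pos_t.size and abs(pos_t[-1] - duration) > duration:
        raise ValidationError("position track misaligned with session time base")
    x = np.interp(t_grid, pos_t, position["x_cm"].to_numpy())
    y = np.interp(t_grid, pos_t, position["y_cm"].to_numpy())
    phase_rad = np.radians(phase_truth)

    blue = laser.protocol == "activation" and laser.n_events > 0
    yellow = laser.protocol == "silencing" and laser.n_events > 0

    # slow shared excitability gain, log-normal with mean 1
    if config.common_gain_sd > 0:
        rng_g = config.rng(_K_GAIN)
        k = max(int(config.common_gain_tau * grid_rate), 1)
        logg = np.convolve(rng_g.normal(size=n), np.ones(k) / k, mode="same")
        logg = logg / max(np.std(logg), 1e-12) * config.common_gain_sd
        gain = np.exp(logg - 0.5 * config.common_gain_sd**2)
    else:
        gain = np.ones(n)

    def base_intensity(u: GroundTruthUnit) -> np.ndarray:
        r = np.full(n, u.base_rate)
        if u.place_center is not None and np.isfinite(u.place_width):
            d2 = (x - u.place_center[0]) ** 2 + (y - u.place_center[1]) ** 2
            f = np.exp(-0.5 * d2 / u.place_width**2)
            m = float(np.mean(f))
            if m > 0:
                r = r * (f / m)
        if u.theta_kappa > 0:
            r = r * np.exp(u.theta_kappa * np.cos(phase_rad - np.radians(u.theta_mu))) / i0(u.theta_kappa)
        return r

    def opto_factor(u: GroundTruthUnit) -> np.ndarray:
        f = np.ones(n)
        use = (u.tag == "chr2_abdgc" and blue) or (u.tag == "archt_abdgc" and yellow)
        if not use or u.opto_gain == 1.0:
            return f
        for on, off in zip(laser.onsets, laser.offsets):
            i0_ = int(np.ceil((on + u.opto_latency) * grid_rate))
            i1_ = int(np.ceil(off * grid_rate))
            f[max(i0_, 0):min(i1_, n)] = u.opto_gain
        return f

    tagged = [u for u in units if u.tag in ("chr2_abdgc", "archt_abdgc")]
    inter = [u for u in units if u.cell_class == "interneuron"]
    principal = [u for u in units if u.cell_class == "principal" and u not in tagged]

    order = {u.unit_id: k for k, u in enumerate(units)}
    trains: dict = {}

    # 1) tagged abDGCs
    tagged_times = []
    for u in tagged:
        rng_u = config.rng(_K_SPIKE, order[u.unit_id])
        rate = base_intensity(u) * gain * opto_factor(u)
        times = _thin_spikes(rate, grid_rate, duration, rng_u)
        if u.tag == "chr2_abdgc" and blue:
            evoked_on = laser.onsets[rng_u.uniform(size=laser.n_events) < config.evoked_prob]
            evoked = evoked_on + u.opto_latency + np.abs(rng_u.normal(0.0, 2e-4, evoked_on.size))
            evoked = np.clip(evoked, evoked_on, evoked_on + 0.0099)
            times = np.sort(np.r_[times, evoked[evoked < duration]])
        trains[u.unit_id] = times
        tagged_times.append(times)
    all_tagged = np.sort(np.concatenate(tagged_times)) if tagged_times else np.empty(0)
    tagged_drive = _lagged_drive(all_tagged, n, grid_rate, *config.motif_lag)

    # 2) interneurons (driven by tagged spikes in the 20-40-ms lag window)
    for u in inter:
        rng_u = config.rng(_K_SPIKE, order[u.unit_id])
        rate = base_intensity(u) * gain * opto_factor(u) * (1.0 + config.motif_gain * tagged_drive)
        trains[u.unit_id] = _thin_spikes(rate, grid_rate, duration, rng_u)

    # 3) principal cells, divisively suppressed by the pooled interneuron
    #    spiking integrated over fast + slow windows; low-rate cells are
    #    under proportionally stronger inhibitory control
    inh_drive = np.zeros(n)
    if inter and (config.suppression_gain > 0 or config.suppression_fast_gain > 0):
        pooled = np.sort(np.concatenate([trains[u.unit_id] for u in inter]))
        slow = _lagged_drive(pooled, n, grid_rate, 0.0, config.suppression_window)
        fast = _lagged_drive(pooled, n, grid_rate, 0.0, config.suppression_fast_window)
        inh_drive = config.suppression_gain * slow + config.suppression_fast_gain * fast
    # normalise each cell's divisor to its baseline (laser-off) mean so
    # principal rates average base_rate in the unperturbed state; only the
    # relative dynamics of inhibition (phasic dips, disinhibition) remain
    off_mask = np.ones(n, dtype=bool)
    if laser.n_events:
        for a, b in zip(laser.onsets, laser.offsets):
            i_a = max(int(a * grid_rate), 0)
            i_b = min(int(np.ceil((b + 0.1) * grid_rate)), n)
            off_mask[i_a:i_b] = False
        if not off_mask.any():
            off_mask[:] = True
    for u in principal:
        rng_u = config.rng(_K_SPIKE, order[u.unit_id])
        c_u = np.clip((1.5 / u.base_rate) ** config.suppression_rate_exponent, 0.3, 3.0)
        divisor = 1.0 + c_u * inh_drive
        divisor = divisor / float(np.mean(divisor[off_mask]))
        rate = base_intensity(u) * gain * opto_factor(u) / divisor
        trains[u.unit_id] = _thin_spikes(rate, grid_rate, duration, rng_u)

    rows_u, rows_t = [], []
    for u in units:
        t = trains.get(u.unit_id, np.empty(0))
        rows_u.extend([u.unit_id] * t.size)
        rows_t.append(t)
    times_all = np.concatenate(rows_t) if rows_t else np.empty(0)
    df = pd.DataFrame({"unit_id": rows_u, "time_s": times_all}).sort_values(
        "time_s", kind="stable", ignore_index=True
    )
    units_df = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "region": [u.region for u in units],
            "cell_class": [u.cell_class for u in units],
            "tag": [u.tag for u in units],
        }
    ).set_index("unit_id")
    return SpikeTable(spikes=df, units=units_df)


# ----------------------------------------------------------- default units

def default_units(config: SimConfig) -> list:
    """Ground-truth population matching the recorded statistics.

    Principal cells carry log-normal base rates (median ≈ 1 Hz), Gaussian
    place fields and moderate theta locking near the descending phase;
    tagged adult-born cells are a high-rate (median ≈ 2.3 Hz), strongly
    theta-locked DG subpopulation; interneurons are fast-firing and
    spatially untuned.
    """
    rng = config.rng(_K_UNITS)
    side = config.arena_side
    units: list[GroundTruthUnit] = []

    tag = "chr2_abdgc" if config.protocol == "activation" else (
        "archt_abdgc" if config.protocol == "silencing" else "none")
    opto_gain = 1.0
    if config.protocol == "silencing":
        opto_gain = 0.05  # near-complete ArchT suppression
    mu_by_region = {"DG": 160.0, "CA3": 140.0, "CA1": -170.0}

    def pc(region, i, *, abdgc=False):
        med = 2.3 if abdgc else (1.0 if region == "DG" else 1.8)
        base = float(rng.lognormal(np.log(med), 0.5 if abdgc else 0.7))
        return GroundTruthUnit(
            unit_id=f"{'abdgc' if abdgc else region.lower()}_{i:02d}",
            region=region,
            cell_class="principal",
            tag=tag if abdgc else "none",
            base_rate=base,
            place_center=tuple(rng.uniform(0.15 * side, 0.85 * side, 2)),
            place_width=float(rng.uniform(5.0, 12.0)),
            theta_kappa=float(rng.uniform(0.8, 1.5)) if abdgc else float(rng.uniform(0.3, 0.8)),
            theta_mu=float(mu_by_region[region] + rng.normal(0.0, 25.0)),
            opto_gain=opto_gain if abdgc else 1.0,
            opto_latency=0.003 if abdgc else 0.0,
        )

    for i in range(config.n_abdgc):
        units.append(pc("DG", i, abdgc=True))
    for i in range(config.n_dg):
        units.append(pc("DG", i))
    for i in range(config.n_ca3):
        units.append(pc("CA3", i))
    for i in range(config.n_ca1):
        units.append(pc("CA1", i))
    for i in range(config.n_interneurons):
        region = ("DG", "CA3", "CA1")[i % 3]
        units.append(
            GroundTruthUnit(
                unit_id=f"int_{region.lower()}_{i:02d}",
                region=region,
                cell_class="interneuron",
                base_rate=float(rng.lognormal(np.log(12.0), 0.4)),
                theta_kappa=float(rng.uniform(0.2, 0.5)),
                theta_mu=float(rng.normal(-90.0, 30.0)),
            )
        )
    return units


def make_session(config: SimConfig, units: list | None = None) -> SyntheticSession:
    """Generate a full session (trajectory, LFP, laser, spikes) from one seed."""
    if units is None:
        units = default_units(config)
    position = simulate_trajectory(config)
    lfp, phase_truth = simulate_lfp(config)
    laser = simulate_laser(config)
    spikes = simulate_spikes(units, position, phase_truth, laser, config)
    return SyntheticSession(spikes=spikes, lfp=lfp, position=position, laser=laser,
                            truth=units, phase_truth=phase_truth, config=config)
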