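"""LFP preprocessing, theta-cycle segmentation and slow-gamma epochs.

Theta cycles are delimited trough-to-trough on the theta component of the
LFP.  A candidate cycle is accepted when (i) its bounding troughs and the
peak between them exceed (in absolute value) the amplitude envelope of the
slower-than-theta component, and (ii) the trough-to-trough duration lies in
[71, 200] ms (≈14 Hz to 5 Hz).  Phase is assigned by piecewise-linear
interpolation through the five anchors of each accepted cycle —
trough −180°, ascending zero-crossing −90°, peak 0°, descending
zero-crossing +90°, trough +180° — so the theta peak is the 0° reference.
Samples outside accepted cycles carry undefined (NaN) phase and spikes
there are excluded from phase analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .core import LfpSignal, ValidationError

__all__ = [
    "ThetaDecomposition",
    "ThetaCycles",
    "GammaEpochs",
    "downsample",
    "decompose_theta",
    "detect_cycles",
    "detect_gamma_epochs",
    "segment_theta",
    "THETA_BAND",
]

THETA_BAND = (5.0, 12.0)  # Hz
CYCLE_MIN_S = 0.071  # ~14 Hz upper frequency bound
CYCLE_MAX_S = 0.200  # 5 Hz lower frequency bound


# ---------------------------------------------------------------- downsample

def downsample(lfp: LfpSignal, target_rate: float) -> LfpSignal:
    """Anti-alias filter (order-8 Chebyshev I) and decimate to ``target_rate``.

    The decimation factor ``lfp.rate / target_rate`` must be an integer
    (e.g. 20,000 → 1,250 samples/s, factor 16).
    """
    q = lfp.rate / float(target_rate)
    if abs(q - round(q)) > 1e-9 or q < 1:
        raise ValidationError(
            f"decimation factor {q:g} is not a positive integer "
            f"({lfp.rate:g} -> {target_rate:g} samples/s)"
        )
    q = int(round(q))
    if q == 1:
        return LfpSignal(samples=lfp.samples.copy(), rate=float(target_rate), t0=lfp.t0)
    # order-8 Chebyshev type I anti-alias filter (scipy's IIR decimator),
    # applied zero-phase; the pass band is normalised to unit DC gain so
    # constant signals pass through unchanged
    sos = sps.cheby1(8, 0.05, 0.8 / q, output="sos")
    dc_gain = float(np.prod(np.sum(sos[:, :3], axis=1) / np.sum(sos[:, 3:], axis=1))) ** 2
    filtered = sps.sosfiltfilt(sos, lfp.samples) / dc_gain
    return LfpSignal(samples=filtered[::q], rate=float(target_rate), t0=lfp.t0)


# ----------------------------------------------------------- decomposition

@dataclass
class ThetaDecomposition:
    """Theta component of the LFP plus the envelope of slower activity.

    ``has_theta`` is False when no oscillatory component with dominant
    frequency in the 5–12-Hz band stands out of the sub-theta activity.
    """

    theta: np.ndarray
    low_env: np.ndarray
    rate: float
    t0: float
    has_theta: bool
    mode: str

    @property
    def n(self) -> int:
        return self.theta.size


def _butter_filtfilt(x: np.ndarray, rate: float, band, btype: str, order: int = 3) -> np.ndarray:
    sos = sps.butter(order, band, btype=btype, fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def _envelope(x: np.ndarray) -> np.ndarray:
    return np.abs(sps.hilbert(x))


def _dominant_freq(x: np.ndarray, rate: float) -> float:
    n = min(x.size, 4096)
    f, p = sps.welch(x, fs=rate, nperseg=n)
    if not np.any(p > 0):
        return 0.0
    return float(f[np.argmax(p)])


def _sift_imf(x: np.ndarray, max_iter: int = 50, sd_stop: float = 0.05):
    """One intrinsic-mode function by standard cubic-spline sifting."""
    h = x.astype(float)
    for _ in range(max_iter):
        pk, _ = sps.find_peaks(h)
        tr, _ = sps.find_peaks(-h)
        if pk.size < 2 or tr.size < 2:
            return None
        i = np.arange(h.size)
        # pad edge extrema by mirroring so splines behave at the boundaries
        pk_i = np.r_[2 * pk[0] - pk[1], pk, 2 * pk[-1] - pk[-2]]
        tr_i = np.r_[2 * tr[0] - tr[1], tr, 2 * tr[-1] - tr[-2]]
        upper = CubicSpline(pk_i, h[np.clip(pk_i, 0, h.size - 1)])(i)
        lower = CubicSpline(tr_i, h[np.clip(tr_i, 0, h.size - 1)])(i)
        mean = 0.5 * (upper + lower)
        h1 = h - mean
        denom = float(np.sum(h**2))
        if denom == 0 or float(np.sum((h - h1) ** 2)) / denom < sd_stop:
            return h1
        h = h1
    return h


def _emd(x: np.ndarray, max_imfs: int = 8):
    imfs = []
    residual = x.astype(float).copy()
    for _ in range(max_imfs):
        imf = _sift_imf(residual)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    return imfs, residual


def decompose_theta(lfp: LfpSignal, mode: str = "bandpass", env_ratio_min: float = 0.25) -> ThetaDecomposition:
    """Split the LFP into a theta (5–12 Hz) component and a sub-theta envelope.

    ``mode='bandpass'`` (default) filters the trace into the theta band and
    takes the Hilbert envelope of the <5-Hz residual activity.
    ``mode='emd'`` decomposes by cubic-spline sifting into intrinsic-mode
    functions, taking as theta the first mode whose dominant frequency lies
    in the band and as the slow component the sum of all slower modes.

    When the theta-band envelope is small relative to the sub-theta
    envelope (median ratio below ``env_ratio_min``) the result is flagged
    ``has_theta=False``.
    """
    x = lfp.samples - np.mean(lfp.samples)
    nyq = lfp.rate / 2.0
    if THETA_BAND[1] >= nyq:
        raise ValidationError(f"sampling rate {lfp.rate:g} too low for the {THETA_BAND} Hz band")

    if mode == "bandpass":
        theta = _butter_filtfilt(x, lfp.rate, THETA_BAND, "bandpass")
        low = _butter_filtfilt(x, lfp.rate, THETA_BAND[0], "lowpass")
    elif mode == "emd":
        imfs, residual = _emd(x)
        doms = [_dominant_freq(imf, lfp.rate) for imf in imfs]
        theta = np.zeros_like(x)
        got = False
        low = residual.copy()
        for imf, f0 in zip(imfs, doms):
            if not got and THETA_BAND[0] <= f0 <= THETA_BAND[1]:
                theta = imf
                got = True
            elif f0 < THETA_BAND[0]:
                low = low + imf
        if not got:
            return ThetaDecomposition(
                theta=np.zeros_like(x), low_env=_envelope(low), rate=lfp.rate,
                t0=lfp.t0, has_theta=False, mode=mode,
            )
    else:
        raise ValueError(f"unknown decomposition mode {mode!r}")

    low_env = _envelope(low)
    theta_env = _envelope(theta)
    rms = float(np.sqrt(np.mean(theta**2)))
    med_low = float(np.median(low_env))
    has_theta = rms > 0 and (med_low == 0 or float(np.median(theta_env)) >= env_ratio_min * med_low)
    return ThetaDecomposition(theta=theta, low_env=low_env, rate=lfp.rate, t0=lfp.t0,
                              has_theta=has_theta, mode=mode)


# -------------------------------------------------------------- theta cycles

@dataclass
class ThetaCycles:
    """Accepted theta cycles and the per-sample phase signal.

    ``anchors`` is an (n_cycles, 5) array of anchor times in seconds:
    (trough_start, ascending_zero, peak, descending_zero, trough_end),
    mapped to phases (−180°, −90°, 0°, +90°, +180°).  ``phase`` holds the
    interpolated phase (degrees in [−180, 180)) per LFP sample, NaN outside
    accepted cycles.
    """

    anchors: np.ndarray
    phase: np.ndarray
    rate: float
    t0: float
    n_candidates: int = 0

    _PHASES = np.array([-180.0, -90.0, 0.0, 90.0, 180.0])

    @property
    def n_cycles(self) -> int:
        return self.anchors.shape[0]

    @property
    def durations(self) -> np.ndarray:
        """Trough-to-trough durations (s) of accepted cycles."""
        if self.n_cycles == 0:
            return np.empty(0)
        return self.anchors[:, 4] - self.anchors[:, 0]

    def cycle_of(self, times: np.ndarray) -> np.ndarray:
        """Index of the accepted cycle containing each time, −1 if none."""
        times = np.asarray(times, dtype=float)
        if self.n_cycles == 0:
            return np.full(times.shape, -1, dtype=int)
        idx = np.searchsorted(self.anchors[:, 0], times, side="right") - 1
        idx = np.clip(idx, 0, self.n_cycles - 1)
        inside = (times >= self.anchors[idx, 0]) & (times < self.anchors[idx, 4])
        return np.where(inside, idx, -1)

    def phase_of(self, times: np.ndarray) -> np.ndarray:
        """Interpolated phase (deg) at arbitrary times; NaN outside cycles."""
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, np.nan)
        idx = self.cycle_of(times)
        ok = idx >= 0
        if not np.any(ok):
            return out
        a = self.anchors[idx[ok]]  # (m, 5)
        t = times[ok]
        seg = np.clip(
            np.sum(t[:, None] >= a[:, 1:4], axis=1), 0, 3
        )  # which of the 4 anchor segments
        lo = a[np.arange(a.shape[0]), seg]
        hi = a[np.arange(a.shape[0]), seg + 1]
        frac = np.where(hi > lo, (t - lo) / np.where(hi > lo, hi - lo, 1.0), 0.0)
        out[ok] = self._PHASES[seg] + 90.0 * frac
        # half-open convention: +180 wraps to -180
        out[ok] = np.where(out[ok] >= 180.0, -180.0, out[ok])
        return out

    def time_of_phase(self, cycle_idx: np.ndarray, phase_deg: np.ndarray) -> np.ndarray:
        """Inverse map: session time at ``phase_deg`` within given cycles."""
        cycle_idx = np.asarray(cycle_idx, dtype=int)
        phase = np.asarray(phase_deg, dtype=float)
        seg = np.clip(((phase + 180.0) // 90.0).astype(int), 0, 3)
        a = self.anchors[cycle_idx]
        lo = a[np.arange(a.shape[0]), seg]
        hi = a[np.arange(a.shape[0]), seg + 1]
        frac = (phase - self._PHASES[seg]) / 90.0
        return lo + frac * (hi - lo)


def detect_cycles(decomp: ThetaDecomposition) -> ThetaCycles:
    """Segment theta cycles from a decomposition and assign per-sample phase.

    Cycles run between consecutive supra-threshold troughs (|trough| above
    the sub-theta envelope) that surround a supra-threshold peak, with
    trough-to-trough duration in [71, 200] ms.
    """
    theta = decomp.theta
    n = theta.size
    phase = np.full(n, np.nan)
    if not decomp.has_theta or n < 3:
        return ThetaCycles(anchors=np.empty((0, 5)), phase=phase, rate=decomp.rate, t0=decomp.t0)

    peaks, _ = sps.find_peaks(theta)
    troughs, _ = sps.find_peaks(-theta)
    env = decomp.low_env
    supra_tr = troughs[-theta[troughs] > env[troughs]]
    supra_pk_arr = peaks[theta[peaks] > env[peaks]]

    anchors = []
    n_candidates = 0
    t_of = lambda i: decomp.t0 + i / decomp.rate
    for ts, te in zip(supra_tr[:-1], supra_tr[1:]):
        lo = np.searchsorted(supra_pk_arr, ts, side="right")
        hi = np.searchsorted(supra_pk_arr, te, side="left")
        between = supra_pk_arr[lo:hi]
        if between.size == 0:
            continue
        n_candidates += 1
        dur = (te - ts) / decomp.rate
        if not (CYCLE_MIN_S <= dur <= CYCLE_MAX_S):
            continue
        pk = int(between[np.argmax(theta[between])])
        # zero crossings on the theta component; ties resolved to the
        # earlier sample
        asc_candidates = np.flatnonzero(theta[ts:pk + 1] >= 0)
        desc_candidates = np.flatnonzero(theta[pk:te + 1] <= 0)
        if asc_candidates.size == 0 or desc_candidates.size == 0:
            continue
        asc = ts + int(asc_candidates[0])
        desc = pk + int(desc_candidates[0])
        if not (ts < asc < pk < desc < te):
            continue
        anchors.append([t_of(ts), t_of(asc), t_of(pk), t_of(desc), t_of(te)])

    anchors = np.asarray(anchors, dtype=float).reshape(-1, 5)
    cycles = ThetaCycles(anchors=anchors, phase=phase, rate=decomp.rate, t0=decomp.t0,
                         n_candidates=n_candidates)
    durs = cycles.durations
    assert np.all((durs >= CYCLE_MIN_S - 1e-12) & (durs <= CYCLE_MAX_S + 1e-12))
    if cycles.n_cycles:
        times = decomp.t0 + np.arange(n) / decomp.rate
        phase[:] = cycles.phase_of(times)
        cycles.phase = phase
    return cycles


def segment_theta(lfp: LfpSignal, mode: str = "bandpass") -> ThetaCycles:
    """Convenience: decompose then detect cycles."""
    return detect_cycles(decompose_theta(lfp, mode=mode))


# -------------------------------------------------------------- slow gamma

@dataclass
class GammaEpochs:
    """Intervals of elevated band-limited (slow-gamma) amplitude."""

    intervals: np.ndarray  # (n, 2) start/end times, s
    band: tuple
    threshold_sd: float

    @property
    def n_epochs(self) -> int:
        return self.intervals.shape[0]

    def total_duration(self) -> float:
        if self.n_epochs == 0:
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def contains(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        mask = np.zeros(times.shape, dtype=bool)
        for s, e in self.intervals:
            mask |= (times >= s) & (times < e)
        return mask


def detect_gamma_epochs(lfp: LfpSignal, band=(30.0, 55.0), threshold_sd: float = 2.0) -> GammaEpochs:
    """Epochs where the band-passed amplitude envelope exceeds
    mean + ``threshold_sd``·s.d. (default 30–55 Hz, 2 s.d.)."""
    nyq = lfp.rate / 2.0
    if band[1] >= nyq:
        raise ValidationError(f"band top {band[1]:g} Hz >= Nyquist {nyq:g} Hz")
    x = lfp.samples - np.mean(lfp.samples)
    env = _envelope(_butter_filtfilt(x, lfp.rate, band, "bandpass"))
    sd = float(np.std(env))
    if sd == 0:
        return GammaEpochs(intervals=np.empty((0, 2)), band=tuple(band), threshold_sd=threshold_sd)
    above = env > (float(np.mean(env)) + threshold_sd * sd)
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    intervals = lfp.t0 + np.column_stack([starts, ends]) / lfp.rate
    return GammaEpochs(intervals=intervals, band=tuple(band), threshold_sd=threshold_sd)
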