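"""Population-vector statistics: sparsity, silencing responses, co-firing
and dimensionality.

Population vectors are spike counts of simultaneously recorded principal
cells in ~theta-cycle-long windows (fixed 100-ms bins around laser pulses,
detected theta cycles, or 5-s epochs).  Sparsity of a vector x (ascending
order, N units) is quantified by the Gini index

    S = Σ_i (2i − N − 1) x_i / (N Σ_i x_i)

and cross-validated with the Hoyer measure

    S = (√N − Σ|x_i| / √(Σ x_i²)) / (√N − 1).

Both are scale- and permutation-invariant and grow as the same total count
concentrates in fewer units.  Laser effects are assessed within session:
per-pulse (or per-epoch) off/on sparsity values are averaged to one paired
value per session, which controls for differences in the number of
simultaneously recorded cells across days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .core import LaserEvents, SpikeTable, ValidationError
from .lfp import ThetaCycles
from .tagging import build_psth

__all__ = [
    "PopulationMatrix",
    "SparsityResult",
    "CofiringResult",
    "build_population_matrix",
    "pulse_pair_windows",
    "epoch_pair_windows",
    "theta_cycle_windows",
    "gini_sparsity",
    "hoyer_sparsity",
    "paired_sparsity_comparison",
    "silencing_response",
    "cofiring_matrix",
    "dimensionality",
    "dimensionality_sweep",
    "MIN_UNITS",
]

MIN_UNITS = 10  # co-firing/dimensionality need MORE than ten units
PULSE_WINDOW_S = 0.100
EPOCH_S = 5.0
SILENCING_BIN_S = 0.875
SILENCING_BASELINE_S = 5.0


@dataclass
class PopulationMatrix:
    """Units × windows spike-count matrix with window provenance.

    ``labels`` marks each window's laser condition: ``off``/``on`` for
    epoch or cycle windows, ``pre``/``post`` for pulse-flanking 100-ms
    windows (paired in order of appearance).
    """

    counts: np.ndarray  # (n_units, n_windows) non-negative ints
    window_spans: np.ndarray  # (n_windows, 2) start/end s, half-open
    window_kind: str  # fixed_100ms | theta_cycle | epoch | custom
    unit_ids: list
    labels: np.ndarray  # str per window
    regions: list | None = None  # per-unit region, aligned with unit_ids

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_windows(self) -> int:
        return self.counts.shape[1]

    def subset(self, mask: np.ndarray) -> "PopulationMatrix":
        """Restrict to a boolean window mask."""
        return PopulationMatrix(counts=self.counts[:, mask], window_spans=self.window_spans[mask],
                                window_kind=self.window_kind, unit_ids=self.unit_ids,
                                labels=self.labels[mask], regions=self.regions)


def build_population_matrix(spike_table: SpikeTable, windows: np.ndarray,
                            unit_ids: list | None = None, labels: np.ndarray | None = None,
                            window_kind: str = "custom") -> PopulationMatrix:
    """Count spikes per unit per half-open window [start, end)."""
    windows = np.asarray(windows, dtype=float).reshape(-1, 2)
    if unit_ids is None:
        unit_ids = spike_table.select(cell_class="principal")
    if len(unit_ids) == 0:
        raise ValidationError("empty unit selection")
    if labels is None:
        labels = np.array(["off"] * windows.shape[0])
    counts = np.empty((len(unit_ids), windows.shape[0]), dtype=int)
    for k, uid in enumerate(unit_ids):
        t = spike_table.times(uid)
        counts[k] = np.searchsorted(t, windows[:, 1]) - np.searchsorted(t, windows[:, 0])
    regions = [spike_table.units.loc[u, "region"] for u in unit_ids]
    return PopulationMatrix(counts=counts, window_spans=windows, window_kind=window_kind,
                            unit_ids=list(unit_ids), labels=np.asarray(labels),
                            regions=regions)


# ------------------------------------------------------- window constructors

def pulse_pair_windows(laser: LaserEvents, width: float = PULSE_WINDOW_S):
    """100-ms windows flanking each pulse onset: [t−0.1, t) and [t, t+0.1)."""
    spans, labels = [], []
    for on in laser.onsets:
        spans.append((on - width, on))
        labels.append("pre")
        spans.append((on, on + width))
        labels.append("post")
    return np.asarray(spans, dtype=float).reshape(-1, 2), np.asarray(labels)


def epoch_pair_windows(laser: LaserEvents, epoch: float = EPOCH_S,
                       width: float = PULSE_WINDOW_S):
    """Theta-cycle-long (100-ms) windows tiling the 5-s epochs immediately
    before vs during each long pulse.

    Sparsity is always estimated on ~100-ms population vectors; the 5-s
    epochs only delimit the laser-off/laser-on periods being compared.
    """
    n_sub = int(round(epoch / width))
    spans, labels = [], []
    for on in laser.onsets:
        for k in range(n_sub):
            spans.append((on - epoch + k * width, on - epoch + (k + 1) * width))
            labels.append("off")
        for k in range(n_sub):
            spans.append((on + k * width, on + (k + 1) * width))
            labels.append("on")
    return np.asarray(spans, dtype=float).reshape(-1, 2), np.asarray(labels)


def theta_cycle_windows(cycles: ThetaCycles, laser: LaserEvents | None = None):
    """Trough-to-trough spans of accepted cycles, labelled off/on by
    whether the cycle midpoint falls inside a laser pulse."""
    spans = cycles.anchors[:, [0, 4]].copy()
    labels = np.array(["off"] * spans.shape[0], dtype=object)
    if laser is not None and laser.n_events:
        mid = spans.mean(axis=1)
        on = np.zeros(mid.size, dtype=bool)
        for a, b in zip(laser.onsets, laser.offsets):
            on |= (mid >= a) & (mid < b)
        labels[on] = "on"
    return spans, labels.astype(str)


# ----------------------------------------------------------------- sparsity

def gini_sparsity(x: np.ndarray) -> float:
    """Gini index of a non-negative population vector (NaN if all-zero).

    Ranges from 0 (all units equal) to (N−1)/N (all spikes in one unit).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    total = x.sum()
    if total <= 0 or n == 0:
        return np.nan
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * total))


def hoyer_sparsity(x: np.ndarray) -> float:
    """Hoyer sparseness in [0, 1] (NaN if all-zero or N < 2)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    ss = float(np.sum(x**2))
    if ss <= 0 or n < 2:
        return np.nan
    return float((np.sqrt(n) - np.sum(np.abs(x)) / np.sqrt(ss)) / (np.sqrt(n) - 1.0))


@dataclass
class SparsityResult:
    """Per-window sparsity plus the session-level paired means."""

    per_window_gini: np.ndarray
    per_window_hoyer: np.ndarray
    labels: np.ndarray
    mean_gini: dict  # label -> mean over valid paired windows
    mean_hoyer: dict
    n_pairs: int
    excluded_fraction: float  # pairs dropped because a window was all-zero


def paired_sparsity_comparison(matrix: PopulationMatrix, mode: str = "pulse_100ms") -> SparsityResult:
    """Within-session paired sparsity: condition A vs B, averaged over pairs.

    ``mode='pulse_100ms'`` pairs consecutive ``pre``/``post`` 100-ms windows
    around 5-ms pulses; ``mode='epoch_5s'`` pairs ``off``/``on`` 5-s epochs
    around 30-s pulses.  Pairs in which either window is all-zero are
    excluded (their fraction is reported).
    """
    if mode == "pulse_100ms":
        a_lab, b_lab = "pre", "post"
    elif mode == "epoch_5s":
        a_lab, b_lab = "off", "on"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    gini = np.array([gini_sparsity(matrix.counts[:, j]) for j in range(matrix.n_windows)])
    hoyer = np.array([hoyer_sparsity(matrix.counts[:, j]) for j in range(matrix.n_windows)])
    ia = np.flatnonzero(matrix.labels == a_lab)
    ib = np.flatnonzero(matrix.labels == b_lab)
    if ia.size == 0 or ib.size == 0:
        raise ValidationError("no valid labelled window pairs")
    if mode == "pulse_100ms":
        # strict pulse-wise pairing of the flanking windows
        if ia.size != ib.size:
            raise ValidationError("unpaired pre/post windows")
        valid = np.isfinite(gini[ia]) & np.isfinite(gini[ib])
        if not np.any(valid):
            raise ValidationError("all window pairs contain an all-zero vector")
        va, vb = ia[valid], ib[valid]
        n_pairs = int(valid.sum())
        excluded = float(np.mean(~valid))
    else:
        # epoch mode: average the ~100-ms window sparsities over each
        # condition; all-zero windows are excluded per condition
        va = ia[np.isfinite(gini[ia])]
        vb = ib[np.isfinite(gini[ib])]
        if va.size == 0 or vb.size == 0:
            raise ValidationError("a condition contains only all-zero vectors")
        n_pairs = min(va.size, vb.size)
        excluded = float((ia.size - va.size + ib.size - vb.size) / (ia.size + ib.size))
    mean_g = {a_lab: float(np.mean(gini[va])), b_lab: float(np.mean(gini[vb]))}
    mean_h = {a_lab: float(np.mean(hoyer[va])), b_lab: float(np.mean(hoyer[vb]))}
    return SparsityResult(per_window_gini=gini, per_window_hoyer=hoyer, labels=matrix.labels,
                          mean_gini=mean_g, mean_hoyer=mean_h, n_pairs=n_pairs,
                          excluded_fraction=excluded)


# -------------------------------------------------------- silencing response

def silencing_response(spike_times: np.ndarray, events: LaserEvents,
                       bin_width: float = SILENCING_BIN_S,
                       baseline: float = SILENCING_BASELINE_S) -> float:
    """Summed Z-scored spike count during 30-s light delivery.

    Counts are binned at 875 ms across laser-on periods (summed over
    pulses), Z-scored against same-width bins from the 5-s pre-onset
    baseline, and summed over the laser-on bins.  Positive values indicate
    disinhibition (rate increase) during silencing.
    """
    if events.n_events < 1:
        raise ValidationError("silencing response requires at least one pulse")
    on_dur = float(np.min(events.durations))
    n_on = int(on_dur / bin_width)
    n_base = int(baseline / bin_width)
    if n_on < 1 or n_base < 2:
        raise ValidationError("pulse or baseline too short for the requested bin width")
    psth = build_psth(np.asarray(spike_times, dtype=float), events,
                      (0.0, n_on * bin_width), bin_width, (-n_base * bin_width, 0.0))
    if psth.z is None:
        warnings.warn("zero baseline variance; summed Z undefined")
        return np.nan
    return float(np.sum(psth.z))


def on_off_rates(spike_times: np.ndarray, events: LaserEvents, duration: float):
    """Absolute rates: spikes in laser-on vs laser-off periods over their
    respective total durations."""
    t = np.asarray(spike_times, dtype=float)
    on_mask = np.zeros(t.size, dtype=bool)
    for a, b in zip(events.onsets, events.offsets):
        on_mask |= (t >= a) & (t < b)
    t_on = float(np.sum(events.durations))
    t_off = duration - t_on
    return (float(np.sum(on_mask)) / t_on if t_on > 0 else np.nan,
            float(np.sum(~on_mask)) / t_off if t_off > 0 else np.nan)


def smooth3(x: np.ndarray) -> np.ndarray:
    """Three-point moving average (group-display smoothing)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return x.copy()
    out = x.copy()
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    return out


# ------------------------------------------------------------------ co-firing

@dataclass
class CofiringResult:
    """Pairwise Pearson correlations of per-cycle spike counts."""

    pair_r: np.ndarray  # one r per valid cross-region pair
    pair_index: list  # (unit_a, unit_b)
    mean_r: float
    n_excluded_pairs: int  # pairs skipped for zero-variance counts


def cofiring_matrix(matrix: PopulationMatrix, region_a: str = "CA3",
                    region_b: str = "CA1") -> CofiringResult:
    """Co-firing of cross-region cell pairs over theta-cycle count vectors."""
    if matrix.n_units <= MIN_UNITS:
        raise ValidationError(f"co-firing requires more than {MIN_UNITS} units")
    if matrix.n_windows < 2:
        raise ValidationError("co-firing requires at least 2 windows")
    if matrix.regions is None:
        raise ValidationError("population matrix lacks region metadata")
    ia = [k for k, r in enumerate(matrix.regions) if r == region_a]
    ib = [k for k, r in enumerate(matrix.regions) if r == region_b]
    x = matrix.counts.astype(float)
    sd = x.std(axis=1)
    xc = x - x.mean(axis=1, keepdims=True)
    rs, pairs, excluded = [], [], 0
    for a in ia:
        for b in ib:
            if sd[a] == 0 or sd[b] == 0:
                excluded += 1
                continue
            r = float(np.dot(xc[a], xc[b]) / (matrix.n_windows * sd[a] * sd[b]))
            rs.append(r)
            pairs.append((matrix.unit_ids[a], matrix.unit_ids[b]))
    rs = np.asarray(rs)
    mean_r = float(np.mean(rs)) if rs.size else np.nan
    return CofiringResult(pair_r=rs, pair_index=pairs, mean_r=mean_r,
                          n_excluded_pairs=excluded)


# -------------------------------------------------------------- dimensionality

def dimensionality(matrix: PopulationMatrix, variance_target: float = 0.80):
    """Components needed to explain ``variance_target`` of the variance.

    PCA is applied to the mean-centred theta-paced activity matrix
    (windows as observations, units as variables; no scaling to unit
    variance).  Returns ``(n_components, score)`` with
    score = n_components / n_units.
    """
    if matrix.n_units <= MIN_UNITS:
        raise ValidationError(f"dimensionality requires more than {MIN_UNITS} units")
    x = matrix.counts.T.astype(float)  # windows × units
    if np.allclose(x.var(axis=0), 0.0):
        warnings.warn("zero-variance activity matrix; dimensionality undefined")
        return np.nan, np.nan
    pca = PCA(n_components=min(matrix.n_units, matrix.n_windows))
    pca.fit(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    return n, n / matrix.n_units


def dimensionality_sweep(matrix: PopulationMatrix,
                         targets=(0.70, 0.75, 0.80, 0.85, 0.90)) -> dict:
    """Dimensionality score at several explained-variance targets."""
    return {t: dimensionality(matrix, variance_target=t) for t in targets}


def compare_dimensionality(matrix_off: PopulationMatrix, matrix_on: PopulationMatrix,
                           variance_target: float = 0.80):
    """Paired off/on dimensionality scores; unit sets must be identical."""
    if list(matrix_off.unit_ids) != list(matrix_on.unit_ids):
        raise ValidationError("off/on matrices must contain the same units")
    _, s_off = dimensionality(matrix_off, variance_target)
    _, s_on = dimensionality(matrix_on, variance_target)
    return s_off, s_on


# --------------------------------------------- session-level laser effects

def _valid_pairs(spans: np.ndarray, labels: np.ndarray, duration: float,
                 per_pair: int = 2):
    """Drop whole pulse groups whose windows leave the session."""
    groups = spans.reshape(-1, per_pair, 2)
    ok = (groups[:, :, 0] >= 0).all(axis=1) & (groups[:, :, 1] <= duration).all(axis=1)
    keep = np.repeat(ok, per_pair)
    return spans[keep], labels[keep]


def activation_sparsity_effect(spike_table: SpikeTable, laser: LaserEvents,
                               duration: float) -> float:
    """Session-level change in CA population Gini sparsity around 5-ms pulses.

    Returns mean(post) − mean(pre) over the 100-ms windows flanking every
    pulse, using the simultaneously recorded CA3/CA1 principal cells.
    """
    spans, labels = pulse_pair_windows(laser)
    spans, labels = _valid_pairs(spans, labels, duration)
    ca = spike_table.select(region=("CA3", "CA1"), cell_class="principal")
    mat = build_population_matrix(spike_table, spans, unit_ids=ca, labels=labels,
                                  window_kind="fixed_100ms")
    res = paired_sparsity_comparison(mat, mode="pulse_100ms")
    return res.mean_gini["post"] - res.mean_gini["pre"]


def silencing_effects(spike_table: SpikeTable, laser: LaserEvents, cycles,
                      duration: float, rng: np.random.Generator | None = None) -> dict:
    """Session-level effects of 30-s silencing pulses.

    Returns the laser-on minus laser-off differences in CA population Gini
    sparsity (100-ms vectors tiling the 5-s epochs around onsets), the mean
    principal-cell summed Z during light, the mean CA3–CA1 theta co-firing,
    and the dimensionality score — the on/off theta-cycle matrices are
    subsampled to matched window counts to avoid the sample-eigenvalue bias
    of unequal matrix widths.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ca = spike_table.select(region=("CA3", "CA1"), cell_class="principal")
    pcs = spike_table.select(cell_class="principal")

    spans, labels = epoch_pair_windows(laser)
    spans, labels = _valid_pairs(spans, labels, duration,
                                 per_pair=2 * int(round(EPOCH_S / PULSE_WINDOW_S)))
    mat = build_population_matrix(spike_table, spans, unit_ids=ca, labels=labels,
                                  window_kind="fixed_100ms")
    res = paired_sparsity_comparison(mat, mode="epoch_5s")
    d_gini = res.mean_gini["on"] - res.mean_gini["off"]

    z = [silencing_response(spike_table.times(u), laser) for u in pcs]
    summed_z = float(np.nanmean(z))

    cyc_spans, cyc_labels = theta_cycle_windows(cycles, laser)
    tmat = build_population_matrix(spike_table, cyc_spans, unit_ids=ca,
                                   labels=cyc_labels, window_kind="theta_cycle")
    i_off = np.flatnonzero(tmat.labels == "off")
    i_on = np.flatnonzero(tmat.labels == "on")
    k = min(i_off.size, i_on.size)
    m_off = np.zeros(tmat.n_windows, dtype=bool)
    m_off[rng.choice(i_off, k, replace=False)] = True
    m_on = np.zeros(tmat.n_windows, dtype=bool)
    m_on[rng.choice(i_on, k, replace=False)] = True
    d_cofire = (cofiring_matrix(tmat.subset(m_on)).mean_r
                - cofiring_matrix(tmat.subset(m_off)).mean_r)
    s_off, s_on = compare_dimensionality(tmat.subset(m_off), tmat.subset(m_on))
    return {"d_gini": float(d_gini), "summed_z": summed_z,
            "d_cofire": float(d_cofire), "d_dim_score": float(s_on - s_off)}
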