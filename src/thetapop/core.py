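"""Shared session containers.

All analyses operate on three primitives: a table of sorted spike times with
per-unit metadata (:class:`SpikeTable`), a uniformly sampled single-channel
field potential (:class:`LfpSignal`), and a table of laser pulses
(:class:`LaserEvents`).  Times are seconds on a common session clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "CellClass",
    "TagStatus",
    "SpikeTable",
    "LfpSignal",
    "LaserEvents",
    "ValidationError",
]

#: Recognised hippocampal subfields.
Region = ("DG", "CA3", "CA1")
#: Putative cell classes from waveform/rate curation (consumed, not derived).
CellClass = ("principal", "interneuron")
#: Optogenetic construct carried by a unit.
TagStatus = ("none", "chr2_abdgc", "archt_abdgc")


class ValidationError(ValueError):
    """A session component failed a structural check (raised with context)."""


@dataclass
class SpikeTable:
    """All sorted spikes of a session, keyed by unit.

    Parameters
    ----------
    spikes
        DataFrame with columns ``unit_id`` and ``time_s``, sorted by time.
    units
        Per-unit metadata indexed by ``unit_id`` with columns ``region``,
        ``cell_class`` and ``tag``.
    """

    spikes: pd.DataFrame
    units: pd.DataFrame

    def __post_init__(self) -> None:
        t = np.asarray(self.spikes["time_s"], dtype=float)
        if t.size and np.any(np.diff(t) < 0):
            bad = int(np.flatnonzero(np.diff(t) < 0)[0]) + 1
            raise ValidationError(f"spike times not sorted (first offending row {bad})")
        if t.size and not np.all(np.isfinite(t)):
            raise ValidationError("spike times contain non-finite values")
        for col in ("region", "cell_class", "tag"):
            if col not in self.units.columns:
                raise ValidationError(f"unit table missing column {col!r}")

    @property
    def unit_ids(self) -> list:
        return list(self.units.index)

    def times(self, unit_id) -> np.ndarray:
        """Sorted spike times (s) of one unit."""
        sel = self.spikes.loc[self.spikes["unit_id"] == unit_id, "time_s"]
        return np.asarray(sel, dtype=float)

    def select(self, region=None, cell_class=None, tag=None) -> list:
        """Unit ids matching the given metadata filters (None = any)."""
        m = np.ones(len(self.units), dtype=bool)
        if region is not None:
            regions = (region,) if isinstance(region, str) else tuple(region)
            m &= self.units["region"].isin(regions).to_numpy()
        if cell_class is not None:
            m &= (self.units["cell_class"] == cell_class).to_numpy()
        if tag is not None:
            tags = (tag,) if isinstance(tag, str) else tuple(tag)
            m &= self.units["tag"].isin(tags).to_numpy()
        return list(self.units.index[m])

    def mean_rate(self, unit_id, duration: float) -> float:
        return self.times(unit_id).size / float(duration)

    def n_spikes(self) -> int:
        return len(self.spikes)


@dataclass
class LfpSignal:
    """Uniformly sampled single-channel LFP.

    ``samples`` are microvolts; ``rate`` is samples/s; ``t0`` is the session
    time of the first sample.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("LFP must be a 1-D trace")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("LFP contains non-finite samples")
        if self.rate <= 0:
            raise ValidationError("LFP sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate


@dataclass
class LaserEvents:
    """Laser pulse table: onsets (s), durations (s) and wavelength (nm).

    The 473-nm protocol uses 5-ms pulses (activation / opto-tagging); the
    561-nm protocol uses 30-s pulses (silencing).
    """

    onsets: np.ndarray
    durations: np.ndarray
    wavelength_nm: float
    protocol: str = "activation"  # "activation" (ms pulses) | "silencing" (30-s)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.onsets.shape != self.durations.shape:
            raise ValidationError("laser onsets/durations length mismatch")
        if self.onsets.size and np.any(np.diff(self.onsets) < 0):
            raise ValidationError("laser onsets not sorted")

    @property
    def n_events(self) -> int:
        return self.onsets.size

    @property
    def offsets(self) -> np.ndarray:
        return self.onsets + self.durations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.onsets,
                "duration_s": self.durations,
                "wavelength_nm": np.full(self.n_events, self.wavelength_nm),
            }
        )

    def mask_times(self, times: np.ndarray, pad_s: float = 0.1) -> np.ndarray:
        """Boolean mask of ``times`` falling OUTSIDE every pulse (+ ``pad_s``).

        Used to restrict analyses declared laser-off: spikes within
        [onset, onset + duration + pad] are masked out.
        """
        times = np.asarray(times, dtype=float)
        keep = np.ones(times.size, dtype=bool)
        for on, off in zip(self.onsets, self.offsets):
            keep &= ~((times >= on) & (times < off + pad_s))
        return keep


def empty_spike_table(units: pd.DataFrame | None = None) -> SpikeTable:
    """A SpikeTable with zero spike rows (degenerate sessions, tests)."""
    if units is None:
        units = pd.DataFrame(columns=["region", "cell_class", "tag"]).rename_axis("unit_id")
    spikes = pd.DataFrame({"unit_id": pd.Series(dtype=object), "time_s": pd.Series(dtype=float)})
    return SpikeTable(spikes=spikes, units=units)
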