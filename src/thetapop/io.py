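"""Readers and writers for the on-disk session format.

A session directory contains:

* ``spikes.tsv`` — unit_id, time_s (seconds, sorted by time);
* ``units.tsv`` — unit_id, region, cell_class, tag;
* ``lfp.bin`` — little-endian signed 16-bit samples, with sidecar
  ``lfp.json`` (sampling_rate_hz, scale_uv_per_lsb, t0_s, n_samples);
* ``position.tsv`` — time_s, x_cm, y_cm;
* ``laser.tsv`` — onset_s, duration_s, wavelength_nm;
* ``session.json`` — configuration echo including the generator seed.

Loading validates structure (sorted times, finite values, binary length
versus sidecar, time-base alignment) and returns a :class:`SessionBundle`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import LaserEvents, LfpSignal, SpikeTable, ValidationError
from .synth import SimConfig, SyntheticSession

__all__ = ["SessionBundle", "write_session", "read_session"]

_FLOAT_FMT = "%.12f"  # sub-ns precision on a session clock


@dataclass
class SessionBundle:
    """A validated on-disk session, parsed into analysis containers."""

    path: Path
    spikes: SpikeTable
    lfp: LfpSignal
    position: pd.DataFrame
    laser: LaserEvents
    meta: dict
    warnings: list


def write_session(session: SyntheticSession, out_dir) -> Path:
    """Write a generated session in the exchange format (round-trips
    losslessly through :func:`read_session` up to int16 LFP quantisation)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    session.spikes.spikes.to_csv(out / "spikes.tsv", sep="\t", index=False,
                                 float_format=_FLOAT_FMT)
    session.spikes.units.reset_index().to_csv(out / "units.tsv", sep="\t", index=False)
    session.position.to_csv(out / "position.tsv", sep="\t", index=False,
                            float_format=_FLOAT_FMT)
    session.laser.to_frame().to_csv(out / "laser.tsv", sep="\t", index=False,
                                    float_format=_FLOAT_FMT)

    x = session.lfp.samples
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    scale = peak / 32000.0 if peak > 0 else 1.0
    (out / "lfp.bin").write_bytes(
        np.round(x / scale).astype("<i2").tobytes()
    )
    sidecar = {
        "sampling_rate_hz": session.lfp.rate,
        "scale_uv_per_lsb": scale,
        "t0_s": session.lfp.t0,
        "n_samples": int(x.size),
    }
    (out / "lfp.json").write_text(json.dumps(sidecar, indent=1))

    meta = {
        "config": dataclasses.asdict(session.config),
        "rng_seed": session.config.rng_seed,
        "protocol": session.laser.protocol,
        "n_units": len(session.spikes.unit_ids),
    }
    (out / "session.json").write_text(json.dumps(meta, indent=1, default=str))
    return out


def _require(path: Path) -> Path:
    if not path.exists():
        raise ValidationError(f"missing session file: {path}")
    return path


def read_session(session_dir) -> SessionBundle:
    """Load and validate a session directory."""
    d = Path(session_dir)
    warn: list[str] = []

    spikes_df = pd.read_csv(_require(d / "spikes.tsv"), sep="\t")
    units_df = pd.read_csv(_require(d / "units.tsv"), sep="\t").set_index("unit_id")
    if spikes_df["time_s"].isna().any():
        raise ValidationError("spikes.tsv contains NaN times")
    spikes = SpikeTable(spikes=spikes_df, units=units_df)  # re-checks ordering

    sidecar = json.loads(_require(d / "lfp.json").read_text())
    raw = np.frombuffer(_require(d / "lfp.bin").read_bytes(), dtype="<i2")
    if raw.size != sidecar["n_samples"]:
        raise ValidationError(
            f"lfp.bin has {raw.size} samples but lfp.json declares {sidecar['n_samples']}"
        )
    lfp = LfpSignal(samples=raw.astype(float) * sidecar["scale_uv_per_lsb"],
                    rate=float(sidecar["sampling_rate_hz"]), t0=float(sidecar["t0_s"]))

    position = pd.read_csv(_require(d / "position.tsv"), sep="\t")
    if position.isna().any().any():
        raise ValidationError("position.tsv contains NaN values")

    laser_df = pd.read_csv(_require(d / "laser.tsv"), sep="\t")
    meta = json.loads(_require(d / "session.json").read_text())
    laser = LaserEvents(onsets=laser_df["onset_s"].to_numpy(),
                        durations=laser_df["duration_s"].to_numpy(),
                        wavelength_nm=float(laser_df["wavelength_nm"].iloc[0])
                        if len(laser_df) else 0.0,
                        protocol=meta.get("protocol", "none"))

    # time-base alignment: all components must share one clock
    duration = meta.get("config", {}).get("duration")
    if duration is not None:
        if abs(lfp.duration - float(duration)) > 1e-3 + 1.0 / lfp.rate:
            raise ValidationError(
                f"LFP spans {lfp.duration:.4f} s but session declares {duration} s"
            )
        if len(position) and position["time_s"].iloc[-1] > float(duration) + 1e-3:
            raise ValidationError("position track extends past the declared session end")
        t = spikes.spikes["time_s"]
        if len(t) and (t.iloc[0] < -1e-3 or t.iloc[-1] > float(duration) + 1e-3):
            raise ValidationError("spike times fall outside the declared session span")

    return SessionBundle(path=d, spikes=spikes, lfp=lfp, position=position,
                         laser=laser, meta=meta, warnings=warn)
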