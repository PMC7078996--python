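"""File formats: spike-event tables, session directories, raw traces, reports.

All structured results are JSON; series are delimited text.  Spike-event
tables are CSV with header ``sweep,time_s[,amplitude]``; sweeps are 0-based
in data files and converted to the 1-based convention only in human-facing
reports (see :func:`sweeps_to_report` / :func:`sweeps_from_report`).
Raw traces are stored as 32-bit little-endian floats next to a JSON header.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (ConfigurationError, DrugEffectSpec, EjectionSchedule,
                        RawTrace, SimulatedSession, SweepStructure, UnitSpec)

__all__ = [
    "FormatError",
    "read_spike_events",
    "write_spike_events",
    "save_session",
    "load_session",
    "write_trace",
    "read_trace",
    "sweeps_to_report",
    "sweeps_from_report",
    "write_json",
    "read_json",
]


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


def sweeps_to_report(sweep_0based):
    """Convert internal 0-based sweep indices to the 1-based report style."""
    return np.asarray(sweep_0based) + 1


def sweeps_from_report(sweep_1based):
    """Convert 1-based report sweep numbers to internal 0-based indices."""
    return np.asarray(sweep_1based) - 1


def write_spike_events(spikes: pd.DataFrame, path) -> None:
    cols = ["sweep", "time_s"] + (["amplitude"] if "amplitude" in spikes else [])
    spikes[cols].to_csv(path, index=False, float_format="%.7g")


def read_spike_events(path, sweep_s: float = 1.0) -> pd.DataFrame:
    """Read and validate a spike-event table.

    Rows must be numeric with ``0 <= time_s < sweep_s`` and integer sweep
    indices >= 0; violations raise :class:`FormatError` naming the first
    offending line (1-based, header is line 1).  The result is sorted by
    (sweep, time).  An empty-but-headered file yields an empty table.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    required = ["sweep", "time_s"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        out = pd.DataFrame({"sweep": np.array([], dtype=np.int64),
                            "time_s": np.array([], dtype=float)})
        if "amplitude" in df.columns:
            out["amplitude"] = np.array([], dtype=float)
        return out

    def _numeric(col):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
        missing = np.flatnonzero(df[col].isna().to_numpy())
        first_bad = min([*bad, *missing], default=None)
        if first_bad is not None:
            raise FormatError(f"{path}: line {first_bad + 2}: "
                              f"malformed value in column {col!r}")
        return vals.to_numpy()

    sweep = _numeric("sweep")
    time_s = _numeric("time_s")
    if np.any(sweep != np.round(sweep)) or np.any(sweep < 0):
        line = int(np.flatnonzero((sweep != np.round(sweep)) | (sweep < 0))[0]) + 2
        raise FormatError(f"{path}: line {line}: sweep must be a non-negative integer")
    bad_t = (time_s < 0) | (time_s >= sweep_s)
    if np.any(bad_t):
        line = int(np.flatnonzero(bad_t)[0]) + 2
        raise FormatError(f"{path}: line {line}: time_s outside [0, {sweep_s:g})")
    out = pd.DataFrame({"sweep": sweep.astype(np.int64), "time_s": time_s})
    if "amplitude" in df.columns:
        out["amplitude"] = _numeric("amplitude")
    return out.sort_values(["sweep", "time_s"], kind="mergesort").reset_index(drop=True)


# --------------------------------------------------------------------------
# sessions
# --------------------------------------------------------------------------

_SPIKES_FILE = "spikes.csv"
_GAINS_FILE = "gain_truth.csv"
_META_FILE = "session.json"


def save_session(session: SimulatedSession, directory) -> None:
    """Write a session as a directory: spike table, gain truth, JSON sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_spike_events(session.spikes, d / _SPIKES_FILE)
    session.gain_truth.to_csv(d / _GAINS_FILE, index=False, float_format="%.9g")
    meta = {
        "unit": session.unit.to_dict(),
        "schedules": [s.to_dict() for s in session.schedules],
        "effects": [e.to_dict() for e in session.effects],
        "seed": session.seed,
        "n_sweeps": session.n_sweeps,
        "sweep_structure": {"sweep_s": session.sweep.sweep_s,
                            "tone_on_s": session.sweep.tone_on_s,
                            "tone_off_s": session.sweep.tone_off_s},
    }
    write_json(meta, d / _META_FILE)


def load_session(directory) -> SimulatedSession:
    d = Path(directory)
    meta = read_json(d / _META_FILE)
    sweep = SweepStructure(**meta["sweep_structure"])
    spikes = read_spike_events(d / _SPIKES_FILE, sweep_s=sweep.sweep_s)
    gains = pd.read_csv(d / _GAINS_FILE)
    return SimulatedSession(
        spikes=spikes, gain_truth=gains,
        unit=UnitSpec.from_dict(meta["unit"]),
        schedules=[EjectionSchedule.from_dict(s) for s in meta["schedules"]],
        effects=[DrugEffectSpec.from_dict(e) for e in meta["effects"]],
        seed=int(meta["seed"]), sweep=sweep)


# --------------------------------------------------------------------------
# raw traces
# --------------------------------------------------------------------------


def write_trace(trace: RawTrace, directory, stem: str = "trace") -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    samples = np.asarray(trace.samples, dtype="<f4")
    samples.tofile(d / f"{stem}.bin")
    header = {"fs_hz": trace.fs_hz, "n_samples": int(len(samples)),
              "dtype": "float32-le", "sweep_s": trace.sweep_s}
    write_json(header, d / f"{stem}.json")
    if trace.truth_spikes is not None:
        write_spike_events(trace.truth_spikes, d / f"{stem}_truth.csv")


def read_trace(directory, stem: str = "trace") -> RawTrace:
    d = Path(directory)
    header = read_json(d / f"{stem}.json")
    samples = np.fromfile(d / f"{stem}.bin", dtype="<f4")
    if len(samples) != header["n_samples"]:
        raise FormatError(f"{d / (stem + '.bin')}: expected "
                          f"{header['n_samples']} samples, found {len(samples)}")
    truth = None
    truth_path = d / f"{stem}_truth.csv"
    if truth_path.exists():
        truth = read_spike_events(truth_path, sweep_s=header.get("sweep_s", 1.0))
    return RawTrace(samples=samples, fs_hz=header["fs_hz"], truth_spikes=truth,
                    sweep_s=header.get("sweep_s", 1.0))


# --------------------------------------------------------------------------
# JSON helpers
# --------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
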