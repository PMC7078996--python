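"""Threshold spike detection and per-sweep spike-shape measurements.

Spikes are detected on the absolute deviation of the voltage trace from its
median: a rising threshold crossing starts an event, which is aligned to
the absolute extremum within 1 ms of the crossing; events closer than the
lockout are suppressed greedily.  The default threshold follows the rule of
never being less than double the peak-to-peak amplitude of the background
noise, with the background peak-to-peak operationalised as the central
99.9% span of a Gaussian (2 x 3.29 robust SDs, from the median absolute
deviation) — a bounded, estimator-stable surrogate for an oscilloscope-eye
measure.

Per 1-s sweep the mean spike waveform is computed and summarised by its
peak-to-peak amplitude and the width of the dominant lobe at half its
height above the pre-spike baseline, with sub-sample interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal  # noqa: F401  (optional band-pass, see below)

from .stats import epoch_composite_decision
from .synthetic import ConfigurationError, RawTrace, _enforce_refractory

__all__ = [
    "DetectionConfig",
    "default_threshold",
    "detect_spikes",
    "sweep_mean_waveform",
    "shape_metrics",
    "compute_shape_series",
    "shape_change_test",
]

#: Central span of a Gaussian containing 99.9% of the mass, in SDs per side.
_GAUSS_999_SPAN = 3.29
_MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class DetectionConfig:
    """Detection threshold (trace units) and waveform excerpt geometry."""

    threshold: float
    lockout_ms: float = 1.0
    window_pre_ms: float = 0.4
    window_post_ms: float = 0.8
    align_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError("threshold must be > 0")
        if self.lockout_ms <= 0:
            raise ConfigurationError("lockout must be > 0")


def default_threshold(trace_segment: np.ndarray) -> float:
    """Detection threshold from a quiet (spike-free) trace segment.

    Returns 2 x the robust background peak-to-peak amplitude, where the
    background peak-to-peak is 2 x 3.29 robust SDs (median absolute
    deviation scaled to SD) — i.e. 13.16 sigma for Gaussian noise.
    """
    x = np.asarray(trace_segment, dtype=float)
    if x.size < 8:
        raise ConfigurationError("segment too short for threshold estimation")
    sd = _MAD_TO_SD * float(np.median(np.abs(x - np.median(x))))
    if sd <= 0:
        raise ConfigurationError("flat segment: cannot estimate noise level")
    return 2.0 * (2.0 * _GAUSS_999_SPAN * sd)


def detect_spikes(trace: RawTrace, config: DetectionConfig) -> pd.DataFrame:
    """Detect spikes by threshold crossing on the absolute trace deviation.

    Events are placed at the absolute extremum within ``align_ms`` after the
    rising crossing and reported as (sweep, time within sweep, signed
    amplitude at the extremum relative to the trace median).
    """
    x = np.asarray(trace.samples, dtype=float)
    med = float(np.median(x))
    dev = np.abs(x - med)
    above = dev >= config.threshold
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        rising = np.concatenate([[0], rising])
    n_align = max(int(round(config.align_ms / 1000.0 * trace.fs_hz)), 1)
    idx = np.empty(len(rising), dtype=np.int64)
    for i, r in enumerate(rising):
        seg = dev[r:r + n_align]
        idx[i] = r + int(np.argmax(seg))
    if len(idx):
        idx = np.unique(idx)
    lockout_s = config.lockout_ms / 1000.0
    t_abs = idx / trace.fs_hz
    _, t_abs = _enforce_refractory(np.zeros(len(t_abs), dtype=int), t_abs, lockout_s)
    idx = np.round(t_abs * trace.fs_hz).astype(np.int64)
    sw = (t_abs // trace.sweep_s).astype(np.int64)
    t_in = t_abs - sw * trace.sweep_s
    return pd.DataFrame({"sweep": sw, "time_s": t_in,
                         "amplitude": x[idx] - med})


def _excerpt_bounds(config: DetectionConfig, fs_hz: float):
    pre = int(round(config.window_pre_ms / 1000.0 * fs_hz))
    post = int(round(config.window_post_ms / 1000.0 * fs_hz))
    return pre, max(post, 1)


def sweep_mean_waveform(trace: RawTrace, events: pd.DataFrame, sweep_index: int,
                        config: DetectionConfig) -> np.ndarray | None:
    """Pointwise mean of aligned waveform excerpts in one sweep.

    Returns ``None`` (a missing value, not an error) for sweeps without
    events.  Events too close to the trace edges are skipped.
    """
    ev = events[events["sweep"] == sweep_index]
    if len(ev) == 0:
        return None
    pre, post = _excerpt_bounds(config, trace.fs_hz)
    x = np.asarray(trace.samples, dtype=float)
    centers = np.round((ev["sweep"].to_numpy() * trace.sweep_s
                        + ev["time_s"].to_numpy()) * trace.fs_hz).astype(np.int64)
    keep = (centers - pre >= 0) & (centers + post <= len(x))
    centers = centers[keep]
    if len(centers) == 0:
        return None
    offsets = np.arange(-pre, post)
    return x[centers[:, None] + offsets[None, :]].mean(axis=0)


def shape_metrics(waveform: np.ndarray, fs_hz: float):
    """(peak-to-peak amplitude, half-amplitude width in ms) of a waveform.

    The width is measured on the dominant lobe (largest excursion from the
    pre-spike baseline, taken as the mean of the leading eighth of the
    excerpt) at half its height, with linear interpolation between samples.
    A lobe without a half-height crossing on either side (monotone
    waveform) yields a NaN width.
    """
    w = np.asarray(waveform, dtype=float)
    if len(w) < 4:
        raise ConfigurationError("waveform too short")
    ptp = float(w.max() - w.min())
    baseline = float(w[: max(len(w) // 8, 2)].mean())
    d = w - baseline
    i = int(np.argmax(np.abs(d)))
    h = d[i]
    if h == 0:
        return ptp, float("nan")
    half = h / 2.0
    sgn = np.sign(h)
    y = d * sgn  # dominant lobe positive
    target = abs(half)
    left = None
    for j in range(i, 0, -1):
        if y[j - 1] <= target <= y[j]:
            left = (j - 1) + (target - y[j - 1]) / (y[j] - y[j - 1])
            break
    right = None
    for j in range(i, len(y) - 1):
        if y[j + 1] <= target <= y[j]:
            right = j + (y[j] - target) / (y[j] - y[j + 1])
            break
    if left is None or right is None:
        return ptp, float("nan")
    return ptp, float((right - left) / fs_hz * 1000.0)


def compute_shape_series(trace: RawTrace, events: pd.DataFrame,
                         config: DetectionConfig) -> pd.DataFrame:
    """Per-sweep mean-waveform metrics: sweep, amplitude, width_ms, n_spikes."""
    n_sweeps = int(math.floor(trace.duration_s / trace.sweep_s + 1e-9))
    rows = []
    for j in range(n_sweeps):
        mw = sweep_mean_waveform(trace, events, j, config)
        n = int((events["sweep"] == j).sum())
        if mw is None:
            rows.append((j, float("nan"), float("nan"), n))
        else:
            amp, wid = shape_metrics(mw, trace.fs_hz)
            rows.append((j, amp, wid, n))
    return pd.DataFrame(rows, columns=["sweep", "amplitude", "width_ms", "n_spikes"])


def shape_change_test(series: pd.DataFrame, plan, alpha: float = 0.05,
                      sweep_s: float = 1.0, min_bins: int = 3) -> dict:
    """Drug-effect test on spike-shape metrics, one verdict per metric.

    The per-sweep amplitude and width series are averaged into the plan's
    time bins (sweeps without spikes are missing) and passed through the
    same composite Kruskal-Wallis + Dunn rule as the firing-rate analysis.
    Epochs with fewer than ``min_bins`` non-missing bins give an
    underpowered, unflagged verdict.
    """
    from .stats import DecisionResult  # local import to avoid cycle at import time

    spb = int(round(plan.bin_width_s / sweep_s))
    out = {}
    for metric in ("amplitude", "width_ms"):
        vals = series[metric].to_numpy(dtype=float)
        sw = series["sweep"].to_numpy()
        bins = sw // spb
        groups = {}
        underpowered = False
        for label, (t0, t1) in plan.epochs.items():
            b0 = int(round(t0 / plan.bin_width_s))
            b1 = int(round(t1 / plan.bin_width_s))
            binned = []
            for b in range(b0, b1):
                v = vals[bins == b]
                v = v[~np.isnan(v)]
                if len(v):
                    binned.append(v.mean())
            if len(binned) < min_bins:
                underpowered = True
            groups[label] = np.asarray(binned)
        if underpowered:
            out[metric] = DecisionResult(flagged=False, direction="none",
                                         protocol=plan.protocol, kw=None,
                                         notes=["underpowered: epoch with < "
                                                f"{min_bins} non-missing bins"])
        else:
            out[metric] = epoch_composite_decision(groups, plan.protocol, alpha)
    return out
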