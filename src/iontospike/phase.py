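"""Vector-strength phase locking and drug-induced phase-locking changes.

Spike times are reduced to phases of the stimulus cycle; locking strength is
the resultant length (vector strength, 0 = uniform, 1 = perfect locking).
Whether a drug altered phase locking is decided from two-sample
Kolmogorov-Smirnov comparisons of the phase distributions in the baseline
(B), ejection (E) and recovery (R) epochs: altered only if E differs
significantly from both B and R while B and R do not differ.

The K-S test on circular data depends on the cut point; phases are
linearised on [0, 2*pi) with a fixed cut at phase 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ks_two_sample
from .synthetic import ConfigurationError, SweepStructure

__all__ = [
    "PhaseSample",
    "VectorStrengthResult",
    "PhaseLockDecision",
    "spike_phases",
    "vector_strength",
    "rayleigh_p",
    "phase_lock_decision",
    "period_histogram",
    "epoch_phase_sample",
]


@dataclass
class PhaseSample:
    """Spike phases (radians in [0, 2*pi)) relative to the stimulus cycle."""

    phases: np.ndarray
    stimulus_freq_hz: float

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if np.any(self.phases < 0) or np.any(self.phases >= 2 * np.pi):
            raise ConfigurationError("phases must lie in [0, 2*pi)")

    @property
    def n(self) -> int:
        return len(self.phases)


@dataclass
class VectorStrengthResult:
    vs: float
    mean_phase_deg: float  # NaN when undefined (vs = 0)
    n: int


@dataclass
class PhaseLockDecision:
    altered: bool
    tests: dict  # {'B_vs_E': (D, p), 'E_vs_R': ..., 'B_vs_R': ...}
    underpowered: bool = False


def spike_phases(spikes, stimulus_freq_hz: float, window=None,
                 sweep: SweepStructure = SweepStructure()) -> PhaseSample:
    """Phases theta = 2*pi*frac(t*f) of in-window spikes.

    ``spikes`` may be a spike-event table (with ``time_s``) or a plain array
    of spike times.  ``window`` defaults to the driven (tone) window.
    """
    if stimulus_freq_hz <= 0:
        raise ConfigurationError("stimulus frequency must be > 0")
    if isinstance(spikes, pd.DataFrame):
        t = spikes["time_s"].to_numpy()
    else:
        t = np.asarray(spikes, dtype=float)
    if window is None:
        window = (sweep.tone_on_s, sweep.tone_off_s)
    t = t[(t >= window[0]) & (t < window[1])]
    phases = 2 * np.pi * np.mod(t * stimulus_freq_hz, 1.0)
    phases = np.mod(phases, 2 * np.pi)  # guard the upper edge
    return PhaseSample(phases=phases, stimulus_freq_hz=stimulus_freq_hz)


def vector_strength(sample: PhaseSample) -> VectorStrengthResult:
    """Resultant length and mean phase of the phase sample (Goldberg-Brown).

    vs = sqrt((sum cos)^2 + (sum sin)^2) / n; the mean phase is the
    four-quadrant arctangent of the resultant and is undefined (NaN) for a
    zero resultant.
    """
    if sample.n == 0:
        raise ConfigurationError("vector strength requires >= 1 spike")
    c = float(np.sum(np.cos(sample.phases)))
    s = float(np.sum(np.sin(sample.phases)))
    vs = math.hypot(c, s) / sample.n
    if vs < 1e-12:
        mean_deg = float("nan")
    else:
        mean_deg = math.degrees(math.atan2(s, c)) % 360.0
    return VectorStrengthResult(vs=min(vs, 1.0), mean_phase_deg=mean_deg, n=sample.n)


def rayleigh_p(sample: PhaseSample) -> float:
    """Rayleigh uniformity test p-value (statistic Z = n * vs^2).

    Uses the standard finite-n corrected approximation
    ``p = exp(-Z) * (1 + (2Z - Z^2)/(4n))`` clipped to [0, 1].
    """
    n = sample.n
    if n == 0:
        raise ConfigurationError("Rayleigh test requires >= 1 spike")
    vs = vector_strength(sample).vs
    z = n * vs * vs
    p = math.exp(-z) * (1.0 + (2.0 * z - z * z) / (4.0 * n))
    return min(max(p, 0.0), 1.0)


def phase_lock_decision(sample_b: PhaseSample, sample_e: PhaseSample,
                        sample_r: PhaseSample, alpha: float = 0.05,
                        min_n: int = 20) -> PhaseLockDecision:
    """Decide whether phase locking was altered during drug ejection.

    Altered requires: B vs E significant, E vs R significant, and B vs R not
    significant.  Samples below ``min_n`` spikes give an underpowered,
    not-altered verdict.
    """
    if min(sample_b.n, sample_e.n, sample_r.n) < min_n:
        return PhaseLockDecision(altered=False, tests={}, underpowered=True)
    tests = {
        "B_vs_E": ks_two_sample(sample_b.phases, sample_e.phases),
        "E_vs_R": ks_two_sample(sample_e.phases, sample_r.phases),
        "B_vs_R": ks_two_sample(sample_b.phases, sample_r.phases),
    }
    altered = (tests["B_vs_E"][1] < alpha and tests["E_vs_R"][1] < alpha
               and tests["B_vs_R"][1] >= alpha)
    return PhaseLockDecision(altered=altered, tests=tests)


def period_histogram(sample: PhaseSample, n_bins: int = 32) -> np.ndarray:
    """Spike counts in ``n_bins`` equal phase bins covering [0, 2*pi)."""
    if n_bins < 4:
        raise ConfigurationError("period histogram needs >= 4 bins")
    edges = np.linspace(0.0, 2 * np.pi, n_bins + 1)
    return np.histogram(sample.phases, bins=edges)[0]


def epoch_phase_sample(spikes: pd.DataFrame, stimulus_freq_hz: float,
                       epoch, sweep: SweepStructure = SweepStructure()
                       ) -> PhaseSample:
    """Phase sample restricted to sweeps whose start time lies in ``epoch``."""
    t0, t1 = epoch
    j0 = int(math.ceil(t0 / sweep.sweep_s - 1e-9))
    j1 = int(math.floor(t1 / sweep.sweep_s + 1e-9))
    sel = (spikes["sweep"] >= j0) & (spikes["sweep"] < j1)
    return spike_phases(spikes[sel], stimulus_freq_hz, sweep=sweep)
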