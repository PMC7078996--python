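"""Synthetic single-unit recording sessions with schedule-locked drug effects.

This module generates spike trains with the statistical structure of the five
ventral cochlear nucleus (VCN) response classes — primary-like, chopper,
onset, phase-locked and unclassified — recorded during hour-long trains of
tone pips (200 ms tone, 800 ms silence, one sweep per second, 3,600 sweeps
by default).  Drug iontophoresis is modelled as a slow, first-order
multiplicative (or additive) modulation of the firing intensity, locked to an
ejection-current schedule, so that every downstream analysis stage can be
exercised against a known ground truth.

Spike generation:

* choppers are gamma-renewal processes with shape ``k`` (regular firing,
  inter-spike-interval CV ~ 1/sqrt(k)), aligned to tone onset;
* all other classes are inhomogeneous Poisson processes, thinned by an
  absolute refractory period (1 ms default).  Poisson intensities are
  dead-time corrected (lambda -> lambda / (1 - lambda * t_refr)) so that the
  realised rate matches the configured rate;
* onset units fire one or two stereotyped spikes in the first 5 ms of the
  tone (1-2 ms apart) over a near-zero sustained rate;
* phase-locked units are driven by a von-Mises-modulated intensity locked to
  the stimulus frequency.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "UNIT_TYPES",
    "SweepStructure",
    "UnitSpec",
    "EjectionSchedule",
    "DrugEffectSpec",
    "SimulatedSession",
    "RawTrace",
    "default_unit",
    "intensity_profile",
    "drug_gain_trajectory",
    "generate_sweep",
    "generate_session",
    "synthesize_trace",
    "biphasic_template",
    "simulate_shape_series",
]

UNIT_TYPES = ("primary_like", "chopper", "onset", "phase_locked", "unclassified")

#: Maximum stimulus frequency at which phase locking is physiologically
#: expected (and at which it is tested downstream).
PHASE_LOCK_CF_LIMIT_HZ = 5000.0

_ONSET_WINDOW_S = 0.005  # onset spikes confined to the first 5 ms of the tone


class ConfigurationError(ValueError):
    """An invalid unit/schedule/effect configuration."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepStructure:
    """Timing of one stimulus sweep: a tone pip followed by silence."""

    sweep_s: float = 1.0
    tone_on_s: float = 0.0
    tone_off_s: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.tone_on_s < self.tone_off_s <= self.sweep_s):
            raise ConfigurationError("tone window must lie inside the sweep")

    @property
    def tone_dur_s(self) -> float:
        return self.tone_off_s - self.tone_on_s


@dataclass(frozen=True)
class UnitSpec:
    """Parameters of one simulated unit.

    ``peak_rate_hz``/``steady_rate_hz``/``adapt_tau_ms`` describe the driven
    intensity during the tone (an onset peak adapting exponentially to a
    steady rate); ``chopper_k`` is the gamma-renewal shape (regularity) used
    for choppers; ``onset_spike_count`` the mean number of onset spikes (1-2)
    for onset units; ``phase_kappa`` the von Mises concentration for
    phase-locked units.
    """

    unit_type: str
    cf_hz: float
    spont_rate_hz: float
    peak_rate_hz: float = 0.0
    steady_rate_hz: float = 0.0
    adapt_tau_ms: float = 15.0
    chopper_k: float = 25.0
    onset_spike_count: float = 1.5
    phase_kappa: float = 5.0
    refractory_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.unit_type not in UNIT_TYPES:
            raise ConfigurationError(f"unknown unit_type {self.unit_type!r}")
        for name in ("cf_hz", "spont_rate_hz", "peak_rate_hz", "steady_rate_hz"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.phase_kappa < 0:
            raise ConfigurationError("phase_kappa must be >= 0")
        if self.chopper_k < 1:
            raise ConfigurationError("chopper_k must be >= 1")
        if self.adapt_tau_ms <= 0 or self.refractory_ms <= 0:
            raise ConfigurationError("time constants must be > 0")
        if self.unit_type == "phase_locked" and self.cf_hz >= PHASE_LOCK_CF_LIMIT_HZ:
            raise ConfigurationError(
                "phase_locked units require cf_hz < %g Hz" % PHASE_LOCK_CF_LIMIT_HZ
            )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "UnitSpec":
        return cls(**d)


#: Default unit specifications, one per response class.  Rates are typical of
#: tone-driven VCN units at 20 dB above threshold.
_DEFAULT_UNITS = {
    "primary_like": dict(cf_hz=9000.0, spont_rate_hz=50.0, peak_rate_hz=600.0,
                         steady_rate_hz=180.0, adapt_tau_ms=15.0),
    "chopper": dict(cf_hz=6000.0, spont_rate_hz=20.0, peak_rate_hz=350.0,
                    steady_rate_hz=200.0, adapt_tau_ms=20.0, chopper_k=25.0),
    "onset": dict(cf_hz=12000.0, spont_rate_hz=5.0, peak_rate_hz=0.0,
                  steady_rate_hz=3.0, onset_spike_count=1.5),
    "phase_locked": dict(cf_hz=400.0, spont_rate_hz=10.0, peak_rate_hz=0.0,
                         steady_rate_hz=150.0, phase_kappa=5.0),
    "unclassified": dict(cf_hz=10000.0, spont_rate_hz=15.0, peak_rate_hz=60.0,
                         steady_rate_hz=60.0, adapt_tau_ms=15.0),
}


def default_unit(unit_type: str, **overrides) -> UnitSpec:
    """Return the default :class:`UnitSpec` for a response class."""
    if unit_type not in _DEFAULT_UNITS:
        raise ConfigurationError(f"unknown unit_type {unit_type!r}")
    params = dict(_DEFAULT_UNITS[unit_type])
    params.update(overrides)
    return UnitSpec(unit_type=unit_type, **params)


@dataclass(frozen=True)
class EjectionSchedule:
    """Iontophoretic ejection blocks for one drug barrel.

    ``blocks`` is a list of ``(current_nA, t_start_s, t_end_s)`` tuples that
    must be ordered, non-overlapping and contained in the recording.
    """

    channel: str
    blocks: tuple = ()
    recording_duration_s: float = 3600.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        prev_end = 0.0
        for cur, t0, t1 in self.blocks:
            if not (0.0 <= t0 < t1 <= self.recording_duration_s):
                raise ConfigurationError("block outside recording window")
            if t0 < prev_end:
                raise ConfigurationError("blocks overlap or are unordered")
            if cur <= 0:
                raise ConfigurationError("ejection current must be > 0 nA")
            prev_end = t1

    def to_dict(self) -> dict:
        return {"channel": self.channel, "blocks": [list(b) for b in self.blocks],
                "recording_duration_s": self.recording_duration_s}

    @classmethod
    def from_dict(cls, d: dict) -> "EjectionSchedule":
        return cls(channel=d["channel"], blocks=tuple(tuple(b) for b in d["blocks"]),
                   recording_duration_s=d.get("recording_duration_s", 3600.0))


@dataclass(frozen=True)
class DrugEffectSpec:
    """How an ejected drug modulates the firing intensity.

    ``mode='gain'`` scales the intensity multiplicatively (level 1 = no
    effect); ``mode='additive'`` adds ``level`` spikes/s across the sweep
    (level 0 = no effect), which is how direct NMDA excitation is modelled.
    ``level_per_current`` maps each ejection current (nA) to its asymptotic
    level; the level relaxes towards the target with time constant
    ``tau_on_s`` during a block and back towards baseline with ``tau_off_s``
    afterwards.  ``applies_to`` selects the affected intensity components:
    ``driven``, ``spontaneous``, and/or ``evoked`` (the additive component of
    *other* drugs, used for modulators of NMDA-evoked excitation).
    ``shape_effect`` optionally drifts the spike waveform:
    ``(amplitude_factor, width_factor)`` at full effect.
    """

    channel: str
    level_per_current: dict = field(default_factory=dict)
    tau_on_s: float = 120.0
    tau_off_s: float = 120.0
    mode: str = "gain"
    applies_to: tuple = ("driven",)
    shape_effect: tuple | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("gain", "additive"):
            raise ConfigurationError("mode must be 'gain' or 'additive'")
        if self.tau_on_s <= 0 or self.tau_off_s <= 0:
            raise ConfigurationError("time constants must be > 0")
        for cur, lvl in self.level_per_current.items():
            if self.mode == "gain" and lvl <= 0:
                raise ConfigurationError("gains must be > 0")
            if self.mode == "additive" and lvl < 0:
                raise ConfigurationError("additive rates must be >= 0")
        bad = set(self.applies_to) - {"driven", "spontaneous", "evoked"}
        if bad:
            raise ConfigurationError(f"unknown applies_to entries: {bad}")
        if self.shape_effect is not None:
            amp, wid = self.shape_effect
            if amp <= 0 or wid <= 0:
                raise ConfigurationError("shape_effect factors must be > 0")
            object.__setattr__(self, "shape_effect", (float(amp), float(wid)))

    @property
    def baseline(self) -> float:
        return 1.0 if self.mode == "gain" else 0.0

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "level_per_current": {str(k): v for k, v in self.level_per_current.items()},
            "tau_on_s": self.tau_on_s, "tau_off_s": self.tau_off_s,
            "mode": self.mode, "applies_to": list(self.applies_to),
            "shape_effect": list(self.shape_effect) if self.shape_effect else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DrugEffectSpec":
        return cls(
            channel=d["channel"],
            level_per_current={float(k): v for k, v in d["level_per_current"].items()},
            tau_on_s=d["tau_on_s"], tau_off_s=d["tau_off_s"], mode=d["mode"],
            applies_to=tuple(d["applies_to"]),
            shape_effect=tuple(d["shape_effect"]) if d.get("shape_effect") else None,
        )


@dataclass
class SimulatedSession:
    """A simulated recording plus the ground truth that generated it."""

    spikes: pd.DataFrame  # columns: sweep (0-based int), time_s (within sweep)
    gain_truth: pd.DataFrame  # sweep, driven_gain, spont_gain, additive_hz
    unit: UnitSpec
    schedules: list
    effects: list
    seed: int
    sweep: SweepStructure = field(default_factory=SweepStructure)

    @property
    def n_sweeps(self) -> int:
        return len(self.gain_truth)


@dataclass
class RawTrace:
    """A synthetic extracellular voltage trace with known spike times."""

    samples: np.ndarray
    fs_hz: float
    truth_spikes: pd.DataFrame | None = None
    sweep_s: float = 1.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ConfigurationError("fs_hz must be > 0")
        self.samples = np.asarray(self.samples, dtype=np.float32)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


# --------------------------------------------------------------------------
# intensity model
# --------------------------------------------------------------------------


def _driven_rate(unit: UnitSpec, t: np.ndarray, sweep: SweepStructure) -> np.ndarray:
    """Deterministic driven intensity (spikes/s) at time ``t`` within the tone."""
    t = np.asarray(t, dtype=float)
    tt = t - sweep.tone_on_s
    if unit.unit_type in ("primary_like", "chopper", "unclassified"):
        tau = unit.adapt_tau_ms / 1000.0
        return unit.steady_rate_hz + (unit.peak_rate_hz - unit.steady_rate_hz) * np.exp(-tt / tau)
    if unit.unit_type == "phase_locked":
        kappa = unit.phase_kappa
        return unit.steady_rate_hz * np.exp(kappa * np.cos(2 * np.pi * unit.cf_hz * tt)) / special.i0(kappa)
    if unit.unit_type == "onset":
        rate = np.full_like(tt, unit.steady_rate_hz, dtype=float)
        rate[tt < _ONSET_WINDOW_S] = unit.onset_spike_count / _ONSET_WINDOW_S
        return rate
    raise ConfigurationError(f"unknown unit_type {unit.unit_type!r}")


def _driven_rate_max(unit: UnitSpec) -> float:
    if unit.unit_type == "phase_locked":
        return unit.steady_rate_hz * math.exp(unit.phase_kappa) / special.i0(unit.phase_kappa)
    if unit.unit_type == "onset":
        return max(unit.onset_spike_count / _ONSET_WINDOW_S, unit.steady_rate_hz)
    return max(unit.peak_rate_hz, unit.steady_rate_hz)


def intensity_profile(unit: UnitSpec, t_in_sweep, driven_gain: float = 1.0,
                      spont_gain: float = 1.0, additive_rate_hz: float = 0.0,
                      sweep: SweepStructure = SweepStructure()) -> np.ndarray:
    """Instantaneous firing intensity (spikes/s) at ``t_in_sweep``.

    The driven component (during the tone) is scaled by ``driven_gain``, the
    spontaneous component (after the tone) by ``spont_gain``; an optional
    additive rate (drug-evoked excitation) applies throughout the sweep.
    """
    t = np.atleast_1d(np.asarray(t_in_sweep, dtype=float))
    if np.any(t < 0) or np.any(t >= sweep.sweep_s):
        raise ValueError("t_in_sweep must lie in [0, sweep_s)")
    out = np.full(t.shape, unit.spont_rate_hz * spont_gain, dtype=float)
    tone = (t >= sweep.tone_on_s) & (t < sweep.tone_off_s)
    if tone.any():
        out[tone] = _driven_rate(unit, t[tone], sweep) * driven_gain
    out += additive_rate_hz
    if np.isscalar(t_in_sweep):
        return float(out[0])
    return out


# --------------------------------------------------------------------------
# drug kinetics
# --------------------------------------------------------------------------


def drug_gain_trajectory(schedule: EjectionSchedule, effect: DrugEffectSpec,
                         n_sweeps: int, sweep_s: float = 1.0) -> np.ndarray:
    """Per-sweep effect level under first-order on/off kinetics.

    The level obeys ``dx/dt = (target - x)/tau`` where the target is the
    mapped level of the active ejection current (baseline between blocks) and
    tau is ``tau_on_s`` inside a block, ``tau_off_s`` outside.  The returned
    array holds the level at the *end* of each sweep; the level is 1 (gain
    mode) or 0 (additive mode) before the first block.
    """
    baseline = effect.baseline
    targets = np.full(n_sweeps, baseline)
    active = np.zeros(n_sweeps, dtype=bool)
    for cur, t0, t1 in schedule.blocks:
        if cur not in effect.level_per_current:
            raise ConfigurationError(
                f"current {cur} nA on channel {schedule.channel!r} has no mapped level")
        j0 = int(round(t0 / sweep_s))
        j1 = min(int(round(t1 / sweep_s)), n_sweeps)
        targets[j0:j1] = effect.level_per_current[cur]
        active[j0:j1] = True
    d_on = math.exp(-sweep_s / effect.tau_on_s)
    d_off = math.exp(-sweep_s / effect.tau_off_s)
    out = np.empty(n_sweeps)
    x = baseline
    for j in range(n_sweeps):
        d = d_on if active[j] else d_off
        x = targets[j] + (x - targets[j]) * d
        out[j] = x
    return out


def _compose_effect_trajectories(unit_refr_unused, schedules, effects, n_sweeps, sweep_s):
    """Combine all drug effects into per-sweep driven/spont gains and additive rate."""
    by_channel = {s.channel: s for s in schedules}
    g_driven = np.ones(n_sweeps)
    g_spont = np.ones(n_sweeps)
    g_evoked = np.ones(n_sweeps)
    additive = np.zeros(n_sweeps)
    for eff in effects:
        if eff.channel not in by_channel:
            raise ConfigurationError(f"effect channel {eff.channel!r} has no schedule")
        traj = drug_gain_trajectory(by_channel[eff.channel], eff, n_sweeps, sweep_s)
        if eff.mode == "additive":
            additive += traj
        else:
            if "driven" in eff.applies_to:
                g_driven = g_driven * traj
            if "spontaneous" in eff.applies_to:
                g_spont = g_spont * traj
            if "evoked" in eff.applies_to:
                g_evoked = g_evoked * traj
    return g_driven, g_spont, additive * g_evoked


# --------------------------------------------------------------------------
# spike generation
# --------------------------------------------------------------------------


def _dead_time_corrected(rate, refr_s):
    # lambda such that a non-paralyzable dead time refr_s yields the target
    # rate: lambda/(1 + lambda*refr) = rate  =>  lambda = rate/(1 - rate*refr).
    # Capped at a factor of 2 to stay finite near saturation.
    x = np.minimum(np.asarray(rate, dtype=float) * refr_s, 0.5)
    return rate / (1.0 - x)


def _enforce_refractory(sweeps: np.ndarray, times: np.ndarray, refr_s: float):
    """Greedy removal of spikes closer than ``refr_s`` to the previous kept spike."""
    while len(times) > 1:
        dt = np.diff(times)
        same = sweeps[1:] == sweeps[:-1]
        viol = np.concatenate([[False], same & (dt < refr_s - 1e-12)])
        if not viol.any():
            break
        # drop only the first violator of each run, then re-evaluate
        prev_viol = np.concatenate([[False], viol[:-1]])
        drop = viol & ~prev_viol
        keep = ~drop
        sweeps, times = sweeps[keep], times[keep]
    return sweeps, times


def _const_rate_poisson(rates, t0, t1, rng):
    """Homogeneous Poisson spikes per sweep; ``rates`` is per-sweep (Hz)."""
    counts = rng.poisson(np.maximum(rates, 0.0) * (t1 - t0))
    sw = np.repeat(np.arange(len(rates)), counts)
    t = rng.uniform(t0, t1, counts.sum())
    return sw, t


def _driven_poisson(unit, g_driven, additive, rng, sweep):
    """Inhomogeneous Poisson spikes in the tone window, by thinning."""
    refr = unit.refractory_ms / 1000.0
    correct = unit.unit_type != "phase_locked"  # correction invalid at fast modulation
    rmax = _driven_rate_max(unit)

    def lam(rate):
        return _dead_time_corrected(rate, refr) if correct else rate

    lam_max = lam(g_driven * rmax) + lam(additive)
    counts = rng.poisson(lam_max * sweep.tone_dur_s)
    sw = np.repeat(np.arange(len(g_driven)), counts)
    t = rng.uniform(sweep.tone_on_s, sweep.tone_off_s, counts.sum())
    u = rng.uniform(0.0, 1.0, counts.sum())
    lam_t = lam(g_driven[sw] * _driven_rate(unit, t, sweep)) + lam(additive[sw])
    acc = u * lam_max[sw] < lam_t
    return sw[acc], t[acc]


def _driven_chopper(unit, g_driven, rng, sweep):
    """Gamma-renewal spikes in the tone window via operational-time rescaling.

    Unit-mean gamma(k, 1/k) increments are accumulated in operational time
    and mapped through the inverse cumulative intensity, so the local rate
    follows the (gain-scaled) adapting intensity profile while inter-spike
    intervals keep CV ~ 1/sqrt(k).  A constant offset of (1 - 1/k)/2 applied
    to the operational clock removes the counting deficit of an
    onset-aligned (ordinary) renewal process so that the realised rate
    matches the configured intensity integral.
    """
    k = unit.chopper_k
    T = sweep.tone_dur_s
    tau = unit.adapt_tau_ms / 1000.0
    t_grid = np.linspace(0.0, T, 2001)
    lam0 = (unit.steady_rate_hz * t_grid
            + (unit.peak_rate_hz - unit.steady_rate_hz) * tau * (1.0 - np.exp(-t_grid / tau)))
    budget = g_driven * lam0[-1]
    c = (1.0 - 1.0 / k) / 2.0
    bmax = budget.max() if len(budget) else 0.0
    if bmax <= 0:
        return np.empty(0, dtype=int), np.empty(0)
    m = int(math.ceil(bmax + c + 6.0 * math.sqrt(max(bmax, 1.0) / k) + 8))
    isis = rng.gamma(k, 1.0 / k, size=(len(budget), m))
    s = np.cumsum(isis, axis=1) - c
    valid = (s > 0.0) & (s < budget[:, None])
    sw = np.nonzero(valid)[0]
    t = np.interp(s[valid] / g_driven[sw], lam0, t_grid) + sweep.tone_on_s
    return sw, t


def _driven_onset(unit, g_driven, rng, sweep):
    """One or two stereotyped onset spikes plus a weak sustained discharge."""
    n = len(g_driven)
    p = np.clip(unit.onset_spike_count * g_driven / 2.0, 0.0, 1.0)
    n_onset = rng.binomial(2, p)
    # first spike at ~2 ms; clipped so a second spike 1-2 ms later still
    # falls inside the 5 ms onset window
    first = np.clip(rng.normal(0.002, 0.0005, n), 0.0006, 0.003) + sweep.tone_on_s
    second = first + rng.uniform(0.001, 0.002, n)
    sw1 = np.nonzero(n_onset >= 1)[0]
    sw2 = np.nonzero(n_onset >= 2)[0]
    refr = unit.refractory_ms / 1000.0
    sus_rate = _dead_time_corrected(unit.steady_rate_hz * g_driven, refr)
    sw3, t3 = _const_rate_poisson(sus_rate, sweep.tone_on_s + _ONSET_WINDOW_S,
                                  sweep.tone_off_s, rng)
    sw = np.concatenate([sw1, sw2, sw3])
    t = np.concatenate([first[sw1], second[sw2], t3])
    return sw, t


def _generate_sweeps(unit, g_driven, g_spont, additive, rng, sweep):
    """Generate spikes for a batch of sweeps (vectorised core)."""
    refr = unit.refractory_ms / 1000.0
    parts_sw, parts_t = [], []

    if unit.unit_type == "chopper":
        sw, t = _driven_chopper(unit, g_driven, rng, sweep)
        parts_sw.append(sw); parts_t.append(t)
        if np.any(additive > 0):
            sw, t = _const_rate_poisson(_dead_time_corrected(additive, refr),
                                        sweep.tone_on_s, sweep.tone_off_s, rng)
            parts_sw.append(sw); parts_t.append(t)
    elif unit.unit_type == "onset":
        sw, t = _driven_onset(unit, g_driven, rng, sweep)
        parts_sw.append(sw); parts_t.append(t)
        if np.any(additive > 0):
            sw, t = _const_rate_poisson(_dead_time_corrected(additive, refr),
                                        sweep.tone_on_s, sweep.tone_off_s, rng)
            parts_sw.append(sw); parts_t.append(t)
    else:
        sw, t = _driven_poisson(unit, g_driven, additive, rng, sweep)
        parts_sw.append(sw); parts_t.append(t)

    spont_rate = _dead_time_corrected(unit.spont_rate_hz * g_spont + additive, refr)
    sw, t = _const_rate_poisson(spont_rate, sweep.tone_off_s, sweep.sweep_s, rng)
    parts_sw.append(sw); parts_t.append(t)

    # silence before tone onset, if any
    if sweep.tone_on_s > 0:
        sw, t = _const_rate_poisson(spont_rate, 0.0, sweep.tone_on_s, rng)
        parts_sw.append(sw); parts_t.append(t)

    sweeps = np.concatenate(parts_sw)
    times = np.concatenate(parts_t)
    order = np.lexsort((times, sweeps))
    sweeps, times = sweeps[order], times[order]
    return _enforce_refractory(sweeps, times, refr)


def generate_sweep(unit: UnitSpec, rng: np.random.Generator,
                   driven_gain: float = 1.0, spont_gain: float = 1.0,
                   additive_rate_hz: float = 0.0,
                   sweep: SweepStructure = SweepStructure()) -> np.ndarray:
    """Spike times (seconds, sorted) for a single sweep."""
    if driven_gain < 0 or spont_gain < 0:
        raise ConfigurationError("gains must be >= 0")
    _, t = _generate_sweeps(unit, np.array([driven_gain]), np.array([spont_gain]),
                            np.array([additive_rate_hz]), rng, sweep)
    return t


def generate_session(unit: UnitSpec, schedules=(), effects=(), n_sweeps: int = 3600,
                     seed: int = 0, sweep: SweepStructure = SweepStructure()
                     ) -> SimulatedSession:
    """Simulate a full recording session.

    Reproducible: identical (unit, schedules, effects, n_sweeps, seed) yield
    bit-identical spike tables.  The per-sweep effect trajectories that
    generated the spikes are stored in ``gain_truth``.
    """
    if n_sweeps < 1:
        raise ConfigurationError("n_sweeps must be >= 1")
    schedules = list(schedules)
    effects = list(effects)
    g_driven, g_spont, additive = _compose_effect_trajectories(
        None, schedules, effects, n_sweeps, sweep.sweep_s)
    rng = np.random.default_rng(seed)
    sw, t = _generate_sweeps(unit, g_driven, g_spont, additive, rng, sweep)
    spikes = pd.DataFrame({"sweep": sw.astype(np.int64), "time_s": t})
    gain_truth = pd.DataFrame({
        "sweep": np.arange(n_sweeps, dtype=np.int64),
        "driven_gain": g_driven, "spont_gain": g_spont, "additive_hz": additive,
    })
    return SimulatedSession(spikes=spikes, gain_truth=gain_truth, unit=unit,
                            schedules=schedules, effects=effects, seed=int(seed),
                            sweep=sweep)


# --------------------------------------------------------------------------
# raw-trace synthesis and waveform drift
# --------------------------------------------------------------------------


def biphasic_template(fs_hz: float = 25000.0, ptp_amplitude: float = 1.0,
                      half_width_ms: float = 0.25, span_ms: float = 1.2) -> np.ndarray:
    """A biphasic (negative-then-positive) extracellular spike template.

    The dominant negative lobe has the requested half-amplitude width
    (FWHM); the waveform is scaled so its peak-to-peak amplitude equals
    ``ptp_amplitude``.
    """
    if ptp_amplitude <= 0:
        raise ConfigurationError("ptp_amplitude must be > 0")
    n = max(int(round(span_ms / 1000.0 * fs_hz)), 8)
    t = np.arange(n) / fs_hz * 1000.0  # ms
    s1 = half_width_ms / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    s2 = 1.6 * s1
    w = (-0.68 * np.exp(-0.5 * ((t - 0.35 * span_ms) / s1) ** 2)
         + 0.36 * np.exp(-0.5 * ((t - 0.62 * span_ms) / s2) ** 2))
    w *= ptp_amplitude / (w.max() - w.min())
    return w.astype(np.float64)


def shape_factor_trajectories(schedules, effects, n_sweeps, sweep_s=1.0):
    """Per-sweep (amplitude_factor, width_factor) from shape-affecting drugs."""
    by_channel = {s.channel: s for s in schedules}
    amp = np.ones(n_sweeps)
    wid = np.ones(n_sweeps)
    for eff in effects:
        if eff.shape_effect is None:
            continue
        if eff.channel not in by_channel:
            raise ConfigurationError(f"effect channel {eff.channel!r} has no schedule")
        # normalised effect level in [0, 1]: same kinetics as the rate effect
        norm = DrugEffectSpec(channel=eff.channel,
                              level_per_current={c: 1.0 for c in eff.level_per_current},
                              tau_on_s=eff.tau_on_s, tau_off_s=eff.tau_off_s,
                              mode="additive", applies_to=())
        x = drug_gain_trajectory(by_channel[eff.channel], norm, n_sweeps, sweep_s)
        a_f, w_f = eff.shape_effect
        amp = amp * (1.0 + (a_f - 1.0) * x)
        wid = wid * (1.0 + (w_f - 1.0) * x)
    return amp, wid


def synthesize_trace(session: SimulatedSession, template: np.ndarray | None = None,
                     noise_sd: float = 0.0, fs_hz: float = 25000.0,
                     seed: int = 0) -> RawTrace:
    """Render a session as a raw voltage trace.

    A scaled copy of ``template`` is summed into the trace at every true
    spike time; additive Gaussian noise of ``noise_sd`` is applied on top.
    Per-sweep amplitude/width drift from any ``shape_effect`` in the
    session's drug effects is applied to each inserted spike.
    """
    if template is None:
        template = biphasic_template(fs_hz)
    template = np.asarray(template, dtype=float)
    if template.max() - template.min() <= 0:
        raise ConfigurationError("template peak-to-peak amplitude must be > 0")
    n_sweeps = session.n_sweeps
    sweep_s = session.sweep.sweep_s
    n_samples = int(round(n_sweeps * sweep_s * fs_hz))
    trace = np.zeros(n_samples)
    amp_f, wid_f = shape_factor_trajectories(session.schedules, session.effects,
                                             n_sweeps, sweep_s)
    tpl_x = np.arange(len(template))
    sw = session.spikes["sweep"].to_numpy()
    t = session.spikes["time_s"].to_numpy()
    for j, tj in zip(sw, t):
        i0 = int(round((j * sweep_s + tj) * fs_hz))
        w = template
        if wid_f[j] != 1.0:
            w = np.interp(tpl_x / wid_f[j], tpl_x, template, left=0.0, right=0.0)
        w = w * amp_f[j]
        i1 = min(i0 + len(w), n_samples)
        if i0 < n_samples:
            trace[i0:i1] += w[: i1 - i0]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, n_samples)
    truth = session.spikes[["sweep", "time_s"]].copy()
    return RawTrace(samples=trace, fs_hz=fs_hz, truth_spikes=truth, sweep_s=sweep_s)


def simulate_shape_series(session: SimulatedSession, amplitude: float = 80.0,
                          width_ms: float = 0.25, noise_cv: float = 0.02,
                          seed: int = 0) -> pd.DataFrame:
    """Per-sweep spike-shape metrics without rendering a full raw trace.

    Emulates the output of the detection stage's waveform measurements: per
    sweep, the mean-waveform amplitude and half-amplitude width including any
    drug-induced drift, with measurement noise shrinking as 1/sqrt(n_spikes).
    Sweeps without spikes carry missing metrics.  Intended for long-session
    statistics where synthesising 25 kHz voltage traces would be wasteful.
    """
    n_sweeps = session.n_sweeps
    amp_f, wid_f = shape_factor_trajectories(session.schedules, session.effects,
                                             n_sweeps, session.sweep.sweep_s)
    counts = np.bincount(session.spikes["sweep"].to_numpy(), minlength=n_sweeps)
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore"):
        sd_scale = noise_cv / np.sqrt(np.maximum(counts, 1))
    amp = amplitude * amp_f * (1.0 + rng.normal(0.0, 1.0, n_sweeps) * sd_scale)
    wid = width_ms * wid_f * (1.0 + rng.normal(0.0, 1.0, n_sweeps) * sd_scale)
    amp[counts == 0] = np.nan
    wid[counts == 0] = np.nan
    return pd.DataFrame({"sweep": np.arange(n_sweeps, dtype=np.int64),
                         "amplitude": amp, "width_ms": wid,
                         "n_spikes": counts.astype(np.int64)})
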