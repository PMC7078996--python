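"""Protocol presets: ejection schedules, analysis epochs and drug effects.

Three iontophoresis protocols are supported:

``donor``
    An NO donor (SIN-1 or SNOG) ejected for 10 min at increasing currents of
    40, 80 and 120 nA at 10-20, 25-35 and 40-50 min of an hour-long
    recording.  Firing rate is analysed in 10-s epochs over seven periods:
    the final 2 min of baseline (B), of each ejection (E40/E80/E120) and of
    each recovery (R1/R2/R3).

``inhibitor``
    A NOS inhibitor (L-NAME) ejected at 80 nA from 15 to 35 min.  Rates are
    analysed in 60-s epochs over the final 10 min of baseline (B), of the
    ejection (E) and of the recording (R).

``nmda``
    NMDA applied at 80 nA for 1 min every 2 min during 10-20, 30-40 and
    50-60 min, with the modulator (L-NAME) at 80 nA from 20 to 40 min,
    giving one baseline (B), one modulated (E) and one recovery (R) period
    of NMDA responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .synthetic import ConfigurationError, DrugEffectSpec, EjectionSchedule

__all__ = [
    "EpochPlan",
    "NmdaProtocol",
    "donor_schedule",
    "inhibitor_schedule",
    "nmda_schedules",
    "donor_plan",
    "inhibitor_plan",
    "nmda_protocol",
    "donor_effect",
    "inhibitor_effect",
    "nmda_effects",
    "PROTOCOLS",
]

PROTOCOLS = ("donor", "inhibitor", "nmda")


@dataclass(frozen=True)
class EpochPlan:
    """Labelled analysis windows mapping a protocol onto groups of rate bins.

    ``epochs`` maps labels (B, E40, R1, ...) to ``(t_start_s, t_end_s)``
    windows, in chronological order.  All windows of one plan must be
    non-overlapping and contained in the recording.
    """

    protocol: str
    bin_width_s: float
    epochs: dict = field(default_factory=dict)
    recording_duration_s: float = 3600.0

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        if self.bin_width_s <= 0:
            raise ConfigurationError("bin_width_s must be > 0")
        prev_end = 0.0
        for label, (t0, t1) in self.epochs.items():
            if not (0.0 <= t0 < t1 <= self.recording_duration_s):
                raise ConfigurationError(f"epoch {label!r} outside recording")
            if t0 < prev_end:
                raise ConfigurationError(f"epoch {label!r} overlaps its predecessor")
            n_bins = (t1 - t0) / self.bin_width_s
            if abs(n_bins - round(n_bins)) > 1e-9:
                raise ConfigurationError(
                    f"epoch {label!r} length is not a multiple of the bin width")
            prev_end = t1

    def bins_per_epoch(self, label: str) -> int:
        t0, t1 = self.epochs[label]
        return int(round((t1 - t0) / self.bin_width_s))

    def to_dict(self) -> dict:
        return {"protocol": self.protocol, "bin_width_s": self.bin_width_s,
                "epochs": {k: list(v) for k, v in self.epochs.items()},
                "recording_duration_s": self.recording_duration_s}

    @classmethod
    def from_dict(cls, d: dict) -> "EpochPlan":
        return cls(protocol=d["protocol"], bin_width_s=d["bin_width_s"],
                   epochs={k: tuple(v) for k, v in d["epochs"].items()},
                   recording_duration_s=d.get("recording_duration_s", 3600.0))


@dataclass(frozen=True)
class NmdaProtocol:
    """Timing of the NMDA-burst protocol.

    ``app_starts`` maps each period (B/E/R) to the start times (s) of its
    five 1-min NMDA applications; ``app_dur_s`` is the application length.
    The per-period baseline is the 180 s preceding the first application.
    """

    app_starts: dict = field(default_factory=lambda: {
        "B": (600.0, 720.0, 840.0, 960.0, 1080.0),
        "E": (1800.0, 1920.0, 2040.0, 2160.0, 2280.0),
        "R": (3000.0, 3120.0, 3240.0, 3360.0, 3480.0),
    })
    app_dur_s: float = 60.0
    baseline_dur_s: float = 180.0
    n_final_apps: int = 3
    n_top_bins: int = 6


def donor_schedule(channel: str = "SIN-1") -> EjectionSchedule:
    return EjectionSchedule(channel=channel, blocks=(
        (40.0, 600.0, 1200.0), (80.0, 1500.0, 2100.0), (120.0, 2400.0, 3000.0)))


def inhibitor_schedule(channel: str = "L-NAME") -> EjectionSchedule:
    return EjectionSchedule(channel=channel, blocks=((80.0, 900.0, 2100.0),))


def nmda_schedules(nmda_channel: str = "NMDA", modulator_channel: str = "L-NAME"):
    """NMDA burst schedule plus the 20-40 min modulator block."""
    proto = NmdaProtocol()
    blocks = tuple((80.0, t0, t0 + proto.app_dur_s)
                   for period in ("B", "E", "R") for t0 in proto.app_starts[period])
    return [EjectionSchedule(channel=nmda_channel, blocks=blocks),
            EjectionSchedule(channel=modulator_channel, blocks=((80.0, 1200.0, 2400.0),))]


def donor_plan() -> EpochPlan:
    return EpochPlan(protocol="donor", bin_width_s=10.0, epochs={
        "B": (480.0, 600.0), "E40": (1080.0, 1200.0), "R1": (1380.0, 1500.0),
        "E80": (1980.0, 2100.0), "R2": (2280.0, 2400.0), "E120": (2880.0, 3000.0),
        "R3": (3480.0, 3600.0)})


def inhibitor_plan() -> EpochPlan:
    return EpochPlan(protocol="inhibitor", bin_width_s=60.0, epochs={
        "B": (300.0, 900.0), "E": (1500.0, 2100.0), "R": (3000.0, 3600.0)})


def nmda_protocol() -> NmdaProtocol:
    return NmdaProtocol()


def donor_effect(levels=None, channel: str = "SIN-1",
                 applies_to=("driven",), tau_s: float = 120.0,
                 shape_effect=None) -> DrugEffectSpec:
    """Default donor effect: dose-dependent gain building over minutes."""
    if levels is None:
        levels = {40.0: 1.2, 80.0: 1.4, 120.0: 1.6}
    return DrugEffectSpec(channel=channel, level_per_current=dict(levels),
                          tau_on_s=tau_s, tau_off_s=tau_s, mode="gain",
                          applies_to=tuple(applies_to), shape_effect=shape_effect)


def inhibitor_effect(level: float = 1.7, channel: str = "L-NAME",
                     applies_to=("driven",), tau_s: float = 360.0) -> DrugEffectSpec:
    """Default inhibitor effect: slow (tens of minutes) gain change."""
    return DrugEffectSpec(channel=channel, level_per_current={80.0: level},
                          tau_on_s=tau_s, tau_off_s=tau_s, mode="gain",
                          applies_to=tuple(applies_to))


def nmda_effects(burst_rate_hz: float = 100.0, modulator_gain: float = 1.5,
                 nmda_channel: str = "NMDA", modulator_channel: str = "L-NAME"):
    """NMDA-evoked excitation plus a modulator scaling the evoked response."""
    nmda = DrugEffectSpec(channel=nmda_channel,
                          level_per_current={80.0: burst_rate_hz},
                          tau_on_s=15.0, tau_off_s=15.0, mode="additive",
                          applies_to=())
    mod = DrugEffectSpec(channel=modulator_channel,
                         level_per_current={80.0: modulator_gain},
                         tau_on_s=360.0, tau_off_s=360.0, mode="gain",
                         applies_to=("evoked",))
    return [nmda, mod]
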