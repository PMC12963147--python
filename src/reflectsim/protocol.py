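"""Experiment protocol: ventilation settings, agent properties, target staircase.

Everything in this module is deterministic configuration arithmetic — phase
timing of a volume-controlled breath, MAC-fraction to vol% conversion, and
the staircase of concentration targets that structures a bench run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "VentilationSettings",
    "AgentSpec",
    "PhaseDurations",
    "TargetSchedule",
    "TargetPeriod",
    "mac_to_volpct",
    "phase_durations",
    "build_staircase_schedule",
]


@dataclass(frozen=True)
class VentilationSettings:
    """Volume-controlled ventilation with constant inspiratory flow.

    Parameters
    ----------
    tidal_volume_ml : float
        Tidal volume VT in mL.
    respiratory_rate : float
        Breaths per minute (RR).
    ie_ratio : tuple of float
        Inspiration:expiration ratio as two positive numbers, default 1:1.
    inspiratory_flow_lpm : float
        Constant inspiratory flow in L/min.  Together with VT this fixes the
        inspiratory-flow time; the remainder of inspiration is a pause.
    peep_hpa, fio2 : float
        Informational only; they do not enter any computation here.
    """

    tidal_volume_ml: float = 500.0
    respiratory_rate: float = 10.0
    ie_ratio: tuple[float, float] = (1.0, 1.0)
    inspiratory_flow_lpm: float = 12.0
    peep_hpa: float = 3.0
    fio2: float = 0.21

    def __post_init__(self) -> None:
        if self.tidal_volume_ml <= 0:
            raise ValueError(f"tidal_volume_ml must be > 0, got {self.tidal_volume_ml}")
        if self.respiratory_rate <= 0:
            raise ValueError(f"respiratory_rate must be > 0, got {self.respiratory_rate}")
        if self.inspiratory_flow_lpm <= 0:
            raise ValueError(
                f"inspiratory_flow_lpm must be > 0, got {self.inspiratory_flow_lpm}"
            )
        i, e = self.ie_ratio
        if i <= 0 or e <= 0:
            raise ValueError(f"ie_ratio components must be > 0, got {self.ie_ratio}")
        # Fails early if the flow phase cannot fit into inspiration.
        phase_durations(self)

    @property
    def cycle_duration_s(self) -> float:
        """Duration of one full respiratory cycle in seconds (60/RR)."""
        return 60.0 / self.respiratory_rate

    @property
    def inspiration_s(self) -> float:
        i, e = self.ie_ratio
        return self.cycle_duration_s * i / (i + e)

    @property
    def expiration_s(self) -> float:
        return self.cycle_duration_s - self.inspiration_s


@dataclass(frozen=True)
class PhaseDurations:
    """Per-breath phase timing: inspiratory flow, inspiratory pause, expiration."""

    flow_s: float
    pause_s: float
    expiration_s: float

    @property
    def cycle_s(self) -> float:
        return self.flow_s + self.pause_s + self.expiration_s


def phase_durations(vent: VentilationSettings) -> PhaseDurations:
    """Derive the three breath phases from volume-controlled settings.

    The inspiratory-flow time is VT divided by the constant flow; the rest of
    inspiration is a pause.  E.g. VT 500 mL at 12 L/min gives a 2.5 s flow
    phase, 0.5 s pause and 3 s expiration at RR 10/min with I:E = 1:1, while
    60 L/min shortens the flow phase to 0.5 s.

    Raises
    ------
    ValueError
        If the flow time exceeds the inspiration (the pause would be negative).
    """
    flow_s = vent.tidal_volume_ml / (vent.inspiratory_flow_lpm * 1000.0 / 60.0)
    insp = vent.inspiration_s
    if flow_s > insp + 1e-9:
        raise ValueError(
            f"inspiratory-flow time {flow_s:.3g} s exceeds inspiration "
            f"duration {insp:.3g} s; increase flow or lengthen inspiration"
        )
    pause_s = insp - flow_s
    return PhaseDurations(flow_s=flow_s, pause_s=pause_s, expiration_s=vent.expiration_s)


@dataclass(frozen=True)
class AgentSpec:
    """A volatile anaesthetic agent.

    ``mac_volpct`` is the concentration equal to 1.0 MAC at the reference age
    of 40 y (a device constant, not an age model).  ``vapour_factor_f`` is F,
    the mL of vapour produced per mL of liquid agent.
    """

    name: str
    mac_volpct: float
    vapour_factor_f: float

    def __post_init__(self) -> None:
        if self.mac_volpct <= 0:
            raise ValueError(f"mac_volpct must be > 0, got {self.mac_volpct}")
        if self.vapour_factor_f <= 0:
            raise ValueError(f"vapour_factor_f must be > 0, got {self.vapour_factor_f}")

    @staticmethod
    def isoflurane() -> "AgentSpec":
        return AgentSpec("isoflurane", mac_volpct=1.2, vapour_factor_f=200.0)

    @staticmethod
    def sevoflurane() -> "AgentSpec":
        return AgentSpec("sevoflurane", mac_volpct=1.9, vapour_factor_f=193.0)

    @staticmethod
    def by_name(name: str) -> "AgentSpec":
        try:
            return {"isoflurane": AgentSpec.isoflurane, "sevoflurane": AgentSpec.sevoflurane}[
                name.lower()
            ]()
        except KeyError:
            raise ValueError(f"unknown agent {name!r}; expected isoflurane or sevoflurane")


def mac_to_volpct(fraction: float, agent: AgentSpec) -> float:
    """Convert a MAC multiple to a concentration target in vol%.

    Linear in the fraction: 1.5 MAC sevoflurane (MAC 1.9 vol%) is 2.85 vol%,
    1.4 MAC isoflurane (MAC 1.2 vol%) is 1.68 vol%.
    """
    if fraction < 0:
        raise ValueError(f"MAC fraction must be >= 0, got {fraction}")
    return fraction * agent.mac_volpct


@dataclass(frozen=True)
class TargetPeriod:
    """One constant-target period of the staircase, in absolute run time."""

    mac_fraction: float
    t_start_s: float
    t_end_s: float

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass(frozen=True)
class TargetSchedule:
    """Ordered (MAC fraction, duration) steps; recording spans their sum."""

    steps: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for frac, dur in self.steps:
            if dur <= 0:
                raise ValueError(f"step durations must be > 0, got {dur}")
            if frac < 0:
                raise ValueError(f"MAC fractions must be >= 0, got {frac}")

    @property
    def total_duration_s(self) -> float:
        return sum(d for _, d in self.steps)

    def periods(self) -> list[TargetPeriod]:
        out, t = [], 0.0
        for frac, dur in self.steps:
            out.append(TargetPeriod(mac_fraction=frac, t_start_s=t, t_end_s=t + dur))
            t += dur
        return out

    def target_at(self, t_s: float) -> float:
        """MAC fraction in force at time ``t_s`` (0 outside the schedule)."""
        for p in self.periods():
            if p.t_start_s <= t_s < p.t_end_s:
                return p.mac_fraction
        return 0.0

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.steps)


def build_staircase_schedule(
    max_fraction: float = 1.5,
    step: float = 0.2,
    step_duration_s: float = 600.0,
    peak_duration_s: float = 1200.0,
) -> TargetSchedule:
    """Symmetric up/down staircase of MAC-fraction targets.

    Ascending multiples of ``step`` below ``max_fraction`` (each held for
    ``step_duration_s``), a single peak period at ``max_fraction`` held for
    ``peak_duration_s``, then the ascending steps mirrored downwards.
    Recording ends when the terminal 0.0 target is set, so the zero target
    contributes no period.  With the defaults this is 0.2…1.4 MAC in 10-min
    periods, 1.5 MAC for 20 min, back down to 0.2 MAC: 15 periods, 160 min.
    """
    if step_duration_s <= 0 or peak_duration_s <= 0:
        raise ValueError("durations must be > 0")
    if step <= 0 or max_fraction <= 0:
        raise ValueError("step and max_fraction must be > 0")
    n = int(round(max_fraction / step))
    ascending = [round(k * step, 10) for k in range(1, n)]
    if ascending and not ascending[-1] < max_fraction - 1e-9:
        ascending = [f for f in ascending if f < max_fraction - 1e-9]
    steps = [(f, float(step_duration_s)) for f in ascending]
    steps.append((float(max_fraction), float(peak_duration_s)))
    steps.extend((f, float(step_duration_s)) for f in reversed(ascending))
    return TargetSchedule(steps=tuple(steps))
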