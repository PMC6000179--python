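"""Temperature forcing protocols T(t).

Temperatures are given in degrees Celsius at the interface and converted to
Kelvin internally; times are in seconds.  Every protocol exposes its
discontinuity times (jumps in T or its first derivative) so the integrator
can be restarted there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

CELSIUS_OFFSET = 273.15

MINUTE = 60.0
HOUR = 3600.0
DAY = 86400.0


def celsius_to_kelvin(T_celsius: float) -> float:
    return T_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(T_kelvin: float) -> float:
    return T_kelvin - CELSIUS_OFFSET


@dataclass(frozen=True)
class TemperatureProtocol:
    """Base class: a temperature trace T(t) with known kinks."""

    def temperature_at(self, t: float) -> float:
        """Temperature in Kelvin at time t (s)."""
        raise NotImplementedError

    def discontinuity_times(self) -> list[float]:
        """Times where T or dT/dt jumps, in increasing order."""
        return []

    @property
    def initial_temperature(self) -> float:
        """Temperature in Kelvin at t = 0."""
        return self.temperature_at(0.0)


@dataclass(frozen=True)
class Constant(TemperatureProtocol):
    T: float  # degC

    def temperature_at(self, t: float) -> float:
        return celsius_to_kelvin(self.T)


@dataclass(frozen=True)
class Step(TemperatureProtocol):
    """T_low before t_shift, T_high from t_shift on."""

    T_low: float   # degC
    T_high: float  # degC
    t_shift: float = 0.0  # s

    def __post_init__(self):
        if self.T_high < self.T_low:
            raise ValueError("T_high must be >= T_low")

    def temperature_at(self, t: float) -> float:
        return celsius_to_kelvin(self.T_high if t >= self.t_shift else self.T_low)

    def discontinuity_times(self) -> list[float]:
        return [self.t_shift]


@dataclass(frozen=True)
class Pulse(TemperatureProtocol):
    """T_high only inside [t_shift, t_shift + duration)."""

    T_low: float
    T_high: float
    t_shift: float
    duration: float  # s

    def __post_init__(self):
        if self.T_high < self.T_low:
            raise ValueError("T_high must be >= T_low")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def temperature_at(self, t: float) -> float:
        inside = self.t_shift <= t < self.t_shift + self.duration
        return celsius_to_kelvin(self.T_high if inside else self.T_low)

    def discontinuity_times(self) -> list[float]:
        return [self.t_shift, self.t_shift + self.duration]


@dataclass(frozen=True)
class DoublePulse(TemperatureProtocol):
    """Two identical heat pulses.

    By default ``interval`` is the recovery time between the END of the first
    pulse and the START of the second; with ``interval_from_start=True`` it is
    measured start-to-start.
    """

    T_low: float
    T_high: float
    t_shift: float
    duration: float
    interval: float  # s
    interval_from_start: bool = False

    def __post_init__(self):
        if self.T_high < self.T_low:
            raise ValueError("T_high must be >= T_low")
        if self.duration <= 0 or self.interval <= 0:
            raise ValueError("duration and interval must be positive")
        if self.interval_from_start and self.interval <= self.duration:
            raise ValueError("start-to-start interval must exceed the duration")

    @property
    def second_start(self) -> float:
        if self.interval_from_start:
            return self.t_shift + self.interval
        return self.t_shift + self.duration + self.interval

    def temperature_at(self, t: float) -> float:
        in_first = self.t_shift <= t < self.t_shift + self.duration
        in_second = self.second_start <= t < self.second_start + self.duration
        return celsius_to_kelvin(self.T_high if in_first or in_second else self.T_low)

    def discontinuity_times(self) -> list[float]:
        return [self.t_shift, self.t_shift + self.duration,
                self.second_start, self.second_start + self.duration]


@dataclass(frozen=True)
class Sinusoid(TemperatureProtocol):
    """Smooth diel cycle with the maximum at a fixed clock time.

    ``t = 0`` is midnight; ``t_peak`` is the clock time of the daily maximum
    in seconds after midnight (default 15:00).
    """

    T_min: float
    T_max: float
    period: float = DAY
    t_peak: float = 15 * HOUR

    def __post_init__(self):
        if self.T_max < self.T_min:
            raise ValueError("T_max must be >= T_min")
        if self.period <= 0:
            raise ValueError("period must be positive")

    def temperature_at(self, t: float) -> float:
        phase = 2.0 * math.pi * (t - self.t_peak) / self.period
        T = self.T_min + (self.T_max - self.T_min) * 0.5 * (1.0 + math.cos(phase))
        return celsius_to_kelvin(T)


@dataclass(frozen=True)
class CosineRamp(TemperatureProtocol):
    """Half-cosine rise from T_low to T_high over a ramp time tau.

    T_low before ``t_start``; smooth monotone half-cosine on
    [t_start, t_start + tau]; T_high afterwards.  As tau -> 0 this degrades
    gracefully to a step.
    """

    T_low: float
    T_high: float
    t_start: float
    tau: float  # s

    def __post_init__(self):
        if self.T_high < self.T_low:
            raise ValueError("T_high must be >= T_low")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def temperature_at(self, t: float) -> float:
        if t < self.t_start:
            T = self.T_low
        elif t < self.t_start + self.tau:
            x = (t - self.t_start) / self.tau
            T = self.T_low + (self.T_high - self.T_low) * 0.5 * (1.0 - math.cos(math.pi * x))
        else:
            T = self.T_high
        return celsius_to_kelvin(T)

    def discontinuity_times(self) -> list[float]:
        return [self.t_start, self.t_start + self.tau]


def temperature_at(protocol: TemperatureProtocol, t: float) -> float:
    """Temperature in Kelvin at time t (s) under the protocol."""
    return protocol.temperature_at(t)


def discontinuity_times(protocol: TemperatureProtocol) -> list[float]:
    """Ordered times where the protocol or its slope is discontinuous."""
    return protocol.discontinuity_times()
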