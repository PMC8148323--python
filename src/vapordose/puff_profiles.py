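"""Transient flow waveforms: e-cigarette puffs, exhalation, nasal breathing.

Sign convention (package-wide): positive flow is *into* the airway
(inhalation), negative flow is out (exhalation).  Every constructed
waveform is normalized so that its trapezoidal integral equals the
requested volume to machine precision — the volumes, not the exact curve
shapes, are the quantities the downstream dose accounting depends on.

Three puff scenarios are supported, distinguished by their inhalation and
exhalation times: short puff (2.43 s in / 1.8 s out), long puff
(5.0 s / 1.8 s) and post puff (1.34 s / 2.5 s), the last being the short,
high-flow mouth-to-lung inhalation that drives vapor toward the bronchial
generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "FlowWaveform",
    "BreathingCycle",
    "PUFF_KINDS",
    "build_puff",
    "build_exhalation",
    "build_nasal_cycle",
    "sample_cycle",
    "waveform_volume",
    "concat_waveforms",
    "standard_puff_timings",
]

PUFF_KINDS = ("short_puff", "long_puff", "post_puff", "exhalation", "custom")

#: (inhalation time s, exhalation time s) per puff scenario.
STANDARD_TIMINGS = {
    "short_puff": (2.43, 1.8),
    "long_puff": (5.0, 1.8),
    "post_puff": (1.34, 2.5),
}

#: Default sampling step, s.  Resolves the shortest (1.34 s) inhalation
#: with >100 points.
DEFAULT_DT = 0.01

#: Default mouth-puff volume, m^3 (55 mL, machine-smoking convention).
DEFAULT_PUFF_VOLUME = 55e-6

#: Default post-puff (mouth-to-lung) inhaled volume, m^3: a deep breath,
#: not a mouth puff.
DEFAULT_POST_PUFF_VOLUME = 500e-6


def standard_puff_timings(kind: str) -> tuple[float, float]:
    """(inhalation, exhalation) durations in seconds for a named scenario."""
    try:
        return STANDARD_TIMINGS[kind]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown puff kind {kind!r}; expected one of {sorted(STANDARD_TIMINGS)}"
        ) from None


@dataclass
class FlowWaveform:
    """A signed volumetric flow time series.

    ``times`` is a strictly increasing grid starting at 0 (s); ``flow`` is
    the volumetric flow at each grid point (m^3/s), positive into the
    airway.
    """

    times: np.ndarray
    flow: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.flow.shape:
            raise InvalidArgumentError("times and flow must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise InvalidArgumentError("a waveform needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if not np.all(np.isfinite(self.flow)):
            raise InvalidArgumentError("flow must be finite everywhere")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def volume(self) -> float:
        """Signed trapezoidal integral of flow, m^3."""
        return float(np.trapezoid(self.flow, self.times))

    def interpolator(self):
        """Return q(t): flow linearly interpolated, zero outside support."""
        t, q = self.times, self.flow

        def _q(tq):
            return np.interp(tq, t, q, left=0.0, right=0.0)

        return _q

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "flow_m3s": self.flow}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "custom") -> "FlowWaveform":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["flow_m3s"].to_numpy(), label=label)


@dataclass
class BreathingCycle:
    """A periodic nasal breathing pattern (sinusoidal half-waves).

    ``minute_volume`` is the *inhaled* air volume per minute (m^3/min);
    ``inhale_fraction`` is the fraction of the period spent inhaling.
    """

    period: float
    minute_volume: float
    inhale_fraction: float = 0.5
    waveform_shape: str = "sinusoidal"

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise InvalidArgumentError("period must be positive")
        if self.minute_volume <= 0:
            raise InvalidArgumentError("minute_volume must be positive")
        if not 0.0 < self.inhale_fraction < 1.0:
            raise InvalidArgumentError("inhale_fraction must be in (0, 1)")
        if self.waveform_shape != "sinusoidal":
            raise InvalidArgumentError("only sinusoidal breathing cycles are supported")

    @property
    def tidal_volume(self) -> float:
        """Inhaled volume per breath, m^3."""
        return self.minute_volume * self.period / 60.0

    def flow_at(self, t):
        """Signed nasal flow (m^3/s) at time(s) t; exact function of t mod period."""
        t = np.asarray(t, dtype=float)
        phase = np.mod(t, self.period)
        t_in = self.inhale_fraction * self.period
        t_ex = self.period - t_in
        v = self.tidal_volume
        q_in = math.pi * v / (2.0 * t_in)
        q_ex = math.pi * v / (2.0 * t_ex)
        inhale = q_in * np.sin(math.pi * phase / t_in)
        exhale = -q_ex * np.sin(math.pi * (phase - t_in) / t_ex)
        return np.where(phase < t_in, inhale, exhale)


def _shape_samples(shape: str, times: np.ndarray, duration: float, peak_frac: float) -> np.ndarray:
    if shape == "half_sine":
        # clamp: sin(pi * t/T) can round to a tiny negative at the endpoint
        return np.maximum(np.sin(math.pi * times / duration), 0.0)
    if shape == "triangular":
        t_peak = peak_frac * duration
        up = times / t_peak
        down = (duration - times) / (duration - t_peak)
        return np.maximum(np.minimum(up, down), 0.0)
    raise InvalidArgumentError(f"unknown waveform shape {shape!r}")


def build_puff(
    kind: str,
    duration: float,
    volume: float,
    shape: str = "half_sine",
    dt: float = DEFAULT_DT,
    peak_frac: float = 0.3,
) -> FlowWaveform:
    """Build an inhalation waveform of the given support and volume.

    The discrete trapezoidal integral is renormalized to equal ``volume``
    exactly, so for a half-sine the peak flow is pi*V/(2*T) up to O(dt^2).
    ``triangular`` with an early ``peak_frac`` models the high-initial-flow
    post puff.
    """
    if kind not in PUFF_KINDS:
        raise InvalidArgumentError(f"unknown puff kind {kind!r}")
    if duration <= 0 or volume <= 0:
        raise InvalidArgumentError("duration and volume must be positive")
    if dt <= 0 or dt >= duration:
        raise InvalidArgumentError("dt must be positive and smaller than duration")
    if not 0.0 < peak_frac < 1.0:
        raise InvalidArgumentError("peak_frac must be in (0, 1)")
    n = max(int(round(duration / dt)), 4)
    times = np.linspace(0.0, duration, n + 1)
    flow = _shape_samples(shape, times, duration, peak_frac)
    area = np.trapezoid(flow, times)
    return FlowWaveform(times, flow * (volume / area), label=kind)


def build_exhalation(volume: float, duration: float, dt: float = DEFAULT_DT) -> FlowWaveform:
    """Half-sine exhalation (negative-signed) of |integral| = volume."""
    w = build_puff("custom", duration, volume, shape="half_sine", dt=dt)
    return FlowWaveform(w.times, -w.flow, label="exhalation")


def build_nasal_cycle(
    minute_volume: float, period: float, inhale_fraction: float = 0.5
) -> BreathingCycle:
    """A sinusoidal nasal breathing cycle with the stated minute volume."""
    return BreathingCycle(period=period, minute_volume=minute_volume, inhale_fraction=inhale_fraction)


def sample_cycle(
    cycle: BreathingCycle, t_start: float, t_end: float, dt: float = DEFAULT_DT
) -> FlowWaveform:
    """Sample a breathing cycle on [t_start, t_end] as a FlowWaveform.

    The returned waveform's times are re-zeroed to start at 0; the flow at
    returned time tau equals the cycle flow at t_start + tau, so sampling a
    window shifted by one whole period reproduces the flow values
    bit-exactly.
    """
    if t_end <= t_start:
        raise InvalidArgumentError("t_end must exceed t_start")
    if dt <= 0 or t_end - t_start < dt:
        raise InvalidArgumentError("window must be at least one dt long")
    n = int(round((t_end - t_start) / dt))
    times = np.arange(n + 1) * dt
    # reduce the window start modulo the period first, so windows shifted by
    # whole periods sample bit-identical flow values
    phase0 = math.fmod(t_start, cycle.period)
    flow = cycle.flow_at(phase0 + times)
    return FlowWaveform(times, flow, label="custom")


def waveform_volume(w: FlowWaveform) -> float:
    """Signed trapezoidal volume of a waveform, m^3."""
    return w.volume()


def concat_waveforms(parts: Iterable[FlowWaveform], gap: float = 0.0) -> FlowWaveform:
    """Concatenate waveforms in time, optionally separated by zero-flow gaps."""
    parts = list(parts)
    if not parts:
        raise InvalidArgumentError("need at least one waveform")
    times = [parts[0].times]
    flows = [parts[0].flow]
    for w in parts[1:]:
        t0 = times[-1][-1]
        if gap > 0:
            times.append(np.array([t0 + 1e-9, t0 + gap]))
            flows.append(np.zeros(2))
            t0 = t0 + gap
        times.append(t0 + w.times + 1e-9)
        flows.append(w.flow)
    return FlowWaveform(np.concatenate(times), np.concatenate(flows), label="custom")
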