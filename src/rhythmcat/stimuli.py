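"""Rhythm stimuli: the performance-space grid, trial assembly, and
stimulus encoding.

A rhythm here is a 1-s pattern of four sound onsets, uniquely determined
by its three inter-onset intervals (IOIs).  The study grid places the
IOIs on a 1/19-s lattice with each IOI at least 3/19 s, which yields the
66 points of the triangular performance space.  A trial embeds a rhythm
in an 8-bar (8-s) sequence — the rhythm sounding in bars 3, 5 and 7 —
optionally interleaved with duple- or triple-meter priming beats, and is
finally rendered as a rectangular-pulse forcing signal for the
oscillator bank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import EncodeConfig, GridConfig, TrialConfig
from .errors import ConfigurationError, ValidationError

__all__ = [
    "RhythmSequence", "MeterCondition", "OnsetTrain", "StimulusSignal",
    "NO_METER", "DUPLE", "TRIPLE", "meter_condition",
    "generate_grid", "make_trial", "encode_stimulus",
    "write_grid_csv", "read_grid_csv",
]

_TOL = 1e-9


@dataclass(frozen=True)
class RhythmSequence:
    """A four-onset rhythm given by its three IOIs (seconds).

    ``grid_units`` holds the integer lattice numerators (over the grid
    denominator) for grid-generated rhythms; ``label`` is a free-text
    identifier such as ``"5-6-8"``.
    """
    iois: tuple[float, float, float]
    grid_units: tuple[int, int, int] | None = None
    label: str | None = None

    def __post_init__(self):
        if len(self.iois) != 3:
            raise ValidationError("a rhythm sequence has exactly three IOIs")
        if any(ioi <= 0 for ioi in self.iois):
            raise ValidationError("IOIs must be positive")
        object.__setattr__(self, "iois", tuple(float(v) for v in self.iois))

    @property
    def total(self) -> float:
        return sum(self.iois)

    @property
    def id(self) -> str:
        if self.label is not None:
            return self.label
        return "-".join(f"{ioi:.6g}" for ioi in self.iois)

    def onsets_within_bar(self) -> tuple[float, float, float]:
        """Offsets of the first three onsets within the bar; the fourth
        onset falls on the next bar's downbeat."""
        a, b, _ = self.iois
        return (0.0, a, a + b)


@dataclass(frozen=True)
class MeterCondition:
    """A metric priming condition: onset offsets (s) sounded in each
    priming bar.  Duple primes two isochronous beats per bar, triple
    three; the no-meter condition primes nothing."""
    name: str
    priming_onsets_per_bar: tuple[float, ...] = ()

    def __post_init__(self):
        if any(not (0 <= t < 1) for t in self.priming_onsets_per_bar):
            raise ValidationError("priming onsets must lie in [0, 1) within the bar")


NO_METER = MeterCondition("none", ())
DUPLE = MeterCondition("duple", (0.0, 0.5))
TRIPLE = MeterCondition("triple", (0.0, 1 / 3, 2 / 3))

_CONDITIONS = {c.name: c for c in (NO_METER, DUPLE, TRIPLE)}


def meter_condition(name: str) -> MeterCondition:
    try:
        return _CONDITIONS[name]
    except KeyError:
        raise ValidationError(
            f"unknown meter condition {name!r}; expected one of {sorted(_CONDITIONS)}"
        ) from None


@dataclass(frozen=True)
class OnsetTrain:
    """Sound onset times (s), nondecreasing, within [0, total_duration]."""
    onset_times: tuple[float, ...]
    total_duration: float

    def __post_init__(self):
        ts = tuple(float(t) for t in self.onset_times)
        if any(t2 < t1 for t1, t2 in zip(ts, ts[1:])):
            raise ValidationError("onset times must be nondecreasing")
        if ts and (ts[0] < -_TOL or ts[-1] > self.total_duration + _TOL):
            raise ValidationError("onset times must lie within [0, total_duration]")
        object.__setattr__(self, "onset_times", ts)


@dataclass(frozen=True)
class StimulusSignal:
    """Sampled nonnegative forcing signal x(t) for the oscillator bank."""
    samples: np.ndarray
    sample_rate: float
    pulse_width: float
    pulse_amplitude: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValidationError("stimulus samples must be one-dimensional")
        if samples.size and samples.min() < 0:
            raise ValidationError("stimulus samples must be nonnegative")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def generate_grid(total: float = 1.0, step: float = 1 / 19,
                  min_ioi: float = 3 / 19) -> list[RhythmSequence]:
    """Enumerate every IOI triple on the step lattice summing to ``total``
    with each IOI >= ``min_ioi``, in lexicographic (ioi1, ioi2) order.

    With the study defaults (1 s total, 1/19-s step, 3/19-s floor) this
    is the grid of 66 rhythms; in general the count is the number of
    compositions of U = total/step into three parts >= m = min_ioi/step,
    i.e. C(U - 3m + 2, 2).
    """
    if total <= 0 or step <= 0:
        raise ConfigurationError("total and step must be positive")
    units = total / step
    min_units = min_ioi / step
    if abs(units - round(units)) > 1e-6 or abs(min_units - round(min_units)) > 1e-6:
        raise ConfigurationError(
            "step must divide total and min_ioi into integer unit counts")
    units = round(units)
    min_units = round(min_units)
    if min_units < 1:
        raise ConfigurationError("min_ioi must be at least one grid step")

    rhythms = []
    for k1 in range(min_units, units - 2 * min_units + 1):
        for k2 in range(min_units, units - k1 - min_units + 1):
            k3 = units - k1 - k2
            rhythms.append(RhythmSequence(
                iois=(k1 * step, k2 * step, k3 * step),
                grid_units=(k1, k2, k3),
                label=f"{k1}-{k2}-{k3}",
            ))
    return rhythms


def grid_from_config(cfg: GridConfig) -> list[RhythmSequence]:
    step = cfg.total_s / cfg.step_denominator
    return generate_grid(cfg.total_s, step, cfg.min_units * step)


def _merge_onsets(times: Iterable[float]) -> tuple[float, ...]:
    """Sort and merge coincident onsets: one physical sound event."""
    out: list[float] = []
    for t in sorted(times):
        if not out or t - out[-1] > _TOL:
            out.append(t)
    return tuple(out)


def make_trial(rhythm: RhythmSequence,
               condition: MeterCondition = NO_METER,
               trial: TrialConfig | None = None) -> OnsetTrain:
    """Assemble the 8-bar trial onset schedule for one rhythm.

    The rhythm sounds in bars 3, 5 and 7 (1-indexed): its first three
    onsets at the bar start plus cumulative IOI offsets, its fourth on
    the following bar's downbeat.  Meter conditions add priming onsets
    in the designated priming bars; coincident onsets are merged.
    """
    trial = trial or TrialConfig()
    if abs(rhythm.total - trial.bar_s) > _TOL:
        raise ValidationError(
            f"rhythm IOIs sum to {rhythm.total!r}, expected bar length {trial.bar_s!r}")
    total_duration = trial.bars * trial.bar_s

    onsets: list[float] = []
    for bar in trial.rhythm_bars:
        start = (bar - 1) * trial.bar_s
        onsets.extend(start + off for off in rhythm.onsets_within_bar())
        onsets.append(start + trial.bar_s)  # fourth onset: next downbeat
    for bar in trial.priming_bars:
        start = (bar - 1) * trial.bar_s
        onsets.extend(start + off * trial.bar_s
                      for off in condition.priming_onsets_per_bar)
    return OnsetTrain(_merge_onsets(onsets), total_duration)


def encode_stimulus(train: OnsetTrain,
                    sample_rate: float = 1000.0,
                    pulse_width: float = 0.02,
                    pulse_amplitude: float = 0.25,
                    epsilon: float = 0.5) -> StimulusSignal:
    """Render an onset train as a rectangular-pulse signal.

    Each onset contributes a pulse of ``pulse_width`` s at
    ``pulse_amplitude``; overlapping pulses take the maximum (one sound,
    not a louder one).  ``epsilon`` is used only to verify that
    sqrt(eps) * amplitude < 1 so the stimulus coupling term stays finite.
    """
    if sample_rate * pulse_width < 1:
        raise ConfigurationError("sample_rate * pulse_width must be >= 1")
    if pulse_amplitude * math.sqrt(epsilon) >= 1:
        raise ConfigurationError(
            "pulse_amplitude * sqrt(epsilon) >= 1: coupling term diverges")
    n = math.ceil(train.total_duration * sample_rate)
    samples = np.zeros(n)
    width = max(1, round(pulse_width * sample_rate))
    for t in train.onset_times:
        i0 = round(t * sample_rate)
        i1 = min(n, i0 + width)
        if i0 < n:
            samples[i0:i1] = np.maximum(samples[i0:i1], pulse_amplitude)
    return StimulusSignal(samples, sample_rate, pulse_width, pulse_amplitude)


def encode_from_config(train: OnsetTrain, cfg: EncodeConfig,
                       epsilon: float = 0.5) -> StimulusSignal:
    return encode_stimulus(train, cfg.sample_rate_hz, cfg.pulse_width_s,
                           cfg.pulse_amplitude, epsilon)


def write_grid_csv(rhythms: Sequence[RhythmSequence], path: str | Path) -> None:
    """Write a rhythm grid as CSV with columns
    id, ioi1_s, ioi2_s, ioi3_s, k1, k2, k3."""
    rows = []
    for r in rhythms:
        k = r.grid_units or (math.nan, math.nan, math.nan)
        rows.append({"id": r.id, "ioi1_s": r.iois[0], "ioi2_s": r.iois[1],
                     "ioi3_s": r.iois[2], "k1": k[0], "k2": k[1], "k3": k[2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_grid_csv(path: str | Path) -> list[RhythmSequence]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        units = None
        if not any(pd.isna(row[c]) for c in ("k1", "k2", "k3")):
            units = (int(row.k1), int(row.k2), int(row.k3))
        out.append(RhythmSequence((row.ioi1_s, row.ioi2_s, row.ioi3_s),
                                  grid_units=units, label=str(row.id)))
    return out
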