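"""Activation patterns and the signal-to-noise consistency statistic.

The oscillator bank's response to a trial is reduced to an *activation
pattern*: per oscillator, the sum of its amplitude over a time window,

    A_i = sum_{t = t_s}^{t_e} a_{i,t}        (inclusive at both ends)

with t_s at half the stimulus length and t_e at the last step by
default, so the initial transient from the resting state is discarded.
The pattern is a point in n-dimensional state space and is never
normalized.

Distinctness of a pattern is measured by a signal-to-noise ratio,

    SNR = A_s / sum_{i != s} A_i,   s = argmax_i A_i,

which predicts how consistently listeners categorize the rhythm: a
pattern dominated by few oscillators (high SNR) is a distinct state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedSNRError, ValidationError
from .oscillators import AmplitudeTimeSeries
from .stimuli import MeterCondition, NO_METER, RhythmSequence

__all__ = [
    "ActivationWindow", "ActivationPattern",
    "activation_pattern", "half_window", "snr", "snr_map",
    "dynamic_activation", "write_snr_csv", "write_pattern_csv",
]

_TOL = 1e-9


@dataclass(frozen=True)
class ActivationWindow:
    """Summation window [t_start, t_end] in seconds, inclusive."""
    t_start: float
    t_end: float

    def __post_init__(self):
        if not (0 <= self.t_start < self.t_end):
            raise ValidationError("need 0 <= t_start < t_end")

    def step_indices(self, sample_rate: float, n_steps: int) -> tuple[int, int]:
        """Inclusive step-index range covered by the window on a grid of
        ``n_steps`` samples at ``sample_rate``."""
        lo = int(np.ceil(self.t_start * sample_rate - _TOL))
        hi = int(np.floor(self.t_end * sample_rate + _TOL))
        lo = max(lo, 0)
        hi = min(hi, n_steps - 1)
        if hi < lo:
            raise ValidationError("window contains no integration steps")
        return lo, hi


@dataclass(frozen=True)
class ActivationPattern:
    """Summed amplitude A_i per oscillator over a window."""
    values: np.ndarray
    frequencies: np.ndarray
    window: ActivationWindow

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        if v.shape != f.shape:
            raise ValidationError("values and frequencies must align")
        if v.size and v.min() < -_TOL:
            raise ValidationError("activation entries must be nonnegative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "frequencies", f)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def peak_frequency(self) -> float:
        """Frequency of the signal oscillator A_s (ties -> lowest index)."""
        return float(self.frequencies[int(np.argmax(self.values))])


def half_window(duration: float) -> ActivationWindow:
    """The default window: the second half of the trial."""
    return ActivationWindow(duration / 2, duration)


def activation_pattern(ts: AmplitudeTimeSeries,
                       window: ActivationWindow | None = None) -> ActivationPattern:
    """Sum each oscillator's amplitude over the window (inclusive)."""
    window = window or half_window(ts.duration)
    if window.t_end > ts.duration + _TOL:
        raise ValidationError("window extends beyond the time series")
    lo, hi = window.step_indices(ts.sample_rate, ts.n_steps)
    values = ts.amplitudes[:, lo:hi + 1].sum(axis=1)
    return ActivationPattern(values, ts.frequencies, window)


def snr(pattern: ActivationPattern) -> float:
    """Peak activation over the summed rest; +inf when the rest is zero.

    Raises UndefinedSNRError for an all-zero pattern — no activity is
    not the same thing as perfectly concentrated activity.
    """
    if pattern.n < 2:
        raise ValidationError("SNR needs at least two oscillators")
    v = pattern.values
    s = int(np.argmax(v))  # ties -> lowest index
    rest = v.sum() - v[s]
    if v[s] == 0:
        raise UndefinedSNRError("SNR of an all-zero activation pattern is undefined")
    if rest == 0:
        return float("inf")
    return float(v[s] / rest)


def snr_map(rhythms: Sequence[RhythmSequence],
            condition: MeterCondition = NO_METER,
            config=None) -> pd.DataFrame:
    """SNR for each rhythm through the full pipeline
    (trial -> encode -> integrate -> activation -> SNR); deterministic.

    Returns a DataFrame with columns id, k1, k2, k3, snr.
    """
    from .pipeline import condition_activation_matrix  # lazy: avoids cycle
    from .config import ModelConfig
    config = config or ModelConfig()
    patterns = condition_activation_matrix(rhythms, condition, config)
    rows = []
    for r, values in zip(rhythms, patterns):
        pat = ActivationPattern(values, patterns.frequencies,
                                patterns.window)
        k = r.grid_units or (np.nan, np.nan, np.nan)
        rows.append({"id": r.id, "k1": k[0], "k2": k[1], "k3": k[2],
                     "snr": snr(pat)})
    return pd.DataFrame(rows)


def dynamic_activation(ts: AmplitudeTimeSeries, t: float,
                       mode: str = "proportional",
                       t_start: float = 0.0) -> ActivationPattern:
    """Activation pattern of the trial truncated at time ``t``.

    ``proportional`` applies the half-window rule to the truncated
    trial, summing over [t/2, t]; ``fixed_start`` sums over
    [t_start, t], a plain cumulative window.  Evaluated over a sweep of
    t this yields the category-over-time traces of the dynamic readout.
    """
    if t > ts.duration + _TOL:
        raise ValidationError("t beyond the time series extent")
    if mode == "proportional":
        window = ActivationWindow(t / 2, t)
    elif mode == "fixed_start":
        window = ActivationWindow(t_start, t)
    else:
        raise ValidationError("mode must be proportional|fixed_start")
    if t <= 0 or window.t_end - window.t_start < 1 / ts.sample_rate:
        raise ValidationError("t too small to contain an integration step")
    return activation_pattern(ts, window)


def write_snr_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_pattern_csv(pattern: ActivationPattern, path: str | Path) -> None:
    pd.DataFrame({"f_hz": pattern.frequencies,
                  "A": pattern.values}).to_csv(path, index=False)
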