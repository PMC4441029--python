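"""End-to-end runs: rhythm -> trial -> stimulus -> bank -> activation.

The map-level entry point batches all rhythms of a condition through
one vectorized integration, accumulating the window sums on the fly,
which is arithmetic-identical to integrating each trial separately and
then summing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .activation import ActivationPattern, ActivationWindow, half_window
from .config import ModelConfig
from .oscillators import (AmplitudeTimeSeries, OscillatorBank,
                          bank_from_config, integrate, integrate_window_sums)
from .stimuli import (MeterCondition, NO_METER, RhythmSequence, StimulusSignal,
                      encode_from_config, make_trial)

__all__ = [
    "ActivationMatrix", "trial_stimulus", "rhythm_amplitudes",
    "rhythm_activation", "condition_activation_matrix",
]


@dataclass(frozen=True)
class ActivationMatrix:
    """Activation patterns for a batch of rhythms: rows align with the
    rhythm list that produced them."""
    values: np.ndarray          # (n_rhythms, n_oscillators)
    frequencies: np.ndarray
    window: ActivationWindow

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.values)

    def pattern(self, row: int) -> ActivationPattern:
        return ActivationPattern(self.values[row], self.frequencies, self.window)


def trial_stimulus(rhythm: RhythmSequence,
                   condition: MeterCondition = NO_METER,
                   config: ModelConfig | None = None) -> StimulusSignal:
    """Assemble and encode the 8-bar trial for one rhythm."""
    config = config or ModelConfig()
    train = make_trial(rhythm, condition, config.trial)
    return encode_from_config(train, config.encode, config.hopf.epsilon)


def _bank_and_window(config: ModelConfig, duration: float,
                     n_steps: int) -> tuple[OscillatorBank, ActivationWindow, tuple[int, int]]:
    bank = bank_from_config(config.bank, config.hopf)
    if config.window.mode == "half":
        window = half_window(duration)
    else:
        window = ActivationWindow(config.window.t_start_s, config.window.t_end_s)
    return bank, window, window.step_indices(config.encode.sample_rate_hz, n_steps)


def rhythm_amplitudes(rhythm: RhythmSequence,
                      condition: MeterCondition = NO_METER,
                      config: ModelConfig | None = None) -> AmplitudeTimeSeries:
    """Full amplitude trajectories for one rhythm (for the dynamic
    readout and activation-over-time figures)."""
    config = config or ModelConfig()
    stim = trial_stimulus(rhythm, condition, config)
    bank = bank_from_config(config.bank, config.hopf)
    return integrate(bank, stim, radical=config.coupling.radical)


def rhythm_activation(rhythm: RhythmSequence,
                      condition: MeterCondition = NO_METER,
                      config: ModelConfig | None = None) -> ActivationPattern:
    """Activation pattern for one rhythm through the full pipeline."""
    config = config or ModelConfig()
    mat = condition_activation_matrix([rhythm], condition, config)
    return mat.pattern(0)


def condition_activation_matrix(rhythms: Sequence[RhythmSequence],
                                condition: MeterCondition = NO_METER,
                                config: ModelConfig | None = None) -> ActivationMatrix:
    """Activation patterns for every rhythm of one condition.

    All trials of the condition share a duration, so they stack into one
    (n_rhythms, n_samples) stimulus matrix integrated in a single
    vectorized RK4 pass that accumulates the window sums directly.
    """
    config = (config or ModelConfig()).validate()
    stims = [trial_stimulus(r, condition, config) for r in rhythms]
    lengths = {s.samples.size for s in stims}
    if len(lengths) != 1:
        raise ValueError("all trials in a condition must share a duration")
    X = np.stack([s.samples for s in stims])
    duration = stims[0].duration
    n_steps = X.shape[1] + 1
    bank, window, idx = _bank_and_window(config, duration, n_steps)
    sums = integrate_window_sums(bank, X, config.encode.sample_rate_hz, idx,
                                 radical=config.coupling.radical)
    return ActivationMatrix(sums, bank.frequencies, window)
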