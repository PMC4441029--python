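"""Structured model configuration.

Every tunable of the model lives here, grouped the way the pipeline is
staged: grid generation, trial assembly, stimulus encoding, oscillator
bank, Hopf parameters, coupling convention, integration, activation
window, dynamic readout, distance metric, and permutation testing.

Configs load from YAML; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

__all__ = [
    "GridConfig", "TrialConfig", "EncodeConfig", "BankConfig", "HopfConfig",
    "CouplingConfig", "IntegrateConfig", "WindowConfig", "DynamicConfig",
    "DistanceConfig", "PermConfig", "PrototypesConfig", "ModelConfig",
    "load_config",
]


@dataclass(frozen=True)
class GridConfig:
    """Performance-space grid: IOI triples of ``total_s`` seconds on a
    1/``step_denominator``-s lattice with at least ``min_units`` per IOI."""
    total_s: float = 1.0
    step_denominator: int = 19
    min_units: int = 3


@dataclass(frozen=True)
class TrialConfig:
    """8-bar trial layout.  Bars are 1-indexed; the rhythm occupies bars
    3, 5 and 7 and metric priming fills the interleaved bars so that the
    induced beat persists through the rhythm presentations."""
    bars: int = 8
    bar_s: float = 1.0
    rhythm_bars: tuple[int, ...] = (3, 5, 7)
    priming_bars: tuple[int, ...] = (1, 2, 4, 6, 8)


@dataclass(frozen=True)
class EncodeConfig:
    """Onset-train to forcing-signal encoding: rectangular pulses."""
    sample_rate_hz: float = 1000.0
    pulse_width_s: float = 0.02
    pulse_amplitude: float = 0.25


@dataclass(frozen=True)
class BankConfig:
    """Gradient-frequency bank: n log-spaced intrinsic frequencies."""
    n: int = 145
    f_min_hz: float = 0.25
    f_max_hz: float = 4.0


@dataclass(frozen=True)
class HopfConfig:
    """Hopf oscillator parameters: alpha damping, beta amplitude
    compression, epsilon scale factor."""
    alpha: float = -0.1
    beta: float = -0.1
    epsilon: float = 0.5


@dataclass(frozen=True)
class CouplingConfig:
    """Radical convention in the stimulus-coupling denominators.

    ``sqrt``  -> x/(1 - sqrt(eps) x) * 1/(1 - sqrt(eps) conj(z))
    ``plain`` -> x/(1 - eps x)       * 1/(1 - eps z)
    """
    radical: str = "sqrt"

    def __post_init__(self):
        if self.radical not in ("sqrt", "plain"):
            raise ConfigurationError(
                f"coupling.radical must be 'sqrt' or 'plain', got {self.radical!r}")


@dataclass(frozen=True)
class IntegrateConfig:
    """Numerical integration: fixed-step RK4 at ``step_hz`` steps/s."""
    method: str = "rk4"
    step_hz: float = 1000.0

    def __post_init__(self):
        if self.method != "rk4":
            raise ConfigurationError(f"unsupported integrator {self.method!r}")


@dataclass(frozen=True)
class WindowConfig:
    """Activation window. ``mode='half'`` sums the second half of the
    trial; ``mode='explicit'`` uses [t_start_s, t_end_s]."""
    mode: str = "half"
    t_start_s: float | None = None
    t_end_s: float | None = None

    def __post_init__(self):
        if self.mode not in ("half", "explicit"):
            raise ConfigurationError(f"window.mode must be half|explicit, got {self.mode!r}")
        if self.mode == "explicit" and (self.t_start_s is None or self.t_end_s is None):
            raise ConfigurationError("explicit window requires t_start_s and t_end_s")


@dataclass(frozen=True)
class DynamicConfig:
    """Windowing rule for time-resolved activation: ``proportional``
    mirrors the half-window rule at every t ([t/2, t]); ``fixed_start``
    keeps t_start pinned and grows the window."""
    window: str = "proportional"

    def __post_init__(self):
        if self.window not in ("proportional", "fixed_start"):
            raise ConfigurationError(
                f"dynamic.window must be proportional|fixed_start, got {self.window!r}")


@dataclass(frozen=True)
class DistanceConfig:
    """Pattern-space metric for nearest-prototype classification.
    Euclidean is the model's definition; cosine is exposed for
    sensitivity analysis only."""
    metric: str = "euclidean"

    def __post_init__(self):
        if self.metric not in ("euclidean", "cosine"):
            raise ConfigurationError(f"distance.metric must be euclidean|cosine")


@dataclass(frozen=True)
class PermConfig:
    """Randomized permutation test defaults."""
    n: int = 10_000
    seed: int = 0
    tail: str = "two"
    tail_method: str = "double"

    def __post_init__(self):
        if self.tail not in ("one", "two"):
            raise ConfigurationError("perm.tail must be one|two")
        if self.tail_method not in ("double", "extreme_count"):
            raise ConfigurationError("perm.tail_method must be double|extreme_count")


@dataclass(frozen=True)
class PrototypesConfig:
    """Prototype category list source; None -> packaged default file."""
    file: str | None = None


@dataclass(frozen=True)
class ModelConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    trial: TrialConfig = field(default_factory=TrialConfig)
    encode: EncodeConfig = field(default_factory=EncodeConfig)
    bank: BankConfig = field(default_factory=BankConfig)
    hopf: HopfConfig = field(default_factory=HopfConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    integrate: IntegrateConfig = field(default_factory=IntegrateConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    dynamic: DynamicConfig = field(default_factory=DynamicConfig)
    distance: DistanceConfig = field(default_factory=DistanceConfig)
    perm: PermConfig = field(default_factory=PermConfig)
    prototypes: PrototypesConfig = field(default_factory=PrototypesConfig)

    def validate(self) -> "ModelConfig":
        """Cross-section consistency checks; returns self for chaining."""
        import math
        if self.encode.sample_rate_hz * self.encode.pulse_width_s < 1:
            raise ConfigurationError("sample_rate_hz * pulse_width_s must be >= 1")
        if self.encode.pulse_amplitude * math.sqrt(self.hopf.epsilon) >= 1:
            raise ConfigurationError(
                "pulse_amplitude * sqrt(epsilon) must be < 1 "
                "(stimulus coupling denominator would vanish)")
        if self.hopf.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")
        return self

    def with_step_hz(self, step_hz: float) -> "ModelConfig":
        """Convenience: same model at a different integration/sampling rate."""
        return replace(self,
                       encode=replace(self.encode, sample_rate_hz=step_hz),
                       integrate=replace(self.integrate, step_hz=step_hz))


_SECTIONS = {f.name: f.type for f in fields(ModelConfig)}


def _build_section(cls, mapping: dict[str, Any], section: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    # YAML lists become tuples for frozen dataclasses
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()}
    return cls(**coerced)


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load a ModelConfig from a YAML file; ``None`` returns defaults.

    The file holds one mapping per section, e.g.::

        bank: {n: 145, f_min_hz: 0.25, f_max_hz: 4.0}
        hopf: {alpha: -0.1, beta: -0.1, epsilon: 0.5}
    """
    if path is None:
        return ModelConfig().validate()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping of sections")
    section_classes = {f.name: f.default_factory for f in fields(ModelConfig)}
    kwargs = {}
    for name, mapping in raw.items():
        if name not in section_classes:
            raise ConfigurationError(f"unknown config section {name!r}")
        cls = section_classes[name]().__class__
        kwargs[name] = _build_section(cls, mapping or {}, name)
    return ModelConfig(**kwargs).validate()
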