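"""Gradient-frequency network of stimulus-driven Hopf oscillators.

The bank holds n oscillators (default 145) with intrinsic frequencies
log-spaced over 0.25–4 Hz, geometrically centered on 1 Hz.  Each
oscillator evolves independently under the fully expanded Hopf normal
form driven by a common scalar stimulus x(t):

    dz/dt = z (alpha + i*omega + beta*eps*|z|^4 / (1 - eps*|z|^2))
            + x / (1 - sqrt(eps) x) * 1 / (1 - sqrt(eps) conj(z))

with alpha the damping term (negative: the origin is the unforced
attractor), beta the amplitude compression factor and eps the scale
factor.  The coupling denominators use the sqrt(eps)/conjugate
convention of the canonical derivation; ``radical="plain"`` switches to
the literal 1/(1 - eps x) * 1/(1 - eps z) form.

Integration is fixed-step 4th-order Runge–Kutta at the stimulus sample
rate with the stimulus held constant within each step (zero-order
hold).  There is no randomness anywhere on this path: identical inputs
give bit-identical amplitude matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import BankConfig, HopfConfig
from .errors import ConfigurationError, IntegrationError, NumericalDomainError
from .stimuli import StimulusSignal

__all__ = [
    "HopfParams", "OscillatorBank", "OscillatorState", "AmplitudeTimeSeries",
    "build_bank", "hopf_derivative", "integrate", "integrate_window_sums",
    "write_amplitudes_csv",
]

_DENOM_TOL = 1e-12


@dataclass(frozen=True)
class HopfParams:
    """alpha: damping; beta: amplitude compression; epsilon: scale."""
    alpha: float = -0.1
    beta: float = -0.1
    epsilon: float = 0.5

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")

    @classmethod
    def from_config(cls, cfg: HopfConfig) -> "HopfParams":
        return cls(cfg.alpha, cfg.beta, cfg.epsilon)


@dataclass(frozen=True)
class OscillatorBank:
    """n oscillators with strictly increasing intrinsic frequencies (Hz)."""
    frequencies: np.ndarray
    params: HopfParams = field(default_factory=HopfParams)

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size < 2:
            raise ConfigurationError("bank needs at least 2 frequencies")
        if np.any(np.diff(f) <= 0):
            raise ConfigurationError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    @property
    def n(self) -> int:
        return self.frequencies.size

    @property
    def omegas(self) -> np.ndarray:
        """Angular frequencies (rad/s) entering the ODE."""
        return 2 * np.pi * self.frequencies


@dataclass(frozen=True)
class OscillatorState:
    """Complex state of every oscillator at one instant."""
    z: np.ndarray
    time: float


@dataclass(frozen=True)
class AmplitudeTimeSeries:
    """|z| for every oscillator (rows) at every integration step (cols)."""
    amplitudes: np.ndarray
    sample_rate: float
    frequencies: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.amplitudes, dtype=float)
        if a.shape[0] != np.asarray(self.frequencies).size:
            raise ConfigurationError("row count must equal bank size")
        object.__setattr__(self, "amplitudes", a)

    @property
    def n_steps(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def duration(self) -> float:
        return (self.n_steps - 1) / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) / self.sample_rate


def build_bank(n: int = 145, f_min: float = 0.25, f_max: float = 4.0,
               params: HopfParams | None = None) -> OscillatorBank:
    """Log-spaced bank: f_i = f_min (f_max/f_min)^((i-1)/(n-1)).

    With the defaults the bank spans four octaves around a geometric
    center of exactly 1 Hz (oscillator 73 of 145).
    """
    if n < 2:
        raise ConfigurationError("bank size must be >= 2")
    if not (0 < f_min < f_max):
        raise ConfigurationError("need 0 < f_min < f_max")
    freqs = f_min * (f_max / f_min) ** (np.arange(n) / (n - 1))
    return OscillatorBank(freqs, params or HopfParams())


def bank_from_config(bank_cfg: BankConfig, hopf_cfg: HopfConfig) -> OscillatorBank:
    return build_bank(bank_cfg.n, bank_cfg.f_min_hz, bank_cfg.f_max_hz,
                      HopfParams.from_config(hopf_cfg))


def _coupling_factors(params: HopfParams, radical: str):
    if radical == "sqrt":
        return math.sqrt(params.epsilon), True
    if radical == "plain":
        return params.epsilon, False
    raise ConfigurationError(f"radical must be 'sqrt' or 'plain', got {radical!r}")


def hopf_derivative(z, omega, params: HopfParams, x, radical: str = "sqrt"):
    """dz/dt for the driven Hopf oscillator; vectorized over z/omega/x.

    Raises NumericalDomainError if any amplitude-compression or coupling
    denominator is within 1e-12 of zero.
    """
    z = np.asarray(z, dtype=complex)
    x = np.asarray(x, dtype=float)
    eps = params.epsilon
    root, conjugate = _coupling_factors(params, radical)

    mag2 = z.real**2 + z.imag**2
    comp_den = 1 - eps * mag2
    drive_z = np.conj(z) if conjugate else z
    couple_den = 1 - root * drive_z
    stim_den = 1 - root * x
    for den in (comp_den, np.abs(couple_den), stim_den):
        if np.any(np.abs(den) < _DENOM_TOL):
            raise NumericalDomainError("denominator within 1e-12 of zero")

    linear = z * (params.alpha + 1j * omega + params.beta * eps * mag2**2 / comp_den)
    return linear + (x / stim_den) * (1 / couple_den)


def _rk4_drive(freqs: np.ndarray, params: HopfParams, stimuli: np.ndarray,
               sample_rate: float, z0: complex | np.ndarray,
               radical: str, window: tuple[int, int] | None):
    """Shared RK4 engine over a batch of stimuli.

    stimuli: (batch, n_samples).  Returns (amplitudes, sums):
    amplitudes is (batch, n_osc, n_samples+1) when window is None, else
    None; sums is (batch, n_osc) of |z| accumulated over the inclusive
    step-index window when window is given, else None.  Step k advances
    the state from t_k to t_{k+1} using stimulus sample k (zero-order
    hold).
    """
    stimuli = np.atleast_2d(np.asarray(stimuli, dtype=float))
    batch, n_samples = stimuli.shape
    n = freqs.size
    omega = 2 * np.pi * freqs[np.newaxis, :]
    eps = params.epsilon
    alpha, beta = params.alpha, params.beta
    root, conjugate = _coupling_factors(params, radical)
    limit2 = 1 / eps  # domain: eps |z|^2 < 1
    dt = 1.0 / sample_rate

    z = np.zeros((batch, n), dtype=complex)
    z += z0
    if np.any(eps * (z.real**2 + z.imag**2) >= 1):
        raise IntegrationError("initial state outside sqrt(eps)|z| < 1 domain")

    def deriv(zc, x):
        mag2 = zc.real**2 + zc.imag**2
        drive_z = np.conj(zc) if conjugate else zc
        linear = zc * (alpha + 1j * omega + beta * eps * mag2**2 / (1 - eps * mag2))
        return linear + (x / (1 - root * x)) / (1 - root * drive_z)

    store = window is None
    if store:
        amps = np.empty((batch, n, n_samples + 1))
        amps[:, :, 0] = np.abs(z)
        sums = None
    else:
        amps = None
        lo, hi = window
        sums = np.zeros((batch, n))
        if lo <= 0 <= hi:
            sums += np.abs(z)

    half = dt / 2
    for k in range(n_samples):
        x = stimuli[:, k, np.newaxis]
        k1 = deriv(z, x)
        k2 = deriv(z + half * k1, x)
        k3 = deriv(z + half * k2, x)
        k4 = deriv(z + dt * k3, x)
        z = z + (dt / 6) * (k1 + 2 * (k2 + k3) + k4)
        mag2 = z.real**2 + z.imag**2
        if np.any(mag2 >= limit2):
            b, i = np.unravel_index(int(np.argmax(mag2)), mag2.shape)
            raise IntegrationError(
                f"oscillator {i} (f={freqs[i]:.4f} Hz) escaped the "
                f"sqrt(eps)|z| < 1 domain at t={(k + 1) * dt:.4f} s",
                oscillator=int(i), time=(k + 1) * dt)
        a = np.sqrt(mag2)
        if store:
            amps[:, :, k + 1] = a
        elif lo <= k + 1 <= hi:
            sums += a
    return amps, sums


def integrate(bank: OscillatorBank, stimulus: StimulusSignal,
              z0: complex | np.ndarray = 0.0,
              radical: str = "sqrt") -> AmplitudeTimeSeries:
    """Integrate the bank under one stimulus, returning |z| at every step.

    The integration step is the stimulus sampling step; a signal of N
    samples produces N+1 amplitude columns (state before and after every
    step).  Oscillators are mutually uncoupled — each is driven only by
    the stimulus — so the bank integrates as one vectorized ODE.
    """
    amps, _ = _rk4_drive(bank.frequencies, bank.params,
                         stimulus.samples[np.newaxis, :], stimulus.sample_rate,
                         z0, radical, window=None)
    return AmplitudeTimeSeries(amps[0], stimulus.sample_rate, bank.frequencies)


def integrate_window_sums(bank: OscillatorBank, stimuli: np.ndarray,
                          sample_rate: float, step_window: tuple[int, int],
                          z0: complex | np.ndarray = 0.0,
                          radical: str = "sqrt") -> np.ndarray:
    """Batch fast path: integrate many stimuli at once, accumulating the
    activation sums sum_t |z_i(t)| over the inclusive step-index window
    instead of storing full trajectories.

    Identical arithmetic to :func:`integrate` followed by a window sum;
    used by the map-level pipelines where only activation patterns are
    needed.  Returns (batch, n_osc).
    """
    _, sums = _rk4_drive(bank.frequencies, bank.params, stimuli, sample_rate,
                         z0, radical, window=step_window)
    return sums


def write_amplitudes_csv(ts: AmplitudeTimeSeries, path: str | Path,
                         downsample: int = 1) -> None:
    """Write an amplitude matrix as CSV: time_s column then one column
    per oscillator named f_<freq>.  ``downsample`` keeps every k-th step."""
    if downsample < 1:
        raise ConfigurationError("downsample factor must be >= 1")
    cols = {"time_s": ts.times()[::downsample]}
    for i, f in enumerate(ts.frequencies):
        cols[f"f_{f:.4f}"] = ts.amplitudes[i, ::downsample]
    pd.DataFrame(cols).to_csv(path, index=False)
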