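"""Synthetic inputs for the shift-sensitivity experiments.

Three generators cover everything the diagnostics need without any
external data:

* :func:`delta_impulse` — the discrete delta probe whose decomposition
  exposes the wavelet atom sitting in each subspace;
* :func:`shifted_family` — circularly shifted copies of a signal, the
  input family of the translation-variability experiments;
* :func:`synth_eeg` — a seeded surrogate of an ictal scalp EEG
  recording: band-limited rhythms (delta/theta/alpha/beta), a 1/f
  background and spike-wave transients, with spectral energy
  concentrated below 40 Hz as in anti-alias-filtered clinical
  recordings.  It emulates the spectral shape of such data, not its
  physiology — no neural mass dynamics, single channel only.

All generators are pure functions of their arguments: the same seed
produces a bit-identical signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import signal as sp_signal

from .errors import InvalidArgumentError
from .signal import DiscreteSignal

__all__ = [
    "RhythmComponent",
    "EEGSurrogateParams",
    "delta_impulse",
    "shifted_family",
    "synth_eeg",
]


def delta_impulse(n: int, location: int, sampling_rate: float = 1000.0) -> DiscreteSignal:
    """Discrete delta impulse: 1 at index ``location`` (0-based), 0 elsewhere."""
    if not (isinstance(n, (int, np.integer)) and n >= 2):
        raise InvalidArgumentError(f"n must be an integer >= 2, got {n!r}")
    if not (isinstance(location, (int, np.integer)) and 0 <= location < n):
        raise InvalidArgumentError(
            f"impulse location must lie in [0, {n}), got {location!r}"
        )
    samples = np.zeros(int(n))
    samples[int(location)] = 1.0
    return DiscreteSignal(samples, sampling_rate)


def shifted_family(x: DiscreteSignal, shifts: Iterable[int]) -> list[DiscreteSignal]:
    """Circular right-shifts of ``x``, one signal per requested shift.

    Each member is an index permutation of ``x`` and therefore has
    identical energy.  Shifts must lie in ``[0, N)`` — wrapping larger
    values silently would make the diagnostics ambiguous.
    """
    return [x.shift(s) for s in shifts]


@dataclass(frozen=True)
class RhythmComponent:
    """One band-limited EEG rhythm: label, band edges in Hz, relative amplitude."""

    label: str
    low_hz: float
    high_hz: float
    relative_amplitude: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_hz < self.high_hz):
            raise InvalidArgumentError(
                f"rhythm {self.label!r}: need 0 <= low < high, "
                f"got [{self.low_hz}, {self.high_hz}]"
            )
        if self.relative_amplitude < 0:
            raise InvalidArgumentError(
                f"rhythm {self.label!r}: amplitude must be >= 0"
            )


def _default_rhythms() -> tuple[RhythmComponent, ...]:
    # Amplitudes fall off with frequency as in ictal recordings, where
    # high-amplitude slow activity dominates.
    return (
        RhythmComponent("delta", 0.5, 4.0, 1.0),
        RhythmComponent("theta", 4.0, 8.0, 0.6),
        RhythmComponent("alpha", 8.0, 13.0, 0.4),
        RhythmComponent("beta", 13.0, 30.0, 0.2),
    )


@dataclass(frozen=True)
class EEGSurrogateParams:
    """Parameters of the EEG surrogate generator.

    Defaults emulate a 10-second single-channel ictal recording sampled
    at 200 Hz: the four standard scalp rhythms with amplitudes decaying
    toward high frequency, a 1/f background and one spike-wave event
    per second on average.
    """

    duration_s: float = 10.0
    sampling_rate: float = 200.0
    rhythms: tuple[RhythmComponent, ...] = field(default_factory=_default_rhythms)
    one_over_f_exponent: float = 1.0
    one_over_f_amplitude: float = 0.3
    transient_rate_hz: float = 1.0
    transient_amplitude: float = 3.0
    transient_width_s: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.duration_s > 0):
            raise InvalidArgumentError("duration_s must be positive")
        if not (self.sampling_rate > 0):
            raise InvalidArgumentError("sampling_rate must be positive")
        nyquist = self.sampling_rate / 2.0
        for r in self.rhythms:
            if r.high_hz >= nyquist:
                raise InvalidArgumentError(
                    f"rhythm {r.label!r} upper edge {r.high_hz} Hz must be "
                    f"below the Nyquist frequency {nyquist} Hz"
                )
        if not any(r.relative_amplitude > 0 for r in self.rhythms):
            raise InvalidArgumentError("at least one rhythm amplitude must be > 0")
        if self.one_over_f_exponent < 0:
            raise InvalidArgumentError("one_over_f_exponent must be >= 0")
        if self.transient_rate_hz < 0:
            raise InvalidArgumentError("transient_rate_hz must be >= 0")


def _bandpassed_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to [low, high] Hz (4th-order Butterworth)."""
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    low_n = max(low, 1e-3) / nyq
    sos = sp_signal.butter(4, [low_n, high / nyq], btype="bandpass", output="sos")
    shaped = sp_signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def _one_over_f_noise(
    rng: np.random.Generator, n: int, exponent: float
) -> np.ndarray:
    """Unit-RMS noise with power spectral density proportional to 1/f**exponent."""
    spectrum = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spectrum * scale, n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def _mexican_hat(width_samples: float, half_support: int) -> np.ndarray:
    """Mexican-hat pulse (negative-second-derivative-of-Gaussian shape)."""
    t = np.arange(-half_support, half_support + 1, dtype=np.float64)
    u = t / width_samples
    return (1.0 - u**2) * np.exp(-(u**2) / 2.0)


def synth_eeg(params: EEGSurrogateParams = EEGSurrogateParams()) -> DiscreteSignal:
    """Generate the EEG surrogate described by ``params``.

    The output is the amplitude-weighted sum of unit-RMS band-limited
    rhythms, a unit-RMS 1/f background and spike-wave transients at
    seeded Poisson times.  Under the default parameters at least 80 %
    of the one-sided spectral energy lies below 40 Hz.
    """
    n = int(round(params.duration_s * params.sampling_rate))
    if n < 2:
        raise InvalidArgumentError("duration_s * sampling_rate must be >= 2 samples")
    rng = np.random.default_rng(params.seed)
    out = np.zeros(n)
    for rhythm in params.rhythms:
        if rhythm.relative_amplitude == 0:
            continue
        out += rhythm.relative_amplitude * _bandpassed_noise(
            rng, n, params.sampling_rate, rhythm.low_hz, rhythm.high_hz
        )
    if params.one_over_f_exponent > 0 and params.one_over_f_amplitude > 0:
        out += params.one_over_f_amplitude * _one_over_f_noise(
            rng, n, params.one_over_f_exponent
        )
    if params.transient_rate_hz > 0 and params.transient_amplitude > 0:
        n_events = rng.poisson(params.transient_rate_hz * params.duration_s)
        width = params.transient_width_s * params.sampling_rate
        half_support = max(1, int(round(4 * width)))
        pulse = _mexican_hat(width, half_support)
        for _ in range(n_events):
            centre = int(rng.integers(0, n))
            amp = params.transient_amplitude * (0.75 + 0.5 * rng.random())
            for k, v in enumerate(pulse):
                out[(centre - half_support + k) % n] += amp * v  # circular placement
    return DiscreteSignal(out, params.sampling_rate)
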