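"""Discrete signal container.

A :class:`DiscreteSignal` is a finite, real-valued sample sequence with
a sampling rate.  All transforms in this package treat the sequence as
one period of a periodic signal (circular boundary), so "shift" always
means a circular shift: a right shift by ``s`` moves sample ``n`` to
``(n + s) mod N``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["DiscreteSignal"]


@dataclass(frozen=True)
class DiscreteSignal:
    """A real-valued sample sequence with a sampling rate in Hz.

    Parameters
    ----------
    samples
        One-dimensional real array, length >= 2, all values finite.
    sampling_rate
        Samples per second, > 0.
    """

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        samples = np.array(self.samples, dtype=np.float64, copy=True)
        if samples.ndim != 1:
            raise InvalidArgumentError("samples must be one-dimensional")
        if samples.size < 2:
            raise InvalidArgumentError("samples must contain at least 2 values")
        if not np.all(np.isfinite(samples)):
            raise InvalidArgumentError("samples must all be finite")
        if not (float(self.sampling_rate) > 0):
            raise InvalidArgumentError("sampling_rate must be positive")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sampling_rate", float(self.sampling_rate))

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate

    def shift(self, s: int) -> "DiscreteSignal":
        """Circular right shift: sample ``n`` moves to ``(n + s) mod N``."""
        n = self.samples.size
        if not (0 <= int(s) < n):
            raise InvalidArgumentError(
                f"shift must lie in [0, {n}); got {s}"
            )
        return DiscreteSignal(np.roll(self.samples, int(s)), self.sampling_rate)

    def energy(self) -> float:
        """Sum of squared samples."""
        return float(np.dot(self.samples, self.samples))
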