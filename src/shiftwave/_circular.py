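"""Circular (periodic) filtering primitives shared by both transforms.

Everything here works on one period of length ``N``.  Filters whose
(possibly dilated) support exceeds ``N`` are wrapped modulo ``N`` before
transforming, which is exactly circular convolution with the periodised
filter.  Frequency-domain products are used throughout: for the à trous
scheme the DFT of a filter dilated by ``d`` is the base-filter DFT
sampled at ``(d * k) mod N``, so no dilated tap array is ever built.
"""

from __future__ import annotations

import numpy as np

__all__ = ["periodized_filter_dft", "circular_convolve", "circular_adjoint"]


def periodized_filter_dft(taps: np.ndarray, n: int, dilation: int = 1) -> np.ndarray:
    """DFT (length ``n``) of the filter dilated by ``dilation`` and wrapped mod ``n``.

    Dilation by ``d`` inserts ``d - 1`` zeros between consecutive taps.
    """
    wrapped = np.zeros(n)
    idx = (np.arange(taps.size) * dilation) % n
    np.add.at(wrapped, idx, taps)
    return np.fft.fft(wrapped)


def circular_convolve(x: np.ndarray, taps: np.ndarray, dilation: int = 1) -> np.ndarray:
    """Circular convolution ``y[n] = sum_m taps_d[m] * x[(n - m) mod N]``."""
    n = x.size
    H = periodized_filter_dft(np.asarray(taps, dtype=np.float64), n, dilation)
    return np.fft.ifft(np.fft.fft(x) * H).real


def circular_adjoint(x: np.ndarray, taps: np.ndarray, dilation: int = 1) -> np.ndarray:
    """Adjoint of :func:`circular_convolve`: ``y[n] = sum_j x[j] * taps_d[(j - n) mod N]``."""
    n = x.size
    H = periodized_filter_dft(np.asarray(taps, dtype=np.float64), n, dilation)
    return np.fft.ifft(np.fft.fft(x) * np.conj(H)).real
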