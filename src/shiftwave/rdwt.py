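"""Redundant (undecimated / stationary) wavelet transform, à trous scheme.

Same filter bank as the decimated pyramid with the down/upsampling
removed: at level ``j`` the analysis filters are dilated by inserting
``2**(j-1) - 1`` zeros between taps and applied by circular
convolution, so every band keeps the full signal length and the
transform commutes exactly with circular shifts (it is LTI).  The
filters stay sqrt(2)-normalised at every level; the inverse averages
the two redundant polyphase branches with a factor 1/2 per level, which
preserves the coefficient-for-coefficient subsampling identity with the
decimated transform: decimated detail ``j`` equals redundant detail
``j`` sampled at stride ``2**j``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._circular import circular_adjoint, circular_convolve
from .errors import (
    DivisibilityError,
    IncompatibleFilterBankError,
    InvalidArgumentError,
    StructuralError,
)
from .filters import WaveletFilterBank
from .signal import DiscreteSignal

__all__ = [
    "RedundantDecomposition",
    "rdwt_decompose",
    "rdwt_reconstruct",
    "rdwt_subspaces",
]


@dataclass(frozen=True)
class RedundantDecomposition:
    """À trous coefficients: J detail bands + 1 approximation, all length N."""

    levels: int
    detail_coeffs: tuple[np.ndarray, ...]
    approx_coeffs: np.ndarray
    original_length: int
    sampling_rate: float
    filterbank_name: str

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise InvalidArgumentError("levels must be >= 1")
        if len(self.detail_coeffs) != self.levels:
            raise StructuralError("need exactly one detail band per level")
        details = []
        for j, band in enumerate(self.detail_coeffs, start=1):
            band = np.asarray(band, dtype=np.float64)
            if band.size != self.original_length:
                raise StructuralError(
                    f"redundant band {j} has {band.size} samples, "
                    f"expected full length {self.original_length}"
                )
            band.setflags(write=False)
            details.append(band)
        approx = np.asarray(self.approx_coeffs, dtype=np.float64)
        if approx.size != self.original_length:
            raise StructuralError("approximation band must have full length")
        approx.setflags(write=False)
        object.__setattr__(self, "detail_coeffs", tuple(details))
        object.__setattr__(self, "approx_coeffs", approx)

    @property
    def n_bands(self) -> int:
        return self.levels + 1

    @property
    def coefficient_count(self) -> int:
        """Total stored coefficients: (J+1) * N (overcomplete expansion)."""
        return (self.levels + 1) * self.original_length

    def band_labels(self) -> list[str]:
        return [f"w{j}r" for j in range(1, self.levels + 1)] + [f"a{self.levels}r"]


def rdwt_decompose(
    x: DiscreteSignal, fb: WaveletFilterBank, levels: int
) -> RedundantDecomposition:
    """À trous analysis: dilated filters, circular convolution, no decimation.

    Divisibility of N by ``2**levels`` is required only so that the
    decimated/redundant subsampling identity and the periodicity
    diagnostics are well posed.
    """
    n = len(x)
    if not isinstance(levels, (int, np.integer)) or isinstance(levels, bool):
        raise InvalidArgumentError(f"levels must be an integer, got {levels!r}")
    if levels < 1:
        raise InvalidArgumentError(f"levels must be >= 1, got {levels}")
    if n % 2**levels != 0:
        raise DivisibilityError(
            f"signal length {n} must be divisible by 2**levels = {2**levels}"
        )
    levels = int(levels)
    a = np.asarray(x.samples, dtype=np.float64)
    details: list[np.ndarray] = []
    for j in range(1, levels + 1):
        dilation = 2 ** (j - 1)
        details.append(circular_convolve(a, fb.analysis_highpass, dilation))
        a = circular_convolve(a, fb.analysis_lowpass, dilation)
    return RedundantDecomposition(
        levels=levels,
        detail_coeffs=tuple(details),
        approx_coeffs=a,
        original_length=n,
        sampling_rate=x.sampling_rate,
        filterbank_name=fb.name,
    )


def _check_compatible(dec: RedundantDecomposition, fb: WaveletFilterBank) -> None:
    if dec.filterbank_name != fb.name:
        raise IncompatibleFilterBankError(
            f"decomposition was built with {dec.filterbank_name!r}, "
            f"got bank {fb.name!r}"
        )


def rdwt_reconstruct(dec: RedundantDecomposition, fb: WaveletFilterBank) -> DiscreteSignal:
    """Invert the à trous transform by branch averaging.

    For an orthonormal pair |H|^2 + |G|^2 = 2 at every frequency, so
    applying the adjoint filters and halving inverts each level exactly.
    """
    _check_compatible(dec, fb)
    a = np.asarray(dec.approx_coeffs, dtype=np.float64)
    for j in range(dec.levels, 0, -1):
        dilation = 2 ** (j - 1)
        a = 0.5 * (
            circular_adjoint(a, fb.analysis_lowpass, dilation)
            + circular_adjoint(dec.detail_coeffs[j - 1], fb.analysis_highpass, dilation)
        )
    return DiscreteSignal(a, dec.sampling_rate)


def rdwt_subspaces(
    dec: RedundantDecomposition, fb: WaveletFilterBank
) -> list[DiscreteSignal]:
    """Full-length band-isolated reconstructions ``[w_1^r, .., w_J^r, approx]``.

    Each subspace is a circular-shift-equivariant function of the input
    and the list sums to the reconstructed signal.
    """
    _check_compatible(dec, fb)
    zero = np.zeros(dec.original_length)
    out: list[DiscreteSignal] = []
    for j in range(dec.levels):
        only = RedundantDecomposition(
            levels=dec.levels,
            detail_coeffs=tuple(
                band if i == j else zero for i, band in enumerate(dec.detail_coeffs)
            ),
            approx_coeffs=zero,
            original_length=dec.original_length,
            sampling_rate=dec.sampling_rate,
            filterbank_name=dec.filterbank_name,
        )
        out.append(rdwt_reconstruct(only, fb))
    only_approx = RedundantDecomposition(
        levels=dec.levels,
        detail_coeffs=tuple(zero for _ in dec.detail_coeffs),
        approx_coeffs=dec.approx_coeffs,
        original_length=dec.original_length,
        sampling_rate=dec.sampling_rate,
        filterbank_name=dec.filterbank_name,
    )
    out.append(rdwt_reconstruct(only_approx, fb))
    return out
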