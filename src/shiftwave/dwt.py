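"""Decimated discrete wavelet transform (Mallat pyramid).

Analysis iterates a two-channel filter bank: at each stage the current
approximation is circularly convolved with the analysis low/high-pass
filters and every second sample is kept (even indices, offset 0 — the
single decimation convention of the package).  Synthesis upsamples by
zero insertion and applies the adjoint filters, which for an
orthonormal bank gives perfect reconstruction under the circular
boundary.

A J-level decomposition of an N-sample signal yields detail bands
``w_1 .. w_J`` with ``N/2**j`` coefficients each and one approximation
band with ``N/2**J`` coefficients; the coefficient count equals N.
Because of the decimation the map from signal to any single band is
only equivariant under shifts that are multiples of ``2**j`` — the
translation variability quantified by :mod:`shiftwave.diagnostics`.
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

__all__ = ["DecimatedDecomposition", "dwt_decompose", "dwt_reconstruct", "dwt_subspaces"]


@dataclass(frozen=True)
class DecimatedDecomposition:
    """Pyramid coefficients of a J-level decimated decomposition.

    ``detail_coeffs[j-1]`` holds band ``w_j`` (length ``N/2**j``);
    ``approx_coeffs`` holds the scaling band (length ``N/2**J``).
    """

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
            if band.size != self.original_length // 2**j:
                raise StructuralError(
                    f"detail band {j} has {band.size} coefficients, "
                    f"expected {self.original_length // 2**j}"
                )
            band.setflags(write=False)
            details.append(band)
        approx = np.asarray(self.approx_coeffs, dtype=np.float64)
        if approx.size != self.original_length // 2**self.levels:
            raise StructuralError(
                f"approximation band has {approx.size} coefficients, "
                f"expected {self.original_length // 2**self.levels}"
            )
        approx.setflags(write=False)
        object.__setattr__(self, "detail_coeffs", tuple(details))
        object.__setattr__(self, "approx_coeffs", approx)

    @property
    def n_bands(self) -> int:
        return self.levels + 1

    def band_labels(self) -> list[str]:
        return [f"w{j}" for j in range(1, self.levels + 1)] + [
            f"a{self.levels}"
        ]

    def coefficient_energy(self) -> float:
        total = float(np.dot(self.approx_coeffs, self.approx_coeffs))
        for band in self.detail_coeffs:
            total += float(np.dot(band, band))
        return total


def _check_levels(n: int, levels: int) -> None:
    if not isinstance(levels, (int, np.integer)) or isinstance(levels, bool):
        raise InvalidArgumentError(f"levels must be an integer, got {levels!r}")
    if levels < 1:
        raise InvalidArgumentError(f"levels must be >= 1, got {levels}")
    if n % 2**levels != 0:
        raise DivisibilityError(
            f"signal length {n} must be divisible by 2**levels = {2**levels}"
        )


def dwt_decompose(
    x: DiscreteSignal, fb: WaveletFilterBank, levels: int
) -> DecimatedDecomposition:
    """Iterated two-channel analysis with decimation by 2 at every stage."""
    _check_levels(len(x), int(levels))
    levels = int(levels)
    a = np.asarray(x.samples, dtype=np.float64)
    details: list[np.ndarray] = []
    for _ in range(levels):
        details.append(circular_convolve(a, fb.analysis_highpass)[::2].copy())
        a = circular_convolve(a, fb.analysis_lowpass)[::2].copy()
    return DecimatedDecomposition(
        levels=levels,
        detail_coeffs=tuple(details),
        approx_coeffs=a,
        original_length=len(x),
        sampling_rate=x.sampling_rate,
        filterbank_name=fb.name,
    )


def _synthesis_stage(
    approx: np.ndarray, detail: np.ndarray, fb: WaveletFilterBank
) -> np.ndarray:
    m = 2 * approx.size
    u_lo = np.zeros(m)
    u_lo[::2] = approx
    u_hi = np.zeros(m)
    u_hi[::2] = detail
    return circular_adjoint(u_lo, fb.analysis_lowpass) + circular_adjoint(
        u_hi, fb.analysis_highpass
    )


def _check_compatible(dec: DecimatedDecomposition, fb: WaveletFilterBank) -> None:
    if dec.filterbank_name != fb.name:
        raise IncompatibleFilterBankError(
            f"decomposition was built with {dec.filterbank_name!r}, "
            f"got bank {fb.name!r}"
        )


def dwt_reconstruct(dec: DecimatedDecomposition, fb: WaveletFilterBank) -> DiscreteSignal:
    """Invert the pyramid; exact to machine precision for orthonormal banks."""
    _check_compatible(dec, fb)
    a = np.asarray(dec.approx_coeffs, dtype=np.float64)
    for detail in reversed(dec.detail_coeffs):
        a = _synthesis_stage(a, detail, fb)
    return DiscreteSignal(a, dec.sampling_rate)


def dwt_subspaces(
    dec: DecimatedDecomposition, fb: WaveletFilterBank
) -> list[DiscreteSignal]:
    """Full-length per-band reconstructions ``[w_1, .., w_J, approximation]``.

    Band ``j`` is the synthesis with every other band zeroed; by
    linearity the returned signals sum to the reconstruction of ``dec``.
    """
    _check_compatible(dec, fb)
    out: list[DiscreteSignal] = []
    zero_approx = np.zeros_like(dec.approx_coeffs)
    for j in range(dec.levels):
        details = tuple(
            band if i == j else np.zeros_like(band)
            for i, band in enumerate(dec.detail_coeffs)
        )
        only = DecimatedDecomposition(
            levels=dec.levels,
            detail_coeffs=details,
            approx_coeffs=zero_approx,
            original_length=dec.original_length,
            sampling_rate=dec.sampling_rate,
            filterbank_name=dec.filterbank_name,
        )
        out.append(dwt_reconstruct(only, fb))
    only_approx = DecimatedDecomposition(
        levels=dec.levels,
        detail_coeffs=tuple(np.zeros_like(b) for b in dec.detail_coeffs),
        approx_coeffs=dec.approx_coeffs,
        original_length=dec.original_length,
        sampling_rate=dec.sampling_rate,
        filterbank_name=dec.filterbank_name,
    )
    out.append(dwt_reconstruct(only_approx, fb))
    return out
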