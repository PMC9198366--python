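"""Translation-variability diagnostics for multirate decompositions.

A decomposition is translation invariant (LTI as a map from signal to
subspace) when shifting the input merely shifts every subspace output.
The decimated pyramid violates this: band ``j`` only commutes with
shifts that are multiples of ``2**j``, so the subspace waveform — and
its magnitude spectrum — depends on the absolute alignment of the
input.  The functions here quantify that effect:

* :func:`fft_magnitude_spectrum` — one-sided spectrum of a subspace;
* :func:`count_distinct_patterns` — number of distinct spectra produced
  by a family of shifted inputs;
* :func:`estimate_tv_periodicity` — smallest shift under which a band
  is exactly equivariant (``2**j`` for decimated detail ``j``, ``2**J``
  for the approximation, 1 for every undecimated band);
* :func:`lti_check` — per-band shift-equivariance audit returning a
  :class:`ShiftSensitivityReport`;
* :func:`theoretical_spb` / :func:`empirical_spb` — nominal versus
  measured spectral passing band of a subspace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence, Union

import numpy as np

from .dwt import dwt_decompose, dwt_subspaces
from .errors import DegenerateInputError, InvalidArgumentError, StructuralError
from .filters import WaveletFilterBank
from .rdwt import rdwt_decompose, rdwt_subspaces
from .signal import DiscreteSignal

__all__ = [
    "Spectrum",
    "SpectralBand",
    "BandShiftStats",
    "ShiftSensitivityReport",
    "fft_magnitude_spectrum",
    "count_distinct_patterns",
    "subspace_signals",
    "estimate_tv_periodicity",
    "lti_check",
    "theoretical_spb",
    "empirical_spb",
]

TRANSFORMS = ("dwt", "rdwt")


class Spectrum(NamedTuple):
    """One-sided magnitude spectrum with its frequency axis in Hz."""

    freq_hz: np.ndarray
    magnitude: np.ndarray


@dataclass(frozen=True)
class SpectralBand:
    """A frequency interval [low_hz, high_hz] with low < high."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_hz < self.high_hz):
            raise InvalidArgumentError(
                f"need 0 <= low_hz < high_hz, got [{self.low_hz}, {self.high_hz}]"
            )

    @property
    def width_hz(self) -> float:
        return self.high_hz - self.low_hz

    def contains(self, f_hz: float) -> bool:
        return self.low_hz <= f_hz <= self.high_hz


@dataclass(frozen=True)
class BandShiftStats:
    """Shift-sensitivity summary for one subspace."""

    band: int  # 1-based; levels+1 denotes the approximation band
    label: str
    estimated_period: int
    distinct_pattern_count: int
    max_equivariance_deviation: float


@dataclass(frozen=True)
class ShiftSensitivityReport:
    """Per-band translation-variability audit of one decomposition scheme."""

    transform_label: str
    levels: int
    per_band: tuple[BandShiftStats, ...]
    tested_shifts: tuple[int, ...]
    tolerance: float

    @property
    def is_lti(self) -> bool:
        """True iff every band is shift-equivariant at the report tolerance."""
        return all(
            b.max_equivariance_deviation < self.tolerance for b in self.per_band
        )

    @property
    def max_deviation(self) -> float:
        return max(b.max_equivariance_deviation for b in self.per_band)

    def to_json_dict(self) -> dict:
        return {
            "schema_version": 1,
            "transform": self.transform_label,
            "levels": self.levels,
            "tested_shifts": list(self.tested_shifts),
            "tolerance": self.tolerance,
            "verdict": "LTI" if self.is_lti else "LTV",
            "bands": [
                {
                    "band": b.band,
                    "label": b.label,
                    "estimated_period": b.estimated_period,
                    "distinct_pattern_count": b.distinct_pattern_count,
                    "max_equivariance_deviation": b.max_equivariance_deviation,
                }
                for b in self.per_band
            ],
        }


def fft_magnitude_spectrum(x: DiscreteSignal) -> Spectrum:
    """One-sided DFT magnitude, bins ``0..floor(N/2)``, frequencies in Hz."""
    samples = np.asarray(x.samples)
    if samples.size < 2:
        raise InvalidArgumentError("signal must contain at least 2 samples")
    mags = np.abs(np.fft.rfft(samples))
    freqs = np.fft.rfftfreq(samples.size, d=1.0 / x.sampling_rate)
    return Spectrum(freq_hz=freqs, magnitude=mags)


def _as_magnitude(obj: Union[Spectrum, np.ndarray]) -> np.ndarray:
    if isinstance(obj, Spectrum):
        return np.asarray(obj.magnitude, dtype=np.float64)
    return np.asarray(obj, dtype=np.float64)


def count_distinct_patterns(
    spectra: Sequence[Union[Spectrum, np.ndarray]], rel_tolerance: float = 1e-8
) -> int:
    """Number of equivalence classes among magnitude spectra.

    Two spectra match when ``max|a - b| <= rel_tolerance * max|a|`` with
    ``a`` the class representative; classes are built greedily in input
    order, so the count is deterministic.  The default tolerance of
    1e-8 cleanly separates machine-precision congruence (undecimated
    bands) from the order-one discrepancies of decimated bands.
    """
    if not spectra:
        raise InvalidArgumentError("need at least one spectrum")
    if not (rel_tolerance > 0):
        raise InvalidArgumentError("rel_tolerance must be positive")
    arrays = [_as_magnitude(s) for s in spectra]
    length = arrays[0].size
    if any(a.size != length for a in arrays):
        raise StructuralError("all spectra must have the same length")
    representatives: list[np.ndarray] = []
    for a in arrays:
        for rep in representatives:
            scale = np.max(np.abs(rep))
            if np.max(np.abs(a - rep)) <= rel_tolerance * scale:
                break
        else:
            representatives.append(a)
    return len(representatives)


def _check_transform(transform: str) -> str:
    label = str(transform).lower()
    if label not in TRANSFORMS:
        raise InvalidArgumentError(
            f"transform must be one of {TRANSFORMS}, got {transform!r}"
        )
    return label


def subspace_signals(
    transform: str, x: DiscreteSignal, fb: WaveletFilterBank, levels: int
) -> list[DiscreteSignal]:
    """Full-length subspaces ``[w_1 .. w_J, approximation]`` of either scheme."""
    label = _check_transform(transform)
    if label == "dwt":
        return dwt_subspaces(dwt_decompose(x, fb, levels), fb)
    return rdwt_subspaces(rdwt_decompose(x, fb, levels), fb)


def _band_index(band: int, levels: int) -> int:
    if not (1 <= band <= levels + 1):
        raise InvalidArgumentError(
            f"band must lie in 1..{levels + 1} (levels+1 = approximation), got {band}"
        )
    return band - 1


def estimate_tv_periodicity(
    transform: str,
    x: DiscreteSignal,
    fb: WaveletFilterBank,
    levels: int,
    band: int,
    max_period: Union[int, None] = None,
    tolerance: float = 1e-10,
) -> int:
    """Smallest shift ``p`` under which band ``band`` is exactly equivariant.

    Exhaustively tests ``p = 1..max_period`` (default ``2**(levels+1)``)
    for ``subspace(shift(x, p)) == shift(subspace(x), p)`` within the
    absolute tolerance.  Returns ``max_period + 1`` as a sentinel when
    no period is found.
    """
    label = _check_transform(transform)
    idx = _band_index(band, levels)
    if max_period is None:
        max_period = 2 ** (levels + 1)
    if not (1 <= max_period <= len(x)):
        raise InvalidArgumentError("max_period must lie in [1, N]")
    baseline = subspace_signals(label, x, fb, levels)[idx].samples
    for p in range(1, max_period + 1):
        shifted = subspace_signals(label, x.shift(p), fb, levels)[idx].samples
        if np.max(np.abs(shifted - np.roll(baseline, p))) < tolerance:
            return p
    return max_period + 1


def lti_check(
    transform: str,
    x: DiscreteSignal,
    fb: WaveletFilterBank,
    levels: int,
    shifts: Iterable[int],
    tolerance: float = 1e-10,
    rel_pattern_tolerance: float = 1e-8,
) -> ShiftSensitivityReport:
    """Audit shift equivariance of every subspace over the given shifts.

    For each band ``j`` and shift ``s`` the deviation
    ``max | w_j(shift(x, s)) - shift(w_j(x), s) |`` is computed (the
    baseline output is shifted, circularly).  The verdict is LTI iff
    every deviation is below ``tolerance``; for the undecimated scheme
    this holds for arbitrary shifts, for the decimated pyramid it fails
    already at ``s = 1``.
    """
    label = _check_transform(transform)
    shifts = tuple(int(s) for s in shifts)
    if not shifts:
        raise InvalidArgumentError("shifts must be non-empty")
    n = len(x)
    if any(not (0 <= s < n) for s in shifts):
        raise InvalidArgumentError(f"shifts must lie in [0, {n})")

    baseline = subspace_signals(label, x, fb, levels)
    n_bands = levels + 1
    deviations = np.zeros(n_bands)
    spectra: list[list[np.ndarray]] = [[] for _ in range(n_bands)]
    for s in shifts:
        shifted_subs = (
            baseline if s == 0 else subspace_signals(label, x.shift(s), fb, levels)
        )
        for b in range(n_bands):
            dev = np.max(
                np.abs(shifted_subs[b].samples - np.roll(baseline[b].samples, s))
            )
            deviations[b] = max(deviations[b], dev)
            spectra[b].append(fft_magnitude_spectrum(shifted_subs[b]).magnitude)

    labels = [f"w{j}" for j in range(1, levels + 1)] + [f"a{levels}"]
    per_band = []
    for b in range(n_bands):
        period = estimate_tv_periodicity(
            label, x, fb, levels, band=b + 1, tolerance=tolerance
        )
        per_band.append(
            BandShiftStats(
                band=b + 1,
                label=labels[b],
                estimated_period=period,
                distinct_pattern_count=count_distinct_patterns(
                    spectra[b], rel_pattern_tolerance
                ),
                max_equivariance_deviation=float(deviations[b]),
            )
        )
    return ShiftSensitivityReport(
        transform_label=label,
        levels=levels,
        per_band=tuple(per_band),
        tested_shifts=shifts,
        tolerance=float(tolerance),
    )


def theoretical_spb(band: int, levels: int, fs: float) -> SpectralBand:
    """Nominal passing band: detail ``j`` occupies ``[fs/2**(j+1), fs/2**j]``.

    The approximation band (``band = levels + 1``) gets the complement
    ``[0, fs/2**(levels+1)]``.
    """
    if not (fs > 0):
        raise InvalidArgumentError("fs must be positive")
    _band_index(band, levels)
    if band == levels + 1:
        return SpectralBand(0.0, fs / 2 ** (levels + 1))
    return SpectralBand(fs / 2 ** (band + 1), fs / 2**band)


def empirical_spb(subspace: DiscreteSignal, energy_fraction: float = 0.9) -> SpectralBand:
    """Smallest contiguous frequency interval holding the given energy share.

    Works on the one-sided power spectrum; among intervals of equal
    (minimal) bin count the lowest-frequency one is returned.  Interval
    edges are reported at bin centres, widened by half a bin when the
    interval is a single bin so the result is a proper band.
    """
    if not (0.0 < energy_fraction <= 1.0):
        raise InvalidArgumentError("energy_fraction must lie in (0, 1]")
    spec = fft_magnitude_spectrum(subspace)
    power = spec.magnitude**2
    total = power.sum()
    if total == 0.0:
        raise DegenerateInputError("all-zero signal has no spectral band")
    target = energy_fraction * total
    prefix = np.concatenate([[0.0], np.cumsum(power)])
    nbins = power.size
    eps = total * 1e-12  # guard against round-off at fraction 1.0
    for width in range(1, nbins + 1):
        sums = prefix[width:] - prefix[:-width]
        hits = np.nonzero(sums >= target - eps)[0]
        if hits.size:
            i = int(hits[0])
            j = i + width - 1
            low = spec.freq_hz[i]
            high = spec.freq_hz[j]
            if i == j:
                df = spec.freq_hz[1] - spec.freq_hz[0]
                low = max(0.0, low - df / 2)
                high = high + df / 2
            return SpectralBand(low, high)
    raise StructuralError("unreachable: full band always satisfies the target")
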