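"""Decimated pyramid: coefficient structure, reconstruction, subspaces."""

import numpy as np
import pytest

from shiftwave import (
    DiscreteSignal,
    DivisibilityError,
    IncompatibleFilterBankError,
    InvalidArgumentError,
    delta_impulse,
    dwt_decompose,
    dwt_reconstruct,
    dwt_subspaces,
    make_daubechies_filterbank,
    theoretical_spb,
)


def test_constant_signal_haar(haar):
    """The highpass annihilates constants; the lowpass scales by sqrt(2)."""
    c = 3.7
    x = DiscreteSignal(np.full(8, c), 1000.0)
    dec = dwt_decompose(x, haar, 1)
    np.testing.assert_allclose(dec.detail_coeffs[0], np.zeros(4), atol=1e-14)
    np.testing.assert_allclose(dec.approx_coeffs, np.full(4, c * np.sqrt(2)), atol=1e-14)


def test_delta_haar_single_level(haar):
    """Hand-computed circular convolution with offset-0 decimation.

    For a delta at index 0, the even-phase decimation picks exactly the
    tap-0 value of each filter: one nonzero coefficient of magnitude
    1/sqrt(2) per band.
    """
    x = delta_impulse(8, 0, 1000.0)
    dec = dwt_decompose(x, haar, 1)
    for band in (dec.detail_coeffs[0], dec.approx_coeffs):
        nz = np.nonzero(np.abs(band) > 1e-14)[0]
        assert nz.tolist() == [0]
        assert abs(band[0]) == pytest.approx(1 / np.sqrt(2))


def test_coefficient_lengths_n1000_db8_three_levels(db8, delta_1000):
    dec = dwt_decompose(delta_1000, db8, 3)
    assert [b.size for b in dec.detail_coeffs] == [500, 250, 125]
    assert dec.approx_coeffs.size == 125
    assert dec.band_labels() == ["w1", "w2", "w3", "a3"]


def test_divisibility_enforced(db8):
    x = DiscreteSignal(np.ones(100), 1000.0)
    with pytest.raises(DivisibilityError, match="2\\*\\*levels = 8"):
        dwt_decompose(x, db8, 3)
    with pytest.raises(InvalidArgumentError):
        dwt_decompose(x, db8, 0)


def test_round_trip_and_energy(db8, rng):
    x = DiscreteSignal(rng.standard_normal(256), 1000.0)
    dec = dwt_decompose(x, db8, 3)
    assert abs(dec.coefficient_energy() - x.energy()) < 1e-10
    xr = dwt_reconstruct(dec, db8)
    assert np.max(np.abs(xr.samples - x.samples)) < 1e-10


def test_zero_coefficients_reconstruct_to_zero(db8):
    dec = dwt_decompose(delta_impulse(64, 10, 1000.0), db8, 2)
    zeroed = type(dec)(
        levels=dec.levels,
        detail_coeffs=tuple(np.zeros_like(b) for b in dec.detail_coeffs),
        approx_coeffs=np.zeros_like(dec.approx_coeffs),
        original_length=dec.original_length,
        sampling_rate=dec.sampling_rate,
        filterbank_name=dec.filterbank_name,
    )
    assert np.max(np.abs(dwt_reconstruct(zeroed, db8).samples)) == 0.0


def test_filterbank_mismatch_rejected(db8, haar, random_signal):
    dec = dwt_decompose(random_signal, db8, 2)
    with pytest.raises(IncompatibleFilterBankError):
        dwt_reconstruct(dec, haar)


def test_subspaces_sum_to_signal(db8, random_signal):
    dec = dwt_decompose(random_signal, db8, 3)
    subs = dwt_subspaces(dec, db8)
    assert len(subs) == 4
    total = sum(s.samples for s in subs)
    assert np.max(np.abs(total - random_signal.samples)) < 1e-10


def test_constant_input_has_no_detail_content(db8):
    x = DiscreteSignal(np.full(64, 2.5), 1000.0)
    subs = dwt_subspaces(dwt_decompose(x, db8, 3), db8)
    for detail in subs[:-1]:
        assert np.max(np.abs(detail.samples)) < 1e-10


def test_detail_subspaces_concentrate_in_their_passing_band(db8, delta_1000):
    """Most detail-band energy falls inside [fs/2^(j+1), fs/2^j].

    The concentration is only approximate (the passing band is an
    idealisation), but for the baseline delta probe each detail
    subspace keeps well over 60 % of its FFT energy inside its band.
    """
    subs = dwt_subspaces(dwt_decompose(delta_1000, db8, 3), db8)
    for j in range(1, 4):
        spec = np.abs(np.fft.rfft(subs[j - 1].samples)) ** 2
        freqs = np.fft.rfftfreq(1000, d=1 / 1000.0)
        band = theoretical_spb(j, 3, 1000.0)
        inside = spec[(freqs >= band.low_hz) & (freqs <= band.high_hz)].sum()
        assert inside / spec.sum() >= 0.6


def test_translation_variance_witness(db8, delta_1000):
    """Shifting the input by one sample visibly changes band w1: LTV."""
    base = dwt_subspaces(dwt_decompose(delta_1000, db8, 3), db8)[0].samples
    shifted = dwt_subspaces(dwt_decompose(delta_1000.shift(1), db8, 3), db8)[0].samples
    deviation = np.max(np.abs(shifted - np.roll(base, 1)))
    assert deviation > 0.01 * np.max(np.abs(base))


def test_shift_by_full_dyadic_stride_commutes(db8, rng):
    """A shift by 2**J moves every coefficient band circularly by 2**J / 2**j."""
    x = DiscreteSignal(rng.standard_normal(256), 1000.0)
    levels = 3
    stride = 2**levels
    dec = dwt_decompose(x, db8, levels)
    dec_shifted = dwt_decompose(x.shift(stride), db8, levels)
    for j in range(1, levels + 1):
        expected = np.roll(dec.detail_coeffs[j - 1], stride // 2**j)
        assert np.max(np.abs(dec_shifted.detail_coeffs[j - 1] - expected)) < 1e-12
    expected = np.roll(dec.approx_coeffs, 1)
    assert np.max(np.abs(dec_shifted.approx_coeffs - expected)) < 1e-12
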