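"""Cross-checks against PyWavelets as an independent implementation.

The two packages use different alignment conventions: this package
correlates with causally stored minimum-phase taps and decimates the
even phase, while PyWavelets convolves with the time-reversed tabulated
filters.  Feeding this package's taps into a custom ``pywt.Wavelet``
makes both convolve identical taps, after which the outputs differ only
by a fixed circular roll per level:

* decimated level ``j``:  roll by ``-L/2 + (L/4) * 2**(1-j)``
  (integer whenever ``L/4 * 2**(1-j)`` is — e.g. db8 up to 3 levels);
* stationary level ``j``: roll by ``-(L/2) * (2**j - 1)``;

with ``L`` the tap count.  The rolls are closed-form functions of the
conventions, not fitted per signal.
"""

import numpy as np
import pytest

pywt = pytest.importorskip("pywt")

from shiftwave import (
    DiscreteSignal,
    dwt_decompose,
    dwt_reconstruct,
    make_daubechies_filterbank,
    rdwt_decompose,
)


def _custom_wavelet(fb):
    return pywt.Wavelet(
        f"{fb.name}-causal",
        filter_bank=(
            fb.analysis_lowpass.tolist(),
            fb.analysis_highpass.tolist(),
            fb.synthesis_lowpass.tolist(),
            fb.synthesis_highpass.tolist(),
        ),
    )


def _dwt_roll(tap_length, level):
    offset = -tap_length // 2 + (tap_length // 4) * 2 ** (1 - level)
    assert offset == int(offset), "alignment not integral for this order/level"
    return int(offset)


@pytest.mark.parametrize("order,levels", [(8, 3), (4, 2), (2, 1)])
def test_decimated_coefficients_match_wavedec(order, levels, rng):
    fb = make_daubechies_filterbank(order)
    wav = _custom_wavelet(fb)
    n = 256
    for _ in range(20):
        x = rng.standard_normal(n)
        dec = dwt_decompose(DiscreteSignal(x, 1000.0), fb, levels)
        ref = pywt.wavedec(x.copy(), wav, mode="periodization", level=levels)
        # ref = [cA_J, cD_J, ..., cD_1]
        for j in range(1, levels + 1):
            mine = np.roll(dec.detail_coeffs[j - 1], _dwt_roll(fb.tap_length, j))
            assert np.max(np.abs(mine - ref[levels + 1 - j])) < 1e-8
        mine = np.roll(dec.approx_coeffs, _dwt_roll(fb.tap_length, levels))
        assert np.max(np.abs(mine - ref[0])) < 1e-8


@pytest.mark.parametrize("order", [2, 8])
def test_stationary_coefficients_match_swt(order, rng):
    fb = make_daubechies_filterbank(order)
    wav = _custom_wavelet(fb)
    n, levels = 128, 3
    for _ in range(20):
        x = rng.standard_normal(n)
        red = rdwt_decompose(DiscreteSignal(x, 1000.0), fb, levels)
        ref = pywt.swt(x.copy(), wav, level=levels, trim_approx=True, norm=False)
        # ref = [cA_J, cD_J, ..., cD_1]
        for j in range(1, levels + 1):
            roll = -(fb.tap_length // 2) * (2**j - 1)
            mine = np.roll(red.detail_coeffs[j - 1], roll)
            assert np.max(np.abs(mine - ref[levels + 1 - j])) < 1e-8
        roll = -(fb.tap_length // 2) * (2**levels - 1)
        mine = np.roll(red.approx_coeffs, roll)
        assert np.max(np.abs(mine - ref[0])) < 1e-8


def test_cross_library_round_trip_db8(rng):
    """PyWavelets inverts this package's decimated coefficients exactly."""
    fb = make_daubechies_filterbank(8)
    wav = _custom_wavelet(fb)
    levels, n = 3, 256
    for _ in range(5):
        x = rng.standard_normal(n)
        dec = dwt_decompose(DiscreteSignal(x, 1000.0), fb, levels)
        coeffs = [np.roll(dec.approx_coeffs, _dwt_roll(fb.tap_length, levels))]
        for j in range(levels, 0, -1):
            coeffs.append(np.roll(dec.detail_coeffs[j - 1], _dwt_roll(fb.tap_length, j)))
        xr = pywt.waverec(coeffs, wav, mode="periodization")
        assert np.max(np.abs(xr - x)) < 1e-8


@pytest.mark.parametrize("order", range(1, 11))
def test_round_trip_agreement_all_orders(order, rng):
    """Both implementations achieve exact round trips on the same inputs."""
    fb = make_daubechies_filterbank(order)
    x = rng.standard_normal(128)
    mine = dwt_reconstruct(dwt_decompose(DiscreteSignal(x, 1000.0), fb, 2), fb)
    assert np.max(np.abs(mine.samples - x)) < 1e-8
    ref = pywt.waverec(
        pywt.wavedec(x.copy(), f"db{order}", mode="periodization", level=2),
        f"db{order}",
        mode="periodization",
    )
    assert np.max(np.abs(ref - x)) < 1e-8
    assert np.max(np.abs(mine.samples - ref)) < 1e-8
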