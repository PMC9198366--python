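"""Translation-variability diagnostics."""

import numpy as np
import pytest

from shiftwave import (
    DegenerateInputError,
    DiscreteSignal,
    InvalidArgumentError,
    count_distinct_patterns,
    delta_impulse,
    empirical_spb,
    estimate_tv_periodicity,
    fft_magnitude_spectrum,
    lti_check,
    shifted_family,
    subspace_signals,
    theoretical_spb,
)
from shiftwave.errors import StructuralError


class TestMagnitudeSpectrum:
    def test_delta_spectrum_is_flat(self):
        spec = fft_magnitude_spectrum(delta_impulse(64, 20, 1000.0))
        assert np.max(np.abs(spec.magnitude - 1.0)) < 1e-12
        assert spec.freq_hz[0] == 0.0
        assert spec.freq_hz[-1] == pytest.approx(500.0)
        assert spec.magnitude.size == 33

    def test_bin_centered_sinusoid_has_single_dominant_bin(self):
        fs, n, f0 = 1000.0, 200, 125.0  # bin 25 exactly
        t = np.arange(n) / fs
        spec = fft_magnitude_spectrum(DiscreteSignal(np.sin(2 * np.pi * f0 * t), fs))
        peak = int(np.argmax(spec.magnitude))
        assert spec.freq_hz[peak] == pytest.approx(f0)
        rest = np.delete(spec.magnitude, peak)
        assert rest.max() < 1e-9 * spec.magnitude[peak]

    def test_shift_invariance(self, rng):
        x = DiscreteSignal(rng.standard_normal(128), 500.0)
        a = fft_magnitude_spectrum(x).magnitude
        for s in (1, 17, 100):
            b = fft_magnitude_spectrum(x.shift(s)).magnitude
            assert np.max(np.abs(a - b)) < 1e-10


class TestPatternCounting:
    def test_identical_spectra_form_one_class(self, rng):
        a = np.abs(rng.standard_normal(65))
        assert count_distinct_patterns([a, a.copy(), a.copy(), a.copy()]) == 1

    def test_dwt_w1_shifted_deltas_two_patterns(self, db8, delta_1000):
        family = shifted_family(delta_1000, [0, 1, 2, 3])
        spectra = [
            fft_magnitude_spectrum(subspace_signals("dwt", m, db8, 3)[0])
            for m in family
        ]
        assert count_distinct_patterns(spectra, rel_tolerance=1e-8) == 2

    def test_rdwt_w1_shifted_deltas_one_pattern(self, db8, delta_1000):
        family = shifted_family(delta_1000, [0, 1, 2, 3])
        spectra = [
            fft_magnitude_spectrum(subspace_signals("rdwt", m, db8, 3)[0])
            for m in family
        ]
        assert count_distinct_patterns(spectra, rel_tolerance=1e-8) == 1

    def test_ragged_lengths_rejected(self):
        with pytest.raises(StructuralError):
            count_distinct_patterns([np.ones(8), np.ones(9)])

    def test_count_is_stable_under_reordering(self, db8, delta_1000):
        family = shifted_family(delta_1000, [0, 1, 2, 3])
        spectra = [
            fft_magnitude_spectrum(subspace_signals("dwt", m, db8, 3)[0]).magnitude
            for m in family
        ]
        counts = {
            count_distinct_patterns([spectra[i] for i in order])
            for order in ([0, 1, 2, 3], [3, 1, 0, 2], [2, 0, 3, 1])
        }
        assert counts == {2}


class TestPeriodicityLaw:
    def test_dwt_detail_periods_are_dyadic(self, db8, delta_1000):
        for band in (1, 2, 3):
            p = estimate_tv_periodicity("dwt", delta_1000, db8, 3, band)
            assert p == 2**band

    def test_dwt_approximation_period_is_full_stride(self, db8, delta_1000):
        assert estimate_tv_periodicity("dwt", delta_1000, db8, 3, 4) == 8

    def test_rdwt_every_band_period_one(self, db8, delta_1000):
        for band in (1, 2, 3, 4):
            assert estimate_tv_periodicity("rdwt", delta_1000, db8, 3, band) == 1

    def test_band_out_of_range(self, db8, delta_1000):
        with pytest.raises(InvalidArgumentError):
            estimate_tv_periodicity("dwt", delta_1000, db8, 3, 5)


class TestLTICheck:
    def test_rdwt_verdict_lti(self, db8, delta_1000):
        report = lti_check("rdwt", delta_1000, db8, 3, range(16))
        assert report.is_lti
        assert report.max_deviation < 1e-10
        assert all(b.distinct_pattern_count == 1 for b in report.per_band)
        assert all(b.estimated_period == 1 for b in report.per_band)

    def test_dwt_verdict_ltv_with_band1_excursion(self, db8, delta_1000):
        report = lti_check("dwt", delta_1000, db8, 3, range(16))
        assert not report.is_lti
        w1 = report.per_band[0]
        peak = np.max(np.abs(subspace_signals("dwt", delta_1000, db8, 3)[0].samples))
        assert w1.max_equivariance_deviation > 0.01 * peak

    def test_dyadic_shifts_pass_for_dwt(self, db8, delta_1000):
        """Shifts that are multiples of 2**J commute with the whole pyramid."""
        report = lti_check("dwt", delta_1000, db8, 3, [0, 8, 16, 24])
        assert report.is_lti

    def test_pattern_count_one_whenever_lti(self, db8, rng):
        x = DiscreteSignal(rng.standard_normal(256), 1000.0)
        report = lti_check("rdwt", x, db8, 3, [0, 1, 3, 7, 12])
        assert report.is_lti
        assert all(b.distinct_pattern_count == 1 for b in report.per_band)

    def test_empty_shift_list_rejected(self, db8, delta_1000):
        with pytest.raises(InvalidArgumentError):
            lti_check("dwt", delta_1000, db8, 3, [])

    def test_report_serialization_shape(self, db8, delta_1000):
        report = lti_check("dwt", delta_1000, db8, 3, [0, 1])
        payload = report.to_json_dict()
        assert payload["verdict"] == "LTV"
        assert len(payload["bands"]) == 4
        assert payload["schema_version"] == 1


class TestPassingBands:
    @pytest.mark.parametrize(
        "band,levels,fs,expected",
        [
            (1, 3, 1000.0, (250.0, 500.0)),
            (3, 3, 200.0, (12.5, 25.0)),
            (4, 3, 1000.0, (0.0, 62.5)),
        ],
    )
    def test_theoretical_band_arithmetic(self, band, levels, fs, expected):
        b = theoretical_spb(band, levels, fs)
        assert (b.low_hz, b.high_hz) == expected

    def test_band_index_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            theoretical_spb(5, 3, 1000.0)

    def test_empirical_band_of_bandpass_noise(self, rng):
        from scipy import signal as sps

        fs, n = 200.0, 4000
        sos = sps.butter(8, [8 / 100.0, 12 / 100.0], btype="bandpass", output="sos")
        x = DiscreteSignal(sps.sosfiltfilt(sos, rng.standard_normal(n)), fs)
        band = empirical_spb(x, energy_fraction=0.9)
        assert band.low_hz >= 6.0
        assert band.high_hz <= 14.0

    def test_empirical_band_of_pure_tone(self):
        fs, n = 1000.0, 500
        t = np.arange(n) / fs
        x = DiscreteSignal(np.sin(2 * np.pi * 100.0 * t), fs)
        band = empirical_spb(x, energy_fraction=0.9)
        df = fs / n
        assert band.contains(100.0)
        assert band.width_hz <= 3 * df

    def test_empirical_band_of_delta_is_everything(self):
        band = empirical_spb(delta_impulse(128, 10, 1000.0), energy_fraction=1.0)
        assert band.low_hz == 0.0
        assert band.high_hz == pytest.approx(500.0)

    def test_all_zero_signal_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            empirical_spb(DiscreteSignal(np.zeros(16), 100.0))
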