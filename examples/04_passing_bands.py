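"""Theoretical versus measured spectral passing bands.

Detail band j nominally occupies [fs/2^(j+1), fs/2^j].  The empirical
band — the narrowest interval holding 90 % of a subspace's spectral
energy — shows how well each subspace honours its nominal band for the
delta probe (alignment-dependent because of translation variability).
"""

from shiftwave import (
    delta_impulse,
    empirical_spb,
    make_daubechies_filterbank,
    subspace_signals,
    theoretical_spb,
)

fb = make_daubechies_filterbank(8)
levels, fs = 3, 1000.0
x = delta_impulse(1000, 500, fs)
subs = subspace_signals("dwt", x, fb, levels)

for band in range(1, levels + 2):
    nominal = theoretical_spb(band, levels, fs)
    measured = empirical_spb(subs[band - 1], energy_fraction=0.9)
    label = f"w{band}" if band <= levels else f"a{levels}"
    print(f"{label}: nominal [{nominal.low_hz:6.1f}, {nominal.high_hz:6.1f}] Hz   "
          f"90% energy in [{measured.low_hz:6.1f}, {measured.high_hz:6.1f}] Hz")

print("\nAt an EEG sampling rate of 200 Hz, detail band 3 nominally covers"
      f" [{theoretical_spb(3, 3, 200.0).low_hz}, {theoretical_spb(3, 3, 200.0).high_hz}] Hz"
      " - the upper alpha/low beta range.")
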