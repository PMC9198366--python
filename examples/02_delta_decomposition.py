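"""Decompose the delta probe with both transforms and reconstruct it.

The decimated pyramid halves the coefficient count per level (500, 250,
125 details + 125 approximation for N=1000, J=3); the undecimated
transform keeps every band at full length.  Both reconstruct the input
to machine precision, and the subspaces of each transform sum back to
the signal exactly.
"""

import numpy as np

from shiftwave import (
    delta_impulse,
    dwt_decompose,
    dwt_reconstruct,
    dwt_subspaces,
    make_daubechies_filterbank,
    rdwt_decompose,
    rdwt_reconstruct,
    rdwt_subspaces,
)

fb = make_daubechies_filterbank(8)
x = delta_impulse(1000, 500, sampling_rate=1000.0)

dec = dwt_decompose(x, fb, levels=3)
print("decimated bands:", {l: b.size for l, b in zip(dec.band_labels()[:-1], dec.detail_coeffs)},
      "+ approx", dec.approx_coeffs.size)
print("coefficient energy == signal energy:",
      np.isclose(dec.coefficient_energy(), x.energy(), atol=1e-12))
err = np.max(np.abs(dwt_reconstruct(dec, fb).samples - x.samples))
print(f"DWT round-trip max error: {err:.2e}")

red = rdwt_decompose(x, fb, levels=3)
print("redundant bands all length", red.original_length,
      "| total coefficients:", red.coefficient_count)
err = np.max(np.abs(rdwt_reconstruct(red, fb).samples - x.samples))
print(f"RDWT round-trip max error: {err:.2e}")

for name, subs in (
    ("DWT", dwt_subspaces(dec, fb)),
    ("RDWT", rdwt_subspaces(red, fb)),
):
    total = sum(s.samples for s in subs)
    print(f"{name} subspace additivity error: {np.max(np.abs(total - x.samples)):.2e}")
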