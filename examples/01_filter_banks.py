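"""Build a Daubechies filter bank and certify its defining invariants.

The DB8 lowpass is computed by spectral factorization (no tabulated
coefficients); the printed residuals show how far each orthonormality
property is from exact — all should be at machine precision.
"""

from shiftwave import filterbank_to_json, make_daubechies_filterbank, validate_filterbank

fb = make_daubechies_filterbank(8)
print(f"{fb.name}: {fb.tap_length} taps, minimum phase")
print("first four lowpass taps:", [round(float(v), 6) for v in fb.analysis_lowpass[:4]])

for check in validate_filterbank(fb):
    status = "pass" if check.passed else "FAIL"
    print(f"  {check.name:28s} {status}  residual {check.residual:.2e}")

print()
print("JSON export (first 120 chars):")
print(filterbank_to_json(fb)[:120], "...")
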