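"""Shift-sensitivity audit of an EEG-like surrogate signal.

Generates a 10 s single-channel surrogate at 200 Hz (scalp rhythms +
1/f background + spike-wave transients, energy concentrated below
40 Hz) and runs the full experiment at 4 levels, so the detail bands
bracket the classical alpha/beta rhythms.  The decimated transform
distorts the transient content band-dependently; the undecimated one
does not.
"""

import numpy as np

from shiftwave import (
    EEGSurrogateParams,
    ExperimentConfig,
    fft_magnitude_spectrum,
    run_shift_experiment,
    synth_eeg,
)

eeg = synth_eeg(EEGSurrogateParams(seed=1))
spec = fft_magnitude_spectrum(eeg)
power = spec.magnitude**2
frac = power[spec.freq_hz < 40.0].sum() / power.sum()
print(f"surrogate: {len(eeg)} samples at {eeg.sampling_rate:g} Hz, "
      f"{100 * frac:.1f}% of spectral energy below 40 Hz")

config = ExperimentConfig(
    generator="eeg",
    generator_params={"seed": 1},
    wavelet="db8",
    levels=4,
    shifts=(0, 1, 2, 3),
    output_dir="scratch/eeg-experiment",
)
reports = run_shift_experiment(config)
for label, report in reports.items():
    print(f"\n{label.upper()}: {'LTI' if report.is_lti else 'LTV'}")
    for band in report.per_band:
        print(f"  {band.label}: max deviation {band.max_equivariance_deviation:.2e}, "
              f"{band.distinct_pattern_count} spectral pattern(s)")
print("\nArtifacts (reports, subspaces, spectra) written to", config.output_dir)
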