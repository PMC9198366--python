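# Methods

## Transforms and conventions

Both transforms operate on one period of a length-N signal: **all
filtering is circular**.  This is the boundary under which the
exactness claims hold as identities — perfect reconstruction, exact
shift equivariance of the undecimated transform, and the
decimated⊂undecimated subsampling identity are all true to machine
precision, with no boundary-artifact caveats.  Padding-based boundary
modes would introduce their own shift artifacts, which is precisely the
effect this package exists to isolate; they are deliberately not
offered.  Signal lengths must be divisible by 2^J (enforced, never
padded) so that every decimated band has an integral length and the
periodicity diagnostics are well posed.

Fixed conventions, used identically everywhere:

- **Analysis** is circular convolution with the causally stored taps,
  `y[n] = Σ_m h[m] x[(n − m) mod N]`, followed (in the decimated
  pyramid) by keeping the even-indexed samples (offset 0).
- **Synthesis** applies the adjoint: upsample by zero insertion, then
  `x̂[n] = Σ_j u[j] h[(j − n) mod N]`.  For an orthonormal bank the
  analysis rows are orthonormal, so the adjoint is the exact inverse.
- **Shift by s** means circular right shift: sample n moves to
  (n + s) mod N.
- The **à trous** scheme dilates the filters at level j by inserting
  2^(j−1) − 1 zeros between taps.  Dilated filters are never
  materialised: the DFT of a filter dilated by d is the base filter's
  DFT sampled at (d·k) mod N, so each level is two FFT products.
  Filters longer than the current period are wrapped modulo N, which
  is the correct periodisation.
- The à trous filters stay √2-normalised at every level and the
  inverse averages the two redundant branches with a factor 1/2 per
  level (valid because |H(ω)|² + |G(ω)|² = 2 pointwise).  This choice —
  rather than renormalising dilated filters — preserves the
  subsampling identity coefficient-for-coefficient: decimated detail j
  equals redundant detail j sampled at stride 2^j, offset 0.

## Filter banks

Daubechies banks of order p (2p taps) are computed, not tabulated:
the maximally flat autocorrelation polynomial
P(y) = Σ_{k<p} C(p−1+k, k) y^k is rooted in y (degree p−1, far better
conditioned than rooting the degree-2(p−1) Laurent form), each y-root
is polished by Newton steps on the exact integer coefficients and
mapped through z² − (2 − 4y)z + 1 = 0, and the roots inside the unit
circle — the **minimum-phase** (extremal-phase) choice — are combined
with the p-fold zero at z = −1.  Tap sums are normalised to √2.
Orders above 20 are refused: beyond that the factorization can no
longer certify the orthonormality invariants in double precision.

The highpass is the alternating flip g[n] = (−1)^n h[2p−1−n]; synthesis
filters are the time reverses (orthogonal bank).  Validation evaluates
each defining invariant plus the two-channel perfect-reconstruction
conditions |H|² + |G|² = 2 and H(ω)H*(ω+π) + G(ω)G*(ω+π) = 0 on a
512-point frequency grid; construction passes everything below 1e-10
for all supported orders.

Phase convention: magnitude-spectrum diagnostics are unaffected by the
minimum-phase-versus-time-reversed choice, so fixing minimum phase
loses no generality.  PyWavelets tabulates the decomposition filters as
the time reverse of the causal sequence stored here and decimates on a
different phase; the cross-library tests feed this
package's taps into a custom `pywt.Wavelet`, after which coefficients
agree up to closed-form circular rolls: −L/2 + (L/4)·2^(1−j) per
decimated level j (integral e.g. for DB8 up to 3 levels) and
−(L/2)(2^j − 1) per stationary level, L the tap count.  These rolls are
functions of the two packages' alignment conventions only, never fitted
to data.

A numerical note on the vanishing-moment check: the p-th moment sums
Σ n^p g[n] involve terms up to ~19^9 for order 10, so even exact filters
leave absolute cancellation residue far above 1e-10 in doubles.  The
test therefore asserts the scale-aware form
|Σ n^p g[n]| ≤ 1e-8 · Σ n^p |g[n]|, which the constructed banks satisfy
with ~1e-16 margin at every order 1–10.

## Diagnostics

**Equivariance deviation.**  For band j and shift s the statistic is
max |w_j(shift(x, s)) − shift(w_j(x), s)|, comparing the shifted
*baseline* output against the output of the shifted input (equivalent,
under the circular convention, to un-shifting the test output; the
former is standardised).  A scheme is declared LTI over a shift set
when every band's deviation is below the tolerance (default 1e-10
absolute).  The gap between the two regimes is enormous — ~1e-16 for
undecimated bands versus ~1e-1 for decimated bands on the delta probe —
so the verdict is insensitive to the tolerance over many orders of
magnitude.

**TV periodicity** is estimated by exhaustive search: the smallest
p ≤ max_period (default 2^(J+1)) with deviation below tolerance at
shift p.  Brute force is its own oracle at these sizes; the measured
law is 2^j for decimated detail j, 2^J for the approximation band, and
1 for every undecimated band.  (The dyadic structure *forces* the
approximation band's period to be 2^J — the same as detail band J —
since both live on the stride-2^J lattice.)

**Distinct spectral patterns.**  Spectra are compared as one-sided DFT
*magnitudes* (pure delays must not count as differences), with relative
L∞ tolerance 1e-8 against greedily built class representatives in input
order — deterministic, and ~6 orders of magnitude away from both the
machine-precision congruences and the order-one discrepancies it must
separate.

**Passing bands.**  The theoretical band of detail j is
[fs/2^(j+1), fs/2^j]; the approximation band is assigned the complement
[0, fs/2^(J+1)].  The empirical band is the narrowest contiguous bin
interval holding a given fraction (default 0.9) of one-sided spectral
energy, ties broken toward lower frequency; a single-bin result is
widened by half a bin on each side so the interval is always proper.

## Synthetic inputs

The delta probe (N = 1000, impulse at 500, fs = 1000 Hz, DB8, 3
levels) is the canonical experiment: the impulse sits far from index 0,
so even under non-circular intuition no boundary is involved, and its
subspaces are the wavelet atoms themselves.

The EEG surrogate emulates a single-channel ictal-style recording at
200 Hz: unit-RMS Gaussian noise band-passed (4th-order Butterworth,
zero-phase) into the four scalp rhythm bands — delta 0.5–4 Hz
(amplitude 1.0), theta 4–8 (0.6), alpha 8–13 (0.4), beta 13–30 (0.2) —
plus a 1/f background (exponent 1, amplitude 0.3) and spike-wave
transients modelled as Mexican-hat pulses (width 40 ms, ~1 event/s) at
seeded Poisson times, placed circularly.  Amplitudes fall off with
frequency so that ≥ 80 % of spectral energy lies below 40 Hz (measured:
≈ 99 %), matching the low-frequency concentration of anti-alias-filtered
clinical recordings.  The default experiment uses 4 levels at 200 Hz so
detail bands 3 and 4 ([12.5, 25] and [6.25, 12.5] Hz) bracket the
alpha/beta rhythms.  What the surrogate does **not** model: neural mass
dynamics, multichannel structure, EMG or baseline-wander artifacts, or
any physiological validity beyond spectral shape — passing tests on it
demonstrates the transform/diagnostic machinery, not clinical claims.
All generators are pure functions of their parameters including the
seed.

## Problem sizes and numerical choices

The experiments are desk-scale by construction (N ≤ 1000, J ≤ 4,
orders ≤ 10 in the sweeps), so the full test suite and the acceptance
script each run in seconds.  Tolerances: 1e-10 for exactness claims
(round trips, equivariance, additivity, subsampling identity) — three
to four orders above observed residuals (~1e-14) and many below any
real effect; 1e-8 relative for spectral pattern equality; 1e-8 for
cross-library agreement.  Degenerate inputs are errors, not silent
results: all-zero signals for the empirical band, out-of-range shifts
and impulse locations, non-dyadic lengths, mismatched filter-bank
names.

## Known limitations

- Single-channel, 1-D, real-valued signals only; no wavelet-packet
  decomposition (also decimation-affected) and no approximately
  invariant transforms (dual-tree complex, harmonic, rational-dilation)
  — the undecimated transform is the exact-invariance reference point.
- Circular boundary only (see above — a design position, not an
  omission).
- Daubechies family only; the translation-variability phenomenon is
  basis-independent, so one orthonormal family suffices to exhibit and
  measure it.
- The undecimated transform costs (J+1)·N coefficients and O(J·N log N)
  time versus the pyramid's N coefficients — the usual price of exact
  shift invariance.
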