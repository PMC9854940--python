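# Methods

## The measurement model

The package evaluates the amplitude-measurement uncertainty of a two-stage
ECG front-end: a three-op-amp instrumentation preamplifier followed by a
non-inverting gain/filter stage. With matched resistor pairs the static
transfer functions are

    v1   = (1 + 2·R1/R2) · (R5/R4) · (vin+ − vin−)
    vout = (1 + R11/R8) · v1

and the first-order corner frequencies of the two blocks are

    f1 = 1 / (2π·C1·R9)          f2 = 1 / (2π·C2·R11).

At the reference component values (R1 = 22, R2 = R4 = 10, R5 = 47, R8 = 5,
R11 = 150 kΩ; R9 = 3.3 MΩ, C1 = 1 µF, C2 = 10 nF) the gains are
G1 = 25.38 and G2 = 31, the corners f1 ≈ 0.048 Hz and f2 ≈ 106 Hz.

Assumptions:

* **Static gain.** Budgets describe amplitude uncertainty at DC/midband.
  No frequency-dependent attenuation is applied to `vout`; the capacitors
  (and R9) shape only the corner frequencies and are tagged
  `block="frequency_only"`, excluded from the output equation. They can be
  propagated separately through `ecg_cutoff_systems()` to obtain
  corner-frequency budgets in Hz.
* **Input-referred disturbances.** Baseline wander and broadband noise are
  added to the differential input before the preamplifier gain:
  `vout = G1·G2·(vin+ − vin− + baseline + noise)`. With the reference
  levels (vin+ = 0.30, baseline = 3.00 mV) this puts the nominal operating
  point at 2596.4 mV, and it makes the baseline/noise rows of the budget
  scale by the full gain, consistent with their reported contributions.
* **Independence.** All uncertainty sources are independent; no correlated
  inputs, no op-amp non-idealities (offset, bias current, CMRR).

One deliberate data correction: the 3.3 MΩ resistor's tolerance interval is
taken as 3.30 MΩ ± 1% = (3.267, 3.333), consistent with every other 1%
resistor; it affects only f1, never the voltage budget.

## Input PDFs

Three families cover the assignments (`distributions.PDFSpec`):

| family       | parameters | mean      | sd             | used for |
|--------------|-----------|-----------|----------------|----------|
| normal       | µ, σ      | µ         | σ              | vin±, baseline, noise |
| rectangular  | a, b      | (a+b)/2   | (b−a)/√12      | resistor tolerances |
| u_shaped     | a, b      | (a+b)/2   | (b−a)/(2√2)    | capacitor drift |

The U-shaped family is the arcsine law, sampled by the inverse CDF
`x = a + (b−a)·sin²(πu/2)`; it is the metrology-standard model for bounded
quantities that dwell near their limits (components under bounded periodic
drift). Tolerance intervals are multiplicative on the nominal:
`from_tolerance(22.0, 0.01)` → rectangular(21.78, 22.22).

Every `UncertainQuantity` must have its nominal on the PDF mean (to 1 part
in 10³); budgets are reported relative to the nominal operating point and a
biased PDF would silently shift every row.

## Monte Carlo propagation

The sample count follows the minimum-count rule `m = ceil(10⁴/(1−p))` for
coverage probability p: 2×10⁵ samples at p = 0.95. Each run draws one
column of m values per input, evaluates the measurement equation row-wise,
and summarises the output into mean, sd (ddof = 1), the expanded
uncertainty `U95 = k·sd` with k = 1.96 at 95% (other coverages use the
normal quantile), and a symmetric-percentile coverage interval.

**Per-source runs reuse the full run's draws.** Every input owns an RNG
substream spawned deterministically from the run seed in declaration order
(`numpy` `SeedSequence.spawn`), so a subset run's varied columns are
bit-identical to the full run's columns for those inputs. Budget rows and
the total row are therefore consistent by construction, and the entire
budget is a pure function of (system, m, seed). Overlapping budget subsets
are allowed but logged, since their variances then no longer add.

**Reporting convention.** U95 is always k times the *unrounded* sd; table
cells round voltages to integer mV and percentages to two decimals, half
away from zero, from unrounded intermediates. At m = 2×10⁵ the standard
error of a reported sd is ≈ sd/√(2m) < 0.1 mV, so rounded values are
seed-stable — except where the underlying value sits essentially on a
rounding boundary, which genuinely happens in this model: the
differential-input row's sd is 44.51 mV (rounds 44 or 45 depending on
seed), the final-stage row's sd is 20.52 mV (20 or 21), and the full-run
relative expanded uncertainty is 4.319% (4.31 or 4.32). The acceptance
tests accept both adjacent values in exactly those cases.

A small genuine nonlinearity is visible in the row means: because
E[1/R] > 1/E[R] for a toleranced resistor, the propagated mean sits
≈ 0.2 mV above the nominal 2596.37 mV. This is real, not sampling error,
and is why a rounded mean occasionally reads 2597.

## Analytic (GUM-style) cross-check

`gum_propagate` combines the inputs' analytic standard uncertainties by
first-order propagation, `u(Y)² = Σ (∂y/∂Xᵢ · u(Xᵢ))²`, `U95 = k·u(Y)`,
taking u(Xᵢ) from the same PDF specs the sampler uses (σ; half-width/√3;
half-width/√2). Sensitivities are central finite differences with relative
step 10⁻⁶ of the nominal (falling back to 10⁻⁶ of u(Xᵢ) for zero
nominals), which keeps contributions invariant under unit-prefix changes
and balances truncation against round-off for this smooth model.

On the reference amplifier the analytic route lands within ~0.2% of the
Monte Carlo sd (57.2 mV, U95 ≈ 112 mV) — the model is nearly linear, so the
two routes must agree. Treatments that skip the √3/√2 reduction and feed
interval half-widths in raw inflate u(Y) by ~40% and are not what this
package computes. `compare_gum_mcm` reports the relative differences plus
the skewness and excess kurtosis of the Monte Carlo output: the full-system
output is near-normal, while the final-stage block alone (two comparable
rectangular tolerances) is triangular-like with excess kurtosis ≈ −0.6 —
the case where the analytic route's normality assumption is weakest and the
Monte Carlo route earns its keep.

## Synthetic ECG signals

`generate_ecg` sums Gaussian-shaped P, Q, R, S, T deflections per beat,
R peaks at (k+½)·RR; amplitudes follow the usual lead-II morphology ratios
scaled so the R peak matches the 0.30 mV input level of the uncertainty
model (P 0.045, Q −0.030, R 0.300, S −0.075, T 0.105 mV); offsets and
widths scale with the beat interval. Defaults: 60 bpm, 10 s, 500 Hz.
`add_baseline_and_noise` superimposes the disturbances the uncertainty
model parameterises: a 3.00 mV offset, respiratory-band sinusoidal drift
(0.05 mV at 0.2 Hz, below the 0.5 Hz trend boundary) and white Gaussian
noise (0.01 mV rms).

What the generator does *not* emulate: beat-to-beat interval and
morphology variability, muscle artifact, electrode motion, mains
interference, or any pathology. Passing round-trip tests therefore show
that the estimators are unbiased on clean morphology plus stationary
disturbances — not that they are robust to clinical recordings.

### Conditioning and estimation choices

* **Detrending** removes the best-fit line plus a sub-0.5 Hz
  moving-average baseline (2 s window, reflect padding) and re-centres to
  exactly zero mean. 0.5 Hz sits below the slowest cardiac fundamental
  (30 bpm); the 2 s uniform window has spectral nulls at multiples of
  0.5 Hz and passes 10 Hz content within 2%.
* **Low-pass** is a 4th-order Butterworth applied zero-phase
  (forward-backward), chosen for passband flatness; the two-pass
  application squares the magnitude response, so a 40 Hz tone retains
  < 1% of its power past a 30 Hz corner while 5 Hz content is untouched.
  The 30 Hz default is the conventional noise-removal corner for
  monitoring-grade ECG displays.
* **Spectra** use the two-sided centred convention `|DFT|²/n`, which makes
  total spectral power equal the summed squared samples exactly; the
  spectrogram is a Hann-windowed short-time version of the same quantity.
* **Parameter recovery** (`estimate_noise_params`): the baseline estimate
  is a two-stage rolling median (0.2 s then 0.6 s) — the standard
  isoelectric-line construction — rather than a moving average, because a
  moving average inherits the waveform's own nonzero beat average (~0.03 mV
  at the default amplitudes, a ~1% bias on a 3 mV baseline) while medians
  reject the sparse deflections outright. The noise sd is the spectral
  floor of the residual above the 30 Hz low-pass, averaged over
  max(2×corner, 0.6×Nyquist)–Nyquist where neither the filter transition
  nor the cardiac deflections retain any energy; 0.5 s of each edge is
  discarded to drop zero-phase filter transients. Measuring the floor in a
  fully-stopped band makes the estimate independent of the filter's
  roll-off shape (a raw residual sd under-reads white noise by ~6% at
  500 Hz).

## Problem sizes and runtime

All reference budgets use m = 2×10⁵ (the minimum-count rule at p = 0.95),
13 declared inputs of which 10 enter the static equation; a full budget
with variants and reports completes in roughly a second on one CPU. Signal
fixtures are 10 s at 500 Hz (5000 samples), generated at run time; nothing
is stored on disk beyond the YAML configuration.

## Known limitations

* Only the three PDF families above; no triangular, t, log-normal or
  empirical inputs, and no correlated sources.
* No adaptive (convergence-stopped) Monte Carlo and no quasi-random
  sequences; m is fixed by the coverage rule or the user.
* The amplifier model is static; uncertainty in the frequency response is
  available only as separate corner-frequency budgets, not folded into the
  voltage budget.
* Expression-based measurement equations support arithmetic, parentheses
  and a small set of unary functions — by design, to keep configuration
  files declarative and safe to evaluate.
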