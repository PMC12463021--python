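# Methods

## Signal model

Each recording channel is modelled as a damped sinusoid

    V(t) = A · sin(2πt/T + φ) · e^(−αt)

with amplitude `A` (mV), period `T` (s), damping factor `α` (1/s) and
phase `φ` (radians). The built-in presets carry the published
per-channel `(A, T)` pairs and observed peak counts for the pure
*E. huxleyi* culture (8 channels, default 1 Hz sampling) and for the
algae–Glu:Phe-proteinoid mixture (8 channels, default 2.5 Hz). All
ensemble work uses `α = 10⁻⁶ s⁻¹`; channel-specific values (e.g.
1.29×10⁻⁶ for the pure-culture ChE model) can be set per
`ChannelParams`.

**Phase convention.** The source channel equations contain no phase
term, so every channel starts at `φ = 0` at `t = 0`. This is a modelling
choice the underlying description implies but never states; it is what
reproduces the published gate high-state frequencies, and it is the main
reason those frequencies should be read as properties of the *stated
model*, not of the recordings.

**Time grid.** Half-open: `floor(duration·rate)` samples at step
`1/rate` starting at 0, so "10 000 s at 1 Hz" is exactly 10 000 samples
(matching the published sample counts).

**Noise and drift.** Measurement noise is i.i.d. Gaussian with SD
expressed as a fraction of the channel's *nominal* amplitude (the preset
value, not a running estimate) — "10% noise" on a 50.41 mV channel means
SD 5.041 mV. Baseline drift is linear, `intercept + slope·t`; real
recordings show slow non-linear drift as well, which the generator does
not emulate. Seeds are explicit everywhere; the CLI default seed is 42.

What the generator deliberately does **not** reproduce: light/dark-cycle
forcing, amplitude/period jitter between cycles, non-Gaussian artefacts,
electrode physics. A green parameter-recovery test therefore establishes
that the metrics pipeline is correct for the assumed signal class, not
that it is robust to every feature of real data.

## Oscillation metrics

Pipeline order: linear detrend → optional low-pass → extrema detection →
cycle segmentation → summary.

- **Detrend:** ordinary least squares on `(t, V)`; residuals have zero
  mean. Applied to recorded data by default, skipped for synthetic model
  signals (zero-mean by construction). Note that a zero-phase sine is
  *not* orthogonal to a linear ramp even over whole periods (the OLS
  slope is O(A·T/L²), ≈3×10⁻³ mV/s for an 80 mV, 500 s sine over
  5000 s); only the cosine phase is. Detrending a barely-sampled slow
  oscillation therefore perturbs it slightly — unavoidable, and shared
  by any linear-detrend convention.
- **Low-pass:** 4th-order zero-phase Butterworth
  (`scipy.signal.sosfiltfilt`). A cutoff at or above Nyquist is a
  documented no-op: the stated acquisition configuration (2 Hz cutoff on
  1–2.5 Hz-sampled data) cannot act below Nyquist, so it reproduces as
  identity rather than as some invented different filter. For noisy
  synthetic channels a sub-Nyquist cutoff (e.g. 0.01 Hz for periods
  ≥ 200 s) is what makes the 5 mV prominence gate effective again:
  broadband noise of SD ≈ 8 mV otherwise seeds spurious peaks.
- **Extrema:** `scipy.signal.find_peaks` with the stated defaults —
  minimum height 10 mV, prominence 5 mV, minimum separation 100 s
  (converted to samples with the channel rate). Troughs are peaks of the
  negated trace with prominence and separation only; no height gate by
  default, because channels with negative baselines make a symmetric
  +10 mV gate on minima meaningless (an optional symmetric gate exists).
  When two peaks compete within the separation window the higher wins;
  exact ties follow scipy's deterministic resolution (they do not arise
  in floating-point data).
- **Cycles:** cycle *j* spans peak *j* to peak *j+1*; its period is the
  peak-to-peak time and its amplitude is peak value minus the deepest
  trough inside the span. Cycles without a trough are skipped. The "100 s
  window" in the source's amplitude description is read as the extrema
  minimum separation, not a separate cycle window.
- **Summary:** `T̄` and `Ā` are plain means; `σ_A` uses the population
  divisor N exactly as the source formula is written; `f = 1/T̄` and
  `P = f·Ā²` are computed from the unrounded means, so the identities
  `f·T̄ = 1` and `P = Ā²/T̄` hold exactly in every summary object.

## Binarization and gates

`state = 1 iff V ≥ θ` (inclusive at equality). Two threshold modes:
fixed `θ` (50 mV in the published single-trace illustrations) and
half-amplitude (`θ = A/2` per channel, using the nominal preset
amplitude). The two conventions are genuinely in conflict in the source
material; half-amplitude is the default for the gate-frequency
experiments because it is the convention that reproduces the published
frequencies (verified numerically before implementation). The seven
gates are evaluated sample-wise; NOT applies to channel A. The
experiment is fully deterministic.

## Noise robustness and correlation

Error rate: the clean pipeline (generate → binarize → gate) and the
noisy pipeline (same deterministic signals + independent per-channel
Gaussian noise streams derived from one seed via `SeedSequence.spawn` →
binarize → gate) are compared sample-wise; the error rate is the
fraction of disagreeing samples. At zero noise it is exactly 0. For the
unary NOT gate the per-sample flip probability is exactly
`Φ(−|V(t)−θ|/σ)`, which provides an independent quadrature oracle for
the Monte Carlo estimate.

The published per-gate error rates (0.10–0.17) are **not** asserted
anywhere: under the stated model, 10% noise and half-amplitude
thresholds, the quadrature value is ≈0.03 per channel, so the exact
procedure behind the published numbers is ambiguous. Likewise the
published pairwise correlations (e.g. 0.98 for two channels whose phase
drifts ≈1.6 cycles over the window) are not consistent with plain
Pearson on the stated model; the correlation matrix is reported, and its
structural properties (symmetry, unit diagonal, entries in [−1, 1],
positive semidefiniteness) are what the tests assert.

## Numerical and design choices

- Threshold resolution must be positive; binarization of an all-negative
  trace against a positive θ is legitimately all-zero.
- `min_separation` must be at least one sample interval; it is converted
  to samples by rounding.
- Summary of an empty cycle set (flat or sub-threshold trace) raises a
  `ValueError`; the report-level table instead records a NaN row for
  such channels so one quiet channel does not abort an 8-channel report.
- Recordings travel as delimited text with a `time_s` column; the rate
  is the reciprocal median step, and steps must be uniform to 1%
  (non-monotone or irregular files raise distinct parse errors).
- The full report writes a JSON manifest (all parameters + seed);
  rerunning from the same config is byte-identical.

## Limitations

- All headline gate/correlation quantities are properties of the damped
  sinusoid model with the published parameters, not re-analyses of the
  deposited raw recordings (which are optional inputs the parser can
  read but which ship nowhere in this repository).
- Spectral estimation (FFT, Lomb–Scargle) is deliberately out of scope;
  the statistics are time-domain peak statistics only.
- No multi-gate circuits, temporal logic, or adaptation: the system
  binarizes and combines signals, it does not compute autonomously.
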