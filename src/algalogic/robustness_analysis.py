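"""Gate reliability under noise and cross-channel synchronization.

Noise robustness is measured by comparing a gate's output on clean
model signals with its output when independent Gaussian noise (SD a
fixed fraction of each channel's nominal amplitude) is added to the
analog traces before binarization; the error rate is the fraction of
samples on which the two outputs differ.  Channel synchronization is
measured as plain Pearson correlation between analog model traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .logic_engine import GateKind, ThresholdSpec, binarize, eval_gate
from .synthetic_signals import (DEFAULT_ALPHA, EnsemblePreset, TimeSeries,
                                add_gaussian_noise, generate_channel,
                                generate_ensemble)

__all__ = [
    "ErrorRateResult",
    "CorrelationMatrix",
    "gate_error_rate",
    "pearson_correlation",
    "correlation_matrix",
]


@dataclass(frozen=True)
class ErrorRateResult:
    gate: GateKind
    noise_sd_fraction: float
    error_rate: float
    n_samples: int
    seed: int


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric, unit-diagonal table of pairwise Pearson r values."""

    labels: tuple[str, ...]
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValueError("coefficient matrix shape must match labels")
        object.__setattr__(self, "coefficients", c)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.coefficients[i, j])


def gate_error_rate(preset: EnsemblePreset, channel_a: str, channel_b: str,
                    gate: GateKind, noise_sd_fraction: float = 0.1,
                    duration: float = 10_000.0, rate: float | None = None,
                    seed: int = 0, alpha: float = DEFAULT_ALPHA) -> ErrorRateResult:
    """Fraction of samples where the noisy gate output differs from the clean one.

    Clean pipeline: generate -> binarize (half-amplitude) -> gate.
    Noisy pipeline: the same deterministic signals with independent
    Gaussian noise streams (derived from ``seed``) added per channel
    before binarization.  The two pipelines share the analog signals, so
    the disagreement isolates the effect of noise.
    """
    if noise_sd_fraction < 0:
        raise ValueError("noise_sd_fraction must be >= 0")
    gate = GateKind(gate)
    rate = preset.default_rate if rate is None else rate
    pa = replace(preset.channel(channel_a), damping_alpha=alpha)
    pb = replace(preset.channel(channel_b), damping_alpha=alpha)
    ts_a = generate_channel(pa, duration, rate)
    ts_b = generate_channel(pb, duration, rate)
    spec_a = ThresholdSpec.half_amplitude(pa.amplitude_A)
    spec_b = ThresholdSpec.half_amplitude(pb.amplitude_A)

    # independent per-channel noise streams from one seed
    child_a, child_b = np.random.SeedSequence(seed).spawn(2)
    seed_a = int(child_a.generate_state(1)[0] % (2 ** 31))
    seed_b = int(child_b.generate_state(1)[0] % (2 ** 31))
    noisy_a = add_gaussian_noise(ts_a, noise_sd_fraction, pa.amplitude_A, seed_a)
    noisy_b = add_gaussian_noise(ts_b, noise_sd_fraction, pb.amplitude_A, seed_b)

    def run(a: TimeSeries, b: TimeSeries) -> np.ndarray:
        ia, ib = binarize(a, spec_a), binarize(b, spec_b)
        if gate.is_unary:
            return eval_gate(gate, ia).output.states
        return eval_gate(gate, ia, ib).output.states

    clean = run(ts_a, ts_b)
    noisy = run(noisy_a, noisy_b)
    return ErrorRateResult(gate=gate, noise_sd_fraction=noise_sd_fraction,
                           error_rate=float(np.mean(clean != noisy)),
                           n_samples=len(clean), seed=seed)


def pearson_correlation(x: TimeSeries, y: TimeSeries) -> float:
    """Pearson product-moment correlation between two traces on one grid."""
    if len(x) != len(y) or x.t0 != y.t0 or x.rate != y.rate:
        raise ValueError("series must share the same time grid")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(x.values) == 0 or np.ptp(y.values) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(x.values, y.values).statistic)


def correlation_matrix(preset: EnsemblePreset, duration: float = 10_000.0,
                       rate: float | None = None,
                       alpha: float = DEFAULT_ALPHA) -> CorrelationMatrix:
    """All pairwise Pearson r over the zero-phase model ensemble."""
    series = generate_ensemble(preset, duration, rate=rate, alpha=alpha)
    n = len(series)
    coef = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = pearson_correlation(series[i], series[j])
            coef[i, j] = coef[j, i] = r
    return CorrelationMatrix(labels=tuple(s.label for s in series),
                             coefficients=coef)
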