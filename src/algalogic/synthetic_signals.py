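"""Synthetic multichannel bioelectric signal generation.

Cultures of *Emiliania huxleyi* (and algae-proteinoid mixtures) produce
spontaneous, slowly decaying voltage oscillations on each recording
electrode.  Per channel the model is a damped sinusoid

    V(t) = A * sin(2*pi*t / T + phi) * exp(-alpha * t)

with amplitude ``A`` (mV), period ``T`` (s) and damping factor ``alpha``
(1/s).  Two presets bundle the published per-channel parameters: one for
the pure algal culture (8 channels, 1 Hz sampling) and one for the
algae-Glu:Phe-proteinoid mixture (8 channels, 2.5 Hz sampling).
Gaussian measurement noise and linear baseline drift can be layered on
top to emulate real logger exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelParams",
    "EnsemblePreset",
    "TimeSeries",
    "PURE_ALGAE",
    "MIXTURE",
    "DEFAULT_ALPHA",
    "damped_sine_value",
    "generate_channel",
    "generate_ensemble",
    "add_gaussian_noise",
    "add_linear_drift",
    "write_preset",
    "read_preset",
]

#: Default damping factor for ensemble work, 1/s.
DEFAULT_ALPHA = 1e-6


@dataclass(frozen=True)
class ChannelParams:
    """Damped-sinusoid model parameters for one recording channel.

    Parameters
    ----------
    label
        Channel name, e.g. ``"ChA"``.
    amplitude_A
        Mean oscillation amplitude, mV.  Must be nonnegative (zero is
        allowed for degenerate test signals).
    period_T
        Mean oscillation period, s.
    damping_alpha
        Exponential damping factor, 1/s.
    n_peaks_observed
        Number of peaks reported for the real recording; informational
        only, never used in generation.
    """

    label: str
    amplitude_A: float
    period_T: float
    damping_alpha: float = DEFAULT_ALPHA
    n_peaks_observed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_A < 0:
            raise ValueError(f"amplitude_A must be >= 0, got {self.amplitude_A}")
        if self.period_T <= 0:
            raise ValueError(f"period_T must be > 0, got {self.period_T}")
        if self.damping_alpha < 0:
            raise ValueError(f"damping_alpha must be >= 0, got {self.damping_alpha}")
        if self.n_peaks_observed < 0:
            raise ValueError("n_peaks_observed must be >= 0")


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled potential trace.

    Sample ``i`` has timestamp ``t0 + i / rate``.  Values are differential
    potentials in mV (positive minus reference electrode; the subtraction
    itself happens in hardware).
    """

    t0: float
    rate: float
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def times(self) -> np.ndarray:
        """Timestamps in seconds, strictly increasing."""
        return self.t0 + np.arange(len(self.values)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.rate

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EnsemblePreset:
    """A named collection of channel parameters plus a default sampling rate."""

    name: str
    channels: tuple[ChannelParams, ...]
    default_rate: float

    def __post_init__(self) -> None:
        if self.default_rate <= 0:
            raise ValueError("default_rate must be > 0")

    def channel(self, label: str) -> ChannelParams:
        for ch in self.channels:
            if ch.label == label:
                return ch
        raise KeyError(f"no channel {label!r} in preset {self.name!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(ch.label for ch in self.channels)


def _preset(name: str, rate: float, rows: Sequence[tuple[str, float, float, int]]) -> EnsemblePreset:
    return EnsemblePreset(
        name=name,
        channels=tuple(
            ChannelParams(label=lab, amplitude_A=a, period_T=t,
                          damping_alpha=DEFAULT_ALPHA, n_peaks_observed=n)
            for lab, a, t, n in rows
        ),
        default_rate=rate,
    )


#: Pure *E. huxleyi* culture: published per-channel mean amplitude (mV),
#: mean period (s) and peak count over 48 h; sampled at 1 Hz.
PURE_ALGAE = _preset("PURE_ALGAE", 1.0, [
    ("ChA", 35.94, 929.53, 185),
    ("ChB", 50.41, 299.88, 480),
    ("ChC", 65.86, 543.99, 317),
    ("ChD", 79.93, 3611.79, 48),
    ("ChE", 80.94, 724.00, 239),
    ("ChF", 54.76, 563.72, 306),
    ("ChG", 43.81, 819.75, 210),
    ("ChH", 48.43, 647.16, 265),
])

#: Algae + Glu:Phe proteinoid mixture; sampled at 2.5 Hz.
MIXTURE = _preset("MIXTURE", 2.5, [
    ("ChA", 25.49, 5471.01, 32),
    ("ChB", 33.75, 3915.16, 45),
    ("ChC", 83.50, 350.49, 493),
    ("ChD", 83.37, 251.92, 627),
    ("ChE", 34.24, 1447.43, 120),
    ("ChF", 191.42, 403.78, 396),
    ("ChG", 33.72, 4482.76, 39),
    ("ChH", 29.32, 1930.98, 89),
])

PRESETS = {"PURE_ALGAE": PURE_ALGAE, "MIXTURE": MIXTURE}


def damped_sine_value(params: ChannelParams, t, phase: float = 0.0):
    """Evaluate the damped-sinusoid channel model at time ``t`` (seconds).

    Returns ``A * sin(2*pi*t/T + phase) * exp(-alpha*t)`` in mV.  Accepts
    scalar or array ``t``.
    """
    t = np.asarray(t, dtype=float)
    out = (params.amplitude_A
           * np.sin(2.0 * np.pi * t / params.period_T + phase)
           * np.exp(-params.damping_alpha * t))
    return out if out.ndim else float(out)


def generate_channel(params: ChannelParams, duration: float, rate: float,
                     phase: float = 0.0) -> TimeSeries:
    """Sample the channel model on the half-open grid [0, duration).

    ``floor(duration * rate)`` samples at step ``1/rate``, so 10 000 s at
    1 Hz yields exactly 10 000 samples.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    n = int(np.floor(duration * rate))
    t = np.arange(n) / rate
    return TimeSeries(t0=0.0, rate=rate,
                      values=damped_sine_value(params, t, phase),
                      label=params.label)


def generate_ensemble(preset: EnsemblePreset, duration: float,
                      rate: float | None = None,
                      alpha: float | None = None,
                      phase: float = 0.0) -> list[TimeSeries]:
    """Generate one zero-phase TimeSeries per preset channel on a common grid.

    ``rate=None`` uses the preset's default sampling rate; ``alpha=None``
    keeps each channel's stored damping factor (1e-6 1/s in the built-in
    presets).
    """
    rate = preset.default_rate if rate is None else rate
    out = []
    for ch in preset.channels:
        if alpha is not None:
            ch = replace(ch, damping_alpha=alpha)
        out.append(generate_channel(ch, duration, rate, phase))
    return out


def add_gaussian_noise(ts: TimeSeries, sd_fraction: float,
                       reference_amplitude: float, seed: int) -> TimeSeries:
    """Add i.i.d. Gaussian noise with SD = ``sd_fraction * reference_amplitude``.

    The noise level is expressed as a fraction of the channel's nominal
    amplitude (e.g. 0.1 for "10% of the average amplitude").  Deterministic
    given ``seed``.
    """
    if sd_fraction < 0:
        raise ValueError(f"sd_fraction must be >= 0, got {sd_fraction}")
    if reference_amplitude <= 0:
        raise ValueError("reference_amplitude must be > 0")
    if sd_fraction == 0:
        return ts
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd_fraction * reference_amplitude, size=len(ts))
    return replace(ts, values=ts.values + noise)


def add_linear_drift(ts: TimeSeries, slope: float, intercept: float = 0.0) -> TimeSeries:
    """Superimpose a linear baseline drift ``intercept + slope * t`` (mV)."""
    return replace(ts, values=ts.values + intercept + slope * ts.times)


# ---------------------------------------------------------------------------
# Serialization

_PRESET_COLUMNS = ["label", "amplitude_mV", "period_s", "alpha_per_s", "n_peaks"]


def write_preset(preset: EnsemblePreset, path: str | Path) -> None:
    """Write channel parameters as delimited text (one row per channel)."""
    df = pd.DataFrame(
        [(c.label, c.amplitude_A, c.period_T, c.damping_alpha, c.n_peaks_observed)
         for c in preset.channels],
        columns=_PRESET_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_preset(path: str | Path, name: str = "custom",
                default_rate: float = 1.0) -> EnsemblePreset:
    """Read a channel-parameter file written by :func:`write_preset`."""
    df = pd.read_csv(path)
    missing = set(_PRESET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"preset file missing columns: {sorted(missing)}")
    channels = tuple(
        ChannelParams(label=str(r.label), amplitude_A=float(r.amplitude_mV),
                      period_T=float(r.period_s), damping_alpha=float(r.alpha_per_s),
                      n_peaks_observed=int(r.n_peaks))
        for r in df.itertuples()
    )
    return EnsemblePreset(name=name, channels=channels, default_rate=default_rate)
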