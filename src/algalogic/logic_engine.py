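"""Threshold binarization and Boolean gates on oscillatory signals.

A channel's analog trace is mapped to a binary train by a voltage
threshold theta: sample i is 1 iff V_i >= theta.  Two conventions are
supported — a fixed threshold (50 mV in the published single-trace
figures) and half the channel's nominal mean amplitude (used for the
gate-frequency experiments).  Seven gates (AND, OR, NOT, XOR, NAND, NOR,
XNOR) are evaluated sample-wise on pairs of binary trains; the summary
statistic is the high-state frequency, the fraction of samples at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .synthetic_signals import (DEFAULT_ALPHA, EnsemblePreset, TimeSeries,
                                generate_channel)

__all__ = [
    "ThresholdMode",
    "ThresholdSpec",
    "BinarySignal",
    "GateKind",
    "GateResult",
    "binarize",
    "eval_gate",
    "truth_table",
    "gate_frequency_experiment",
]


class ThresholdMode(str, Enum):
    FIXED = "FIXED"
    HALF_AMPLITUDE = "HALF_AMPLITUDE"


class GateKind(str, Enum):
    AND = "AND"
    OR = "OR"
    NOT = "NOT"
    XOR = "XOR"
    NAND = "NAND"
    NOR = "NOR"
    XNOR = "XNOR"

    @property
    def is_unary(self) -> bool:
        return self is GateKind.NOT


@dataclass(frozen=True)
class ThresholdSpec:
    """Binarization threshold: fixed theta or half a reference amplitude."""

    mode: ThresholdMode = ThresholdMode.HALF_AMPLITUDE
    theta: float | None = None
    reference_amplitude: float | None = None

    @staticmethod
    def fixed(theta: float) -> "ThresholdSpec":
        return ThresholdSpec(mode=ThresholdMode.FIXED, theta=theta)

    @staticmethod
    def half_amplitude(reference_amplitude: float) -> "ThresholdSpec":
        return ThresholdSpec(mode=ThresholdMode.HALF_AMPLITUDE,
                             reference_amplitude=reference_amplitude)

    def resolve(self) -> float:
        """Resolved threshold in mV; must be positive."""
        if self.mode is ThresholdMode.FIXED:
            if self.theta is None:
                raise ValueError("FIXED threshold requires theta")
            theta = self.theta
        else:
            if self.reference_amplitude is None:
                raise ValueError("HALF_AMPLITUDE threshold requires reference_amplitude")
            theta = self.reference_amplitude / 2.0
        if theta <= 0:
            raise ValueError(f"resolved threshold must be > 0, got {theta}")
        return float(theta)


@dataclass(frozen=True)
class BinarySignal:
    """A 0/1 train on the same grid as its source TimeSeries."""

    t0: float
    rate: float
    states: np.ndarray
    threshold_used: float
    source_label: str = ""

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.uint8)
        if states.size and not np.isin(states, (0, 1)).all():
            raise ValueError("states must be 0/1")
        object.__setattr__(self, "states", states)

    @property
    def high_state_frequency(self) -> float:
        return float(np.mean(self.states)) if self.states.size else 0.0

    def same_grid(self, other: "BinarySignal") -> bool:
        return (self.t0 == other.t0 and self.rate == other.rate
                and len(self.states) == len(other.states))

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class GateResult:
    gate: GateKind
    output: BinarySignal
    high_state_frequency: float


def binarize(ts: TimeSeries, spec: ThresholdSpec) -> BinarySignal:
    """Threshold a trace: state 1 iff value >= theta (inclusive at equality)."""
    theta = spec.resolve()
    return BinarySignal(t0=ts.t0, rate=ts.rate,
                        states=(ts.values >= theta).astype(np.uint8),
                        threshold_used=theta, source_label=ts.label)


_GATE_FUNCS = {
    GateKind.AND: lambda a, b: a & b,
    GateKind.OR: lambda a, b: a | b,
    GateKind.XOR: lambda a, b: a ^ b,
    GateKind.NAND: lambda a, b: 1 - (a & b),
    GateKind.NOR: lambda a, b: 1 - (a | b),
    GateKind.XNOR: lambda a, b: 1 - (a ^ b),
    GateKind.NOT: lambda a, b: 1 - a,
}


def eval_gate(gate: GateKind, a: BinarySignal,
              b: BinarySignal | None = None) -> GateResult:
    """Apply a gate sample-wise; NOT is unary, all others binary."""
    gate = GateKind(gate)
    if gate.is_unary:
        if b is not None:
            raise ValueError("NOT takes a single input")
        states = _GATE_FUNCS[gate](a.states.astype(np.uint8), None)
    else:
        if b is None:
            raise ValueError(f"{gate.value} requires two inputs")
        if not a.same_grid(b):
            raise ValueError("inputs must share the same time grid")
        states = _GATE_FUNCS[gate](a.states.astype(np.uint8), b.states.astype(np.uint8))
    out = BinarySignal(t0=a.t0, rate=a.rate, states=states.astype(np.uint8),
                       threshold_used=a.threshold_used,
                       source_label=f"{gate.value}({a.source_label}"
                                    + (f",{b.source_label})" if b is not None else ")"))
    return GateResult(gate=gate, output=out,
                      high_state_frequency=out.high_state_frequency)


def truth_table(gate: GateKind) -> list[tuple[tuple[int, ...], int]]:
    """Exhaustive truth table: 2 rows for NOT, 4 rows for binary gates."""
    gate = GateKind(gate)
    rows: list[tuple[tuple[int, ...], int]] = []
    if gate.is_unary:
        for a in (0, 1):
            out = _GATE_FUNCS[gate](np.uint8(a), None)
            rows.append(((a,), int(out)))
    else:
        for a in (0, 1):
            for b in (0, 1):
                out = _GATE_FUNCS[gate](np.uint8(a), np.uint8(b))
                rows.append(((a, b), int(out)))
    return rows


def gate_frequency_experiment(preset: EnsemblePreset, channel_a: str = "ChA",
                              channel_b: str = "ChB", duration: float = 10_000.0,
                              rate: float | None = None,
                              threshold_mode: ThresholdMode = ThresholdMode.HALF_AMPLITUDE,
                              fixed_theta: float = 50.0,
                              alpha: float = DEFAULT_ALPHA,
                              ) -> dict[GateKind, float]:
    """High-state frequency of all seven gates on a two-channel simulation.

    Generates zero-phase damped sinusoids for the two named preset
    channels (common damping factor ``alpha``), binarizes each at half
    its own nominal amplitude (or at ``fixed_theta`` in FIXED mode), and
    evaluates every gate sample-wise; NOT is applied to ``channel_a``.
    Fully deterministic.
    """
    from dataclasses import replace as _replace

    rate = preset.default_rate if rate is None else rate
    pa = _replace(preset.channel(channel_a), damping_alpha=alpha)
    pb = _replace(preset.channel(channel_b), damping_alpha=alpha)
    ts_a = generate_channel(pa, duration, rate)
    ts_b = generate_channel(pb, duration, rate)
    if threshold_mode is ThresholdMode.HALF_AMPLITUDE:
        spec_a = ThresholdSpec.half_amplitude(pa.amplitude_A)
        spec_b = ThresholdSpec.half_amplitude(pb.amplitude_A)
    else:
        spec_a = spec_b = ThresholdSpec.fixed(fixed_theta)
    ia, ib = binarize(ts_a, spec_a), binarize(ts_b, spec_b)
    out: dict[GateKind, float] = {}
    for gate in GateKind:
        if gate.is_unary:
            out[gate] = eval_gate(gate, ia).high_state_frequency
        else:
            out[gate] = eval_gate(gate, ia, ib).high_state_frequency
    return out
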