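"""File I/O, run configuration and command-line orchestration.

Multichannel recordings travel as delimited text: a ``time_s`` column in
seconds plus one potential column (mV) per channel, uniformly sampled —
the layout produced by common data-logger exports.  ``run_report`` ties
the pipeline stages together (simulate -> metrics -> gates -> noise ->
correlate) and writes every table plus a JSON manifest of the exact
parameters and seed, so a run can be reproduced from its outputs alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import synthetic_signals as syn
from .logic_engine import (GateKind, ThresholdMode, ThresholdSpec,
                           gate_frequency_experiment)
from .oscillation_metrics import analyze_channel
from .robustness_analysis import correlation_matrix, gate_error_rate
from .synthetic_signals import (MIXTURE, PRESETS, PURE_ALGAE, EnsemblePreset,
                                TimeSeries, add_gaussian_noise,
                                generate_ensemble)

__all__ = [
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "summary_table",
    "run_report",
    "cli",
]

logger = logging.getLogger("algalogic")

DEFAULT_SEED = 42


class TimeSeriesParseError(ValueError):
    """Raised when a delimited-text recording cannot be parsed."""


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters for a full pipeline run."""

    preset: str = "PURE_ALGAE"
    duration: float = 10_000.0
    rate: float | None = None          # None -> preset default
    threshold_mode: str = "HALF_AMPLITUDE"
    fixed_theta: float = 50.0
    min_height: float = 10.0
    prominence: float = 5.0
    min_separation: float = 100.0
    noise_sd_fraction: float = 0.1
    seed: int = DEFAULT_SEED
    channel_a: str = "ChA"
    channel_b: str = "ChB"
    out_dir: str = "algalogic_report"

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.rate is not None and self.rate <= 0:
            raise ValueError("rate must be > 0")
        ThresholdMode(self.threshold_mode)
        if self.fixed_theta <= 0:
            raise ValueError("fixed_theta must be > 0")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        if self.min_height < 0 or self.prominence < 0 or self.min_separation <= 0:
            raise ValueError("extrema thresholds must be nonnegative (separation > 0)")

    @property
    def resolved_rate(self) -> float:
        return PRESETS[self.preset].default_rate if self.rate is None else self.rate


# ---------------------------------------------------------------------------
# Delimited-text series I/O

def write_timeseries(series: list[TimeSeries], path: str | Path,
                     delimiter: str = ",") -> None:
    """Write a common-grid ensemble as ``time_s,<label>,...`` text."""
    if not series:
        raise ValueError("nothing to write")
    n = len(series[0])
    if any(len(s) != n or s.rate != series[0].rate or s.t0 != series[0].t0
           for s in series):
        raise ValueError("all series must share one time grid")
    df = pd.DataFrame({"time_s": series[0].times})
    for s in series:
        df[s.label or "Ch?"] = s.values
    df.to_csv(path, index=False, sep=delimiter)


def read_timeseries(path: str | Path, delimiter: str = ",") -> list[TimeSeries]:
    """Read a multichannel delimited-text recording.

    The first column must be monotone time in seconds; the sampling rate
    is inferred from the median step and steps must be uniform to within
    1%.  Returns one TimeSeries per remaining column.
    """
    path = Path(path)
    if not path.exists():
        raise TimeSeriesParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=delimiter)
    except Exception as exc:  # malformed text
        raise TimeSeriesParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise TimeSeriesParseError("need >= 2 rows and a time column plus >= 1 channel")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise TimeSeriesParseError("time column must be strictly increasing")
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > 0.01 * step):
        raise TimeSeriesParseError("sampling is non-uniform beyond 1% tolerance")
    rate = 1.0 / step
    return [TimeSeries(t0=float(t[0]), rate=rate,
                       values=df[col].to_numpy(dtype=float), label=str(col))
            for col in df.columns[1:]]


# ---------------------------------------------------------------------------
# Report orchestration

def summary_table(series: list[TimeSeries], detrend: bool = True,
                  min_height: float = 10.0, prominence: float = 5.0,
                  min_separation: float = 100.0) -> pd.DataFrame:
    """Per-channel oscillation summary as a table.

    Channels with too few detected cycles to summarise (e.g. a slow
    oscillator observed for under two periods) get a NaN row rather than
    aborting the whole table.
    """
    rows = []
    for s in series:
        try:
            _, summ = analyze_channel(s, detrend=detrend, min_height=min_height,
                                      prominence=prominence,
                                      min_separation=min_separation)
            rows.append({"label": s.label,
                         "mean_amplitude_mV": summ.mean_amplitude_Abar,
                         "mean_period_s": summ.mean_period_Tbar,
                         "n_peaks": summ.n_peaks_N,
                         "frequency_Hz": summ.frequency_f,
                         "power_mV2Hz": summ.power_P,
                         "sd_amplitude_mV": summ.sd_amplitude_sigmaA})
        except ValueError:
            logger.warning("channel %s: too few cycles to summarise", s.label)
            rows.append({"label": s.label, "mean_amplitude_mV": np.nan,
                         "mean_period_s": np.nan, "n_peaks": 0,
                         "frequency_Hz": np.nan, "power_mV2Hz": np.nan,
                         "sd_amplitude_mV": np.nan})
    return pd.DataFrame(rows)


def run_report(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write all report tables plus a manifest.

    Returns a mapping of artifact name to written path.  Deterministic
    given the config (including its seed).
    """
    preset = PRESETS[config.preset]
    rate = config.resolved_rate
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    try:
        t0 = stage("simulate")
        series = generate_ensemble(preset, config.duration, rate=rate)
        p = out / "series.csv"
        write_timeseries(series, p)
        artifacts["series"] = p
        logger.info("stage simulate done in %.2fs", time.perf_counter() - t0)

        t0 = stage("metrics")
        p = out / "summary.csv"
        # model signals are zero-mean by construction; no detrend
        summary_table(series, detrend=False, min_height=config.min_height,
                      prominence=config.prominence,
                      min_separation=config.min_separation).to_csv(p, index=False)
        artifacts["summary"] = p
        logger.info("stage metrics done in %.2fs", time.perf_counter() - t0)

        t0 = stage("gates")
        freqs = gate_frequency_experiment(
            preset, config.channel_a, config.channel_b, config.duration, rate,
            threshold_mode=ThresholdMode(config.threshold_mode),
            fixed_theta=config.fixed_theta)
        p = out / "gate_frequencies.csv"
        pd.DataFrame({"gate": [g.value for g in freqs],
                      "high_state_frequency": list(freqs.values())}
                     ).to_csv(p, index=False)
        artifacts["gate_frequencies"] = p
        logger.info("stage gates done in %.2fs", time.perf_counter() - t0)

        t0 = stage("noise")
        rows = []
        for gate in GateKind:
            res = gate_error_rate(preset, config.channel_a, config.channel_b,
                                  gate, config.noise_sd_fraction,
                                  config.duration, rate, seed=config.seed)
            rows.append({"gate": gate.value, "noise_sd_fraction": res.noise_sd_fraction,
                         "error_rate": res.error_rate, "n_samples": res.n_samples,
                         "seed": res.seed})
        p = out / "error_rates.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        artifacts["error_rates"] = p
        logger.info("stage noise done in %.2fs", time.perf_counter() - t0)

        t0 = stage("correlate")
        cm = correlation_matrix(preset, config.duration, rate)
        p = out / "correlation_matrix.csv"
        pd.DataFrame(cm.coefficients, index=list(cm.labels),
                     columns=list(cm.labels)).to_csv(p)
        artifacts["correlation_matrix"] = p
        logger.info("stage correlate done in %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"report stage failed: {exc}") from exc

    manifest = {"config": asdict(config), "resolved_rate": rate,
                "artifacts": {k: str(v) for k, v in artifacts.items()}}
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = p
    return artifacts


# ---------------------------------------------------------------------------
# CLI

def _preset_opt(name: str) -> EnsemblePreset:
    return {"pure": PURE_ALGAE, "mixture": MIXTURE}[name]


def _parse_threshold(text: str) -> tuple[ThresholdMode, float]:
    if text == "half":
        return ThresholdMode.HALF_AMPLITUDE, 50.0
    if text.startswith("fixed:"):
        return ThresholdMode.FIXED, float(text.split(":", 1)[1])
    raise click.BadParameter("threshold must be 'half' or 'fixed:<mV>'")


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Enable stage logging.")
def cli(verbose: bool) -> None:
    """Oscillation statistics and Boolean logic from bioelectric recordings."""
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING,
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--preset", type=click.Choice(["pure", "mixture"]), default="pure")
@click.option("--duration", type=float, default=10_000.0, show_default=True)
@click.option("--rate", type=float, default=None, help="Hz; default: preset rate.")
@click.option("--noise-sd", type=float, default=0.0, show_default=True,
              help="Gaussian noise SD as a fraction of each channel amplitude.")
@click.option("--seed", type=int, default=DEFAULT_SEED, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def simulate(preset, duration, rate, noise_sd, seed, out):
    """Generate a synthetic multichannel recording as delimited text."""
    p = _preset_opt(preset)
    series = generate_ensemble(p, duration, rate=rate)
    if noise_sd > 0:
        children = np.random.SeedSequence(seed).spawn(len(series))
        series = [add_gaussian_noise(s, noise_sd, ch.amplitude_A,
                                     int(c.generate_state(1)[0] % 2 ** 31))
                  for s, ch, c in zip(series, p.channels, children)]
    write_timeseries(series, out)
    click.echo(f"wrote {len(series)} channels x {len(series[0])} samples to {out}")


@cli.command()
@click.argument("recording", type=click.Path(exists=True))
@click.option("--delimiter", default=",", show_default=True)
@click.option("--no-detrend", is_flag=True, help="Skip linear detrending.")
@click.option("--min-height", type=float, default=10.0, show_default=True)
@click.option("--prominence", type=float, default=5.0, show_default=True)
@click.option("--min-separation", type=float, default=100.0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def metrics(recording, delimiter, no_detrend, min_height, prominence,
            min_separation, out):
    """Per-channel oscillation summary table from a recording file."""
    series = read_timeseries(recording, delimiter)
    df = summary_table(series, detrend=not no_detrend, min_height=min_height,
                       prominence=prominence, min_separation=min_separation)
    df.to_csv(out, index=False)
    click.echo(f"wrote {len(df)} channel summaries to {out}")


@cli.command()
@click.option("--preset", type=click.Choice(["pure", "mixture"]), default="pure")
@click.option("--channels", default="ChA,ChB", show_default=True)
@click.option("--duration", type=float, default=10_000.0, show_default=True)
@click.option("--rate", type=float, default=None)
@click.option("--threshold", default="half", show_default=True,
              help="'half' or 'fixed:<mV>'.")
@click.option("--out", type=click.Path(), required=True)
def gates(preset, channels, duration, rate, threshold, out):
    """Gate high-state frequency table for a two-channel simulation."""
    cha, chb = (c.strip() for c in channels.split(","))
    mode, theta = _parse_threshold(threshold)
    freqs = gate_frequency_experiment(_preset_opt(preset), cha, chb, duration,
                                      rate, threshold_mode=mode, fixed_theta=theta)
    pd.DataFrame({"gate": [g.value for g in freqs],
                  "high_state_frequency": list(freqs.values())}
                 ).to_csv(out, index=False)
    for g, f in freqs.items():
        click.echo(f"{g.value}\t{f:.3f}")


@cli.command()
@click.option("--preset", type=click.Choice(["pure", "mixture"]), default="pure")
@click.option("--channels", default="ChA,ChB", show_default=True)
@click.option("--sd-fraction", type=float, default=0.1, show_default=True)
@click.option("--duration", type=float, default=10_000.0, show_default=True)
@click.option("--seed", type=int, default=DEFAULT_SEED, show_default=True)
@click.option("--replicates", type=int, default=1, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def noise(preset, channels, sd_fraction, duration, seed, replicates, out):
    """Per-gate noise-induced error rates (mean +/- SE over replicates)."""
    cha, chb = (c.strip() for c in channels.split(","))
    p = _preset_opt(preset)
    rows = []
    for gate in GateKind:
        rates = [gate_error_rate(p, cha, chb, gate, sd_fraction, duration,
                                 seed=seed + k).error_rate
                 for k in range(replicates)]
        rows.append({"gate": gate.value, "noise_sd_fraction": sd_fraction,
                     "error_rate": float(np.mean(rates)),
                     "se": float(np.std(rates) / np.sqrt(len(rates))) if replicates > 1 else 0.0,
                     "replicates": replicates, "seed": seed})
    pd.DataFrame(rows).to_csv(out, index=False)
    click.echo(f"wrote {len(rows)} gate error rates to {out}")


@cli.command()
@click.option("--preset", type=click.Choice(["pure", "mixture"]), default="pure")
@click.option("--duration", type=float, default=10_000.0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def correlate(preset, duration, out):
    """Pairwise Pearson correlation matrix over the model ensemble."""
    cm = correlation_matrix(_preset_opt(preset), duration)
    pd.DataFrame(cm.coefficients, index=list(cm.labels),
                 columns=list(cm.labels)).to_csv(out)
    click.echo(f"wrote {len(cm.labels)}x{len(cm.labels)} matrix to {out}")


@cli.command()
@click.option("--preset", type=click.Choice(["pure", "mixture"]), default="pure")
@click.option("--duration", type=float, default=10_000.0, show_default=True)
@click.option("--seed", type=int, default=DEFAULT_SEED, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def report(preset, duration, seed, out):
    """Full pipeline: simulate, metrics, gates, noise, correlate."""
    cfg = RunConfig(preset={"pure": "PURE_ALGAE", "mixture": "MIXTURE"}[preset],
                    duration=duration, seed=seed, out_dir=out)
    artifacts = run_report(cfg)
    for name, path in artifacts.items():
        click.echo(f"{name}: {path}")


if __name__ == "__main__":  # pragma: no cover
    cli()
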