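# algalogic

Analysis pipeline for multichannel bioelectric recordings of the marine
microalga *Emiliania huxleyi* and of algae–proteinoid (Glu:Phe
microsphere) mixtures, treated as a substrate for unconventional
Boolean computing.

Cultures of these biohybrid systems generate spontaneous, slowly
decaying voltage oscillations on each of eight recording electrodes
(ChA…ChH). This package:

1. **models** each channel as a damped sinusoid
   `V(t) = A sin(2πt/T) e^(−αt)` (amplitude `A` in mV, period `T` in s,
   damping `α` in 1/s) and ships presets with the published per-channel
   parameters for the pure culture (1 Hz sampling) and the mixture
   (2.5 Hz);
2. **extracts** time-domain oscillation statistics from any uniformly
   sampled trace — detrend, optional zero-phase low-pass, peak/trough
   detection (10 mV height, 5 mV prominence, 100 s minimum separation),
   peak-to-peak cycle segmentation — and summarises them as mean period
   `T̄`, mean peak-to-trough amplitude `Ā`, population SD `σ_A`,
   frequency `f = 1/T̄` and power `P = f·Ā²` (mV²·Hz);
3. **binarizes** traces by threshold (`1` iff `V ≥ θ`, with `θ` either
   fixed at 50 mV or half the channel's nominal amplitude) and evaluates
   the seven Boolean gates AND, OR, NOT, XOR, NAND, NOR, XNOR
   sample-wise on channel pairs, reporting each gate's high-state
   frequency (fraction of samples at 1);
4. **quantifies robustness**: gate error rates under Gaussian noise
   (SD a fraction of channel amplitude, added to the analog signal
   before binarization) and pairwise Pearson correlation across the
   channel ensemble.

It is aimed at researchers in unconventional / biohybrid computing and
bioelectrical signal analysis who want a tested, reproducible version of
this oscillations-to-logic workflow.

## Worked example

High-state frequencies of all seven gates on channels ChA
(A = 35.94 mV, T = 929.53 s) and ChB (A = 50.41 mV, T = 299.88 s) of the
pure-culture preset, 10 000 s at 1 Hz, half-amplitude thresholds:

```python
from algalogic import PURE_ALGAE, gate_frequency_experiment

freqs = gate_frequency_experiment(PURE_ALGAE, "ChA", "ChB",
                                  duration=10_000, rate=1.0)
for gate, f in freqs.items():
    print(f"{gate.value}\t{f:.4f}")
```

prints

```
AND	0.1133
OR	0.5635
NOT	0.6601
XOR	0.4502
NAND	0.8867
NOR	0.4365
XNOR	0.5498
```

i.e. both inputs are simultaneously high 11.3% of the time, at least one
is high 56.4% of the time, and ChA spends 66% of the run below half its
amplitude (the NOT output). NAND/NOR/XNOR are the exact complements of
AND/OR/XOR, and `freq(OR) = freq(A) + freq(B) − freq(AND)` holds to the
sample.

The same from the shell, plus a full report (per-channel summary table,
gate table, noise error rates, correlation matrix, manifest):

```sh
algalogic gates --preset pure --channels ChA,ChB --duration 10000 --out gates.csv
algalogic report --preset pure --seed 42 --out report/
```

Per-channel summaries from a recording file (`time_s` column + one mV
column per channel):

```sh
algalogic metrics recording.csv --out summary.csv
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the high-state frequencies of the AND, OR,
NOT and NAND gates for the pure-culture two-channel model (10 000
samples at 1 Hz) and of the OR and NAND gates for the mixture model
(25 000 samples at 2.5 Hz), writing one JSON entry per quantity. The
experiments are deterministic; `--seed` is accepted for interface
parity.
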