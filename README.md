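# cortexnet

Quantitative analysis of spontaneous network activity in developing
cortical cultures recorded by calcium imaging, for researchers studying
how stem-cell-derived (or primary) neuronal networks wire up *in vitro*.

During development these cultures pass through stereotyped regimes:
sparse asynchronous firing, synchronised network bursts (oscillations)
whose frequency rises to a peak (~0.18 Hz) and falls again, and finally
complex but highly structured activity. `cortexnet` implements the
analyses that characterise each regime:

* **Transient & burst detection** (`cortexnet.transients`) — convert raw
  per-cell fluorescence to ΔF/F = (F − F₀)/F₀ against a rolling-percentile
  baseline; detect calcium transients (fast onset < 0.6 s, slow decay
  ~1–8 s) by robust MAD-thresholded peak detection; group onsets across
  cells into network bursts (a maximal chain of onsets each within a sync
  window, recruiting at least a minimum fraction of cells) and report
  burst frequency (bursts per unit time), participation and amplitude.
* **Symbolic recurrence analysis** (`cortexnet.recurrence`) — compile the
  temporally ordered sequence of activated cell IDs; embed it into all
  subsequences of length *m*; score subsequence pairs by the mismatch
  (Hamming) distance — identical subsequences have distance zero; build
  the binary recurrence matrix R(i,j) = 1 iff distance < θ. Repeating
  firing motifs appear as slope-1 diagonal lines: total recurrence is the
  off-diagonal sum of R, determinism (DET) the same sum restricted to
  diagonal runs of length ≥ 2. Significance comes from recomputing the
  statistic on uniformly shuffled surrogate sequences, with the add-one
  permutation p-value p = (1 + #{surrogate ≥ observed}) / (1 + n).
* **Connectivity-distribution fitting** (`cortexnet.degreefit`) — fit the
  per-neuron presynaptic input-count histogram (e.g. from rabies
  trans-synaptic tracing) by least squares under three models: Poisson
  P(k) = e^(−λ)λ^k/k! (random wiring into a large pool), binomial
  B(k; n, P) (random wiring into a small candidate set), and a scale-free
  power law p(k) = c·k^m with negative exponent m (hub-dominated
  network); rank the models by SSE on relative frequencies.
* **Synthetic data** (`cortexnet.synthetic`) — a seeded generator of
  ground-truth event trains and fluorescence traces for every regime
  (asynchronous, synchronized, complex_recurrent, plus pharmacology
  presets: ttx, cnqx_apv, gaba_agonist, bicuculline) and of degree
  sequences from all candidate connectivity models, so every stage of
  the pipeline is testable end to end without any recording.

## Worked example

```python
import numpy as np
from cortexnet import *

# synchronised oscillations at the developmental peak (0.18 Hz)
config = ScenarioConfig("synchronized", n_cells=80, duration_s=120.0,
                        burst_frequency_hz=0.18, participation_fraction=0.9, seed=7)
traces = render_traces(generate_events(config), KernelConfig(), seed=8)
detected = detect_transients(compute_dff(traces))
bursts = detect_network_bursts(detected)
print(f"{bursts.n_bursts} network bursts -> frequency {bursts.burst_frequency_hz:.3f} Hz")
# 22 network bursts -> frequency 0.183 Hz

# structured complex activity: a 12-cell activation motif replayed with 10% noise
config = ScenarioConfig("complex_recurrent", n_cells=60, duration_s=120.0,
                        motif_length=12, motif_noise=0.1, seed=9)
traces = render_traces(generate_events(config), KernelConfig(), seed=10)
detected = detect_transients(compute_dff(traces))
seq = activation_sequence(detected)
res = surrogate_test(seq, EmbeddingConfig(m=5, distance_threshold=1),
                     "determinism_raw", n_surrogates=999, seed=11)
print(f"determinism {res.observed:.0f} over {len(seq)} symbols, p = {res.p_value:.4g}")
# determinism 2202 over 237 symbols, p = 0.001

# hub-dominated connectivity: 66 sparsely connected neurons + hubs at 14/17/43
deg = generate_degree_sequence("hub_mix", n_neurons=69, seed=0)
hist = DegreeHistogram.from_sequence(deg)
print(compare_fits(hist).report())
```

which prints

```
model       parameters                      SSE
poisson     lambda=2.246 (moment)          1.177e-01
binomial    n=2000, P=0.001123            1.178e-01
power law   m=-0.8901, c=0.1577 (k>=1, log)  1.032e-01
best model by SSE: powerlaw
```

Reading the numbers: the detected burst frequency (0.183 Hz) recovers the
generating 0.18 Hz; the replayed activation motif yields a determinism
count far above every one of the 999 shuffles, so the p-value is at its
floor 1/1000 — the activation order is structured, not random; and on the
hub-dominated connectivity sample the scale-free model beats both the
Poisson (λ ≈ 2.25 mean inputs) and binomial alternatives on SSE. The
fitted exponent on a 69-neuron sample is noisy (single-count hub bins
flatten the log–log regression); the generating exponent −2 is recovered
to ±0.2 at 10⁴ draws (see the test suite).

The same pipeline is scriptable from the shell:

```bash
cortexnet simulate --scenario synchronized --n-cells 100 --duration 120 --freq 0.18 --seed 7 --out run/
cortexnet detect --traces run/traces.csv --sync-window 1.0 --min-participation 0.5 --out run/
cortexnet recurrence --events run/events.csv -m 5 --surrogates 1999 --seed 11 --out run/
cortexnet fitdeg --hist degrees.csv --kmin 1 --space log --out run/
cortexnet run --config pipeline.yaml   # full simulate -> detect -> recurrence/fitdeg
```

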