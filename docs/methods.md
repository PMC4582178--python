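# Methods

This note documents the models behind `cortexnet`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical decisions taken where the underlying procedures are
genuinely open.

## 1. Fluorescence forward model and ΔF/F

A calcium transient reflects a burst of action potentials; its amplitude
scales with the number of spikes fired. The simulator's indicator kernel
is a linear rise over `rise_s` (default 0.4 s; onsets in these
preparations are faster than 0.6 s) followed by a single-exponential
decay with constant `decay_s` (default 3 s; observed decays span roughly
1–8 s). Each event contributes `amplitude_per_event × weight` kernels by
linear superposition, where the integer weight (1–5, uniform by default)
stands in for the spike count. Raw fluorescence is
`F = f0 · (1 + ΔF/F)` with i.i.d. Gaussian noise (SD `noise_sd`,
default 0.02) added on the ΔF/F scale — the simplest calibratable noise
model. Noiseless renders are reproduced exactly (zero error) by an
independent closed-form kernel-sum oracle in the test suite.

ΔF/F conversion uses a per-cell rolling 20th-percentile baseline over a
30 s centred window. The percentile track is then smoothed with a rolling
mean of the same width: a raw rolling percentile changes value in steps
as samples enter and leave the window rank, and such steps can mimic the
fast rise of a genuine transient. Non-positive raw fluorescence anywhere
is rejected (ΔF/F is undefined there), naming the offending cell.

## 2. Transient detection

Detection operates per cell on ΔF/F and is scale-free (invariant to
multiplicative rescaling of raw fluorescence; additive offsets change
ΔF/F itself by construction). Candidate events are local maxima found by
`scipy.signal.find_peaks` with

* prominence ≥ `threshold_mads × σ`, and
* absolute height ≥ 20th percentile of the trace + `threshold_mads × σ`,

where σ is the successive-difference MAD estimate of the noise SD,
`median_abs_deviation(diff(x)) / √2`, floored at 0.01 ΔF/F. The
difference-based estimator matters: in recordings dominated by bursting,
the MAD of the trace itself tracks the signal envelope rather than the
noise and would suppress detection precisely where activity is densest.
The absolute-height anchor uses the lower envelope (20th percentile)
rather than the median for the same reason. The floor keeps near-noiseless
recordings from triggering on numerical ripple; it corresponds to a
minimum resolvable transient of ~4% ΔF/F at the default threshold.

Each candidate must then satisfy the kinetic constraints of a calcium
transient:

* **fast onset** — from the onset frame (the last near-baseline frame in
  the rise window before the peak) the trace must climb one threshold
  height within `min_rise_s` (default 0.6 s);
* **slow decay** — the mean of the ~0.5 s after the peak must stay above
  onset + 0.7 × (peak − onset). A transient decaying with a 3 s constant
  retains ~0.9 of its height over that window; a single-frame noise spike
  does not. At the extreme 1 s decay bound the theoretical retention is
  ~0.75, so very small events with the fastest decays sit close to this
  criterion — a documented trade-off against false alarms on quiet
  (e.g. TTX) recordings;
* **refractoriness** — at most one onset per cell per `refractory_s`
  (default 1 s) after the previous accepted peak.

The default threshold is 4.0 robust SDs, chosen for margin on both sides:
recall/precision on ground-truth recordings are unchanged between 3.5 and
4.0 (simulated transients sit ≥ 25 σ above the noise), while 4.0 yields
zero false events on pure-noise (sodium-channel-blockade) recordings at
the default noise level. Events whose peak would fall beyond the final
frame of a recording are undetectable in principle; round-trip guarantees
therefore apply to the detected prefix of a recording.

## 3. Network bursts

A network burst is a maximal chain of transient onsets in which
consecutive onsets (across all cells) are separated by at most
`sync_window_s` (default 1 s) and which recruits at least
`min_participation × n_cells` distinct cells (default 0.5 — anchored to
the observation that nascent synchrony recruits fewer than half the
cells, so 0.5 separates the sparse from the fully synchronised regime).
Burst frequency is the number of bursting events per unit time, i.e.
count / recording duration, computed per recording. Participation is the
fraction of distinct recruited cells; the amplitude summary is the mean
transient peak ΔF/F over onsets inside bursts (the quantity downstream
plasticity comparisons consume; the statistical test itself is left to
the user). Lowering `min_participation` can only add bursts
(monotonicity), since the chain partition is independent of the
participation filter.

## 4. Symbolic recurrence quantification

The activation sequence is the temporally ordered list of cell IDs at
transient onset (simultaneous onsets break ties lexicographically by ID;
the rule is recorded in metadata). The sequence is embedded as all
overlapping windows of length `m` (default 5, in the customary 3–10
range). The distance between two windows is the number of non-identical
corresponding members; the recurrence matrix thresholds this distance at
`distance_threshold` (default 1, i.e. recurrence = exact subsequence
identity, the strictest reading of "distance less than threshold" —
configurable). With the default threshold the implementation collapses
each window to an integer code and compares codes, which makes the
1999-surrogate test on 1000-symbol sequences run in seconds; for larger
thresholds the full pairwise mismatch count is computed.

Quantification excludes the band `|i − j| ≤ theiler_window` (default 0:
only the self-matching line of identity) from all sums. Total recurrence
is the remaining sum of the matrix; determinism is the same sum
restricted to slope-1 diagonal runs of length ≥ `l_min` (default 2); the
determinism fraction DET is their ratio (defined as 0 when there is no
recurrence). Note one boundary consequence of the run-length definition:
the two corner cells of the matrix lie on diagonals of length 1 and can
never belong to a run, so even an all-ones matrix has DET slightly below
1. All three statistics are validated against a naive O(N²·m) enumerator,
exactly, over property-sampled sequences.

Surrogate significance: the symbol sequence is shuffled uniformly
(symbol counts preserved — the null hypothesis is "same cells, same
firing counts, no temporal order"), the statistic recomputed with the
identical configuration, and the p-value estimated with the add-one
permutation estimator `p = (1 + #{surrogate ≥ observed}) / (1 + n)`,
whose floor is `1/(n+1)` and which can never report 0. Shuffling operates
on the compiled ID sequence, not on event times. The estimator is exactly
calibrated for continuous statistics and conservative under ties; the
calibration test in the suite uses a configuration (sequence length 200,
alphabet 10, m = 3, threshold 2, total-recurrence statistic) chosen so
the null distribution is spread enough for ties to be negligible.

## 5. Connectivity-distribution fits

The input is a histogram of per-neuron presynaptic input counts k. All
fits operate on relative frequencies, making the SSE invariant to sample
size. Three models are compared:

* **Poisson** — default fit is the method of moments (λ = sample mean,
  "the Poisson distribution with the same mean number of connections");
  a least-squares λ is available as a variant.
* **Binomial** — exhaustive grid over integer pool size
  n ∈ [k_max, n_grid_max] (default 2000); for each n the connection
  probability P is found by bounded 1-D SSE minimisation (with the moment
  start mean/n as a safeguard candidate); ties go to the smaller n. n and
  P are individually weakly identified — their product (the mean) is the
  well-determined quantity, and the tests assert exactly that.
* **Power law** — `p(k) = c·k^m` fitted on k ≥ `k_min_fit` (default 1;
  k = 0 lies outside any power law's support, and how a zero-connection
  class should enter a scale-free fit is genuinely undefined). The
  default is log–log linear regression over nonzero bins, which recovers
  a noiseless power law exactly; a direct linear-space least-squares
  variant is provided. Small samples flatten the fitted exponent (isolated
  single-count tail bins enter the regression with full weight); the
  generating exponent is recovered to ±0.2 at 10⁴ draws.

Models are ranked by SSE — the Poisson/binomial SSE over k ∈ [0, k_max],
the power law over its fit support (documented asymmetry). No
goodness-of-fit p-values are attached; the comparison is purely by SSE.
Maximum-likelihood power-law fitting with data-driven k_min selection
(Clauset-style) is the modern alternative and is deliberately out of
scope here, where the least-squares comparison itself is the method
under study.

## 6. Synthetic scenarios: what they emulate, and what not

`generate_events` produces ground-truth event trains per regime:

* `asynchronous` — independent homogeneous Poisson trains per cell
  (default 0.02 Hz/cell, ~2.4 events per cell per 2-min recording).
* `synchronized` — burst times with a Poisson-distributed count of
  expectation `burst_frequency_hz × duration_s`, placed uniformly subject
  to a hard minimum separation (default 2 s, a network refractory period;
  distinct bursts closer than the synchrony window would otherwise merge
  at analysis time and no finite recording could distinguish them). Each
  burst recruits every cell independently with probability
  `participation_fraction` inside a 0.5 s recruitment window — well below
  inter-burst intervals even at the 0.18 Hz peak. Background events at
  0.005 Hz/cell ride on top.
* `complex_recurrent` — a fixed random motif of `motif_length` distinct
  cells replayed cyclically at a fixed event spacing (default 0.5 s),
  each symbol replaced by a uniformly random cell with probability
  `motif_noise`.
* Pharmacology presets: `ttx` and `gaba_agonist` produce silence;
  `cnqx_apv` produces asynchronous activity only (synchrony requires
  glutamatergic transmission); `bicuculline` is bit-identical to
  `synchronized` at equal seed (a purely excitatory network is
  insensitive to GABA-A antagonism).

All randomness flows through one seeded generator per call and seeds are
recorded in output metadata, so equal configurations are bit-identical.

The generator is phenomenological. It does not model conductances,
synaptic dynamics, plasticity, developmental drift within a recording,
indicator saturation or bleaching, movement artefacts, or correlated
noise; cells are statistically exchangeable within a scenario. Passing
tests therefore demonstrate that the analysis recovers the statistical
structure it targets under this event/kernel/noise model — not detector
performance on real movies, where baseline drift and correlated noise
make detection strictly harder.

## 7. Problem sizes used in the validating runs

Round-trip detection checks use 100 cells × 1000 s at 10 Hz (about 2000
events); the burst-frequency recovery check uses the 0.18 Hz regime over
1000 s (~180 bursts, so Poisson sampling error ~7.5% of the count at 1 SD);
the surrogate significance benchmark uses a 50-ID permutation replayed 20
times (1000 symbols) against 1999 shuffles; recovery checks for the
degree models use 10⁵ (Poisson, binomial) and 10⁴ (power law) draws; the
type-I calibration uses 500 independent surrogate tests at 99 shuffles
each. These sizes keep the full suite within a few minutes on one core
while leaving the statistical margins described above.

## 8. File formats

Traces: CSV with frame times in the first row (`time_s,...`) and one
cell per subsequent row (ID string first), plus a JSON sidecar with fps,
duration and provenance (scenario, seeds, kernel). Events: CSV
`cell_id,onset_time_s,peak_dff` (detected) or `cell_id,time_s,weight`
(ground truth), each with a JSON sidecar. Degrees: CSV `neuron_id,k` or
histogram `k,count`. Floats are written with `repr` (shortest exact
round-trip), so write→read reproduces every value bit-exactly and
re-writing is byte-identical. Times are seconds as floats, frames are
0-based, intervals half-open `[start, end)`. Malformed files are rejected
with file, line and field in the message. The `run` subcommand executes a
YAML/JSON-configured pipeline and writes a manifest (package version,
config, seeds, SHA-256 of every artifact); identical configs yield
identical manifests.
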