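# Methods

## The analysis model

The pipeline infers a functional connectivity graph from spontaneous
multielectrode-array activity. Its assumptions are deliberately weak: no
generative model of the neural dynamics is fitted. Spikes are whatever
crosses a noise-relative threshold after bandpass filtering; synchrony is
measured pairwise by the spike-time tiling coefficient (STTC); a
connection is declared wherever STTC exceeds a fixed threshold; and the
significance of network-level structure is judged only against surrogate
data that preserve each electrode's spike count while destroying spike
timing.

### Spike-time tiling coefficient

For trains A and B on a window of length T with half-window Δt,

    STTC = 1/2 [ (P_A − T_B)/(1 − P_A·T_B) + (P_B − T_A)/(1 − P_B·T_A) ],

where T_A is the fraction of [0, T] covered by the union of the tiles
[t − Δt, t + Δt] around A's spikes (tiles clipped to the window, overlaps
merged, never summed) and P_A is the proportion of A's spikes lying within
Δt of at least one spike of B (closed window: |a − b| ≤ Δt counts). The
subtraction of the partner's tiled fraction makes the statistic close to 0
for independent trains at any rate, and the denominator normalizes it into
[−1, 1]. Identical non-empty trains score 1 whenever their tiled fraction
is below 1.

Degenerate inputs carry no synchrony information and are reported as NaN
rather than 0, because 0 is a meaningful result ("uncorrelated"): either
train empty, or a zero denominator (P_A·T_B = 1, e.g. Δt covering the
whole window). Graph construction treats NaN as no-edge and flags the
electrode in the node table, so the node count stays fixed at the array
size.

The production implementation computes each tiled fraction once per train
(sorted tiles, vectorized overlap subtraction) and each coincidence term
with sorted-array bisection, O(N·n log n + N²·n) for N trains of ~n
spikes; a 60-electrode, 6-minute matrix at 2 Hz takes ~0.2 s. Correctness
is anchored in the test suite to an independent brute-force oracle
(explicit interval-list union, exhaustive O(n²) coincidence enumeration),
with agreement to 1e−12 on ≥ 1000 random pairs; pairs whose denominator is
within 1e−9 of zero are exercised by a dedicated NaN-contract test instead,
since on that measure-zero boundary the two algorithms may legitimately
round to opposite sides of singularity.

### Detection

The raw signal is bandpass-filtered with a Butterworth design (third-order
analog prototype, 600–8,000 Hz) applied forward–backward. Zero-phase
filtering avoids group-delay bias in spike times at the documented cost
that the effective magnitude response is the square of the designed one;
the filter tests therefore compare sinusoid gains against |H(f)|²
evaluated from the designed transfer function. Band edges at or above
Nyquist raise an error rather than being clipped silently.

Background noise σ defaults to the robust Gaussian estimator
median(|x|)/0.6745, because the plain standard deviation is inflated by
the spikes themselves; both are available. The first and last ten
time-constants of the low corner (10/f_low seconds) are excluded from
noise estimation only — never from detection — to keep filter edge
transients out of σ.

Events are threshold crossings of k·σ in the configured polarity
(default negative-going, the dominant polarity of extracellular somatic
spikes); each contiguous supra-threshold excursion yields one event at its
local extremum, which is stabler under noise than the first crossing
sample; after each accepted event all crossings within the refractory
period (1.5 ms) are discarded. Detection is invariant under uniform
rescaling of a channel, since the threshold is noise-relative.

**Threshold multiplier in validation experiments.** The analysis default
is k = 3, the convention this pipeline reproduces. On ideal Gaussian
background noise bandlimited to 600–8,000 Hz, however, level crossings at
3σ occur at the Rice rate ν₀·e^(−k²/2) ≈ 50 Hz — noise alone produces
tens of spurious events per second at k = 3, for any detector. The
synthetic recovery and false-positive experiments, whose purpose is to
verify the detector's mechanics (timing accuracy, refractory enforcement,
rate recovery) rather than to recommend an operating point, therefore run
at k = 5, where the Gaussian noise-crossing rate is ≈ 0.02 Hz and injected
10σ spikes (≈ 9.3σ after filtering) are recovered with > 99.8% per-spike
probability. Real recordings at k = 3 rely on the fact that genuine units
dominate the supra-threshold events; that trade-off is the user's to make
and k is a first-class parameter.

### Graph construction

Edges require STTC strictly greater than the threshold (default 0.6);
boundary equality is excluded. Node degree is the binary degree of the
thresholded graph; STTC values are retained as edge weights. Exported
global metrics: edge count, mean degree, edge density, mean firing rate.
Raising the threshold can only remove edges, so every node's degree is
monotone non-increasing in the threshold (tested).

### Surrogate null model

"No temporal coordination beyond what the rates imply" is operationalized
by redrawing each train's spike times uniformly on [0, T) with the spike
count preserved exactly — the weakest-assumption scheme that provably
preserves the across-electrode rate distribution. Two stricter
alternatives are exposed (`isi_shuffle`, preserving each train's
inter-spike-interval histogram; `jitter`, Gaussian displacement reflected
at the window edges, default SD 350 ms = 2Δt, preserving slow rate
structure). Each of the n surrogates (default 100) is rebuilt into an
STTC matrix and thresholded graph; per-surrogate seeds derive from the
root seed by fixed spawn keys, so results are independent of execution
order.

Comparison reports numbers, not verdicts: add-one exceedance fractions
(1 + #{surrogate ≥ observed})/(n + 1) for mean degree and edge count, and
the two-sample Kolmogorov–Smirnov statistic between observed node degrees
and pooled surrogate degrees. The add-one convention never yields an
exact zero and is conservative when the statistic is discrete: ties count
against the observed value, inflating the exceedance by ≈ P(tie)/2. The
calibration test accounts for this by checking exact uniformity on the
tie-randomized exceedance, which is the statistically exact statement of
"well calibrated under the null"; the reported quantity keeps the
conservative convention. A second calibration fact is asserted outright:
at the 0.6 edge threshold, pure-rate null data produce no edges at all,
so the null comparison for realistic thresholds is a one-sided power
question, and the uniformity check instead sets the threshold at the bulk
of the null STTC distribution (0), where edge counts genuinely vary.

## Synthetic data: what it emulates and what it does not

The generator emulates the study conditions the pipeline targets:
6-minute (360 s) windows, a 60-electrode grid (8×8 minus corners, 200 µm
pitch, 12 µm contacts), per-electrode rates of order 0.1–5 Hz, and an
acquisition rate of 25 kHz (the container requires the rate explicitly;
25 kHz is the generator default, comfortably above twice the 8 kHz corner).

* **Poisson trains** are drawn exactly (Poisson count, ordered uniform
  times).
* **Correlated groups** use a multiple-interaction process (MIP): a
  mother Poisson train at rate r/c thinned independently into each child
  with probability c, so each child is Poisson at rate r and any pair
  shares a fraction ≈ c of its spikes. One interpretable parameter
  controls pairwise synchrony; c = 0 falls back exactly to independent
  trains. Optional Gaussian per-copy jitter decouples exact coincidence
  from synchrony at the Δt scale.
* **Raw rendering** adds a biphasic template (0.25 ms negative trough,
  0.45-amplitude rebound, 0.8 ms total — a typical somatic extracellular
  spike whose spectrum lies inside the detection band; the trough equals
  −SNR·σ_noise exactly) at the sample nearest each spike time, on white
  Gaussian noise, plus an optional low-frequency sinusoid to exercise the
  high-pass side of the filter. Per-channel and per-train random
  substreams are spawned from the root seed, so adding an electrode never
  perturbs existing ones.

Not emulated, hence not demonstrated by passing tests: bursting and other
non-Poisson temporal structure, waveform propagation or overlap across
electrodes, electrode drift and artifacts, non-Gaussian or nonstationary
noise, and any biophysics. Conclusions about the pipeline's behavior on
real organoid recordings beyond rate-matched Poisson assumptions must come
from the surrogate comparison itself, which is distribution-free given
the detected spikes.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| band_low_hz / band_high_hz | 600 / 8000 | Hz | bandpass corners |
| filter_order | 3 | — | Butterworth analog-prototype order |
| threshold_k | 3.0 | σ | detection threshold multiplier |
| refractory_ms | 1.5 | ms | minimum inter-event interval per channel |
| noise_estimator | robust | — | median-based σ vs plain SD |
| polarity | negative | — | crossing direction (negative/positive/both) |
| sttc_dt_ms | 175 | ms | STTC synchronicity half-window |
| edge_threshold | 0.6 | STTC | strict lower bound for an edge |
| n_surrogates | 100 | — | null-ensemble size |
| surrogate_scheme | uniform | — | uniform / isi_shuffle / jitter |
| seed | 0 | — | root seed for every random stream |

The filtering/detection/STTC/threshold defaults are the analysis settings
this pipeline reproduces; the surrogate count, scheme, noise estimator and
polarity are this package's own documented choices where the method leaves
them open.

## Numerical choices

* Spike times are 64-bit float seconds on the half-open window [0, T); a
  spike at exactly T belongs to the next window. Trains are strictly
  increasing (exact float ties are invalid; generators deduplicate).
* Undefined STTC values are NaN end-to-end; NaN never creates an edge.
* CSV round trips are lossless (`%.17g` on write, `round_trip` float
  parsing on read); reports contain no timestamps or hostnames, so
  identical inputs and seed reproduce every output byte-exactly.
* Config precedence: explicit override > config file > default; the
  effective configuration is echoed into `summary.json` and the run
  manifest, which also fingerprints inputs by SHA-256.

## Problem sizes used by the test and acceptance runs

STTC distributional checks use 360 s windows (200 independent pairs per
rate at 0.5/2/10 Hz; 20–30 seeds per MIP synchrony level). The
planted-structure power experiment runs at full scale: 60 electrodes,
360 s, 100 surrogates. The null-calibration experiment runs at reduced
size — 50 replicates of 10 electrodes × 60 s against 39 surrogates each —
which is ample for a uniformity check on 50 exceedance values. Raw-signal
experiments use 25 kHz channels of 3–120 s. A full run of the test suite
plus the acceptance script completes in about a minute on one CPU.

## Known limitations

* STTC is computed on whole recordings; sub-window or lag-resolved
  profiles are out of scope.
* No spike sorting: an electrode's train mixes all units it sees.
* The surrogate scheme preserves rates but not burst structure; for
  strongly bursty data the `isi_shuffle` or `jitter` schemes are the more
  conservative nulls.
* Proprietary vendor containers are not parsed; convert to the documented
  HDF5/binary layout first.
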