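# meanet

Functional-network analysis of multielectrode-array (MEA) recordings, for
electrophysiologists working with spontaneous activity in neural tissue
such as brain-organoid slice cultures on 60-electrode grids.

The pipeline goes from raw extracellular voltage to a functional
connectivity graph in four stages:

1. **Filtering** — zero-phase Butterworth bandpass (third order,
   600–8,000 Hz by default).
2. **Spike detection** — per-channel threshold at *k* standard deviations
   of the background noise (*k* = 3 default, robust noise estimate
   median(|x|)/0.6745), with a 1.5 ms refractory period; event time is the
   local extremum of each supra-threshold excursion.
3. **Connectivity** — the spike-time tiling coefficient (STTC) for every
   electrode pair with synchronicity window Δt = 175 ms:

   ```
   STTC = 1/2 [ (P_A − T_B)/(1 − P_A·T_B) + (P_B − T_A)/(1 − P_B·T_A) ]
   ```

   where T_A is the fraction of the recording within ±Δt of a spike of A
   (tiles merged and clipped to the window) and P_A the proportion of A's
   spikes within ±Δt of a spike of B. STTC is symmetric, bounded in
   [−1, 1] and by construction insensitive to firing rate, which matters
   when electrodes differ by orders of magnitude in activity.
4. **Graph + null model** — an edge joins electrodes with STTC > 0.6
   (strict), weighted by STTC; node degree and firing rate are the
   per-electrode metrics. Observed metrics are compared against surrogate
   ensembles built from temporally randomized spike trains that exactly
   preserve each electrode's spike count (hence the array's rate
   distribution), reported as add-one empirical exceedance fractions and a
   Kolmogorov–Smirnov distance between degree distributions.

A synthetic-data module generates Poisson and MIP-correlated spike trains
(one parameter *c* controls pairwise synchrony) and renders them into raw
multichannel voltage with a biphasic spike template and Gaussian noise, so
every stage is testable against exact ground truth without any recordings.

The stages are scikit-learn-style estimators (`SpikeDetector`,
`STTCAnalyzer`, `NetworkBuilder`, `SurrogateNull`) that chain
`RawRecording → SpikeMatrix → STTCMatrix → ConnectivityGraph`, with plain
functions (`sttc_pair`, `build_graph`, …) underneath.

## Worked example

Fifteen electrodes over 6 minutes: a planted group of 5 sharing 80% of
their spikes (MIP *c* = 0.8 at 2 Hz) among 10 independent 2 Hz electrodes.

```python
import numpy as np
from meanet import (gen_correlated_trains, gen_poisson_train, SpikeMatrix,
                    STTCAnalyzer, NetworkBuilder, SurrogateNull)

grp, _ = gen_correlated_trains(5, 2.0, 0.8, 360.0, seed=0)
indep = [gen_poisson_train(2.0, 360.0, seed=100 + k).times for k in range(10)]
spikes = SpikeMatrix.from_times([tr.times for tr in grp] + indep, 360.0)

m = STTCAnalyzer(dt_s=0.175).fit_transform(spikes)
graph = NetworkBuilder(edge_threshold=0.6).fit_transform(m)
null = SurrogateNull(n_surrogates=100, seed=0).fit(spikes)
report = null.compare(graph)

print(f"electrodes: {graph.n_nodes}, edges: {graph.n_edges}")
print(f"mean within-group STTC: "
      f"{np.nanmean(m.values[:5,:5][np.triu_indices(5,1)]):.3f}")
print(f"mean degree: {graph.mean_degree:.3f}  "
      f"(surrogate mean: {report['surrogate_mean_degree_mean']:.3f})")
print(f"exceedance of mean degree vs null: "
      f"{report['exceedance_mean_degree']:.4f}")
print(f"KS distance, degree distributions: "
      f"{report['ks_degree_distribution']:.3f}")
```

prints

```
electrodes: 15, edges: 10
mean within-group STTC: 0.713
mean degree: 1.333  (surrogate mean: 0.000)
exceedance of mean degree vs null: 0.0099
KS distance, degree distributions: 0.333
```

The planted group's pairwise STTC (≈0.71) clears the 0.6 threshold, so the
5 synchronous electrodes form a complete subgraph (10 edges); the 10
independent electrodes contribute none. All 100 count-preserving
surrogates have zero edges, so the observed mean degree exceeds every
surrogate: exceedance 1/101 ≈ 0.0099, the smallest value the add-one
convention allows.

The same chain runs from the shell:

```sh
meanet simulate --seed 1 --out sim --n-electrodes 60 --duration-s 360 \
    --rate-hz 2 -c 0.8 --group-size 10
meanet run-all --seed 1 --out results --spike-table sim/ground_truth_spikes.csv \
    --duration-s 360
```

writing `sttc_matrix.csv`, `edges.csv`, `nodes.csv`, `summary.json` and a
`manifest.json` that, together with the inputs, reproduces every output
byte-exactly.

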