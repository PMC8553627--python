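"""Synthetic spike trains and raw recordings with known ground truth.

Emulates 6-minute spontaneous recordings on a 60-electrode grid: Gaussian
background noise, a stereotyped extracellular waveform injected at known
spike times, Poisson spike trains, and correlated trains generated by a
multiple-interaction process (MIP) whose single parameter ``c`` controls
pairwise synchrony.  Nothing here models biophysics — no membrane dynamics,
bursting, or waveform propagation across electrodes; the generators exist so
that detection, STTC, graph and surrogate stages can all be validated
against exact ground truth without any recorded data.

Every generator is a pure function of its arguments including the seed.
Per-train / per-channel random substreams are derived from the root seed by
``numpy.random.SeedSequence`` spawn keys, so adding a train or channel never
perturbs the ones already generated.
"""

from __future__ import annotations

import numpy as np

from .containers import GroundTruth, RawRecording, SpikeMatrix, SpikeTrain
from .errors import ValidationError

__all__ = [
    "gen_poisson_train",
    "gen_correlated_trains",
    "synth_raw",
    "default_waveform",
]


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _uniform_sorted(rng: np.random.Generator, n: int, duration_s: float) -> np.ndarray:
    t = np.sort(rng.uniform(0.0, duration_s, size=n))
    return np.unique(t)  # exact float ties are invalid spike trains


def gen_poisson_train(rate_hz: float, duration_s: float,
                      seed: int | np.random.Generator = 0) -> SpikeTrain:
    """Homogeneous Poisson spike train on ``[0, duration_s)``.

    Drawn as a Poisson-distributed count followed by uniform ordered times,
    which is the exact conditional construction of the process.
    """
    if rate_hz < 0:
        raise ValidationError("rate_hz must be non-negative")
    if not duration_s > 0:
        raise ValidationError("duration_s must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else _substream(int(seed))
    n = rng.poisson(rate_hz * duration_s)
    return SpikeTrain(_uniform_sorted(rng, n, duration_s), duration_s)


def gen_correlated_trains(
    n_trains: int,
    rate_hz: float,
    c: float,
    duration_s: float,
    seed: int = 0,
    jitter_ms: float = 0.0,
) -> tuple[SpikeMatrix, GroundTruth]:
    """Correlated trains via a multiple-interaction process (MIP).

    A mother Poisson train of rate ``rate_hz / c`` is thinned independently
    into each child with copy probability ``c``, so every child is itself a
    Poisson train of expected rate ``rate_hz`` and any two children share a
    fraction ``c`` of their spikes — pairwise spike-count correlation ~ c.
    ``c = 0`` falls back exactly to independent Poisson trains (no division
    by zero).  ``jitter_ms`` adds independent Gaussian timing noise to each
    copied spike (default 0: copies are exactly synchronous).
    """
    if n_trains < 2:
        raise ValidationError("n_trains must be >= 2")
    if not 0.0 <= c <= 1.0:
        raise ValidationError("correlation c must be in [0, 1]")
    if not rate_hz > 0:
        raise ValidationError("rate_hz must be positive")
    if not duration_s > 0:
        raise ValidationError("duration_s must be positive")

    if c == 0.0:
        trains = [gen_poisson_train(rate_hz, duration_s, _substream(seed, k + 1))
                  for k in range(n_trains)]
    else:
        mother = gen_poisson_train(rate_hz / c, duration_s, _substream(seed, 0))
        jitter_s = jitter_ms / 1000.0
        trains = []
        for k in range(n_trains):
            rng = _substream(seed, k + 1)
            kept = mother.times[rng.random(mother.n_spikes) < c]
            if jitter_s > 0 and kept.size:
                kept = kept + rng.normal(0.0, jitter_s, size=kept.size)
                kept = kept[(kept >= 0.0) & (kept < duration_s)]
            trains.append(SpikeTrain(np.unique(kept), duration_s))

    sm = SpikeMatrix(tuple(trains), tuple(range(n_trains)))
    gt = GroundTruth(
        true_spikes=sm,
        target_rate_hz=np.full(n_trains, rate_hz),
        injected_correlation=c,
        seed=seed,
        correlated_group=tuple(range(n_trains)) if c > 0 else (),
    )
    return sm, gt


def default_waveform(sampling_rate_hz: float, amplitude: float = 1.0,
                     duration_ms: float = 0.8,
                     trough_ms: float = 0.25) -> np.ndarray:
    """Biphasic extracellular spike template.

    Sharp negative trough (0.25 ms half-sine, the width of a typical
    somatic extracellular spike) followed by a broader, smaller positive
    rebound, 0.8 ms total.  The trough width puts the template's energy
    inside the 600-8,000 Hz detection band, so zero-phase filtering leaves
    its peak nearly intact.  The negative peak equals ``-amplitude``
    exactly, so amplitude expressed as a multiple of the noise SD is the
    signal-to-noise ratio; polarity matches the detector's
    negative-polarity default.
    """
    if not amplitude > 0:
        raise ValidationError("amplitude must be positive")
    if not 0 < trough_ms < duration_ms:
        raise ValidationError("need 0 < trough_ms < duration_ms")
    n = max(int(round(duration_ms * 1e-3 * sampling_rate_hz)), 3)
    t = np.arange(n) / sampling_rate_hz
    t_neg = trough_ms * 1e-3
    t_total = duration_ms * 1e-3
    w = np.where(
        t < t_neg,
        -np.sin(np.pi * t / t_neg),
        0.45 * np.sin(np.pi * (t - t_neg) / (t_total - t_neg)),
    )
    return amplitude * w / np.abs(w.min())


def synth_raw(
    spike_matrix: SpikeMatrix,
    sampling_rate_hz: float,
    waveform: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    lfp_amplitude: float = 0.0,
    lfp_freq_hz: float = 0.0,
) -> tuple[RawRecording, GroundTruth]:
    """Render a spike matrix into a raw multichannel voltage trace.

    Each channel is white Gaussian noise of standard deviation ``noise_sd``
    plus the waveform template added starting at the sample nearest each true
    spike time (truncated at the window edges), plus an optional
    low-frequency sinusoid common to all channels (an LFP-like confound used
    to exercise the high-pass side of the bandpass filter).  The returned
    ground truth carries the input spike times verbatim.
    """
    if not sampling_rate_hz > 0:
        raise ValidationError("sampling_rate_hz must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    T = spike_matrix.duration_s
    n_samples = int(round(T * sampling_rate_hz))
    if waveform is None:
        waveform = default_waveform(
            sampling_rate_hz, amplitude=10.0 * noise_sd if noise_sd > 0 else 1.0)
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.ndim != 1 or waveform.size == 0:
        raise ValidationError("waveform must be a non-empty 1-D array")
    if waveform.size > n_samples:
        raise ValidationError("waveform longer than the recording")

    signal = np.empty((spike_matrix.n_electrodes, n_samples))
    for ch, train in enumerate(spike_matrix):
        rng = _substream(seed, ch)
        x = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 \
            else np.zeros(n_samples)
        starts = np.rint(train.times * sampling_rate_hz).astype(np.int64)
        for s in starts:
            stop = min(s + waveform.size, n_samples)
            if stop > s:
                x[s:stop] += waveform[: stop - s]
        signal[ch] = x
    if lfp_amplitude != 0.0 and lfp_freq_hz > 0.0:
        tt = np.arange(n_samples) / sampling_rate_hz
        signal += lfp_amplitude * np.sin(2.0 * np.pi * lfp_freq_hz * tt)

    rec = RawRecording(signal, sampling_rate_hz)
    gt = GroundTruth(
        true_spikes=spike_matrix,
        target_rate_hz=np.array([tr.firing_rate_hz for tr in spike_matrix]),
        injected_correlation=0.0,
        seed=seed,
        waveform=waveform,
        noise_sd=noise_sd,
    )
    return rec, gt
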