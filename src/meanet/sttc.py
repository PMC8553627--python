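"""Spike-time tiling coefficient (STTC).

The STTC of two trains A and B recorded over a window of length ``T`` with
synchronicity half-window ``dt`` is

    STTC = 1/2 * [ (P_A - T_B) / (1 - P_A * T_B) + (P_B - T_A) / (1 - P_B * T_A) ]

where ``T_A`` is the fraction of the recording tiled by the union of the
intervals ``[t - dt, t + dt]`` around the spikes of A (clipped to the
recording window), and ``P_A`` is the proportion of A's spikes falling
within ``dt`` of at least one spike of B.  The statistic is symmetric,
bounded in [-1, 1], and by construction insensitive to the firing rates of
the two trains, which is why it is preferred over raw correlation for
electrodes with very different activity levels.

Degenerate cases carry no synchrony information and are reported as NaN
rather than 0 (0 means "uncorrelated", which is a real result): either
train empty, or a denominator of zero (``P_A * T_B = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import SpikeMatrix, SpikeTrain
from .errors import ValidationError

__all__ = [
    "tiled_fraction",
    "coincident_fraction",
    "sttc_pair",
    "sttc_matrix",
    "STTCMatrix",
    "STTCAnalyzer",
]


def tiled_fraction(train: SpikeTrain, dt_s: float) -> float:
    """Fraction of the recording within ``dt_s`` of any spike (the T term).

    Tiles are intersected with ``[0, T]`` before the union, so mass outside
    the recording never counts; overlapping tiles are merged, not summed.
    """
    if not dt_s > 0:
        raise ValidationError("dt_s must be positive")
    t = train.times
    if t.size == 0:
        return 0.0
    T = train.duration_s
    starts = np.clip(t - dt_s, 0.0, T)
    ends = np.clip(t + dt_s, 0.0, T)
    # times sorted => starts and ends sorted; each tile contributes its
    # length minus any overlap with the previous tile
    lower = np.maximum(starts[1:], ends[:-1])
    total = (ends[0] - starts[0]) + np.sum(np.maximum(ends[1:] - lower, 0.0))
    return float(total / T)


def coincident_fraction(train_a: SpikeTrain, train_b: SpikeTrain,
                        dt_s: float) -> float:
    """Proportion of A's spikes within ``dt_s`` of at least one B spike (P_A).

    Returns NaN for an empty A (the proportion is undefined) and 0 when B is
    empty.  The coincidence window is closed: ``|a - b| <= dt_s`` counts.
    """
    if not dt_s > 0:
        raise ValidationError("dt_s must be positive")
    a, b = train_a.times, train_b.times
    if a.size == 0:
        return float("nan")
    if b.size == 0:
        return 0.0
    # nearest B spike on each side of every A spike
    idx = np.searchsorted(b, a)
    right_ok = (idx < b.size) & (b[np.minimum(idx, b.size - 1)] - a <= dt_s)
    left_ok = (idx > 0) & (a - b[np.maximum(idx - 1, 0)] <= dt_s)
    return float(np.mean(right_ok | left_ok))


def sttc_pair(train_a: SpikeTrain, train_b: SpikeTrain, dt_s: float) -> float:
    """STTC of one train pair; NaN if either train is empty or a denominator is 0."""
    if train_a.duration_s != train_b.duration_s:
        raise ValidationError("trains must share duration_s")
    if train_a.n_spikes == 0 or train_b.n_spikes == 0:
        return float("nan")
    ta = tiled_fraction(train_a, dt_s)
    tb = tiled_fraction(train_b, dt_s)
    pa = coincident_fraction(train_a, train_b, dt_s)
    pb = coincident_fraction(train_b, train_a, dt_s)
    return _combine(pa, pb, ta, tb)


def _combine(pa: float, pb: float, ta: float, tb: float) -> float:
    da = 1.0 - pa * tb
    db = 1.0 - pb * ta
    if da == 0.0 or db == 0.0:
        return float("nan")
    return 0.5 * ((pa - tb) / da + (pb - ta) / db)


@dataclass(frozen=True)
class STTCMatrix:
    """Symmetric pairwise STTC matrix over electrodes.

    Diagonal entries are 1 for non-empty trains and NaN for empty ones;
    off-diagonal NaN marks an undefined pair.  Keeps a reference to the
    spike matrix it was computed from so downstream graph construction can
    attach firing rates without re-plumbing.
    """

    values: np.ndarray
    dt_s: float
    duration_s: float
    electrode_ids: tuple[int, ...]
    spike_matrix: SpikeMatrix | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("STTC matrix must be square")
        if v.shape[0] != len(self.electrode_ids):
            raise ValidationError("one electrode id per row required")
        if not np.array_equal(v, v.T, equal_nan=True):
            raise ValidationError("STTC matrix must be symmetric")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
            raise ValidationError("STTC values must lie in [-1, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "electrode_ids",
                           tuple(int(i) for i in self.electrode_ids))

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]


def sttc_matrix(spike_matrix: SpikeMatrix, dt_s: float) -> STTCMatrix:
    """Pairwise STTC over all unordered electrode pairs.

    Tiled fractions are computed once per train; each pair is then two
    sorted-array coincidence sweeps, so the full matrix is
    O(N * n log n + N^2 * n) for N trains of ~n spikes.
    """
    n = spike_matrix.n_electrodes
    if n == 0:
        raise ValidationError("spike matrix is empty")
    T = spike_matrix.duration_s
    tiled = np.array([tiled_fraction(tr, dt_s) if tr.n_spikes else np.nan
                      for tr in spike_matrix])
    vals = np.full((n, n), np.nan)
    for i, tr in enumerate(spike_matrix):
        if tr.n_spikes:
            vals[i, i] = 1.0
    for i in range(n):
        a = spike_matrix[i]
        if a.n_spikes == 0:
            continue
        for j in range(i + 1, n):
            b = spike_matrix[j]
            if b.n_spikes == 0:
                continue
            pa = coincident_fraction(a, b, dt_s)
            pb = coincident_fraction(b, a, dt_s)
            vals[i, j] = vals[j, i] = _combine(pa, pb, tiled[i], tiled[j])
    return STTCMatrix(vals, dt_s=dt_s, duration_s=T,
                      electrode_ids=spike_matrix.electrode_ids,
                      spike_matrix=spike_matrix)


class STTCAnalyzer(TransformerMixin, BaseEstimator):
    """Transformer computing the pairwise STTC matrix of a spike matrix.

    Parameters
    ----------
    dt_s : float, default=0.175
        Synchronicity half-window in seconds (175 ms default).

    Attributes
    ----------
    electrode_ids_ : tuple of int
        Electrodes seen during :meth:`fit`.
    """

    def __init__(self, dt_s: float = 0.175):
        self.dt_s = dt_s

    def fit(self, X: SpikeMatrix, y=None) -> "STTCAnalyzer":
        if not isinstance(X, SpikeMatrix):
            raise ValidationError("STTCAnalyzer expects a SpikeMatrix")
        if not self.dt_s > 0:
            raise ValidationError("dt_s must be positive")
        self.electrode_ids_ = X.electrode_ids
        return self

    def transform(self, X: SpikeMatrix) -> STTCMatrix:
        if not hasattr(self, "electrode_ids_"):
            self.fit(X)
        return sttc_matrix(X, self.dt_s)
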