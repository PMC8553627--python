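"""In-memory containers for multielectrode-array (MEA) analysis.

The recording window is half-open, ``[0, T)``: a spike at exactly ``T``
belongs to the next window and is rejected.  Spike times are seconds as
64-bit floats throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "RawRecording",
    "SpikeTrain",
    "SpikeMatrix",
    "MEALayout",
    "GroundTruth",
    "standard_60_electrode_layout",
]


@dataclass(frozen=True)
class RawRecording:
    """Multichannel extracellular voltage.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Voltage in consistent (arbitrary) amplitude units, e.g. µV.
    sampling_rate_hz : float
        Acquisition rate; must be positive.
    """

    signal: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=np.float64)
        if sig.ndim != 2:
            raise ValidationError(
                f"signal must be 2-D (channels x samples), got ndim={sig.ndim}"
            )
        if not np.isfinite(sig).all():
            raise ValidationError("signal contains non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")
        object.__setattr__(self, "signal", sig)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one electrode over a common window ``[0, T)``."""

    times: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        if t.ndim != 1:
            raise ValidationError("spike times must be a 1-D array")
        if not self.duration_s > 0:
            raise ValidationError("duration_s must be positive")
        if t.size:
            if not np.isfinite(t).all():
                raise ValidationError("spike times must be finite")
            if np.any(np.diff(t) <= 0):
                raise ValidationError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] >= self.duration_s:
                raise ValidationError(
                    "spike times must lie in the half-open window [0, duration_s)"
                )
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def firing_rate_hz(self) -> float:
        return self.n_spikes / self.duration_s

    def __len__(self) -> int:
        return self.n_spikes


@dataclass(frozen=True)
class SpikeMatrix:
    """Collection of spike trains over a shared window, one per electrode."""

    trains: tuple[SpikeTrain, ...]
    electrode_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        trains = tuple(self.trains)
        ids = tuple(int(i) for i in self.electrode_ids)
        if len(trains) != len(ids):
            raise ValidationError("one electrode id per train required")
        if len(set(ids)) != len(ids):
            raise ValidationError("electrode ids must be unique")
        if trains:
            T = trains[0].duration_s
            if any(tr.duration_s != T for tr in trains):
                raise ValidationError("all trains must share duration_s")
        object.__setattr__(self, "trains", trains)
        object.__setattr__(self, "electrode_ids", ids)

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    @property
    def duration_s(self) -> float:
        if not self.trains:
            raise ValidationError("empty spike matrix has no duration")
        return self.trains[0].duration_s

    @property
    def n_spikes_per_electrode(self) -> np.ndarray:
        return np.array([tr.n_spikes for tr in self.trains], dtype=np.int64)

    def __iter__(self) -> Iterator[SpikeTrain]:
        return iter(self.trains)

    def __getitem__(self, idx: int) -> SpikeTrain:
        return self.trains[idx]

    def train_for(self, electrode_id: int) -> SpikeTrain:
        try:
            return self.trains[self.electrode_ids.index(int(electrode_id))]
        except ValueError:
            raise KeyError(f"no electrode {electrode_id}") from None

    @classmethod
    def from_times(
        cls,
        times_per_electrode: Sequence[np.ndarray],
        duration_s: float,
        electrode_ids: Sequence[int] | None = None,
    ) -> "SpikeMatrix":
        if electrode_ids is None:
            electrode_ids = range(len(times_per_electrode))
        trains = tuple(SpikeTrain(np.asarray(t, dtype=np.float64), duration_s)
                       for t in times_per_electrode)
        return cls(trains, tuple(int(i) for i in electrode_ids))


@dataclass(frozen=True)
class MEALayout:
    """Electrode geometry: integer IDs and coordinates in micrometres."""

    electrode_ids: tuple[int, ...]
    positions_um: np.ndarray  # (n, 2) or (n, 3)
    diameter_um: float = 12.0
    pitch_um: float = 200.0

    def __post_init__(self) -> None:
        ids = tuple(int(i) for i in self.electrode_ids)
        pos = np.asarray(self.positions_um, dtype=np.float64)
        if len(set(ids)) != len(ids):
            raise ValidationError("electrode ids must be unique")
        if len(ids) < 2:
            raise ValidationError("a layout needs at least 2 electrodes")
        if pos.ndim != 2 or pos.shape[0] != len(ids) or pos.shape[1] not in (2, 3):
            raise ValidationError("positions_um must be (n_electrodes, 2 or 3)")
        if not np.isfinite(pos).all():
            raise ValidationError("electrode coordinates must be finite")
        if not self.diameter_um > 0:
            raise ValidationError("diameter_um must be positive")
        object.__setattr__(self, "electrode_ids", ids)
        object.__setattr__(self, "positions_um", pos)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    def to_frame(self) -> pd.DataFrame:
        cols = ["x_um", "y_um", "z_um"][: self.positions_um.shape[1]]
        df = pd.DataFrame(self.positions_um, columns=cols)
        df.insert(0, "electrode_id", self.electrode_ids)
        return df


def standard_60_electrode_layout(pitch_um: float = 200.0,
                                 diameter_um: float = 12.0) -> MEALayout:
    """The common 60-electrode grid: an 8 x 8 array with the four corners absent.

    Electrode IDs are assigned row-major (0-based) over the occupied sites;
    coordinates are site centres at the given pitch.
    """
    ids, pos = [], []
    k = 0
    for r in range(8):
        for c in range(8):
            if (r, c) in ((0, 0), (0, 7), (7, 0), (7, 7)):
                continue
            ids.append(k)
            pos.append((c * pitch_um, r * pitch_um))
            k += 1
    return MEALayout(tuple(ids), np.array(pos, dtype=np.float64),
                     diameter_um=diameter_um, pitch_um=pitch_um)


@dataclass(frozen=True)
class GroundTruth:
    """Known truth attached to synthetic data so every stage is verifiable.

    ``true_spikes`` holds the exact injected spike times; ``target_rate_hz``
    the intended per-electrode rates; ``injected_correlation`` the pairwise
    synchrony parameter of any correlated group (``c`` of the
    multiple-interaction process); ``waveform`` the sampled template added to
    the raw trace and ``noise_sd`` the background standard deviation in the
    same amplitude units.
    """

    true_spikes: SpikeMatrix
    target_rate_hz: np.ndarray
    injected_correlation: float
    seed: int
    waveform: np.ndarray | None = None
    noise_sd: float = 0.0
    correlated_group: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.injected_correlation <= 1.0:
            raise ValidationError("injected_correlation must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        object.__setattr__(
            self, "target_rate_hz",
            np.asarray(self.target_rate_hz, dtype=np.float64))
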