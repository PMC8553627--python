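"""Run configuration.

Defaults follow the analysis settings the pipeline reproduces: third-order
Butterworth bandpass 600-8,000 Hz, detection threshold 3 standard deviations
of the background noise with a 1.5 ms refractory period, STTC synchronicity
window 175 ms, and graph edges for STTC > 0.6.  The remaining knobs
(surrogate count and scheme, noise estimator, polarity, seed) are artifact
decisions documented in docs/methods.md.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ValidationError

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    band_low_hz: float = Field(default=600.0, gt=0)
    band_high_hz: float = Field(default=8000.0, gt=0)
    filter_order: int = Field(default=3, ge=1)
    threshold_k: float = Field(default=3.0, gt=0)
    refractory_ms: float = Field(default=1.5, gt=0)
    sttc_dt_ms: float = Field(default=175.0, gt=0)
    edge_threshold: float = Field(default=0.6, ge=0.0, le=1.0)
    n_surrogates: int = Field(default=100, ge=1)
    seed: int = 0
    noise_estimator: Literal["robust", "plain"] = "robust"
    polarity: Literal["negative", "positive", "both"] = "negative"
    surrogate_scheme: Literal["uniform", "isi_shuffle", "jitter"] = "uniform"
    surrogate_jitter_ms: float = Field(default=350.0, gt=0)

    @model_validator(mode="after")
    def _band_ordered(self) -> "RunConfig":
        if not self.band_low_hz < self.band_high_hz:
            raise ValueError(
                f"band_low_hz ({self.band_low_hz}) must be below "
                f"band_high_hz ({self.band_high_hz})")
        return self

    @property
    def sttc_dt_s(self) -> float:
        return self.sttc_dt_ms / 1000.0

    @property
    def refractory_s(self) -> float:
        return self.refractory_ms / 1000.0

    def to_dict(self) -> dict[str, Any]:
        return self.model_dump()


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Precedence: explicit keyword overrides > file values > defaults.  An
    empty or absent file yields all defaults.  Out-of-range or unknown
    fields raise :class:`~meanet.errors.ValidationError` naming the field.
    """
    data: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must be a mapping")
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**data)
    except (ValueError, TypeError) as exc:  # pydantic ValidationError included
        raise ValidationError(f"invalid configuration: {exc}") from exc
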