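"""End-to-end orchestration: detect -> STTC -> graph -> surrogates -> report.

``run_all`` accepts either a raw recording (detection runs first) or a
pre-detected spike table (detection is skipped; supplying detection flags
together with a spike table is an error).  A single :class:`RunConfig`
drives every stage, and the returned :class:`RunManifest` — the config
echo, content hashes of the inputs, and the stage output paths — together
with the original inputs reproduces every output byte-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .config import RunConfig
from .containers import MEALayout, RawRecording, SpikeMatrix
from .detect import SpikeDetector
from .errors import MeanetError, ValidationError
from .io import (read_recording, read_spike_table, write_report,
                 write_spike_table)
from .network import NetworkBuilder
from .sttc import STTCAnalyzer
from .surrogate import SurrogateNull

__all__ = ["run_all", "RunManifest"]

log = logging.getLogger("meanet")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-execute a run and verify its outputs.

    Stage output paths are relative to the run directory so identical runs
    in different locations produce identical manifests.
    """

    config: dict[str, Any]
    input_fingerprints: dict[str, str]
    stage_outputs: dict[str, str]
    version: str = __version__
    complete: bool = False
    stage_log: list[dict[str, Any]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)


def run_all(
    config: RunConfig,
    outdir: str | Path,
    recording_path: str | Path | None = None,
    spike_table_path: str | Path | None = None,
    spike_table_duration_s: float | None = None,
    layout: MEALayout | None = None,
    detection_flags_supplied: bool = False,
) -> RunManifest:
    """Run the full analysis chain on one input and write all result files.

    Exactly one of ``recording_path`` / ``spike_table_path`` must be given.
    With a spike table, ``spike_table_duration_s`` (the recording window
    length) is required and detection flags must not be supplied.
    """
    if (recording_path is None) == (spike_table_path is None):
        raise ValidationError(
            "provide exactly one input: a raw recording or a spike table")
    if spike_table_path is not None and detection_flags_supplied:
        raise ValidationError(
            "detection flags are meaningless with a pre-detected spike table")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fingerprints: dict[str, str] = {}
    manifest = RunManifest(config=config.to_dict(), input_fingerprints=fingerprints,
                           stage_outputs={})
    extra: dict[str, Any] = {}

    try:
        if recording_path is not None:
            fingerprints["recording"] = _sha256(Path(recording_path))
            rec = read_recording(recording_path)
            log.info("detect: %d channels, %.1f s at %.0f Hz",
                     rec.n_channels, rec.duration_s, rec.sampling_rate_hz)
            detector = SpikeDetector(
                band_low_hz=config.band_low_hz, band_high_hz=config.band_high_hz,
                filter_order=config.filter_order, threshold_k=config.threshold_k,
                refractory_ms=config.refractory_ms, polarity=config.polarity,
                noise_estimator=config.noise_estimator)
            det = detector.fit_transform(rec)
            spikes = det.spike_matrix
            write_spike_table(spikes, outdir / "spikes.csv")
            manifest.stage_outputs["spike_table"] = "spikes.csv"
            extra["noise_sd_per_channel"] = det.noise_sd_per_channel.tolist()
            manifest.stage_log.append(
                {"stage": "detect",
                 "spikes_per_electrode": spikes.n_spikes_per_electrode.tolist()})
        else:
            if spike_table_duration_s is None:
                raise ValidationError(
                    "spike_table_duration_s is required with a spike table")
            fingerprints["spike_table"] = _sha256(Path(spike_table_path))
            spikes = read_spike_table(spike_table_path, spike_table_duration_s,
                                      layout)
            manifest.stage_log.append(
                {"stage": "load_spikes",
                 "spikes_per_electrode": spikes.n_spikes_per_electrode.tolist()})

        sttc = STTCAnalyzer(dt_s=config.sttc_dt_s).fit_transform(spikes)
        manifest.stage_log.append({"stage": "sttc",
                                   "n_electrodes": sttc.n_electrodes})

        graph = NetworkBuilder(edge_threshold=config.edge_threshold
                               ).fit_transform(sttc)
        manifest.stage_log.append({"stage": "network", "n_edges": graph.n_edges})

        null = SurrogateNull(
            n_surrogates=config.n_surrogates, seed=config.seed,
            dt_s=config.sttc_dt_s, edge_threshold=config.edge_threshold,
            scheme=config.surrogate_scheme,
            jitter_s=config.surrogate_jitter_ms / 1000.0).fit(spikes)
        comparison = null.compare(graph)
        manifest.stage_log.append({"stage": "surrogate",
                                   "n_surrogates": config.n_surrogates})

        paths = write_report(outdir, sttc=sttc, graph=graph, config=config,
                             surrogate_comparison=comparison,
                             extra_summary=extra)
        manifest.stage_outputs.update({k: v.name for k, v in paths.items()})
        manifest.complete = True
    except MeanetError:
        (outdir / "manifest.json").write_text(manifest.to_json())
        raise

    manifest.stage_outputs["manifest"] = "manifest.json"
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
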