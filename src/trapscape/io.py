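"""Trace and spec serialization.

Two trace formats: two-column delimited text (time_s, voltage_V) with a
commented header, and flat binary float64 with a JSON sidecar carrying the
acquisition metadata.  Ground-truth and acquisition specs round-trip through
JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .core import TransmissionTrace
from .synthetic import AcquisitionSpec, GroundTruthSpec

__all__ = [
    "save_trace", "load_trace", "spec_to_json", "spec_from_json",
    "acquisition_to_json", "acquisition_from_json", "json_ready",
]


def json_ready(obj):
    """Recursively convert numpy scalars/arrays so json.dumps accepts them."""
    if isinstance(obj, dict):
        return {k: json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [json_ready(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return json_ready(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def save_trace(trace: TransmissionTrace, path: str | Path, fmt: str = "bin") -> Path:
    """Write a trace as text ('txt') or binary-with-sidecar ('bin')."""
    path = Path(path)
    if fmt == "txt":
        t = np.arange(trace.samples.size) / trace.sampling_rate
        header = (f"transmission trace\nsampling_rate_Hz: {trace.sampling_rate}\n"
                  f"temperature_K: {trace.temperature}\n"
                  f"metadata: {json.dumps(json_ready(trace.metadata))}\n"
                  "time_s\tvoltage_V")
        np.savetxt(path, np.column_stack([t, trace.samples]),
                   fmt="%.9g", delimiter="\t", header=header)
    elif fmt == "bin":
        trace.samples.astype("<f8").tofile(path)
        sidecar = {
            "sampling_rate": trace.sampling_rate,
            "temperature": trace.temperature,
            "dtype": "<f8",
            "metadata": json_ready(trace.metadata),
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    else:
        raise ValueError("fmt must be 'txt' or 'bin'")
    return path


def load_trace(path: str | Path) -> TransmissionTrace:
    """Load a trace written by :func:`save_trace` (format auto-detected)."""
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        samples = np.fromfile(path, dtype=meta.get("dtype", "<f8"))
        return TransmissionTrace(samples, meta["sampling_rate"],
                                 meta.get("temperature", 310.0),
                                 meta.get("metadata", {}))
    header_meta = {"sampling_rate": None, "temperature": 310.0, "metadata": {}}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("sampling_rate_Hz:"):
                header_meta["sampling_rate"] = float(body.split(":", 1)[1])
            elif body.startswith("temperature_K:"):
                header_meta["temperature"] = float(body.split(":", 1)[1])
            elif body.startswith("metadata:"):
                header_meta["metadata"] = json.loads(body.split(":", 1)[1])
    data = np.loadtxt(path)
    if header_meta["sampling_rate"] is None:
        dt = np.median(np.diff(data[:, 0]))
        header_meta["sampling_rate"] = 1.0 / dt
    return TransmissionTrace(data[:, 1], header_meta["sampling_rate"],
                             header_meta["temperature"], header_meta["metadata"])


def spec_to_json(spec: GroundTruthSpec, path: str | Path | None = None) -> str:
    payload = json.dumps(json_ready(dataclasses.asdict(spec)), indent=2)
    if path is not None:
        Path(path).write_text(payload)
    return payload


def spec_from_json(source: str | Path) -> GroundTruthSpec:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    return GroundTruthSpec(**json.loads(text))


def acquisition_to_json(acq: AcquisitionSpec, path: str | Path | None = None) -> str:
    payload = json.dumps(json_ready(dataclasses.asdict(acq)), indent=2)
    if path is not None:
        Path(path).write_text(payload)
    return payload


def acquisition_from_json(source: str | Path) -> AcquisitionSpec:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    return AcquisitionSpec(**json.loads(text))
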