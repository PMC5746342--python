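"""File round-tripping: CSV traces/curves/events with JSON sidecars, and
run manifests.

Traces are written as two-column CSV (``time_ms,value``) with a JSON sidecar
(``<path>.json``) holding units, dt, site and any metadata; I–V curves as
``v_mV,i_nA``; event series as ``time_ms[,amplitude]``.  Text formats keep
runs diffable and dependency-light.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
import datetime as _dt
import hashlib
import json
import pathlib

import numpy as np
import pandas as pd

from .records import EventSeries, IVCurve, TraceRecord

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_iv_curve",
    "read_iv_curve",
    "write_events",
    "read_events",
    "RunManifest",
]

_UNITS = {"voltage": "mV", "current": "nA", "conductance": "uS"}


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_timeseries(record: TraceRecord, path) -> None:
    """CSV (time_ms, value) plus a JSON sidecar at ``<path>.json``."""
    path = pathlib.Path(path)
    df = pd.DataFrame({"time_ms": record.time, "value": record.samples})
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "kind": record.kind,
        "units": _UNITS[record.kind],
        "dt_ms": record.dt,
        "t0_ms": record.t0,
        "site": record.site,
        "n_samples": int(record.samples.size),
        "meta": _jsonable(record.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_timeseries(path) -> TraceRecord:
    path = pathlib.Path(path)
    df = pd.read_csv(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = {}
    kind, site, t0 = "voltage", "unknown", float(df["time_ms"].iloc[0])
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        kind = sc.get("kind", kind)
        site = sc.get("site", site)
        t0 = sc.get("t0_ms", t0)
        meta = sc.get("meta", {})
    dt = float(np.median(np.diff(df["time_ms"].to_numpy())))
    return TraceRecord(dt=dt, samples=df["value"].to_numpy(), kind=kind,
                       site=site, t0=t0, meta=meta)


def write_iv_curve(curve: IVCurve, path) -> None:
    path = pathlib.Path(path)
    pd.DataFrame({"v_mV": curve.v, "i_nA": curve.i}).to_csv(
        path, index=False, float_format="%.9g")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps({
        "condition": curve.condition,
        "ramp_duration_ms": curve.ramp_duration,
    }, indent=1))


def read_iv_curve(path) -> IVCurve:
    path = pathlib.Path(path)
    df = pd.read_csv(path)
    cond, dur = "", None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        sc = json.loads(sidecar.read_text())
        cond = sc.get("condition", "")
        dur = sc.get("ramp_duration_ms")
    return IVCurve(v=df["v_mV"].to_numpy(), i=df["i_nA"].to_numpy(),
                   condition=cond, ramp_duration=dur)


def write_events(events: EventSeries, path) -> None:
    path = pathlib.Path(path)
    data = {"time_ms": events.times}
    if events.amplitudes is not None:
        data["amplitude"] = events.amplitudes
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"meta": _jsonable(events.meta)}, indent=1))


def read_events(path) -> EventSeries:
    df = pd.read_csv(path)
    amp = df["amplitude"].to_numpy() if "amplitude" in df.columns else None
    return EventSeries(times=df["time_ms"].to_numpy(), amplitudes=amp)


@dataclass
class RunManifest:
    """Record of one CLI invocation: config hash, seeds, outputs."""

    command: str
    config_hash: str = ""
    seeds: list = field(default_factory=list)
    version: str = "0.1.0"
    started: str = ""
    finished: str = ""
    outputs: list = field(default_factory=list)
    status: str = "running"

    @staticmethod
    def hash_config(payload) -> str:
        text = json.dumps(_jsonable(payload), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def start(self) -> "RunManifest":
        self.started = _dt.datetime.now(_dt.timezone.utc).isoformat()
        return self

    def finish(self, status: str = "ok") -> "RunManifest":
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        self.status = status
        return self

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        pathlib.Path(path).write_text(json.dumps(asdict(self), indent=1))
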