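"""File formats and table validation.

Tables are CSV with unit-suffixed headers (``y_um``, ``velocity_m_s``...).
Traces are two-column float32 binary with a JSON sidecar (or CSV); frames go
to multi-page TIFF with per-page timestamp metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simkit import Frame, ImpedanceTrace

__all__ = [
    "write_table", "read_table",
    "write_trace", "read_trace",
    "write_frames_tiff", "read_frames_tiff",
    "write_manifest", "read_manifest",
    "validate_tables",
]

EVENT_COLUMNS = ("event_id", "t_extremum1_s", "t_extremum2_s", "dt1_s",
                 "velocity_m_s", "dI1", "dI2", "t_trigger_s", "ed_raw")
OPTICS_COLUMNS = ("frame_index", "od", "y_um", "n_objects_in_frame")
CORRELATED_COLUMNS = ("event_id", "frame_index", "ed", "od", "y_um",
                      "coincident")


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trace(trace: ImpedanceTrace, path_base) -> tuple[Path, Path]:
    """float32 little-endian binary (C order, n x 2) plus JSON sidecar."""
    base = Path(path_base)
    bin_path = base.with_suffix(".f32")
    json_path = base.with_suffix(".json")
    data = np.ascontiguousarray(trace.data, dtype="<f4")
    data.tofile(bin_path)
    sidecar = {"sample_rate_hz": trace.sample_rate_hz,
               "n_samples": int(data.shape[0]),
               "n_channels": int(data.shape[1]),
               "dtype": "<f4", "order": "C", "meta": trace.meta}
    json_path.write_text(json.dumps(sidecar, indent=1))
    return bin_path, json_path


def read_trace(path_base) -> ImpedanceTrace:
    base = Path(path_base)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    data = np.fromfile(base.with_suffix(".f32"), dtype=sidecar["dtype"])
    data = data.reshape(sidecar["n_samples"], sidecar["n_channels"])
    return ImpedanceTrace(data=data.astype(np.float32),
                          sample_rate_hz=sidecar["sample_rate_hz"],
                          meta=sidecar.get("meta", {}))


def write_frames_tiff(frames, path) -> Path:
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for f in frames:
            tif.write(np.asarray(f.image, dtype=np.float32),
                      description=json.dumps(
                          {"timestamp_s": f.timestamp_s,
                           "frame_index": f.frame_index,
                           "n_objects": f.n_objects}),
                      contiguous=False)
    return path


def read_frames_tiff(path) -> list[Frame]:
    frames = []
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            meta = {}
            if page.description:
                try:
                    meta = json.loads(page.description)
                except (ValueError, TypeError):
                    meta = {}
            frames.append(Frame(image=page.asarray(),
                                timestamp_s=float(meta.get("timestamp_s", i)),
                                frame_index=int(meta.get("frame_index", i)),
                                n_objects=int(meta.get("n_objects", 0))))
    return frames


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _require_columns(df: pd.DataFrame, cols, table: str, out: list) -> bool:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        out.append({"table": table, "rule": "schema",
                    "detail": f"missing columns: {missing}", "count": 1})
        return False
    return True


def validate_tables(events: pd.DataFrame | None = None,
                    optics: pd.DataFrame | None = None,
                    correlated: pd.DataFrame | None = None,
                    gate_halfwidth_um: float = 6.3,
                    channel_width_um: float = 40.0) -> list[dict]:
    """Schema, unit and invariant audit.  Always returns diagnostics."""
    out: list[dict] = []
    if events is not None and _require_columns(events, EVENT_COLUMNS,
                                               "events", out):
        for col, rule in (("dt1_s", "dt1_s > 0"), ("dI1", "dI1 > 0"),
                          ("dI2", "dI2 > 0")):
            bad = int((events[col] <= 0).sum())
            if bad:
                out.append({"table": "events", "rule": rule, "count": bad,
                            "detail": col})
        bad = int((events["t_trigger_s"] <= events["t_extremum2_s"]).sum())
        if bad:
            out.append({"table": "events",
                        "rule": "t_trigger_s > t_extremum2_s", "count": bad,
                        "detail": "trigger precedes event"})
    if optics is not None and _require_columns(optics, OPTICS_COLUMNS,
                                               "optics", out):
        bad = int((optics["od"] < 1).sum())
        if bad:
            out.append({"table": "optics", "rule": "OD >= 1", "count": bad,
                        "detail": "od"})
        bad = int((optics["y_um"].abs() > channel_width_um / 2).sum())
        if bad:
            out.append({"table": "optics",
                        "rule": "|y_um| <= channel half-width",
                        "count": bad, "detail": "y_um"})
    if correlated is not None and _require_columns(
            correlated, CORRELATED_COLUMNS, "correlated", out):
        finite = correlated["od"].notna()
        bad = int((correlated.loc[finite, "od"] < 1).sum())
        if bad:
            out.append({"table": "correlated", "rule": "OD >= 1",
                        "count": bad, "detail": "od"})
        if "ed" in correlated:
            fin = correlated["ed"].notna()
            bad = int((correlated.loc[fin, "ed"] <= 0).sum())
            if bad:
                out.append({"table": "correlated", "rule": "ED > 0",
                            "count": bad, "detail": "ed"})
        if "gate_pass" in correlated.columns:
            y = correlated["y_um"].to_numpy(dtype=float)
            expect = np.abs(y) <= gate_halfwidth_um
            expect[~np.isfinite(y)] = False
            bad = int((correlated["gate_pass"].to_numpy(bool)
                       != expect).sum())
            if bad:
                out.append({"table": "correlated",
                            "rule": "gate_pass consistent with y_um",
                            "count": bad, "detail": "gate_pass"})
    return out
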