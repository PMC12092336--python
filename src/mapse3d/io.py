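"""Interchange formats for detection streams, tables, and results.

The canonical on-disk form of a detection stream is versioned JSON (nested
per-volume records); a flat CSV encoding of the same data is provided for
spreadsheet audit.  Both round-trip losslessly (full-precision floats).
Result files embed the schema version, the seed, and a configuration hash so
reruns are traceable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import DetectionStream, RecordingMeasurement, VolumeFrame
from .stats import MonitoringSeries

SCHEMA_VERSION = "1"

__all__ = [
    "SCHEMA_VERSION",
    "read_stream",
    "write_stream",
    "write_ground_truth",
    "read_replicate_table",
    "write_replicate_table",
    "read_monitoring_series",
    "write_monitoring_series",
    "write_measurement",
    "config_hash",
]


class StreamFormatError(ValueError):
    """A stream file does not conform to the interchange schema."""


def config_hash(config: dict) -> str:
    """SHA-256 of a canonical JSON rendering of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# detection streams


def _stream_to_dict(stream: DetectionStream) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "volume_rate": stream.volume_rate,
        "r_times": stream.r_times.tolist(),
        "metadata": dict(stream.metadata),
        "volumes": [
            {
                "t": v.t,
                "points": [
                    {
                        "azimuth_deg": float(v.azimuth_deg[j]),
                        "x": float(v.positions[j, 0]),
                        "y": float(v.positions[j, 1]),
                        "z": float(v.positions[j, 2]),
                        "confidence": (
                            None if v.confidence is None else float(v.confidence[j])
                        ),
                    }
                    for j in range(v.n_points)
                ],
            }
            for v in stream.volumes
        ],
    }


def _stream_from_dict(doc: dict, where: str = "<stream>") -> DetectionStream:
    if "schema_version" not in doc:
        raise StreamFormatError(f"{where}: missing field 'schema_version'")
    if str(doc["schema_version"]) != SCHEMA_VERSION:
        raise StreamFormatError(
            f"{where}: schema version {doc['schema_version']!r} "
            f"not supported (expected {SCHEMA_VERSION!r})"
        )
    for key in ("volume_rate", "r_times", "volumes"):
        if key not in doc:
            raise StreamFormatError(f"{where}: missing field {key!r}")
    volumes = []
    for i, rec in enumerate(doc["volumes"]):
        pts = rec.get("points", [])
        az = np.array([p["azimuth_deg"] for p in pts], dtype=float)
        pos = np.array([[p["x"], p["y"], p["z"]] for p in pts], dtype=float).reshape(-1, 3)
        confs = [p.get("confidence") for p in pts]
        conf = None if any(c is None for c in confs) or not confs else np.array(confs)
        try:
            volumes.append(VolumeFrame(t=float(rec["t"]), azimuth_deg=az, positions=pos, confidence=conf))
        except (KeyError, ValueError) as exc:
            raise StreamFormatError(f"{where}: volume record {i}: {exc}") from exc
    try:
        return DetectionStream(
            volumes=tuple(volumes),
            r_times=np.asarray(doc["r_times"], dtype=float),
            volume_rate=float(doc["volume_rate"]),
            metadata=doc.get("metadata", {}),
        )
    except ValueError as exc:
        raise StreamFormatError(f"{where}: {exc}") from exc


def write_stream(stream: DetectionStream, path: str | Path) -> Path:
    """Write a stream as JSON (``.json``) or flat CSV (``.csv``) by suffix."""
    path = Path(path)
    if path.suffix == ".csv":
        _write_stream_csv(stream, path)
    else:
        path.write_text(json.dumps(_stream_to_dict(stream), indent=1))
    return path


def read_stream(path: str | Path) -> DetectionStream:
    """Read a stream written by :func:`write_stream` (JSON or CSV)."""
    path = Path(path)
    if path.suffix == ".csv":
        return _read_stream_csv(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise StreamFormatError(f"{path}: not valid JSON: {exc}") from exc
    return _stream_from_dict(doc, where=str(path))


def _write_stream_csv(stream: DetectionStream, path: Path) -> None:
    header = {
        "schema_version": SCHEMA_VERSION,
        "volume_rate": stream.volume_rate,
        "r_times": stream.r_times.tolist(),
        "metadata": dict(stream.metadata),
        "volume_times": stream.times.tolist(),
    }
    rows = []
    for i, v in enumerate(stream.volumes):
        for j in range(v.n_points):
            rows.append(
                {
                    "volume": i,
                    "t": v.t,
                    "azimuth_deg": v.azimuth_deg[j],
                    "x": v.positions[j, 0],
                    "y": v.positions[j, 1],
                    "z": v.positions[j, 2],
                    "confidence": np.nan if v.confidence is None else v.confidence[j],
                }
            )
    df = pd.DataFrame(rows, columns=["volume", "t", "azimuth_deg", "x", "y", "z", "confidence"])
    buf = _io.StringIO()
    buf.write("# " + json.dumps(header) + "\n")
    df.to_csv(buf, index=False, float_format="%.17g")  # lossless float64 round-trip
    path.write_text(buf.getvalue())


def _read_stream_csv(path: Path) -> DetectionStream:
    text = path.read_text().splitlines()
    if not text or not text[0].startswith("# "):
        raise StreamFormatError(f"{path}: missing '# ' JSON header line")
    header = json.loads(text[0][2:])
    if "r_times" not in header:
        raise StreamFormatError(f"{path}: missing field 'r_times'")
    if str(header.get("schema_version")) != SCHEMA_VERSION:
        raise StreamFormatError(
            f"{path}: schema version {header.get('schema_version')!r} not supported"
        )
    df = pd.read_csv(_io.StringIO("\n".join(text[1:])), float_precision="round_trip")
    volume_times = header["volume_times"]
    volumes = []
    grouped = dict(tuple(df.groupby("volume"))) if len(df) else {}
    for i, t in enumerate(volume_times):
        g = grouped.get(i)
        if g is None:
            volumes.append(
                VolumeFrame(t=float(t), azimuth_deg=np.empty(0), positions=np.empty((0, 3)))
            )
        else:
            conf = g["confidence"].to_numpy(dtype=float)
            volumes.append(
                VolumeFrame(
                    t=float(t),
                    azimuth_deg=g["azimuth_deg"].to_numpy(dtype=float),
                    positions=np.ascontiguousarray(g[["x", "y", "z"]].to_numpy(dtype=float)),
                    confidence=None if np.isnan(conf).all() else conf,
                )
            )
    return DetectionStream(
        volumes=tuple(volumes),
        r_times=np.asarray(header["r_times"], dtype=float),
        volume_rate=float(header["volume_rate"]),
        metadata=header.get("metadata", {}),
    )


def write_ground_truth(truth, stream_path: str | Path) -> Path:
    """Write the simulator ground truth next to its stream (same basename)."""
    stream_path = Path(stream_path)
    path = stream_path.with_suffix(".truth.json")
    path.write_text(json.dumps({"schema_version": SCHEMA_VERSION, **truth.to_dict()}, indent=1))
    return path


# ---------------------------------------------------------------------------
# tables and results


def write_replicate_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Replicate table CSV with columns subject, method, replicate, value_mm."""
    path = Path(path)
    table[["subject", "method", "replicate", "value_mm"]].to_csv(path, index=False)
    return path


def read_replicate_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"subject", "method", "replicate", "value_mm"} - set(df.columns)
    if missing:
        raise StreamFormatError(f"{path}: replicate table missing columns {sorted(missing)}")
    return df


def write_monitoring_series(series: MonitoringSeries, path: str | Path) -> Path:
    """Monitoring series CSV with columns t_min, value_mm."""
    path = Path(path)
    series.to_frame().to_csv(path, index=False)
    return path


def read_monitoring_series(path: str | Path) -> MonitoringSeries:
    df = pd.read_csv(path)
    missing = {"t_min", "value_mm"} - set(df.columns)
    if missing:
        raise StreamFormatError(f"{path}: monitoring series missing columns {sorted(missing)}")
    return MonitoringSeries(
        t_min=df["t_min"].to_numpy(dtype=float), value_mm=df["value_mm"].to_numpy(dtype=float)
    )


def write_measurement(
    result: RecordingMeasurement, out_dir: str | Path, header: dict | None = None
) -> tuple[Path, Path]:
    """Write a recording measurement as JSON plus a per-wall CSV table.

    The CSV mirrors a per-wall summary layout: wall, the fraction of cycles
    that yielded a feasible sub-measurement, and the wall's mean MAPSE.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "schema_version": SCHEMA_VERSION,
        **(header or {}),
        "mapse_mm": result.mapse_mm,
        "feasible": result.feasible,
        "n_walls_contributing": result.n_walls_contributing,
        "n_cycles_contributing": result.n_cycles_contributing,
        "sub_measurements": [
            {
                "wall": r.wall,
                "cycle": int(r.cycle),
                "value_mm": None if pd.isna(r.value_mm) else float(r.value_mm),
                "feasible": bool(r.feasible),
            }
            for r in result.sub_measurements.itertuples()
        ],
        "diagnostics": {
            k: v for k, v in result.diagnostics.items() if k != "candidates_used"
        },
    }
    json_path = out_dir / "measurement.json"
    json_path.write_text(json.dumps(doc, indent=1))

    subs = result.sub_measurements
    rows = []
    for wall, g in subs.groupby("wall", sort=False):
        ok = g[g["feasible"]]
        rows.append(
            {
                "wall": wall,
                "feasibility_pct": 100.0 * len(ok) / len(g) if len(g) else 0.0,
                "mapse_mm": float(ok["value_mm"].mean()) if len(ok) else np.nan,
                "n_cycles_feasible": len(ok),
            }
        )
    csv_path = out_dir / "walls.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return json_path, csv_path
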