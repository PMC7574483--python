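"""Readers and writers for the package's tabular dialects.

There is no standard interchange format for perimetry exports, so the
package defines one:

* monocular field CSV — columns ``eye, pattern, x_deg, y_deg, tv_db, td_db``,
  one row per tested location, one eye per file (a JSON mirror of the same
  schema is also supported);
* telemetry CSV — columns ``t_s, speed_mps, steer_deg, lat_acc, long_acc``;
* binocular output — a per-location CSV plus a JSON summary
  ``{ou_vfi, n_locations, pattern}``.

Numeric output is printed at 6 significant digits, so writer/reader pairs
round-trip losslessly at that precision and reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binocular import BinocularField, IntegrationError, MonocularField
from .driving import TelemetryError, TelemetryTrace
from .geometry import Eye, Pattern, build_pattern

__all__ = [
    "SchemaError",
    "FLOAT_FORMAT",
    "read_monocular_field",
    "write_monocular_field",
    "read_telemetry",
    "write_telemetry",
    "write_binocular_field",
]

FLOAT_FORMAT = "%.6g"

_FIELD_COLUMNS = ["eye", "pattern", "x_deg", "y_deg", "tv_db", "td_db"]
_TELEMETRY_COLUMNS = ["t_s", "speed_mps", "steer_deg", "lat_acc", "long_acc"]


class SchemaError(ValueError):
    """Raised when a file does not match its documented schema."""


def _field_from_frame(frame: pd.DataFrame, source: str) -> MonocularField:
    missing = [c for c in _FIELD_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{source}: missing required columns {missing}")
    eyes = frame["eye"].unique()
    if len(eyes) != 1:
        raise SchemaError(f"{source}: expected exactly one eye per file, found {list(eyes)}")
    patterns = frame["pattern"].unique()
    if len(patterns) != 1:
        raise SchemaError(f"{source}: expected exactly one pattern per file, found {list(patterns)}")
    try:
        eye = Eye.coerce(str(eyes[0]))
        pattern = Pattern.coerce(str(patterns[0]))
    except ValueError as exc:
        raise SchemaError(f"{source}: {exc}") from None

    dup = frame.duplicated(["x_deg", "y_deg"])
    if dup.any():
        bad = [int(i) + 2 for i in frame.index[dup]]  # +2: header + 1-based
        raise SchemaError(f"{source}: duplicated (x, y) locations at rows {bad}")

    grid = build_pattern(pattern, eye)
    lookup = {}
    for i, row in frame.iterrows():
        try:
            key = (float(row["x_deg"]), float(row["y_deg"]))
            lookup[key] = (float(row["tv_db"]), float(row["td_db"]))
        except (TypeError, ValueError):
            raise SchemaError(f"{source}: non-numeric value at row {int(i) + 2}") from None
    grid_keys = {(p.x, p.y) for p in grid.points}
    extra = set(lookup) - grid_keys
    if extra:
        raise SchemaError(f"{source}: locations not on the {pattern.value} {eye.value} grid: {sorted(extra)[:5]}")

    tv = np.full(grid.n_locations, np.nan)
    td = np.full(grid.n_locations, np.nan)
    for i, p in enumerate(grid.points):
        if (p.x, p.y) in lookup:
            tv[i], td[i] = lookup[(p.x, p.y)]
        elif not p.is_blind_spot:
            raise SchemaError(f"{source}: missing location ({p.x:g}, {p.y:g})")
    try:
        return MonocularField(eye=eye, grid=grid, tv=tv, td=td)
    except IntegrationError as exc:
        raise SchemaError(f"{source}: {exc}") from None


def read_monocular_field(path: str | Path) -> MonocularField:
    """Read one eye's field from the documented CSV or JSON dialect."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        if not isinstance(payload, dict) or "locations" not in payload:
            raise SchemaError(f"{path}: JSON field files need a 'locations' list")
        frame = pd.DataFrame(payload["locations"])
        for key in ("eye", "pattern"):
            if key in payload and key not in frame.columns:
                frame[key] = payload[key]
    else:
        frame = pd.read_csv(path)
    return _field_from_frame(frame, str(path))


def write_monocular_field(field: MonocularField, path: str | Path) -> Path:
    """Write a field to CSV or JSON (by extension); drops blind-spot NaNs."""
    path = Path(path)
    frame = field.to_frame()
    keep = np.isfinite(frame["tv_db"].to_numpy()) & np.isfinite(frame["td_db"].to_numpy())
    frame = frame.loc[keep]
    if path.suffix.lower() == ".json":
        payload = {
            "eye": field.eye.value,
            "pattern": field.grid.pattern.value,
            "locations": json.loads(
                frame[["x_deg", "y_deg", "tv_db", "td_db"]].to_json(orient="records", double_precision=10)
            ),
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_telemetry(path: str | Path, sample_rate: float = 60.0) -> TelemetryTrace:
    """Read a telemetry trace from the documented CSV dialect."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in _TELEMETRY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    t = frame["t_s"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        sample_rate = 1.0 / float(np.median(dt))
    try:
        return TelemetryTrace(
            t=t,
            speed=frame["speed_mps"].to_numpy(dtype=float),
            steering_angle=frame["steer_deg"].to_numpy(dtype=float),
            lat_accel=frame["lat_acc"].to_numpy(dtype=float),
            long_accel=frame["long_acc"].to_numpy(dtype=float),
            sample_rate=sample_rate,
        )
    except TelemetryError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def write_telemetry(trace: TelemetryTrace, path: str | Path) -> Path:
    path = Path(path)
    trace.to_frame().to_csv(path, index=False, float_format="%.8g")
    return path


def write_binocular_field(field: BinocularField, csv_path: str | Path, json_path: str | Path | None = None) -> Path:
    """Write the per-location binocular table and its JSON summary."""
    csv_path = Path(csv_path)
    field.to_frame().to_csv(csv_path, index=False, float_format=FLOAT_FORMAT)
    if json_path is not None:
        summary = field.summary()
        summary["ou_vfi"] = round(summary["ou_vfi"], 6)
        Path(json_path).write_text(json.dumps(summary, indent=1) + "\n")
    return csv_path
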