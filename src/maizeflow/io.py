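"""File formats: geometry (WKT/GeoJSON/JSON), sample sheets (CSV),
simulator configs (YAML), reports (JSON) and the bundled survey table.

All numeric I/O is locale-independent (dot decimal) and %GM values stay
on the 0-100 percent scale end to end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .geometry import FieldGeometry
from .sampling import SamplePoint, SampleSet
from .simulator import SimulationConfig

__all__ = [
    "load_geometry",
    "load_samples",
    "save_samples",
    "write_report",
    "load_sim_config",
    "load_table1",
]

SAMPLE_COLUMNS = ["id", "role", "x", "y", "d", "n_cobs"]


class SchemaError(ValueError):
    """A file did not match its documented schema."""


def load_geometry(path: str | Path) -> FieldGeometry:
    """Read a field geometry from .wkt, .geojson or a plain JSON summary.

    JSON summaries carry ``{"area_m2": ..., "perimeter_m": ...}`` (no
    outline); .wkt and .geojson files carry a single planar Polygon in
    metre coordinates.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise SchemaError(f"{path}: empty geometry file")
    suffix = path.suffix.lower()
    if suffix == ".wkt":
        return FieldGeometry.from_wkt(text)
    if suffix == ".geojson":
        return FieldGeometry.from_geojson(text)
    if suffix == ".json":
        obj = json.loads(text)
        if "area_m2" in obj and "perimeter_m" in obj:
            return FieldGeometry(
                area_m2=float(obj["area_m2"]), perimeter_m=float(obj["perimeter_m"])
            )
        return FieldGeometry.from_geojson(obj)
    raise SchemaError(f"{path}: unsupported geometry format {suffix!r}")


def load_samples(path: str | Path, geometry: FieldGeometry) -> SampleSet:
    """Read a sample sheet CSV into a :class:`SampleSet`.

    Required columns: id, role, x, y, d, n_cobs; optional: value_pct,
    perimeter_position, transect, arm, design.  Schema violations are
    reported with the offending column or row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty sample sheet") from exc
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    points = []
    for row_idx, row in df.iterrows():
        try:
            points.append(
                SamplePoint(
                    id=str(row["id"]),
                    role=str(row["role"]),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    depth_d=float(row["d"]),
                    n_cobs=int(row["n_cobs"]),
                    perimeter_position=_opt_float(row, "perimeter_position"),
                    transect=_opt_int(row, "transect"),
                    arm=_opt_int(row, "arm"),
                    value_pct=_opt_float(row, "value_pct"),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: row {row_idx}: {exc}") from exc
    design = str(df["design"].iloc[0]) if "design" in df.columns else "simplified"
    return SampleSet(design=design, points=points, geometry=geometry)


def _opt_float(row, col) -> float | None:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def _opt_int(row, col) -> int | None:
    if col not in row or pd.isna(row[col]):
        return None
    return int(row[col])


def save_samples(ss: SampleSet, path: str | Path) -> None:
    """Write a sample sheet CSV (round-trips through :func:`load_samples`)."""
    rows = []
    for p in ss.points:
        rows.append(
            {
                "id": p.id,
                "role": p.role,
                "x": p.x,
                "y": p.y,
                "d": p.depth_d,
                "n_cobs": p.n_cobs,
                "perimeter_position": p.perimeter_position,
                "transect": p.transect,
                "arm": p.arm,
                "value_pct": p.value_pct,
                "design": ss.design,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report(obj, path: str | Path, *, config: dict | None = None) -> None:
    """Write a JSON report stamped with package version and config hash."""
    if hasattr(obj, "to_dict"):
        payload = obj.to_dict()
    elif is_dataclass(obj) and not isinstance(obj, type):
        payload = asdict(obj)
    else:
        payload = obj
    envelope = {
        "maizeflow_version": __version__,
        "config": config or {},
        "config_sha256": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True).encode()
        ).hexdigest(),
        "report": payload,
    }
    Path(path).write_text(json.dumps(envelope, indent=2, default=float) + "\n")


def load_sim_config(path: str | Path, geometry: FieldGeometry) -> SimulationConfig:
    """Read simulator parameters from YAML; keys mirror SimulationConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a YAML mapping")
    return SimulationConfig(geometry=geometry, **raw)


def load_table1() -> pd.DataFrame:
    """The bundled 19-field survey compilation.

    Columns: season, field_id, area_m2, I_m, d_m (periphery sampling
    depth), K_d_pct and K_c_pct (pooled periphery and centre qPCR means;
    sub-LOD entries are stored as 0 with the matching *_below_lod flag),
    the printed simplified and standard %GM estimates, and a note
    marking rows whose printed estimates cannot be recomputed from the
    tabulated K_d/K_c columns (the published numbers for those rows came
    from the pooled-sample qPCR reading rather than the column values).
    """
    with resources.files("maizeflow.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    df["note"] = df["note"].fillna("")
    return df
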