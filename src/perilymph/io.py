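"""Readers/writers for the package's file formats.

TIFF stacks with a JSON spacing sidecar (``{"spacing_um": [x, y, z]}``,
note x-first on disk vs array-axis order in memory), CSV tables for cells,
tracks, rhythm series, bioluminescence and profiles, and YAML run configs.
Units are µm at the boundary; core modules never see raw pixels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ValidationError
from .gradient import DistanceProfile
from .localization import CellRecord
from .rhythm import LumiSeries, RhythmSeries
from .tracks import Track

__all__ = [
    "read_stack",
    "write_stack",
    "read_table",
    "read_cells",
    "read_tracks",
    "read_series",
    "read_lumi",
    "read_polygons",
    "read_profiles",
    "write_profiles",
    "write_zone_map",
    "RunConfig",
    "RunRecord",
]

# required / numeric columns per table kind
TABLE_SCHEMAS: dict[str, dict[str, list[str]]] = {
    "cells": {
        "required": ["cell_id", "x_um", "y_um"],
        "numeric": ["x_um", "y_um", "z_um"],
    },
    "tracks": {
        "required": ["track_id", "frame", "t_s", "x_um", "y_um"],
        "numeric": ["frame", "t_s", "x_um", "y_um"],
    },
    "series": {"required": ["time_h", "value"], "numeric": ["time_h", "value"]},
    "lumi": {"required": ["t_min", "counts"], "numeric": ["t_min", "counts"]},
    "polygons": {
        "required": ["polygon_id", "vertex_index", "x_um", "y_um"],
        "numeric": ["vertex_index", "x_um", "y_um"],
    },
    "profiles": {
        "required": ["sample_id", "bin_center_um", "mean_intensity", "n_voxels"],
        "numeric": ["bin_center_um", "mean_intensity", "n_voxels"],
    },
}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _spacing_from_disk(spacing_um: Sequence[float], ndim: int) -> tuple[float, ...]:
    # sidecar order is (x, y[, z]); arrays are (y, x) / (z, y, x)
    sp = tuple(float(s) for s in spacing_um)
    if len(sp) < ndim:
        raise ValidationError(f"sidecar spacing {sp} shorter than stack ndim {ndim}")
    return tuple(reversed(sp[:ndim]))


def read_stack(
    path: str | Path,
    spacing: Sequence[float] | None = None,
    sidecar: str | Path | None = None,
) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a TIFF stack as a (z, y, x) float grid plus per-axis µm spacing.

    2D images become single-plane 3D grids. Spacing comes from ``spacing``
    (array-axis order) or a sidecar JSON ``{"spacing_um": [x, y, z]}``;
    with neither available an explicit error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            if arr.ndim == 2 and len(tif.pages) > 1:
                # pages written one by one land in separate series
                arr = np.stack([page.asarray() for page in tif.pages])
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface as a validation failure
        raise ValidationError(f"{path} is not a readable TIFF: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValidationError(f"{path}: expected a 2D or 3D stack, got {arr.ndim}D")
    if spacing is not None:
        sp = tuple(float(s) for s in spacing)
        if len(sp) == 2:
            sp = (1.0,) + sp
        if len(sp) != 3:
            raise ValidationError("spacing must have 2 or 3 entries")
    else:
        sc = Path(sidecar) if sidecar is not None else _sidecar_path(path)
        if not sc.exists():
            raise ValidationError(
                f"no spacing for {path}: pass spacing= or provide sidecar {sc}"
            )
        meta = json.loads(sc.read_text())
        disk = meta["spacing_um"]
        if len(disk) == 2:
            disk = list(disk) + [1.0]
        sp = _spacing_from_disk(disk, 3)
    return arr.astype(float), sp


def write_stack(
    path: str | Path, array: np.ndarray, spacing: Sequence[float]
) -> None:
    """Write a grid as TIFF plus a spacing sidecar JSON (x-first on disk)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array), photometric="minisblack")
    disk = list(reversed([float(s) for s in spacing]))
    _sidecar_path(path).write_text(json.dumps({"spacing_um": disk}))


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read + validate a CSV against a named schema.

    Missing required columns are reported by name; non-numeric entries in
    numeric columns are reported with their (1-based data) row number.
    Unknown columns are preserved.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValidationError(f"unknown table schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path)
    spec = TABLE_SCHEMAS[schema]
    for col in spec["required"]:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    for col in spec["numeric"]:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValidationError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}, row {row}"
            )
        df[col] = coerced
    return df


def read_cells(path: str | Path) -> list[CellRecord]:
    df = read_table(path, "cells")
    cells = []
    for _, r in df.iterrows():
        z = r["z_um"] if "z_um" in df.columns and pd.notna(r.get("z_um")) else None
        cells.append(
            CellRecord(
                id=str(r["cell_id"]),
                x=float(r["x_um"]),
                y=float(r["y_um"]),
                z=None if z is None else float(z),
                label=str(r["label"]) if "label" in df.columns else "",
            )
        )
    return cells


def write_cells(path: str | Path, cells: Sequence[CellRecord]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "cell_id": [c.id for c in cells],
            "x_um": [c.x for c in cells],
            "y_um": [c.y for c in cells],
            "z_um": [c.z for c in cells],
            "label": [c.label for c in cells],
        }
    ).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[Track]:
    df = read_table(path, "tracks")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t_s")
        tracks.append(
            Track(
                track_id=str(tid),
                t=g["t_s"].to_numpy(float),
                x=g["x_um"].to_numpy(float),
                y=g["y_um"].to_numpy(float),
                frames=g["frame"].to_numpy(int),
                group=str(g["group"].iloc[0]) if "group" in df.columns else "",
            )
        )
    return tracks


def write_tracks(path: str | Path, tracks: Sequence[Track]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in tracks:
        frames = tr.frames if tr.frames is not None else np.arange(1, tr.n_samples + 1)
        for f, t, x, y in zip(frames, tr.t, tr.x, tr.y):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": int(f),
                    "t_s": t,
                    "x_um": x,
                    "y_um": y,
                    "group": tr.group,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_series(path: str | Path) -> RhythmSeries:
    df = read_table(path, "series")
    reps = (
        df["replicate_id"].to_numpy()
        if "replicate_id" in df.columns
        else None
    )
    gid = str(df["group_id"].iloc[0]) if "group_id" in df.columns else ""
    return RhythmSeries(
        times=df["time_h"].to_numpy(float),
        values=df["value"].to_numpy(float),
        replicate_ids=reps,
        group_id=gid,
    )


def write_series(path: str | Path, series: RhythmSeries) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_h": series.times, "value": series.values})
    if series.replicate_ids is not None:
        df["replicate_id"] = series.replicate_ids
    if series.group_id:
        df["group_id"] = series.group_id
    df.to_csv(path, index=False)


def read_lumi(path: str | Path) -> LumiSeries:
    df = read_table(path, "lumi")
    return LumiSeries(
        t_min=df["t_min"].to_numpy(float), counts=df["counts"].to_numpy(float)
    )


def write_lumi(path: str | Path, series: LumiSeries) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t_min": series.t_min, "counts": series.counts}).to_csv(
        path, index=False
    )


def read_polygons(path: str | Path) -> list[np.ndarray]:
    """Closed polygons as (N, 2) arrays of (x_um, y_um), ordered by vertex."""
    df = read_table(path, "polygons")
    polys = []
    for _, g in df.groupby("polygon_id", sort=True):
        g = g.sort_values("vertex_index")
        polys.append(g[["x_um", "y_um"]].to_numpy(float))
    return polys


def read_profiles(path: str | Path) -> list[DistanceProfile]:
    df = read_table(path, "profiles")
    out = []
    for sid, g in df.groupby("sample_id", sort=True):
        g = g.sort_values("bin_center_um")
        tl = (
            float(g["time_label"].iloc[0])
            if "time_label" in df.columns and pd.notna(g["time_label"].iloc[0])
            else None
        )
        out.append(
            DistanceProfile(
                bin_centers=g["bin_center_um"].to_numpy(float),
                mean_intensity=g["mean_intensity"].to_numpy(float),
                n_voxels=g["n_voxels"].to_numpy(int),
                source=str(sid),
                time_label=tl,
            )
        )
    return out


def write_profiles(path: str | Path, profiles: Sequence[DistanceProfile]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in profiles:
        for c, m, n in zip(p.bin_centers, p.mean_intensity, p.n_voxels):
            rows.append(
                {
                    "sample_id": p.source or "sample",
                    "time_label": p.time_label,
                    "bin_center_um": c,
                    "mean_intensity": m,
                    "n_voxels": int(n),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_zone_map(path: str | Path, labels: np.ndarray, edges: Sequence[float]) -> None:
    """Integer-label TIFF plus a JSON edge list next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))
    path.with_suffix(".edges.json").write_text(
        json.dumps({"edges_um": [float(e) for e in edges]})
    )


@dataclass
class RunConfig:
    """Parameters of a reproducible pipeline run."""

    out_dir: str = "run_out"
    seed: int = 0
    spacing: tuple[float, ...] = (1.0, 0.5, 0.5)
    shape: tuple[int, ...] = (8, 96, 96)
    vessel_radius: float = 10.0
    decay_length: float = 20.0
    baseline: float = 10.0
    noise_sigma: float = 5.0
    mesor: float = 100.0
    amplitude: float = 40.0
    acrophase: float = 7.0
    times: tuple[float, ...] = (1.0, 7.0, 13.0, 19.0)
    n_replicates: int = 3
    zone_edges: tuple[float, ...] = (0.0, 10.0, 20.0, 40.0, 80.0)
    max_distance: float = 100.0
    cosinor_period: float = 24.0
    detrend_window_h: float = 24.0

    def __post_init__(self) -> None:
        for name in (
            "vessel_radius",
            "decay_length",
            "noise_sigma",
            "max_distance",
            "cosinor_period",
            "detrend_window_h",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be strictly positive")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.shape = tuple(int(s) for s in self.shape)
        self.times = tuple(float(t) for t in self.times)
        self.zone_edges = tuple(float(e) for e in self.zone_edges)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class RunRecord:
    """Provenance of one pipeline run: config, version, seeds, warnings."""

    config: dict
    version: str
    seeds: dict[str, int] = field(default_factory=dict)
    warnings: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
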