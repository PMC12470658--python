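"""File formats: TIFF cubes, CSV boundary tables, map grids and cohorts.

Interchange formats are deliberately plain: multi-frame TIFF for intensity
cubes (frame order = slow axis, float32), long-format CSV for boundary
surfaces (one row per A-scan), a bare CSV grid for thickness maps (NaN =
invalid), and a flat one-row-per-eye CSV for cohorts.  Schemas are strict:
a missing column raises :class:`~ezmap.exceptions.SchemaError` naming the
field; unknown extra columns are preserved and passed through on write.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .boundaries import BOUNDARY_NAMES, BoundarySet
from .cohort import (
    CATEGORICAL_COVARIATES,
    CONTINUOUS_COVARIATES,
    LABEL_FIELDS,
    CohortRecord,
)
from .exceptions import GeometryError, SchemaError
from .geometry import CubeGeometry
from .mapping import EZRPEMap, OuterRetinalMetrics

# -- intensity cubes ---------------------------------------------------------


def write_cube(path, cube: np.ndarray) -> None:
    """Write an intensity cube as a multi-frame float32 TIFF (frames = B-scans)."""
    cube = np.asarray(cube, dtype=np.float32)
    if cube.ndim != 3:
        raise GeometryError("cube must be 3-D (n_slow, n_axial, n_fast)")
    tifffile.imwrite(str(path), cube, photometric="minisblack")


def read_cube(path, geometry: CubeGeometry | None = None) -> np.ndarray:
    """Read a multi-frame TIFF cube, optionally checking it against a geometry."""
    cube = tifffile.imread(str(path))
    if cube.ndim == 2:
        cube = cube[np.newaxis]
    if geometry is not None:
        if cube.shape[0] != geometry.n_slow or cube.shape[2] != geometry.n_fast:
            raise GeometryError(
                f"cube shape {cube.shape} does not match geometry "
                f"(n_slow={geometry.n_slow}, n_fast={geometry.n_fast})"
            )
    return cube


# -- boundary surfaces -------------------------------------------------------

BOUNDARY_COLUMNS = ("slow_index", "fast_index", "ilm_um", "opl_um",
                    "ez_um", "rpe_um", "valid")


def write_boundaries(path, boundaries: BoundarySet) -> None:
    """Write a BoundarySet as long-format CSV, one row per A-scan."""
    n_slow, n_fast = boundaries.shape
    slow, fast = np.meshgrid(np.arange(n_slow), np.arange(n_fast), indexing="ij")
    frame = pd.DataFrame({
        "slow_index": slow.ravel(),
        "fast_index": fast.ravel(),
        "ilm_um": boundaries.ilm_um.ravel(),
        "opl_um": boundaries.opl_um.ravel(),
        "ez_um": boundaries.ez_um.ravel(),
        "rpe_um": boundaries.rpe_um.ravel(),
        "valid": boundaries.valid.ravel().astype(int),
    })
    if boundaries.extras is not None:
        for col in boundaries.extras.columns:
            frame[col] = boundaries.extras[col].to_numpy()
    frame.to_csv(path, index=False)


def read_boundaries(path) -> BoundarySet:
    """Read a long-format boundary CSV back into a BoundarySet.

    Extra columns are kept on ``BoundarySet.extras`` and round-trip.
    """
    frame = pd.read_csv(path)
    for col in BOUNDARY_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"boundary file missing required column {col!r}")
    n_slow = int(frame["slow_index"].max()) + 1
    n_fast = int(frame["fast_index"].max()) + 1
    if len(frame) != n_slow * n_fast:
        raise SchemaError("boundary file does not cover a complete grid")
    frame = frame.sort_values(["slow_index", "fast_index"], kind="stable")
    shape = (n_slow, n_fast)
    grids = {name: frame[f"{name}_um"].to_numpy().reshape(shape)
             for name in BOUNDARY_NAMES}
    valid = frame["valid"].to_numpy().astype(bool).reshape(shape)
    extra_cols = [c for c in frame.columns if c not in BOUNDARY_COLUMNS]
    extras = frame[extra_cols].reset_index(drop=True) if extra_cols else None
    return BoundarySet(grids["ilm"], grids["opl"], grids["ez"], grids["rpe"],
                       valid, extras=extras)


# -- thickness maps ----------------------------------------------------------


def write_map(path, ezmap: EZRPEMap) -> None:
    """Write a thickness map as a bare CSV grid; invalid points become NaN."""
    grid = np.where(ezmap.valid, ezmap.thickness_um, np.nan)
    np.savetxt(path, grid, delimiter=",", fmt="%.6g")


def read_map(path, geometry: CubeGeometry) -> EZRPEMap:
    """Read a CSV thickness grid; NaN cells are marked invalid."""
    grid = np.loadtxt(path, delimiter=",", ndmin=2)
    if grid.shape != geometry.shape:
        raise GeometryError(
            f"map grid {grid.shape} does not match geometry {geometry.shape}"
        )
    valid = np.isfinite(grid)
    return EZRPEMap(np.nan_to_num(grid, nan=0.0), valid, geometry)


# -- metrics -----------------------------------------------------------------


def write_metrics(path, metrics: OuterRetinalMetrics) -> None:
    """Write one metric vector as JSON (.json) or a one-row CSV (anything else)."""
    path = Path(path)
    data = metrics.as_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        pd.DataFrame([data]).to_csv(path, index=False)


def read_metrics(path) -> OuterRetinalMetrics:
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
    else:
        data = pd.read_csv(path).iloc[0].to_dict()
    missing = set(OuterRetinalMetrics.field_names()) - set(data)
    if missing:
        raise SchemaError(f"metrics file missing fields {sorted(missing)}")
    return OuterRetinalMetrics(
        **{k: float(data[k]) for k in OuterRetinalMetrics.field_names()})


# -- cohorts -----------------------------------------------------------------

_METRIC_FIELDS = OuterRetinalMetrics.field_names()
COHORT_COLUMNS = (
    ["eye_id", "laterality"]
    + list(CONTINUOUS_COVARIATES) + list(CATEGORICAL_COVARIATES)
    + [f"oct1_{m}" for m in _METRIC_FIELDS]
    + [f"oct2_{m}" for m in _METRIC_FIELDS]
    + list(LABEL_FIELDS)
)


def frame_from_records(records: list[CohortRecord]) -> pd.DataFrame:
    """Flatten cohort records to the one-row-per-eye table schema."""
    rows = []
    for r in records:
        row: dict = {"eye_id": r.eye_id, "laterality": r.laterality}
        for name in CONTINUOUS_COVARIATES:
            row[name] = getattr(r, name)
        for name in CATEGORICAL_COVARIATES:
            row[name] = getattr(r, name)
        for prefix, metrics in (("oct1", r.metrics_oct1), ("oct2", r.metrics_oct2)):
            for m, v in metrics.as_dict().items():
                row[f"{prefix}_{m}"] = v
        for name in LABEL_FIELDS:
            row[name] = bool(getattr(r, name))
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def records_from_frame(frame: pd.DataFrame) -> list[CohortRecord]:
    """Parse a cohort table back into records; extra columns are ignored."""
    for col in COHORT_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"cohort table missing required column {col!r}")
    records = []
    for _, row in frame.iterrows():
        kwargs: dict = {"eye_id": str(row["eye_id"]),
                        "laterality": str(row["laterality"])}
        for name in CONTINUOUS_COVARIATES:
            kwargs[name] = float(row[name])
        for name in CATEGORICAL_COVARIATES:
            v = row[name]
            kwargs[name] = bool(v) if isinstance(v, (bool, np.bool_)) else str(v)
        for name in LABEL_FIELDS:
            kwargs[name] = _parse_bool(row[name])
        for prefix, key in (("oct1", "metrics_oct1"), ("oct2", "metrics_oct2")):
            kwargs[key] = OuterRetinalMetrics(
                **{m: float(row[f"{prefix}_{m}"]) for m in _METRIC_FIELDS})
        records.append(CohortRecord(**kwargs))
    return records


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "t", "yes")
    return bool(v)


def write_cohort(path, records: list[CohortRecord]) -> None:
    frame_from_records(records).to_csv(path, index=False)


def read_cohort(path) -> list[CohortRecord]:
    frame = pd.read_csv(path)
    # tamoxifen / kidney_disease columns arrive as strings from CSV
    for col in ("tamoxifen", "kidney_disease"):
        if col in frame.columns:
            frame[col] = frame[col].map(_parse_bool)
    return records_from_frame(frame)
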