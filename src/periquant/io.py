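"""Readers and writers for the package's plain-text and TIFF formats.

Cell tables are CSV with one row per cell:

    embryo_id, cell_id, tissue, x_um, y_um, z_um
    [, intensity_<channel>...] [, lineage_id] [, timepoint_min]
    [, origin_x_um, origin_y_um, origin_z_um, axis_x, axis_y, axis_z]
    [, stage_label]

The reference frame (distal-tip origin, unit proximal-distal axis) may be
given as the per-row columns above (constant within an embryo) or in a JSON
sidecar mapping embryo_id -> {"origin": [...], "axis": [...]}. Label volumes
are multi-page integer TIFF stacks, page order = z.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ParseError, SchemaError, ValidationError
from .model import CellRecord, Cohort, CohortRecord, EmbryoFrame, LabelVolume, Tissue

log = logging.getLogger(__name__)

_MANDATORY = ["embryo_id", "cell_id", "tissue", "x_um", "y_um", "z_um"]
_FRAME_COLS = ["origin_x_um", "origin_y_um", "origin_z_um", "axis_x", "axis_y", "axis_z"]


def read_cell_table(path, frames_path: Optional[str] = None) -> list[EmbryoFrame]:
    """Read a CSV cell table into one :class:`EmbryoFrame` per embryo_id.

    Coordinates are preserved exactly as written. Unknown tissue strings are
    rejected. Returns frames in order of first appearance of each embryo.
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"embryo_id": str, "cell_id": str}, float_precision="round_trip"
    )
    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    if df.empty:
        log.warning("%s: cell table has a header but no rows", path)
        return []

    for col in ("x_um", "y_um", "z_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric coordinate in column {col!r} at data row "
                f"{row} (value {df[col].iloc[row]!r})"
            )
        df[col] = coerced

    sidecar = {}
    if frames_path is not None:
        with open(frames_path) as fh:
            sidecar = json.load(fh)

    intensity_cols = [c for c in df.columns if c.startswith("intensity_")]
    frames: list[EmbryoFrame] = []
    for embryo_id, sub in df.groupby("embryo_id", sort=False):
        cells = []
        for _, row in sub.iterrows():
            intensities = None
            if intensity_cols:
                intensities = {
                    c[len("intensity_"):]: float(row[c])
                    for c in intensity_cols
                    if pd.notna(row[c])
                }
            cells.append(
                CellRecord(
                    cell_id=str(row["cell_id"]),
                    tissue=Tissue.parse(row["tissue"]),
                    position=np.array([row["x_um"], row["y_um"], row["z_um"]]),
                    intensities=intensities,
                    lineage_id=(
                        str(row["lineage_id"])
                        if "lineage_id" in sub.columns and pd.notna(row["lineage_id"])
                        else None
                    ),
                    timepoint_min=(
                        float(row["timepoint_min"])
                        if "timepoint_min" in sub.columns
                        and pd.notna(row["timepoint_min"])
                        else None
                    ),
                )
            )
        if str(embryo_id) in sidecar:
            meta = sidecar[str(embryo_id)]
            origin = np.asarray(meta["origin"], dtype=float)
            axis = np.asarray(meta["axis"], dtype=float)
            stage = meta.get("stage_label", "")
        elif all(c in sub.columns for c in _FRAME_COLS):
            first = sub.iloc[0]
            origin = np.array([first[c] for c in _FRAME_COLS[:3]], dtype=float)
            axis = np.array([first[c] for c in _FRAME_COLS[3:]], dtype=float)
            stage = str(first["stage_label"]) if "stage_label" in sub.columns else ""
        else:
            origin = np.zeros(3)
            axis = np.array([0.0, 0.0, 1.0])
            stage = ""
        if np.linalg.norm(axis) < 1e-12:
            raise ValidationError(f"{path}: embryo {embryo_id!r} has a zero-norm axis")
        frames.append(
            EmbryoFrame(
                embryo_id=str(embryo_id),
                cells=cells,
                origin=origin,
                axis=axis,
                stage_label=stage,
            )
        )
    return frames


def write_cell_table(frames: Sequence[EmbryoFrame], path) -> None:
    """Write frames to CSV in the schema read by :func:`read_cell_table`."""
    rows = []
    channels: list[str] = []
    for fr in frames:
        for c in fr.cells:
            if c.intensities:
                for ch in c.intensities:
                    if ch not in channels:
                        channels.append(ch)
    for fr in frames:
        for c in fr.cells:
            row = {
                "embryo_id": fr.embryo_id,
                "cell_id": c.cell_id,
                "tissue": c.tissue.value,
                "x_um": c.position[0],
                "y_um": c.position[1],
                "z_um": c.position[2],
            }
            for ch in channels:
                row[f"intensity_{ch}"] = (
                    c.intensities.get(ch, np.nan) if c.intensities else np.nan
                )
            row["lineage_id"] = c.lineage_id
            row["timepoint_min"] = c.timepoint_min
            for col, val in zip(_FRAME_COLS, np.concatenate([fr.origin, fr.axis])):
                row[col] = val
            row["stage_label"] = fr.stage_label
            rows.append(row)
    # %.17g guarantees exact binary64 round-trip through text
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_label_volume(path, voxel_size) -> LabelVolume:
    """Read a multi-page integer TIFF stack as a :class:`LabelVolume`.

    ``voxel_size`` is (z, y, x) µm per voxel; anisotropic sizes are
    propagated to all downstream volume computations.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if np.issubdtype(arr.dtype, np.floating):
        raise ValidationError(
            f"{path}: voxel data are floating point ({arr.dtype}); label "
            "volumes must be integer — convert (e.g. arr.astype(np.uint16)) "
            "before writing"
        )
    vol = LabelVolume(labels=arr, voxel_size=np.asarray(voxel_size, dtype=float))
    log.info("%s: %d labels %s", path, vol.label_set().size, vol.labels.shape)
    return vol


def write_label_volume(vol: LabelVolume, path) -> None:
    tifffile.imwrite(str(path), vol.labels)


def read_cohort(path) -> Cohort:
    """Read a cohort CSV with columns embryo_id, initial_cell_count,
    formed_egg_cylinder, [ave_asymmetric]. Booleans accept 0/1/true/false;
    an empty ave_asymmetric cell means "not evaluated"."""
    df = pd.read_csv(path)
    for col in ("embryo_id", "initial_cell_count", "formed_egg_cylinder"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")

    def _bool(x):
        if pd.isna(x):
            return None
        if isinstance(x, str):
            return x.strip().lower() in ("1", "true", "yes")
        return bool(x)

    records = []
    for _, row in df.iterrows():
        records.append(
            CohortRecord(
                embryo_id=str(row["embryo_id"]),
                initial_cell_count=int(row["initial_cell_count"]),
                formed_egg_cylinder=bool(_bool(row["formed_egg_cylinder"])),
                ave_asymmetric=(
                    _bool(row["ave_asymmetric"]) if "ave_asymmetric" in df.columns else None
                ),
            )
        )
    return Cohort(records=records)


def write_cohort(cohort: Cohort, path) -> None:
    pd.DataFrame(
        [
            {
                "embryo_id": r.embryo_id,
                "initial_cell_count": r.initial_cell_count,
                "formed_egg_cylinder": r.formed_egg_cylinder,
                "ave_asymmetric": r.ave_asymmetric,
            }
            for r in cohort.records
        ]
    ).to_csv(path, index=False)


def write_json(obj, path) -> None:
    """Write a JSON result file with stable key order and native types."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
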