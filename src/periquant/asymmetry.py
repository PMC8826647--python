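"""AVE asymmetry index: anterior-posterior axis specification scoring.

At ~E6.0 the anterior visceral endoderm (AVE) migrates from the distal tip
to one side of the egg cylinder, breaking rotational symmetry. Each VE cell
is reduced to polar coordinates about the proximal-distal axis: linear
distance from the distal tip r = |p| and rotation angle θ = atan2(y, x).
The AVE cells are mapped into the 2D polar-plot plane as
(r·cosθ, r·sinθ); the norm of their centroid r_cent, scaled by the largest
VE distance r_max of that embryo, is the asymmetry index:

    index = r_cent / r_max  ∈ [0, 1]

An embryo is classified axis-specified ("asymmetric") when the index is
strictly larger than the threshold (default 0.15, the value below which
qualitatively symmetric reference embryos fall).

The centroid is deliberately computed in the 2D plane, not in 3D: a
rotationally symmetric AVE ring of any height scores 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ValidationError
from .model import VE_TISSUES, EmbryoFrame, Tissue

#: Classification threshold on the asymmetry index (strict inequality).
DEFAULT_THRESHOLD = 0.15


@dataclass
class PolarCell:
    """One cell in embryo polar coordinates: distance r (µm) from the
    distal-tip origin and rotation angle theta ∈ (−π, π] about the
    proximal-distal axis. On-axis cells get theta = 0 by convention."""

    cell_id: str
    r: float
    theta: float
    is_ave: bool

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValidationError(f"r must be >= 0, got {self.r}")
        if not (-math.pi < self.theta <= math.pi):
            raise ValidationError(f"theta out of (-pi, pi]: {self.theta}")


class Classification(Enum):
    ASYMMETRIC = "asymmetric"
    SYMMETRIC = "symmetric"


@dataclass
class AsymmetryResult:
    index: float
    r_cent: float
    r_max: float
    centroid_xy: np.ndarray
    n_ve: int
    n_ave: int
    classification: Classification


def to_polar(frame: EmbryoFrame, tissue_filter=VE_TISSUES) -> list[PolarCell]:
    """Polar coordinates (r, θ) of the cells passing ``tissue_filter``.

    r is the full 3D distance from the distal-tip origin; θ is the rotation
    angle about the proximal-distal axis in the frame's deterministic basis.
    """
    if isinstance(tissue_filter, Tissue):
        tissue_filter = {tissue_filter}
    tissue_filter = frozenset(tissue_filter)
    selected = frame.select(tissue_filter)
    if not selected:
        raise ValidationError(
            f"embryo {frame.embryo_id!r}: no cells with tissue in "
            f"{sorted(t.value for t in tissue_filter)}"
        )
    out = []
    for cell in selected:
        x, y, z = frame.frame_coords(cell.position)
        r = float(math.hypot(x, y, z))
        theta = 0.0 if (x == 0.0 and y == 0.0) else float(math.atan2(y, x))
        if theta == -math.pi:
            theta = math.pi
        out.append(
            PolarCell(
                cell_id=cell.cell_id,
                r=r,
                theta=theta,
                is_ave=cell.tissue is Tissue.AVE,
            )
        )
    return out


def asymmetry_index(
    frame: EmbryoFrame, threshold: float = DEFAULT_THRESHOLD
) -> AsymmetryResult:
    """Compute the AVE asymmetry index of one embryo.

    Requires at least one AVE cell; the VE selection includes the AVE cells
    (AVE ⊆ VE). Raises :class:`DegenerateGeometryError` when every VE cell
    sits at the origin (r_max = 0).
    """
    polar = to_polar(frame, VE_TISSUES)
    ave = [p for p in polar if p.is_ave]
    if not ave:
        raise ValidationError(f"embryo {frame.embryo_id!r}: no AVE cells")
    r_max = max(p.r for p in polar)
    if r_max <= 0.0:
        raise DegenerateGeometryError(
            f"embryo {frame.embryo_id!r}: all VE cells at the origin (r_max = 0)"
        )
    pts = np.array([[p.r * math.cos(p.theta), p.r * math.sin(p.theta)] for p in ave])
    centroid = pts.mean(axis=0)
    r_cent = float(np.linalg.norm(centroid))
    index = r_cent / r_max
    cls = Classification.ASYMMETRIC if index > threshold else Classification.SYMMETRIC
    return AsymmetryResult(
        index=index,
        r_cent=r_cent,
        r_max=r_max,
        centroid_xy=centroid,
        n_ve=len(polar),
        n_ave=len(ave),
        classification=cls,
    )


def classify_cohort(
    frames: Sequence[EmbryoFrame], threshold: float = DEFAULT_THRESHOLD
) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-embryo asymmetry table and the asymmetric fraction.

    Embryos for which the index is undefined (no AVE cells, degenerate
    geometry) are recorded with missing values rather than aborting the
    cohort, and are excluded from the fraction's denominator. The fraction
    is None when no embryo could be evaluated.
    """
    rows = []
    for fr in frames:
        try:
            res = asymmetry_index(fr, threshold=threshold)
            rows.append(
                {
                    "embryo_id": fr.embryo_id,
                    "index": res.index,
                    "r_cent": res.r_cent,
                    "r_max": res.r_max,
                    "n_ve": res.n_ve,
                    "n_ave": res.n_ave,
                    "classification": res.classification.value,
                }
            )
        except ValidationError as exc:
            rows.append(
                {
                    "embryo_id": fr.embryo_id,
                    "index": np.nan,
                    "r_cent": np.nan,
                    "r_max": np.nan,
                    "n_ve": len(fr.select(VE_TISSUES)),
                    "n_ave": len(fr.select(Tissue.AVE)),
                    "classification": f"error: {exc}",
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "embryo_id", "index", "r_cent", "r_max", "n_ve", "n_ave",
            "classification",
        ],
    )
    evaluated = table["index"].notna()
    if not evaluated.any():
        return table, None
    n_asym = int((table.loc[evaluated, "classification"] == "asymmetric").sum())
    return table, n_asym / int(evaluated.sum())
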