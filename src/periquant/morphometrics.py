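"""Per-cell 3D shape and spatial statistics from labeled volumes.

Volume is voxel count × voxel volume. Shape comes from an ellipsoid fit:
the eigen-decomposition of the second-moment (covariance) matrix of the
cell's voxel centers, with semi-axes a_i = sqrt(5 λ_i) — the solid uniform
ellipsoid whose second moments match the voxel cloud. Aspect ratio is
LA / ((MA + SA)/2); long-axis radial alignment is the angle (folded into
[0°, 90°], the axis being unsigned) between the long axis and the segment
from the cell centroid to its voxel farthest from the embryo center, so a
low angle means the cell elongates along the inside-outside direction.

Voxel-derived coordinates are in µm, axis order (z, y, x); voxel centers
sit at (index + 0.5) · voxel_size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateGeometryError, LabelNotFoundError, ValidationError
from .model import LabelVolume


@dataclass
class CellShape:
    """Ellipsoid-fit summary of one labeled cell. Semi-axes are sorted
    LA >= MA >= SA (µm); ``la_direction`` is the unit long-axis direction in
    (z, y, x) µm coordinates; ``alignment_deg`` is filled by
    :func:`radial_alignment`."""

    cell_id: str
    volume_um3: float
    semi_axes: tuple[float, float, float]
    la_direction: np.ndarray
    aspect_ratio: float
    centroid: np.ndarray
    alignment_deg: Optional[float] = None


def _voxel_centers_um(vol: LabelVolume, label: int) -> np.ndarray:
    idx = np.argwhere(vol.labels == label)
    if idx.size == 0:
        raise LabelNotFoundError(f"label {label} not present in volume")
    return (idx + 0.5) * vol.voxel_size


def cell_volume(vol: LabelVolume, label: int) -> float:
    """Volume of one label in µm³ (voxel count × voxel volume)."""
    n = int(np.count_nonzero(vol.labels == label))
    if n == 0:
        raise LabelNotFoundError(f"label {label} not present in volume")
    return n * vol.voxel_volume_um3


def fit_ellipsoid(vol: LabelVolume, label: int) -> CellShape:
    """Fit an ellipsoid to a labeled cell via second moments.

    Raises :class:`DegenerateGeometryError` when the voxel set has fewer
    than 4 voxels or is coplanar (covariance rank < 3).
    """
    pts = _voxel_centers_um(vol, label)
    if pts.shape[0] < 4:
        raise DegenerateGeometryError(
            f"label {label}: needs >= 4 voxels for an ellipsoid fit, "
            f"got {pts.shape[0]}"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / pts.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    if eigvals[0] <= 1e-12 * max(eigvals[-1], 1.0):
        raise DegenerateGeometryError(
            f"label {label}: voxel set is degenerate (rank < 3)"
        )
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    semi = tuple(float(np.sqrt(5.0 * lam)) for lam in eigvals)
    la, ma, sa = semi
    return CellShape(
        cell_id=str(label),
        volume_um3=pts.shape[0] * vol.voxel_volume_um3,
        semi_axes=(la, ma, sa),
        la_direction=eigvecs[:, 0].copy(),
        aspect_ratio=la / ((ma + sa) / 2.0),
        centroid=centroid,
    )


def radial_alignment(
    shape: CellShape, vol: LabelVolume, label: int, embryo_center
) -> float:
    """Angle (degrees, in [0, 90]) between the cell's long axis and the
    segment from the cell centroid to the cell's outermost voxel.

    The outermost voxel is the voxel center farthest (Euclidean, µm) from
    ``embryo_center`` (given in (z, y, x) µm); ties break to the
    lexicographically smallest voxel index.
    """
    center = np.asarray(embryo_center, dtype=float)
    if not np.all(np.isfinite(center)):
        raise ValidationError(f"embryo_center must be finite, got {center}")
    pts = _voxel_centers_um(vol, label)
    d = np.linalg.norm(pts - center, axis=1)
    outer = pts[int(np.argmax(d))]  # argmax = first max in C order = lex smallest
    ref = outer - shape.centroid
    n = np.linalg.norm(ref)
    if n < 1e-12:
        raise DegenerateGeometryError(
            f"label {label}: outermost voxel coincides with the centroid"
        )
    cosang = abs(float(np.dot(ref / n, shape.la_direction)))
    ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    shape.alignment_deg = ang
    return ang


def cluster_dispersion(positions_per_timepoint: Sequence) -> list[float]:
    """Mean 3D distance of a tracked cell cluster from its centroid, one
    value per timepoint — an indicator of cell dispersion over time."""
    out = []
    for t, positions in enumerate(positions_per_timepoint):
        p = np.asarray(positions, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
            raise ValidationError(
                f"timepoint {t}: need >= 2 positions of dimension 3, got "
                f"shape {p.shape}"
            )
        out.append(float(np.linalg.norm(p - p.mean(axis=0), axis=1).mean()))
    return out


def neighbor_distance(cell_position, cluster_positions) -> float:
    """Euclidean distance from a cell to the centroid of a cell cluster."""
    cluster = np.asarray(cluster_positions, dtype=float)
    if cluster.size == 0:
        raise ValidationError("cluster is empty")
    cluster = cluster.reshape(-1, 3)
    p = np.asarray(cell_position, dtype=float).reshape(3)
    return float(np.linalg.norm(p - cluster.mean(axis=0)))


def apical_domain_distance(spots, embryo_center, epi_mean_radius: float) -> np.ndarray:
    """Relative distance of apical-domain spots from the embryo center,
    scaled by the mean EPI radius at that timepoint (1 = on the mean-radius
    surface). Used to follow lumen-precursor positioning."""
    if not epi_mean_radius > 0:
        raise ValidationError(f"epi_mean_radius must be > 0, got {epi_mean_radius}")
    spots = np.asarray(spots, dtype=float).reshape(-1, 3)
    center = np.asarray(embryo_center, dtype=float).reshape(3)
    return np.linalg.norm(spots - center, axis=1) / epi_mean_radius
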