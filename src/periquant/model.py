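"""Core domain types for peri-implantation embryo analysis.

Coordinates are stored in micrometres in the embryo reference frame: the
origin sits at the distal tip of the egg cylinder and the frame axis points
along the proximal-distal direction. Label volumes use 0-based voxel
indexing with axis order (z, y, x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError


class Tissue(Enum):
    """Closed vocabulary of tissue labels.

    AVE (anterior visceral endoderm) is a subpopulation of the VE: every AVE
    cell also counts as VE in any VE selection (see :data:`VE_TISSUES`).
    """

    EPI = "EPI"
    VE = "VE"
    AVE = "AVE"
    EXE = "ExE"
    PTE = "pTE"
    OTHER = "other"

    @classmethod
    def parse(cls, text: str) -> "Tissue":
        for t in cls:
            if t.value.lower() == str(text).strip().lower():
                return t
        raise ValidationError(
            f"unknown tissue label {text!r}; expected one of "
            f"{[t.value for t in cls]}"
        )


#: Tissues that participate in any "VE" selection (AVE implies VE).
VE_TISSUES = frozenset({Tissue.VE, Tissue.AVE})


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise ValidationError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{name} must be finite, got {v}")
    return v


@dataclass
class CellRecord:
    """One cell: identity, tissue class, 3D position (µm), optional
    per-channel intensities, lineage and timepoint metadata."""

    cell_id: str
    tissue: Tissue
    position: np.ndarray
    intensities: Optional[Mapping[str, float]] = None
    lineage_id: Optional[str] = None
    timepoint_min: Optional[float] = None

    def __post_init__(self) -> None:
        self.position = _as_vec3(self.position, "position")
        if not isinstance(self.tissue, Tissue):
            self.tissue = Tissue.parse(self.tissue)
        if self.intensities is not None:
            for ch, val in self.intensities.items():
                if not np.isfinite(val) or val < 0:
                    raise ValidationError(
                        f"intensity {ch!r} of cell {self.cell_id!r} must be a "
                        f"non-negative finite number, got {val}"
                    )


@dataclass
class EmbryoFrame:
    """A set of cells plus the embryo reference frame.

    ``origin`` is the distal tip in µm; ``axis`` is the unit proximal-distal
    direction (the Z of the reference frame). The constructor normalizes
    ``axis`` and rejects a zero-norm axis.
    """

    embryo_id: str
    cells: Sequence[CellRecord]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    stage_label: str = ""
    timepoint_min: Optional[float] = None

    def __post_init__(self) -> None:
        self.origin = _as_vec3(self.origin, "origin")
        axis = _as_vec3(self.axis, "axis")
        norm = float(np.linalg.norm(axis))
        if norm < 1e-12:
            raise ValidationError("axis has zero norm")
        self.axis = axis / norm
        self.cells = list(self.cells)

    def select(self, tissues) -> list[CellRecord]:
        """Cells whose tissue is in ``tissues`` (a Tissue or iterable)."""
        if isinstance(tissues, Tissue):
            tissues = {tissues}
        tissues = frozenset(tissues)
        return [c for c in self.cells if c.tissue in tissues]

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Deterministic right-handed orthonormal basis (u, v, w) with
        w = the proximal-distal axis.

        The in-plane directions u, v are fixed by the axis alone (Gram-
        Schmidt against the least-aligned Cartesian unit vector), so polar
        angles are reproducible for a given frame.
        """
        w = self.axis
        e = np.zeros(3)
        e[int(np.argmin(np.abs(w)))] = 1.0
        u = e - np.dot(e, w) * w
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        return u, v, w

    def frame_coords(self, position) -> np.ndarray:
        """Express a µm position in frame coordinates (x, y, z) with z along
        the proximal-distal axis and the origin at the distal tip."""
        u, v, w = self.basis()
        p = _as_vec3(position, "position") - self.origin
        return np.array([p @ u, p @ v, p @ w])


@dataclass
class LabelVolume:
    """3D integer-labeled image (axis order z, y, x; 0 = background) with
    per-axis voxel size in µm."""

    labels: np.ndarray
    voxel_size: np.ndarray
    frame_of_reference: Optional[EmbryoFrame] = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValidationError(f"labels must be 3D, got ndim={labels.ndim}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError(
                f"labels must be an integer array, got dtype {labels.dtype}; "
                "convert floating-point segmentations to integer labels first"
            )
        if labels.size and labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        self.labels = labels
        vs = _as_vec3(self.voxel_size, "voxel_size")
        if np.any(vs <= 0):
            raise ValidationError(f"voxel_size must be strictly positive, got {vs}")
        self.voxel_size = vs

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size))

    def label_set(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        labs = np.unique(self.labels)
        return labs[labs != 0]


@dataclass
class CohortRecord:
    """One embryo of a culture cohort: initial cell count at day 0 and the
    binary outcomes used for rate and threshold analyses."""

    embryo_id: str
    initial_cell_count: int
    formed_egg_cylinder: bool
    ave_asymmetric: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.initial_cell_count < 0:
            raise ValidationError(
                f"initial_cell_count must be >= 0, got {self.initial_cell_count}"
            )
        if self.ave_asymmetric is not None and not self.formed_egg_cylinder:
            raise ValidationError(
                f"embryo {self.embryo_id!r}: ave_asymmetric may only be set "
                "when formed_egg_cylinder is true"
            )


@dataclass
class Cohort:
    """A list of :class:`CohortRecord`."""

    records: Sequence[CohortRecord]

    def __post_init__(self) -> None:
        self.records = list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def counts(self) -> np.ndarray:
        return np.array([r.initial_cell_count for r in self.records], dtype=int)

    def outcomes(self) -> np.ndarray:
        return np.array([r.formed_egg_cylinder for r in self.records], dtype=bool)
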