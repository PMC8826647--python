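"""Signaling-landscape statistics on the epiblast (EPI).

Signaling activity (e.g. BMP read out by Id1, FGF by a Dusp4 reporter) is
heterogeneous across EPI cells, so local activity is summarized as the
proportion of cells in a "high" expression state: per-cell marker intensity
is normalized by the Hoechst (DNA) channel and a cell is high when its
normalized value strictly exceeds the median over all EPI cells of that
embryo. Spatial structure is summarized two ways:

* proximal vs distal high-percentages, splitting the EPI at the midpoint of
  its axial extent, optionally discarding the lateral-most 20% of cells on
  each side first (for misshapen EPIs lacking an ExE);
* a 1°-step angular profile: a linear ROI radiating from the EPI center is
  rotated clockwise through 360°, each channel's per-ray means are
  normalized by the channel's mean over all rays, and the deviation of the
  marker/reference ratio from its mean over rays is reported per degree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.restoration import rolling_ball

from .errors import ValidationError
from .model import CellRecord, EmbryoFrame, Tissue

log = logging.getLogger(__name__)


class Compartment(Enum):
    PROXIMAL = "proximal"
    DISTAL = "distal"
    TRIMMED = "trimmed"


@dataclass
class SignalingAnnotation:
    cell_id: str
    marker_raw: float
    hoechst_raw: float
    normalized: float
    is_high: bool
    compartment: Optional[Compartment] = None


@dataclass
class AngularProfile:
    """Ratio deviation per integer degree 0..359."""

    angle_deg: np.ndarray
    ratio_deviation: np.ndarray

    def __post_init__(self) -> None:
        if len(self.angle_deg) != 360 or len(self.ratio_deviation) != 360:
            raise ValidationError("angular profile must have exactly 360 entries")


def annotate_high(
    cells: Sequence[CellRecord], marker: str, reference: str = "hoechst"
) -> list[SignalingAnnotation]:
    """Median-split high/low annotation of EPI cells.

    normalized = marker / reference per cell; a cell is high when its
    normalized value strictly exceeds the median of normalized over all
    annotated cells. Cells with non-positive reference intensity are
    excluded with a warning.
    """
    usable: list[tuple[CellRecord, float, float, float]] = []
    for c in cells:
        if c.intensities is None or marker not in c.intensities or reference not in c.intensities:
            raise ValidationError(
                f"cell {c.cell_id!r}: missing channel {marker!r} or {reference!r}"
            )
        m = float(c.intensities[marker])
        h = float(c.intensities[reference])
        if h <= 0:
            log.warning(
                "cell %s: non-positive reference intensity %g, excluded", c.cell_id, h
            )
            continue
        usable.append((c, m, h, m / h))
    if not usable:
        raise ValidationError("no cells with a positive reference intensity")
    median = float(np.median([u[3] for u in usable]))
    return [
        SignalingAnnotation(
            cell_id=c.cell_id,
            marker_raw=m,
            hoechst_raw=h,
            normalized=norm,
            is_high=norm > median,
        )
        for c, m, h, norm in usable
    ]


def proximal_distal_fractions(
    frame: EmbryoFrame,
    annotations: Sequence[SignalingAnnotation],
    trim_fraction: float = 0.20,
    trim: bool = False,
) -> tuple[float, float]:
    """Percent of high cells in the proximal and the distal half of the EPI.

    Cells are located by their axial coordinate (projection on the
    proximal-distal axis, distal tip = 0); the halves split at the midpoint
    of the axial extent, a cell exactly at the midpoint counting as distal.
    With ``trim`` set, the floor(trim_fraction·n) lateral-most cells on each
    side (ranked by the first in-plane frame coordinate) are first removed
    and marked :attr:`Compartment.TRIMMED`.
    """
    if not (0.0 <= trim_fraction < 0.5):
        raise ValidationError(f"trim_fraction must be in [0, 0.5), got {trim_fraction}")
    by_id = {c.cell_id: c for c in frame.select(Tissue.EPI)}
    ann = [a for a in annotations if a.cell_id in by_id]
    if not ann:
        raise ValidationError("no annotations matching the frame's EPI cells")
    coords = {a.cell_id: frame.frame_coords(by_id[a.cell_id].position) for a in ann}

    kept = list(ann)
    if trim:
        k = int(math.floor(trim_fraction * len(ann)))
        if k > 0:
            order = sorted(kept, key=lambda a: coords[a.cell_id][0])
            for a in order[:k] + order[-k:]:
                a.compartment = Compartment.TRIMMED
            kept = order[k:-k]
    if len(kept) < 2:
        raise ValidationError(f"only {len(kept)} cells remain after trimming")

    axial = {a.cell_id: coords[a.cell_id][2] for a in kept}
    lo, hi = min(axial.values()), max(axial.values())
    mid = 0.5 * (lo + hi)
    prox = [a for a in kept if axial[a.cell_id] > mid]
    dist = [a for a in kept if axial[a.cell_id] <= mid]
    for a in prox:
        a.compartment = Compartment.PROXIMAL
    for a in dist:
        a.compartment = Compartment.DISTAL

    def _pct(group):
        if not group:
            return float("nan")
        return 100.0 * sum(a.is_high for a in group) / len(group)

    return _pct(prox), _pct(dist)


def rolling_ball_background(image: np.ndarray, radius_px: int) -> np.ndarray:
    """Rolling-ball background subtraction, output clipped at zero."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError(f"image must be 2D, got ndim={image.ndim}")
    if radius_px < 1:
        raise ValidationError(f"radius must be >= 1 px, got {radius_px}")
    if radius_px > max(image.shape):
        raise ValidationError(
            f"rolling-ball radius {radius_px} px exceeds image extent {image.shape}"
        )
    background = rolling_ball(image, radius=radius_px)
    return np.clip(image - background, 0.0, None)


def angular_profile(
    image_marker: np.ndarray,
    image_reference: np.ndarray,
    center,
    ray_length: int,
) -> AngularProfile:
    """1°-step angular landscape of the marker/reference intensity ratio.

    For each integer degree d (clockwise in image coordinates, 0° pointing
    "up" = decreasing row index), a ray of ``ray_length`` unit-pixel steps
    from ``center`` is sampled with bilinear interpolation and averaged per
    channel. Per-channel ray means are normalized by the channel's mean over
    all 360 rays; the per-ray ratio's deviation from its mean over rays is
    returned, so the deviations have exactly zero mean. Rays leaving the
    image are truncated to their in-bounds pixels (with a warning).
    """
    a = np.asarray(image_marker, dtype=float)
    b = np.asarray(image_reference, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValidationError("marker and reference images must be 2D and same shape")
    cy, cx = float(center[0]), float(center[1])
    if not (0 <= cy <= a.shape[0] - 1 and 0 <= cx <= a.shape[1] - 1):
        raise ValidationError(f"center {center} outside image of shape {a.shape}")
    if ray_length < 2:
        raise ValidationError(f"ray_length must be >= 2, got {ray_length}")

    t = np.arange(ray_length, dtype=float)
    mean_m = np.empty(360)
    mean_r = np.empty(360)
    truncated = 0
    for d in range(360):
        th = math.radians(d)
        # clockwise from "up": up is -row; clockwise rotation moves toward +col
        rows = cy - t * math.cos(th)
        cols = cx + t * math.sin(th)
        ok = (rows >= 0) & (rows <= a.shape[0] - 1) & (cols >= 0) & (cols <= a.shape[1] - 1)
        if not ok.all():
            truncated += 1
        if not ok.any():
            raise ValidationError(f"ray at {d} deg has no in-bounds pixels")
        coords = np.vstack([rows[ok], cols[ok]])
        mean_m[d] = map_coordinates(a, coords, order=1, mode="nearest").mean()
        mean_r[d] = map_coordinates(b, coords, order=1, mode="nearest").mean()
    if truncated:
        log.warning("%d of 360 rays truncated at the image border", truncated)

    norm_m = mean_m / mean_m.mean()
    norm_r = mean_r / mean_r.mean()
    ratio = norm_m / norm_r
    return AngularProfile(
        angle_deg=np.arange(360),
        ratio_deviation=ratio - ratio.mean(),
    )
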