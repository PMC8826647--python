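"""Synthetic embryos with known ground truth.

Every analysis stage in this package is validated on synthetic data from
this module: egg-cylinder cell geometries with a tunable AVE patch,
rasterized ellipsoidal cells, proximal-distal signaling gradients with
per-cell noise and a normalization channel, aspiration pressure series,
exponential growth series, and culture cohorts with count-dependent
success. All generators are pure functions of their spec + seed and return
their ground truth alongside the data.

Default geometric and cohort parameters are chosen at the scale of an
~E6.0 mouse egg cylinder (length ~120 µm, diameter ~70 µm) and of the
culture experiments they emulate (initial cell counts ranging roughly
55-230 with a success midpoint near 110 cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .errors import ValidationError
from .mechanics import AspirationMeasurement
from .model import CellRecord, Cohort, CohortRecord, EmbryoFrame, LabelVolume, Tissue


@dataclass
class EggCylinderSpec:
    """Geometry of a synthetic egg cylinder: a hemispherical distal cap of
    radius diameter/2 continuing into a cylinder up to ``length``, with
    ``n_ve`` VE cells on the surface of which ``n_ave`` form an AVE patch.

    The patch center sits ``ave_axial_offset`` µm from the distal tip along
    the surface (arc length); its azimuth is von-Mises distributed around
    ``ave_azimuth`` with concentration ``ave_concentration`` (0 = uniform
    ring = rotationally symmetric)."""

    length: float = 120.0
    diameter: float = 70.0
    n_ve: int = 80
    n_ave: int = 15
    ave_axial_offset: float = 40.0
    ave_azimuth: float = 0.0
    ave_concentration: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.diameter > 0):
            raise ValidationError("length and diameter must be > 0")
        if self.diameter / 2.0 > self.length:
            raise ValidationError("cap radius (diameter/2) exceeds length")
        if self.n_ave > self.n_ve:
            raise ValidationError(
                f"n_ave ({self.n_ave}) must be <= n_ve ({self.n_ve})"
            )
        if self.ave_concentration < 0:
            raise ValidationError("ave_concentration must be >= 0")


@dataclass
class GradientSpec:
    """Proximal-distal signaling gradient in the EPI: each cell carries a
    latent high/low state with probability interpolated linearly along the
    axis between ``high_fraction_proximal`` and ``high_fraction_distal``;
    the marker channel mean is 2× higher in high cells, the Hoechst channel
    is state-independent, and both carry multiplicative Gaussian noise of
    coefficient of variation ``noise_cv``."""

    n_epi: int = 200
    high_fraction_proximal: float = 0.8
    high_fraction_distal: float = 0.2
    marker_scale: float = 1000.0
    hoechst_scale: float = 1000.0
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("high_fraction_proximal", "high_fraction_distal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not (self.marker_scale > 0 and self.hoechst_scale > 0):
            raise ValidationError("scales must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")


def _surface_point(s: float, azimuth: float, radius: float) -> np.ndarray:
    """Point on the capped cylinder at arc length s from the distal tip
    along the meridian, at the given azimuth. Frame: origin = distal tip,
    z along the cylinder axis (proximal direction)."""
    s_cap = 0.5 * math.pi * radius
    if s <= s_cap:
        phi = s / radius  # polar angle from the tip
        rho = radius * math.sin(phi)
        z = radius * (1.0 - math.cos(phi))
    else:
        rho = radius
        z = radius + (s - s_cap)
    return np.array([rho * math.cos(azimuth), rho * math.sin(azimuth), z])


def make_egg_cylinder(spec: EggCylinderSpec) -> EmbryoFrame:
    """Synthetic VE/AVE cell coordinates on an egg-cylinder surface.

    VE cells are area-uniform on the capped cylinder; AVE cells are drawn
    around the patch center (von Mises azimuth, Gaussian arc-length spread
    of diameter/4). Tissue labels are the ground truth. Deterministic for a
    fixed seed."""
    rng = np.random.default_rng(spec.seed)
    radius = spec.diameter / 2.0
    s_cap = 0.5 * math.pi * radius
    s_max = s_cap + (spec.length - radius)
    area_cap = 2.0 * math.pi * radius**2
    area_cyl = 2.0 * math.pi * radius * (spec.length - radius)

    cells: list[CellRecord] = []
    # AVE patch
    az = rng.vonmises(spec.ave_azimuth, spec.ave_concentration, size=spec.n_ave)
    s_sd = spec.diameter / 4.0
    s_ave = np.clip(
        rng.normal(spec.ave_axial_offset, s_sd, size=spec.n_ave), 0.0, s_max
    )
    for i in range(spec.n_ave):
        cells.append(
            CellRecord(
                cell_id=f"ave_{i:03d}",
                tissue=Tissue.AVE,
                position=_surface_point(float(s_ave[i]), float(az[i]), radius),
            )
        )
    # remaining VE, uniform by surface area
    n_rest = spec.n_ve - spec.n_ave
    on_cap = rng.random(n_rest) < area_cap / (area_cap + area_cyl)
    az_ve = rng.uniform(-math.pi, math.pi, size=n_rest)
    for i in range(n_rest):
        if on_cap[i]:
            # area-uniform on a hemisphere: cos(phi) uniform in [0, 1]
            phi = math.acos(rng.uniform(0.0, 1.0))
            s = radius * phi
        else:
            s = s_cap + rng.uniform(0.0, spec.length - radius)
        cells.append(
            CellRecord(
                cell_id=f"ve_{i:03d}",
                tissue=Tissue.VE,
                position=_surface_point(float(s), float(az_ve[i]), radius),
            )
        )
    return EmbryoFrame(
        embryo_id=f"synthetic_{spec.seed}",
        cells=cells,
        origin=np.zeros(3),
        axis=np.array([0.0, 0.0, 1.0]),
        stage_label="synthetic",
    )


@dataclass
class EllipsoidTruth:
    """Ground-truth parameters of one rasterized cell."""

    label: int
    center: np.ndarray        # (z, y, x) µm
    semi_axes: np.ndarray     # descending, µm
    axes: np.ndarray          # rotation matrix, columns = principal directions


def make_label_volume(
    cells: Sequence[tuple],
    voxel_size,
    shape: tuple[int, int, int],
) -> tuple[LabelVolume, list[EllipsoidTruth]]:
    """Rasterize non-overlapping ellipsoids into an integer label volume.

    ``cells`` is a list of (center_um, semi_axes_um, rotation) with center
    in (z, y, x) µm, semi-axes in µm, and rotation a 3×3 matrix whose
    columns are the principal directions (None = axis-aligned). A voxel is
    labeled i+1 iff its center lies inside ellipsoid i. Overlap of bounding
    spheres or an ellipsoid leaving the volume raises a validation error.
    """
    vs = np.asarray(voxel_size, dtype=float)
    if vs.shape != (3,) or np.any(vs <= 0):
        raise ValidationError(f"voxel_size must be a positive 3-vector, got {vs}")
    extent = np.asarray(shape, dtype=float) * vs

    parsed = []
    for i, cell in enumerate(cells):
        center = np.asarray(cell[0], dtype=float)
        semi = np.asarray(cell[1], dtype=float)
        rot = np.eye(3) if (len(cell) < 3 or cell[2] is None) else np.asarray(cell[2], dtype=float)
        if np.any(semi <= 0):
            raise ValidationError(f"cell {i}: semi-axes must be > 0")
        r = float(semi.max())
        if np.any(center - r < 0) or np.any(center + r > extent):
            raise ValidationError(
                f"cell {i}: bounding sphere leaves the volume (extent {extent})"
            )
        parsed.append((center, semi, rot, r))
    for i in range(len(parsed)):
        for j in range(i + 1, len(parsed)):
            d = np.linalg.norm(parsed[i][0] - parsed[j][0])
            if d <= parsed[i][3] + parsed[j][3]:
                raise ValidationError(
                    f"cells {i} and {j}: bounding spheres overlap "
                    f"(distance {d:.3g} <= {parsed[i][3] + parsed[j][3]:.3g})"
                )

    labels = np.zeros(shape, dtype=np.uint16)
    truths = []
    for i, (center, semi, rot, r) in enumerate(parsed):
        lo = np.maximum(np.floor((center - r) / vs).astype(int), 0)
        hi = np.minimum(np.ceil((center + r) / vs).astype(int), np.asarray(shape))
        zz, yy, xx = np.meshgrid(
            *(np.arange(lo[k], hi[k]) for k in range(3)), indexing="ij"
        )
        pts = (np.stack([zz, yy, xx], axis=-1) + 0.5) * vs - center
        q = pts @ rot  # coordinates in the ellipsoid's principal frame
        inside = np.sum((q / semi) ** 2, axis=-1) <= 1.0
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = i + 1
        semi_sorted = np.sort(semi)[::-1]
        truths.append(
            EllipsoidTruth(label=i + 1, center=center, semi_axes=semi_sorted, axes=rot)
        )
    return LabelVolume(labels=labels, voxel_size=vs), truths


def make_signaling_frame(
    spec: GradientSpec, geometry: Optional[EggCylinderSpec] = None
) -> tuple[EmbryoFrame, np.ndarray]:
    """Synthetic EPI with a proximal-distal gradient of high-state cells.

    EPI cells fill the cylinder interior above the distal cap; each carries
    a latent high/low state (probability linear in the axial coordinate)
    and intensities marker = marker_scale·(2 if high else 1)·(1+noise),
    hoechst = hoechst_scale·(1+noise). Returns the frame and the boolean
    ground-truth state array (ordered as the cells)."""
    geometry = geometry or EggCylinderSpec()
    rng = np.random.default_rng(spec.seed)
    radius = geometry.diameter / 2.0
    z_lo, z_hi = radius, geometry.length
    n = spec.n_epi
    z = rng.uniform(z_lo, z_hi, size=n)
    rho = 0.8 * radius * np.sqrt(rng.random(n))
    phi = rng.uniform(-math.pi, math.pi, size=n)
    frac = (z - z_lo) / (z_hi - z_lo)  # 0 = distal, 1 = proximal
    p_high = spec.high_fraction_distal + frac * (
        spec.high_fraction_proximal - spec.high_fraction_distal
    )
    states = rng.random(n) < p_high
    marker_mean = np.where(states, 2.0, 1.0) * spec.marker_scale
    marker = marker_mean * np.clip(1.0 + spec.noise_cv * rng.standard_normal(n), 1e-6, None)
    hoechst = spec.hoechst_scale * np.clip(
        1.0 + spec.noise_cv * rng.standard_normal(n), 1e-6, None
    )
    cells = [
        CellRecord(
            cell_id=f"epi_{i:04d}",
            tissue=Tissue.EPI,
            position=np.array(
                [rho[i] * math.cos(phi[i]), rho[i] * math.sin(phi[i]), z[i]]
            ),
            intensities={"marker": float(marker[i]), "hoechst": float(hoechst[i])},
        )
        for i in range(n)
    ]
    frame = EmbryoFrame(
        embryo_id=f"signaling_{spec.seed}",
        cells=cells,
        origin=np.zeros(3),
        axis=np.array([0.0, 0.0, 1.0]),
        stage_label="synthetic",
    )
    return frame, states


def make_cohort(
    n: int,
    count_mean: float = 130.0,
    count_sd: float = 40.0,
    logistic_midpoint: float = 110.0,
    logistic_slope: float = 0.1,
    seed: int = 0,
    ave_rate: Optional[float] = None,
) -> tuple[Cohort, dict]:
    """Synthetic culture cohort with count-dependent success.

    Initial cell counts are truncated-at-zero normal, rounded to integers;
    the egg-cylinder outcome is Bernoulli with success probability logistic
    in the count, p = expit(slope·(count − midpoint)). When ``ave_rate`` is
    given, embryos that formed a cylinder get an AVE-asymmetry outcome with
    that success probability; otherwise it stays missing. Returns the
    cohort and the ground-truth parameter dict."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if count_sd < 0:
        raise ValidationError("count_sd must be >= 0")
    rng = np.random.default_rng(seed)
    counts = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.normal(count_mean, count_sd, size=remaining.size)
        ok = draw >= 0
        counts[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    counts = np.rint(counts).astype(int)
    p = expit(logistic_slope * (counts - logistic_midpoint))
    formed = rng.random(n) < p
    records = []
    for i in range(n):
        ave = None
        if ave_rate is not None and formed[i]:
            ave = bool(rng.random() < ave_rate)
        records.append(
            CohortRecord(
                embryo_id=f"embryo_{i:03d}",
                initial_cell_count=int(counts[i]),
                formed_egg_cylinder=bool(formed[i]),
                ave_asymmetric=ave,
            )
        )
    truth = {
        "count_mean": count_mean,
        "count_sd": count_sd,
        "logistic_midpoint": logistic_midpoint,
        "logistic_slope": logistic_slope,
        "ave_rate": ave_rate,
    }
    return Cohort(records=records), truth


def make_growth_series(
    a: float,
    b: float,
    timepoints: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential cell-count series counts = a·e^{b·t}·(1+noise), floored
    at 1 cell. Returns (hours, counts)."""
    t = np.asarray(list(timepoints), dtype=float)
    if t.size == 0:
        raise ValidationError("timepoints must be non-empty")
    rng = np.random.default_rng(seed)
    noise = noise_cv * rng.standard_normal(t.size) if noise_cv > 0 else np.zeros(t.size)
    counts = np.maximum(a * np.exp(b * t) * (1.0 + noise), 1.0)
    return t, counts


def make_aspiration_series(
    gamma_true: float,
    rp_um: float,
    rc_um: float,
    n: int,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[AspirationMeasurement]:
    """Synthetic micropipette aspiration measurements.

    Critical pressures follow the forward Young-Laplace model
    P_c = 2·γ·(1/R_p − 1/R_c)·(1+noise) with radii converted from µm to m,
    so :func:`periquant.mechanics.cortical_tension` inverts them exactly at
    zero noise."""
    if not rp_um < rc_um:
        raise ValidationError(f"need rp < rc, got rp={rp_um}, rc={rc_um}")
    rng = np.random.default_rng(seed)
    rp, rc = rp_um * 1e-6, rc_um * 1e-6
    base = 2.0 * gamma_true * (1.0 / rp - 1.0 / rc)
    out = []
    for _ in range(n):
        noise = noise_cv * rng.standard_normal() if noise_cv > 0 else 0.0
        out.append(AspirationMeasurement(p_c=base * (1.0 + noise), r_p=rp, r_c=rc))
    return out
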