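"""Nucleation theory of lumen formation: heterogeneous vs homogeneous case.

A spherical lumen of radius R under interfacial tension γ and constant
active pumping pressure P_L obeys (Young-Laplace balance plus a dissipative
pressure term with coefficient α):

    α dR/dt = P_L − 2γ/R

so a lumen grows iff R exceeds the critical radius R_crit = 2γ/P_L. A
proto-lumen of fixed initialization volume V nucleating in the bulk
("homogeneous") starts as a sphere of radius R_Hom = (3V/4π)^{1/3}. At a
wall (a neighboring tissue, "heterogeneous") the proto-lumen is a spherical
cap whose contact angle obeys the Young equation cosθ = γ_W/γ with
γ_W = γ_W2 − γ_W1 (wall-tissue minus wall-lumen tension); a stable cap
exists only in the partial-wetting regime −γ < γ_W < γ. At fixed volume the
cap's radius of curvature

    R_Het = (3Vγ³ / (π (γ−γ_W)² (2γ+γ_W)))^{1/3}

always exceeds R_Hom, so wall contact lowers the effective nucleation
threshold: heterogeneous nucleation is easier. The state diagram classifies
(P_L/P_Norm, γ_W/γ) into regions where both, only the heterogeneous, or
neither proto-lumen grows, with P_Norm = 2γ/R_Min and R_Min = R_Hom(V).

All quantities are in SI units (N/m, Pa, m, m³); boundary cases are
assigned to the non-growing side (growth requires a strict inequality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ValidationError, WettingRegimeError


@dataclass
class NucleationParams:
    """Tensions (N/m), pumping pressure (Pa), dissipative coefficient
    (Pa·s/m) and proto-lumen initialization volume (m³)."""

    gamma: float
    gamma_w1: float = 0.0
    gamma_w2: float = 0.0
    p_l: float = 0.0
    alpha: float = 1.0
    v_init: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValidationError(f"gamma must be > 0, got {self.gamma}")
        if not self.alpha > 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")
        if not self.v_init > 0:
            raise ValidationError(f"v_init must be > 0, got {self.v_init}")
        for name in ("gamma_w1", "gamma_w2", "p_l"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    @property
    def gamma_w(self) -> float:
        """Effective wall tension difference γ_W = γ_W2 − γ_W1."""
        return self.gamma_w2 - self.gamma_w1

    @property
    def w(self) -> float:
        """Dimensionless wetting parameter γ_W/γ."""
        return self.gamma_w / self.gamma


class WettingRegime(Enum):
    ZERO_WETTING = "zero_wetting"        # γ_W/γ <= −1: wall contact unfavourable
    PARTIAL_WETTING = "partial_wetting"  # −1 < γ_W/γ < 1: stable contact angle
    TOTAL_WETTING = "total_wetting"      # γ_W/γ >= 1: lumen spreads along the wall


class Region(Enum):
    BOTH_GROW = "both_grow"
    HET_ONLY_GROW = "het_only_grow"
    NONE_GROW = "none_grow"
    OUTSIDE_PARTIAL_WETTING = "outside_partial_wetting"


@dataclass
class RegimeCell:
    pl_norm: float
    w: float
    region: Region


def wetting_regime(params: NucleationParams) -> WettingRegime:
    w = params.w
    if w <= -1.0:
        return WettingRegime.ZERO_WETTING
    if w >= 1.0:
        return WettingRegime.TOTAL_WETTING
    return WettingRegime.PARTIAL_WETTING


def laplace_pressure(gamma: float, radius: float) -> float:
    """Pressure jump 2γ/R across a spherical interface."""
    if not radius > 0:
        raise ValidationError(f"radius must be > 0, got {radius}")
    return 2.0 * gamma / radius


def critical_radius(params: NucleationParams) -> float:
    """R_crit = 2γ/P_L; no finite critical radius when P_L <= 0."""
    if not params.p_l > 0:
        raise ValidationError(
            f"p_l must be > 0 for a finite critical radius (got {params.p_l}): "
            "without net pumping no lumen can grow"
        )
    return 2.0 * params.gamma / params.p_l


def growth_rate(radius: float, params: NucleationParams) -> float:
    """dR/dt = (P_L − 2γ/R)/α; positive iff R > R_crit."""
    if not radius > 0:
        raise ValidationError(f"radius must be > 0, got {radius}")
    return (params.p_l - 2.0 * params.gamma / radius) / params.alpha


def r_hom(v: float) -> float:
    """Radius of the sphere of volume v: R_Hom = (3v/4π)^{1/3}."""
    if not v > 0:
        raise ValidationError(f"volume must be > 0, got {v}")
    return (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)


def contact_angle(params: NucleationParams) -> float:
    """Young contact angle θ = arccos(γ_W/γ), defined for partial wetting."""
    regime = wetting_regime(params)
    if regime is not WettingRegime.PARTIAL_WETTING:
        raise WettingRegimeError(
            f"contact angle undefined in {regime.value} (γ_W/γ = {params.w:g}); "
            "requires −γ < γ_W < γ"
        )
    return math.acos(params.w)


def cap_volume(radius_of_curvature: float, theta: float) -> float:
    """Spherical-cap volume V = (π/3) R³ (2 + cosθ)(1 − cosθ)².

    θ = π recovers the full sphere."""
    if not radius_of_curvature > 0:
        raise ValidationError(f"radius must be > 0, got {radius_of_curvature}")
    if not (0.0 < theta <= math.pi):
        raise ValidationError(f"theta must be in (0, pi], got {theta}")
    c = math.cos(theta)
    return (math.pi / 3.0) * radius_of_curvature**3 * (2.0 + c) * (1.0 - c) ** 2


def r_het(params: NucleationParams) -> float:
    """Radius of curvature of the wall-attached proto-lumen of volume V:

    R_Het = (3Vγ³ / (π (γ−γ_W)² (2γ+γ_W)))^{1/3}

    Defined in the partial-wetting regime; always >= R_Hom(V)."""
    regime = wetting_regime(params)
    if regime is not WettingRegime.PARTIAL_WETTING:
        raise WettingRegimeError(
            f"r_het undefined in {regime.value} (γ_W/γ = {params.w:g})"
        )
    g, gw, v = params.gamma, params.gamma_w, params.v_init
    return (3.0 * v * g**3 / (math.pi * (g - gw) ** 2 * (2.0 * g + gw))) ** (1.0 / 3.0)


def het_threshold(w: float) -> float:
    """Normalized pressure threshold for heterogeneous growth,
    f(w) = R_Min/R_Het = ((1−w)² (2+w) / 4)^{1/3} for w in (−1, 1).

    Derived from R_Hom and R_Het; f(−1) = 1 (the advantage vanishes at the
    zero-wetting edge) and f → 0 as w → 1."""
    if not -1.0 < w < 1.0:
        raise WettingRegimeError(f"het_threshold defined for |w| < 1, got {w}")
    return ((1.0 - w) ** 2 * (2.0 + w) / 4.0) ** (1.0 / 3.0)


def classify_regime(pl_norm: float, w: float) -> RegimeCell:
    """Classify one point of the state diagram.

    pl_norm = P_L/P_Norm with P_Norm = 2γ/R_Min and R_Min the radius of the
    minimal initial spherical lumen of volume V. Homogeneous growth requires
    pl_norm > 1; heterogeneous growth requires pl_norm > f(w); |w| >= 1 is
    outside partial wetting. Boundary values go to the non-growing side.
    """
    if not (math.isfinite(pl_norm) and math.isfinite(w)):
        raise ValidationError("pl_norm and w must be finite")
    if abs(w) >= 1.0:
        region = Region.OUTSIDE_PARTIAL_WETTING
    elif pl_norm > 1.0:
        region = Region.BOTH_GROW
    elif pl_norm > het_threshold(w):
        region = Region.HET_ONLY_GROW
    else:
        region = Region.NONE_GROW
    return RegimeCell(pl_norm=pl_norm, w=w, region=region)


def state_diagram(pl_norm_grid, w_grid) -> list[list[RegimeCell]]:
    """classify_regime over a grid; rows index pl_norm, columns index w."""
    pl = list(pl_norm_grid)
    ws = list(w_grid)
    if not pl or not ws:
        raise ValidationError("grids must be non-empty")
    return [[classify_regime(p, w) for w in ws] for p in pl]


def state_diagram_frame(pl_norm_grid, w_grid):
    """State diagram as a tidy DataFrame (pl_norm, w, region)."""
    import pandas as pd

    rows = [
        {"pl_norm": cell.pl_norm, "w": cell.w, "region": cell.region.value}
        for row in state_diagram(pl_norm_grid, w_grid)
        for cell in row
    ]
    return pd.DataFrame(rows)


def simulate_radius(
    r0: float, params: NucleationParams, dt: float, t_end: float
) -> tuple[np.ndarray, np.ndarray, str]:
    """Integrate α dR/dt = P_L − 2γ/R from r0.

    Explicit classical Runge-Kutta with automatic step halving until two
    successive refinements differ by < 1e-6 relative. The trajectory is
    monotone: growing for r0 > R_crit, shrinking for r0 < R_crit.
    Integration stops with status "collapsed" when the radius reaches the
    floor 1e-3·r0; otherwise status is "ok". Returns (times, radii, status).
    """
    if not (r0 > 0 and dt > 0 and t_end > 0):
        raise ValidationError("r0, dt and t_end must be > 0")
    if not all(map(math.isfinite, (r0, dt, t_end, params.p_l))):
        raise ValidationError("non-finite inputs")
    floor = 1e-3 * r0

    def f(r: float) -> float:
        # clamped so intermediate RK stages never divide by <= 0
        return (params.p_l - 2.0 * params.gamma / max(r, 0.5 * floor)) / params.alpha

    def integrate(step: float):
        n = int(math.ceil(t_end / step))
        times = [0.0]
        radii = [r0]
        r = r0
        status = "ok"
        for i in range(n):
            k1 = f(r)
            k2 = f(r + 0.5 * step * k1)
            k3 = f(r + 0.5 * step * k2)
            k4 = f(r + step * k3)
            r = r + step * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            if r <= floor:
                r = floor
                times.append((i + 1) * step)
                radii.append(r)
                status = "collapsed"
                break
            times.append((i + 1) * step)
            radii.append(r)
        return np.array(times), np.array(radii), status

    t, r, status = integrate(dt)
    for _ in range(12):
        t2, r2, status2 = integrate(dt / 2.0)
        # compare on the coarse grid (every 2nd fine point)
        m = min(len(r), (len(r2) + 1) // 2)
        diff = np.max(np.abs(r2[: 2 * m : 2] - r[:m]) / np.maximum(np.abs(r[:m]), floor))
        t, r, status, dt = t2, r2, status2, dt / 2.0
        if diff < 1e-6:
            break
    return t, r, status
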