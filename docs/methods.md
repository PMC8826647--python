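# Methods

This note records the models implemented in periquant, the conventions
chosen where the underlying measurements leave freedom, and what the
synthetic-data tests do and do not establish.

## Coordinate conventions

All cell coordinates are micrometres in an embryo reference frame: origin
at the distal tip of the egg cylinder, frame axis = unit proximal-distal
direction. `EmbryoFrame.basis()` completes the axis into a deterministic
right-handed orthonormal triad (Gram-Schmidt against the least-aligned
Cartesian unit vector), so polar angles are reproducible; every statistic
that matters is invariant under the residual in-plane rotation freedom
(checked by the rotation-invariance tests). Label volumes are 0-based
(z, y, x) arrays; voxel centers sit at (index + 0.5)·voxel_size; voxel
sizes may be anisotropic and propagate to all volume computations.

## AVE asymmetry index

The index r_cent/r_max is computed exactly as a polar-plot construction:
each VE cell contributes r = its full 3D distance from the distal tip and
θ = its rotation angle about the axis; AVE cells are mapped to
(r cos θ, r sin θ) in the 2D polar plane and averaged. Computing the
centroid in the plane (not in 3D) is deliberate: a rotationally symmetric
AVE ring of any axial height scores 0. On-axis cells (x = y = 0) take
θ = 0 by convention and contribute their axial distance to r_max.
Classification is strict (index > 0.15 ⇒ asymmetric), so an index exactly
at the threshold counts as symmetric. The 0.15 default is the operating
point below which qualitatively symmetric reference embryos fall.

## Morphometrics

* **Ellipsoid fit.** Eigen-decomposition of the voxel-center covariance;
  semi-axes aᵢ = √(5λᵢ) — the solid uniform ellipsoid with matching second
  moments. Aspect ratio and alignment only use ratios and directions, so
  the √5 scaling is inert for them; it is fixed here so the semi-axes also
  read as physical lengths (recovered within ~3% on rasterized ground
  truth at 0.25 µm voxels).
* **Radial alignment.** The inside-outside reference direction is the
  segment from the cell centroid to the cell's voxel center farthest from
  a caller-supplied embryo center (ties → lexicographically smallest
  (z, y, x) index); the angle to the fitted long axis is folded into
  [0°, 90°] because the axis is unsigned. This farthest-voxel estimator is
  exact in the continuum but voxelization-noisy: for a cell lying
  tangentially, the farthest voxel wanders along the long axis within the
  radially-extreme voxel layer, by an angle ~atan(LA·√(voxel/MA)/MA), so a
  perpendicular configuration reads ~55–75° rather than 90° at 0.25–0.5 µm
  voxels, while radial configurations read within a few degrees of 0°. The
  tests therefore bound the radial case tightly (<10°) and the tangential
  case loosely (>45°); the fitted long-axis *direction* itself is recovered
  within 5° of the construction axis. Low angles — the regime the
  measurement is used to detect — are trustworthy; angles near 90° are
  compressed downward.
* **Embryo center** is a point, supplied per call (per timepoint if
  needed); using the egg-cylinder axis instead would be a different
  definition and is not implemented.

## Signaling landscapes

Per-cell normalized intensity is marker/Hoechst; "high" means strictly
above the median over all annotated EPI cells of the embryo (cells with
non-positive reference intensity are excluded with a warning, and the
median is taken over the surviving cells, before any lateral trimming —
trimming is a compartment operation, not an annotation operation). The
proximal/distal split is at the midpoint of the EPI's axial extent, a cell
exactly at the midpoint counting as distal; the lateral trim removes
⌊0.2·n⌋ cells per side ranked by the first in-plane frame coordinate.
Angular profiles sample 360 rays (1° steps, clockwise in image
coordinates from "up", bilinear interpolation at unit-pixel steps,
rays truncated at the border with a warning); per-channel ray means are
normalized by the channel's mean over rays, and the reported quantity is
the ratio's deviation from its own mean, which is zero-mean exactly. Only
relative angular structure is meaningful — the start angle and
interpolation order are conventions. Rolling-ball background subtraction
delegates to scikit-image's `rolling_ball` and clips at zero.

## Lumen nucleation

All quantities in SI units. The radius dynamics α dR/dt = P_L − 2γ/R give
R_crit = 2γ/P_L; a fixed initialization volume V gives R_Hom = (3V/4π)^⅓
for a free (homogeneous) proto-lumen and, at a wall under partial wetting
(cos θ = γ_W/γ, γ_W = γ_W2 − γ_W1), the spherical-cap radius of curvature
R_Het = (3Vγ³/(π(γ−γ_W)²(2γ+γ_W)))^⅓. The state diagram uses the
dimensionless coordinates p = P_L/P_Norm (P_Norm = 2γ/R_Min, R_Min =
R_Hom(V)) and w = γ_W/γ: homogeneous growth ⇔ p > 1, heterogeneous growth
⇔ p > f(w) with f(w) = R_Min/R_Het = ((1−w)²(2+w)/4)^⅓. f is derived here
from the two radius formulas and is validated only against a brute-force
classifier that works in physical units; boundary points (p exactly at a
threshold, |w| = 1) are assigned to the non-growing / outside-partial-
wetting side because growth requires a strict inequality. The ODE
integrator (classical RK4 with step halving until two refinements agree
to 1e-6 relative, collapse floor 10⁻³·r0) is an artifact choice — the
theory itself only uses signs and fixed points.

## Mechanics and staging

Cortical tension inverts the Young-Laplace aspiration balance
γ = P_c/(2(1/R_p − 1/R_c)), with R_p < R_c enforced. The growth law
y = a·e^{bx} is fitted by ordinary least squares on (x, ln y) — so R² is
the log-scale statistic — and inverted as day = 4.5 + ln(y/a)/(24b): x is
measured in hours past E4.5, the origin consistent with a prefactor at the
E4.5 count scale (a ≈ 75 cells); constant counts are special-cased to
b = 0, R² = 1 (zero residuals) and cannot be inverted. The threshold scan
uses an inclusive rule (count ≥ threshold = "above"), the printed accuracy
formula (TP+TN)/n, and breaks accuracy ties toward the smallest threshold
(maximum sample retention). Cohort rates are egg-cylinder formation,
AVE asymmetry among evaluated cylinders, and their product; the count-based
`success_rates` entry point exists because the two published denominators
(23 embryos; 18 evaluated cylinders) cannot coexist in a single
record-level cohort under the "evaluated ⊆ formed" invariant.

## Synthetic embryos

The generator emulates the study conditions, not microscopy: an ~E6.0-scale
egg cylinder (length 120 µm, diameter 70 µm, 80 VE cells of which 15 AVE)
with cells on the surface of a hemispherically-capped cylinder; the AVE
patch has a von Mises azimuth (concentration = the single asymmetry knob,
0 = symmetric ring) and Gaussian arc-length spread (σ = diameter/4) around
a 40 µm offset from the tip. The EPI gradient assigns latent high states
with probability linear along the axis (defaults 0.8 proximal / 0.2
distal, n = 200, 10% intensity CV, high state = 2× marker mean). Cohorts
draw counts from a truncated normal (mean 130, SD 40 — spanning the
observed 55–230 range) with logistic success probability (midpoint 110
cells); the scale constants a = 75.06, b = 0.0712/h (total) and a = 36.77,
b = 0.0818/h (EPI) parameterize the growth series. Aspiration series use
a 3.5 µm pipette on 10 µm cells at 0.5 mN/m tension with 5% pressure CV.

Not emulated: optics (PSF, attenuation, stripes), segmentation errors,
tissue deformation, cell division, or spatial correlation between
neighboring cells' states. Passing parameter-recovery tests therefore
shows the estimators are correct for their stated models at realistic
scales and noise — not that they are robust to imaging artifacts.

## Problem sizes and numerical choices

Stochastic test batteries use 100–200 seeds at n = 100–500 cells/embryos —
large enough that the binomial/regression checks have negligible
flakiness, small enough that the whole suite runs in well under a minute
per module. Monotonicity of the asymmetry index in the concentration knob
is asserted on 20–25-seed averages with a 0.01 slack for sampling noise.
The binomial-coverage check accepts ≥ 90% observed coverage of a true-95%
interval over 200 trials (3+ SD below the mean). Rasterization tests use
0.25–0.5 µm voxels on 8–10 µm semi-axis cells. Cell-table CSVs are written
with 17 significant digits and read with round-trip float parsing, so
coordinate round trips are bit-exact.
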