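"""Lumen nucleation theory: formulas, wetting regimes, state diagram, ODE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periquant import nucleation as nuc
from periquant.errors import ValidationError, WettingRegimeError
from periquant.nucleation import (
    NucleationParams,
    Region,
    WettingRegime,
    cap_volume,
    classify_regime,
    contact_angle,
    critical_radius,
    growth_rate,
    het_threshold,
    laplace_pressure,
    r_het,
    r_hom,
    simulate_radius,
    state_diagram,
    wetting_regime,
)


def params(gamma=1.0, gw=0.0, p_l=1.0, v=1.0, alpha=1.0):
    return NucleationParams(
        gamma=gamma, gamma_w1=0.0, gamma_w2=gw, p_l=p_l, alpha=alpha, v_init=v
    )


class TestBasicFormulas:
    def test_laplace_pressure(self):
        assert laplace_pressure(1.0, 2.0) == pytest.approx(1.0)
        assert laplace_pressure(1.0, 4.0) == pytest.approx(0.5)  # halves with 2R
        # embryo-scale units: gamma = 5e-4 N/m, R = 10 um -> 100 Pa
        assert laplace_pressure(5e-4, 10e-6) == pytest.approx(100.0)
        with pytest.raises(ValidationError):
            laplace_pressure(1.0, 0.0)

    def test_critical_radius(self):
        assert critical_radius(params(gamma=1.0, p_l=2.0)) == pytest.approx(1.0)
        assert critical_radius(params(gamma=2.0, p_l=2.0)) == pytest.approx(2.0)
        with pytest.raises(ValidationError, match="no lumen can grow"):
            critical_radius(params(p_l=0.0))

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.01, 100))
    def test_growth_rate_vanishes_at_critical_radius(self, gamma, p_l, alpha):
        p = params(gamma=gamma, p_l=p_l, alpha=alpha)
        assert growth_rate(critical_radius(p), p) == pytest.approx(0.0, abs=1e-12)

    def test_growth_rate_values_and_limit(self):
        p = params(gamma=1.0, p_l=2.0)  # R_crit = 1
        assert growth_rate(2.0, p) == pytest.approx(1.0)  # 2 - 2/2
        assert growth_rate(1e9, p) == pytest.approx(p.p_l / p.alpha, rel=1e-6)

    def test_r_hom(self):
        assert r_hom(4 * math.pi / 3) == pytest.approx(1.0)
        assert r_hom(8 * 4 * math.pi / 3) == pytest.approx(2.0)
        with pytest.raises(ValidationError):
            r_hom(0.0)

    def test_cap_volume_sphere_and_hemisphere(self):
        assert cap_volume(1.0, math.pi) == pytest.approx(4 * math.pi / 3)
        assert cap_volume(1.0, math.pi / 2) == pytest.approx(2 * math.pi / 3)
        assert cap_volume(1.0, 1e-6) < 1e-15
        with pytest.raises(ValidationError):
            cap_volume(1.0, 0.0)
        with pytest.raises(ValidationError):
            cap_volume(1.0, 3.5)

    def test_cap_full_sphere_roundtrip_with_r_hom(self):
        v = 2.7
        assert cap_volume(r_hom(v), math.pi) == pytest.approx(v, rel=1e-12)

    def test_contact_angle(self):
        assert contact_angle(params(gw=0.0)) == pytest.approx(math.pi / 2)
        assert contact_angle(params(gw=0.5)) == pytest.approx(math.pi / 3)
        assert contact_angle(params(gw=-0.5)) == pytest.approx(2 * math.pi / 3)
        for gw in (1.0, -1.0, 2.0):
            with pytest.raises(WettingRegimeError):
                contact_angle(params(gw=gw))


class TestWettingRegimes:
    @pytest.mark.parametrize(
        "gw,expected",
        [
            (-1.5, WettingRegime.ZERO_WETTING),
            (-1.0, WettingRegime.ZERO_WETTING),
            (0.0, WettingRegime.PARTIAL_WETTING),
            (0.999, WettingRegime.PARTIAL_WETTING),
            (1.0, WettingRegime.TOTAL_WETTING),
            (3.0, WettingRegime.TOTAL_WETTING),
        ],
    )
    def test_regime_boundaries(self, gw, expected):
        assert wetting_regime(params(gw=gw)) is expected

    def test_wetting_conditions_under_gamma_w1_equals_gamma(self):
        """With the lumen-wall tension equal to the lumen-tissue tension
        (γ_W1 = γ), total wetting ⇔ γ_W2 > 2γ and zero wetting ⇔ γ_W2 < 0."""
        gamma = 0.7
        for gw2 in np.linspace(-2.0, 3.5, 45):
            p = NucleationParams(gamma=gamma, gamma_w1=gamma, gamma_w2=gw2, p_l=1.0)
            regime = wetting_regime(p)
            if gw2 > 2 * gamma:
                assert regime is WettingRegime.TOTAL_WETTING
            elif gw2 < 0:
                assert regime is WettingRegime.ZERO_WETTING
            elif 0 < gw2 < 2 * gamma:
                assert regime is WettingRegime.PARTIAL_WETTING


class TestRHet:
    def test_zero_wetting_limit_recovers_r_hom(self):
        v = 3.0
        p = params(gw=-1.0 + 1e-9, v=v)
        assert r_het(p) == pytest.approx(r_hom(v), rel=1e-6)

    def test_neutral_wetting_value(self):
        p = params(gw=0.0, v=1.0)
        assert r_het(p) == pytest.approx(2 ** (1 / 3) * r_hom(1.0), rel=1e-12)
        assert r_het(p) == pytest.approx((3 / (2 * math.pi)) ** (1 / 3), rel=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(
        st.floats(0.01, 10),  # gamma
        st.floats(-0.999, 0.999),  # w
        st.floats(1e-3, 1e3),  # v
    )
    def test_cap_volume_self_consistency(self, gamma, w, v):
        """cap_volume(r_het, contact_angle) returns v_init to 1e-10 rel."""
        p = params(gamma=gamma, gw=w * gamma, v=v)
        assert cap_volume(r_het(p), contact_angle(p)) == pytest.approx(v, rel=1e-10)

    @settings(deadline=None, max_examples=200)
    @given(st.floats(-0.999, 0.999))
    def test_r_het_always_larger_than_r_hom(self, w):
        p = params(gw=w, v=1.0)
        assert r_het(p) >= r_hom(1.0) * (1 - 1e-12)

    def test_outside_partial_wetting_rejected(self):
        with pytest.raises(WettingRegimeError):
            r_het(params(gw=1.0))


class TestClassifyRegime:
    def test_threshold_closes_at_zero_wetting_edge(self):
        assert het_threshold(-1 + 1e-12) == pytest.approx(1.0)

    def test_known_points(self):
        assert classify_regime(1.5, 0.0).region is Region.BOTH_GROW
        assert classify_regime(0.9, 0.0).region is Region.HET_ONLY_GROW
        assert classify_regime(0.5, 0.0).region is Region.NONE_GROW
        assert classify_regime(0.5, 1.2).region is Region.OUTSIDE_PARTIAL_WETTING
        assert het_threshold(0.0) == pytest.approx(0.5 ** (1 / 3))

    def test_boundary_assigned_to_non_growing_side(self):
        assert classify_regime(1.0, 0.0).region is Region.HET_ONLY_GROW
        f0 = het_threshold(0.0)
        assert classify_regime(f0, 0.0).region is Region.NONE_GROW

    def test_brute_force_physical_units_oracle(self):
        """classify_regime agrees with an explicit physical-units classifier
        (compute R_Hom, R_Het, R_crit and compare radii) on 10^4 random
        parameter sets."""
        rng = np.random.default_rng(42)
        for _ in range(10_000):
            gamma = rng.uniform(0.1, 10.0)
            v = rng.uniform(0.01, 100.0)
            w = rng.uniform(-1.5, 1.5)
            pl_norm = rng.uniform(0.0, 2.0)
            got = classify_regime(pl_norm, w).region
            if abs(w) >= 1.0:
                assert got is Region.OUTSIDE_PARTIAL_WETTING
                continue
            r_min = r_hom(v)
            p_norm = 2.0 * gamma / r_min
            p_l = pl_norm * p_norm
            p = params(gamma=gamma, gw=w * gamma, v=v, p_l=max(p_l, 1e-300))
            r_crit = critical_radius(p)
            hom_grows = r_min > r_crit
            het_grows = r_het(p) > r_crit
            if hom_grows:
                expected = Region.BOTH_GROW
            elif het_grows:
                expected = Region.HET_ONLY_GROW
            else:
                expected = Region.NONE_GROW
            assert got is expected, (pl_norm, w)

    def test_region_monotone_in_pressure(self):
        order = {Region.NONE_GROW: 0, Region.HET_ONLY_GROW: 1, Region.BOTH_GROW: 2}
        for w in np.linspace(-0.95, 0.95, 10):
            levels = [
                order[classify_regime(p, w).region] for p in np.linspace(0, 2, 100)
            ]
            assert levels == sorted(levels)


class TestStateDiagram:
    def test_four_region_topology(self):
        grid = state_diagram(np.arange(0, 2.01, 0.05), np.arange(-1.5, 1.51, 0.05))
        regions = {cell.region for row in grid for cell in row}
        assert regions == set(Region)

    def test_single_region_when_all_above_thresholds(self):
        grid = state_diagram([1.5, 1.8], [-0.5, 0.0, 0.5])
        assert {c.region for row in grid for c in row} == {Region.BOTH_GROW}

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            state_diagram([], [0.0])


class TestSimulateRadius:
    def test_fixed_point_stays_constant(self):
        p = params(gamma=1.0, p_l=2.0)  # R_crit = 1
        t, r, status = simulate_radius(1.0, p, dt=0.01, t_end=1.0)
        np.testing.assert_allclose(r, 1.0, rtol=1e-9)
        assert status == "ok"

    def test_supercritical_grows_with_asymptotic_slope(self):
        p = params(gamma=1.0, p_l=2.0, alpha=1.0)
        t, r, status = simulate_radius(1.1, p, dt=0.01, t_end=50.0)
        assert status == "ok"
        assert np.all(np.diff(r) > 0)
        # at t = 50 the radius is ~100, so dR/dt = 2 - 2/R is within ~1% of
        # the asymptote P_L/alpha
        slope = (r[-1] - r[-10]) / (t[-1] - t[-10])
        assert slope == pytest.approx(p.p_l / p.alpha, rel=0.02)

    def test_subcritical_collapses(self):
        p = params(gamma=1.0, p_l=2.0)
        t, r, status = simulate_radius(0.9, p, dt=0.001, t_end=10.0)
        assert status == "collapsed"
        assert np.all(np.diff(r) <= 0)
        assert r[-1] == pytest.approx(0.9 * 1e-3)

    def test_matches_fine_reference_integration(self):
        """The adaptive integrator agrees with an independent very-fine-step
        Euler reference."""
        p = params(gamma=1.0, p_l=2.0, alpha=2.0)
        r0, t_end = 1.5, 2.0
        t, r, _ = simulate_radius(r0, p, dt=0.1, t_end=t_end)
        # independent reference
        steps = 400_000
        dt_ref = t_end / steps
        rr = r0
        for _ in range(steps):
            rr += dt_ref * (p.p_l - 2 * p.gamma / rr) / p.alpha
        assert r[-1] == pytest.approx(rr, rel=1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            simulate_radius(0.0, params(p_l=1.0), 0.1, 1.0)
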