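"""Median-split annotation, compartment fractions, background subtraction
and angular profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periquant import signaling
from periquant.errors import ValidationError
from periquant.model import CellRecord, Tissue
from periquant.synthetic import GradientSpec, make_signaling_frame


def cells_from_values(values, reference=1.0):
    return [
        CellRecord(
            f"c{i}", Tissue.EPI, [0, 0, 0],
            intensities={"marker": float(v), "hoechst": float(reference)},
        )
        for i, v in enumerate(values)
    ]


class TestAnnotateHigh:
    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.integers(1, 10**6), min_size=2, max_size=40, unique=True))
    def test_high_count_matches_order_statistics(self, values):
        """With distinct well-separated values: #\\{v > median\\} = n/2 for
        even n, (n-1)/2 for odd n. (Integer-valued inputs keep the two-middle
        mean exactly representable; adjacent floats can round their midpoint
        onto the upper value and defeat the strict inequality.)"""
        values = [float(v) for v in values]
        ann = signaling.annotate_high(cells_from_values(values), "marker")
        n = len(values)
        expected = n // 2 if n % 2 == 0 else (n - 1) // 2
        assert sum(a.is_high for a in ann) == expected

    def test_all_equal_values_none_high(self):
        ann = signaling.annotate_high(cells_from_values([5.0] * 7), "marker")
        assert sum(a.is_high for a in ann) == 0

    def test_scale_invariance_of_split(self):
        values = [1.0, 2.0, 3.0, 10.0]
        a1 = signaling.annotate_high(cells_from_values(values), "marker")
        a2 = signaling.annotate_high(cells_from_values(values, reference=2.0), "marker")
        assert [a.is_high for a in a1] == [a.is_high for a in a2]
        for x, y in zip(a1, a2):
            assert y.normalized == pytest.approx(x.normalized / 2.0)

    def test_zero_reference_cell_excluded_with_warning(self, caplog):
        cells = cells_from_values([1.0, 2.0, 3.0])
        cells.append(
            CellRecord("bad", Tissue.EPI, [0, 0, 0],
                       intensities={"marker": 1.0, "hoechst": 0.0})
        )
        with caplog.at_level("WARNING"):
            ann = signaling.annotate_high(cells, "marker")
        assert len(ann) == 3
        assert "excluded" in caplog.text

    def test_missing_channel_raises(self):
        cells = [CellRecord("c", Tissue.EPI, [0, 0, 0], intensities={"marker": 1.0})]
        with pytest.raises(ValidationError, match="missing channel"):
            signaling.annotate_high(cells, "marker")


class TestProximalDistalFractions:
    def test_gradient_recovered(self):
        spec = GradientSpec(seed=0, n_epi=300, high_fraction_proximal=0.8,
                            high_fraction_distal=0.2, noise_cv=0.0)
        frame, _ = make_signaling_frame(spec)
        ann = signaling.annotate_high(frame.select(Tissue.EPI), "marker")
        prox, dist = signaling.proximal_distal_fractions(frame, ann)
        assert prox > dist

    def test_uniform_probability_small_difference(self):
        """Under a flat gradient the two halves differ only by sampling
        noise: mean |Δ| < 5 points at n = 400 over 100 seeds."""
        deltas = []
        for seed in range(100):
            spec = GradientSpec(seed=seed, n_epi=400, high_fraction_proximal=0.5,
                                high_fraction_distal=0.5, noise_cv=0.05)
            frame, _ = make_signaling_frame(spec)
            ann = signaling.annotate_high(frame.select(Tissue.EPI), "marker")
            prox, dist = signaling.proximal_distal_fractions(frame, ann)
            deltas.append(abs(prox - dist))
        assert np.mean(deltas) < 5.0

    def test_trim_zero_identical_to_untrimmed(self):
        spec = GradientSpec(seed=1, n_epi=100)
        frame, _ = make_signaling_frame(spec)
        ann = signaling.annotate_high(frame.select(Tissue.EPI), "marker")
        untrimmed = signaling.proximal_distal_fractions(frame, ann, trim=False)
        trimmed0 = signaling.proximal_distal_fractions(
            frame, ann, trim=True, trim_fraction=0.0
        )
        assert untrimmed == trimmed0

    def test_trim_removes_lateral_extremes(self):
        spec = GradientSpec(seed=2, n_epi=50)
        frame, _ = make_signaling_frame(spec)
        ann = signaling.annotate_high(frame.select(Tissue.EPI), "marker")
        signaling.proximal_distal_fractions(frame, ann, trim=True, trim_fraction=0.2)
        trimmed = [a for a in ann if a.compartment is signaling.Compartment.TRIMMED]
        assert len(trimmed) == 2 * int(0.2 * len(ann))
        # trimmed cells are the lateral extremes of the first in-plane coord
        by_id = {c.cell_id: c for c in frame.select(Tissue.EPI)}
        lat = {a.cell_id: frame.frame_coords(by_id[a.cell_id].position)[0] for a in ann}
        kept = [lat[a.cell_id] for a in ann if a.compartment is not signaling.Compartment.TRIMMED]
        cut = [lat[a.cell_id] for a in trimmed]
        assert all(c <= min(kept) or c >= max(kept) for c in cut)

    def test_too_few_cells_after_trim_rejected(self):
        # floor(0.45 * 3) = 1 removed per side leaves a single cell
        spec = GradientSpec(seed=3, n_epi=3)
        frame, _ = make_signaling_frame(spec)
        ann = signaling.annotate_high(frame.select(Tissue.EPI), "marker")
        with pytest.raises(ValidationError):
            signaling.proximal_distal_fractions(frame, ann, trim=True, trim_fraction=0.45)


class TestRollingBall:
    def test_constant_image_goes_to_zero(self):
        img = np.full((64, 64), 37.0)
        out = signaling.rolling_ball_background(img, 10)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_small_bright_spot_preserved(self):
        img = np.full((220, 220), 50.0)
        img[110:113, 110:113] += 400.0
        out = signaling.rolling_ball_background(img, 100)
        assert out[111, 111] == pytest.approx(400.0, rel=0.01)
        assert abs(out[20, 20]) < 1.0

    def test_output_never_negative(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, size=(50, 50))
        out = signaling.rolling_ball_background(img, 5)
        assert out.min() >= 0.0

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValidationError):
            signaling.rolling_ball_background(np.zeros((10, 10)), 100)


class TestAngularProfile:
    def test_uniform_channels_zero_deviation(self):
        img = np.full((101, 101), 10.0)
        prof = signaling.angular_profile(img, img.copy(), (50, 50), 40)
        np.testing.assert_allclose(prof.ratio_deviation, 0.0, atol=1e-12)

    def test_deviations_mean_zero_exactly(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(1, 10, size=(101, 101))
        b = rng.uniform(1, 10, size=(101, 101))
        prof = signaling.angular_profile(a, b, (50, 50), 40)
        assert prof.ratio_deviation.mean() == pytest.approx(0.0, abs=1e-12)

    def test_bright_sector_positive_deviation(self):
        h = w = 201
        yy, xx = np.mgrid[:h, :w]
        center = (100, 100)
        img = np.full((h, w), 10.0)
        # bright wedge "up and slightly right": rows above center, |dx| small
        wedge = (yy < 95) & (np.abs(xx - 100) < (100 - yy) * 0.3)
        img[wedge] += 50.0
        ref = np.full((h, w), 10.0)
        prof = signaling.angular_profile(img, ref, center, 80)
        dev = prof.ratio_deviation
        in_sector = np.r_[dev[:17], dev[343:]]
        out_sector = dev[60:300]
        assert in_sector.mean() > 0
        assert out_sector.mean() < in_sector.mean()

    def test_rotating_both_images_shifts_profile(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(1, 10, size=(101, 101))
        b = np.full((101, 101), 3.0)
        prof = signaling.angular_profile(a, b, (50, 50), 40)
        # np.rot90 rotates counterclockwise; in image coords ("up" toward
        # row 0) the content moves 90 deg clockwise, shifting the profile
        a_rot = np.rot90(a)
        prof_rot = signaling.angular_profile(a_rot, b, (50, 50), 40)
        shifted = np.roll(prof.ratio_deviation, 90)
        candidates = [
            np.max(np.abs(prof_rot.ratio_deviation - np.roll(prof.ratio_deviation, k)))
            for k in (90, -90)
        ]
        assert min(candidates) < 1e-6

    def test_ray_truncation_warns_and_counts_valid_pixels(self, caplog):
        img = np.full((41, 41), 2.0)
        with caplog.at_level("WARNING"):
            prof = signaling.angular_profile(img, img.copy(), (20, 20), 60)
        assert "truncated" in caplog.text
        np.testing.assert_allclose(prof.ratio_deviation, 0.0, atol=1e-12)

    def test_center_outside_image_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValidationError):
            signaling.angular_profile(img, img, (50, 50), 5)


class TestGroundTruthCoverage:
    def test_half_counts_within_binomial_interval(self):
        """Per-seed high-state counts in each half (ground-truth states at
        constant p = 0.5) fall inside the central 95% binomial interval in
        >= 90% of 200 seeds."""
        from scipy.stats import binom

        hits = 0
        trials = 0
        for seed in range(200):
            spec = GradientSpec(seed=seed, n_epi=120, high_fraction_proximal=0.5,
                                high_fraction_distal=0.5, noise_cv=0.0)
            frame, states = make_signaling_frame(spec)
            axial = np.array([frame.frame_coords(c.position)[2] for c in frame.cells])
            mid = 0.5 * (axial.min() + axial.max())
            for half in (axial > mid, axial <= mid):
                n = int(half.sum())
                if n == 0:
                    continue
                k = int(states[half].sum())
                lo, hi = binom.ppf(0.025, n, 0.5), binom.ppf(0.975, n, 0.5)
                trials += 1
                hits += int(lo <= k <= hi)
        assert hits / trials >= 0.90
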