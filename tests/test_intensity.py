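"""Background correction, normalization, filters and ratio statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spindlekin.congression import AnalysisConfig
from spindlekin.intensity import (IntensitySample, corrected_intensity,
                                  gradient_regression, normalize_to_reference,
                                  normalized_value, pole_exclusion_filter,
                                  pole_ratio, polar_vs_aligned_ratio)
from spindlekin.synthetic import (get_preset, simulate_cell,
                                  simulate_intensities)


def make_sample(**kw) -> IntensitySample:
    base = dict(cell_id="c", roi_id="r", channel_label="pAurB",
                roi_kind="kinetochore_pair", mean_signal=150.0,
                background_mean=30.0, reference_mean=270.0, n_z_planes=6,
                location_class="polar", dist_to_nearest_pole=2.0,
                dist_to_plane=4.0)
    base.update(kw)
    return IntensitySample(**base)


class TestCorrectedIntensity:
    def test_simple_subtraction(self):
        assert corrected_intensity(make_sample()).value == pytest.approx(120.0)

    def test_integrated_per_plane_scaling(self):
        s = make_sample(mean_signal=1200.0, background_mean=30.0,
                        n_z_planes=6, is_integrated=True)
        assert corrected_intensity(s).value == pytest.approx(170.0)

    def test_clamped_at_zero_with_flag(self):
        s = make_sample(mean_signal=150.0, background_mean=200.0)
        out = corrected_intensity(s)
        assert out.value == 0.0 and out.clipped

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            make_sample(mean_signal=-1.0)


class TestNormalization:
    def test_examples(self):
        assert normalize_to_reference(120, 240) == pytest.approx(0.5)
        assert normalize_to_reference(0, 240) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference(120, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(c=st.floats(min_value=1e-3, max_value=1e4, allow_nan=False))
    def test_scale_invariance(self, c):
        """Multiplying signal, background and reference by c > 0 leaves the
        normalized value unchanged."""
        v0 = normalized_value(make_sample())
        sc = make_sample(mean_signal=150 * c, background_mean=30 * c,
                         reference_mean=270 * c)
        assert normalized_value(sc) == pytest.approx(v0, rel=1e-9)


class TestPoleExclusion:
    def test_boundary_excluded(self, cfg):
        samples = [make_sample(roi_id=f"r{d}", dist_to_nearest_pole=d)
                   for d in (0.8, 1.0, 1.2)]
        kept, removed = pole_exclusion_filter(samples, cfg)
        assert [s.dist_to_nearest_pole for s in kept] == [1.2]
        assert removed == 2

    def test_empty_input(self, cfg):
        assert pole_exclusion_filter([], cfg) == ([], 0)

    def test_radius_zero_removes_nothing(self):
        cfg0 = AnalysisConfig(pole_exclusion_radius=0.0)
        samples = [make_sample(roi_id=f"r{d}", dist_to_nearest_pole=d)
                   for d in (0.3, 0.9)]
        kept, removed = pole_exclusion_filter(samples, cfg0)
        assert removed == 0 and len(kept) == 2

    def test_idempotent(self, cfg):
        samples = [make_sample(roi_id=f"r{i}", dist_to_nearest_pole=d)
                   for i, d in enumerate((0.5, 1.5, 2.5, 0.9))]
        once, _ = pole_exclusion_filter(samples, cfg)
        twice, removed2 = pole_exclusion_filter(once, cfg)
        assert twice == once and removed2 == 0


def pole_sample(cls, signal, cell="c"):
    return make_sample(cell_id=cell, roi_id=f"{cls}_{signal}", roi_kind="pole",
                       channel_label="pAurA", mean_signal=signal,
                       background_mean=0.0, reference_mean=None,
                       location_class=cls, dist_to_nearest_pole=0.0)


class TestPoleRatio:
    def test_centriolar_over_acentriolar(self):
        r = pole_ratio([pole_sample("pole_centriolar", 400),
                        pole_sample("pole_acentriolar", 100)])
        assert r.value == pytest.approx(4.0) and not r.symmetric_pair

    def test_equal_symmetric_poles(self):
        r = pole_ratio([pole_sample("pole_centriolar", 250),
                        pole_sample("pole_centriolar", 250)])
        assert r.value == pytest.approx(1.0) and r.symmetric_pair

    def test_zero_acentriolar_rejected(self):
        with pytest.raises(ValueError):
            pole_ratio([pole_sample("pole_centriolar", 400),
                        pole_sample("pole_acentriolar", 0.0)])

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            pole_ratio([pole_sample("pole_centriolar", 400)])

    def test_zero_noise_generator_ratio_is_inverse_rho(self, cfg):
        """On noiseless generator output the 1:0 pole ratio is exactly
        1/rho (the acentriolar amplitude factor)."""
        preset = get_preset("cenpe_inhibited_1v0").zero_noise()
        cell, _ = simulate_cell(preset, 5)
        samples = simulate_intensities(preset, cell, 5)
        assert pole_ratio(samples).value == pytest.approx(
            1.0 / preset.acentriolar_factor, abs=1e-12)


class TestPolarVsAligned:
    def test_simple_ratio(self):
        samples = [
            make_sample(roi_id="p1", location_class="polar",
                        mean_signal=30 + 240 * 2, reference_mean=270),
            make_sample(roi_id="a1", location_class="aligned",
                        mean_signal=30 + 240 * 1, reference_mean=270),
        ]
        assert polar_vs_aligned_ratio(samples) == pytest.approx(2.0)

    def test_single_polar_matching_aligned(self):
        samples = [
            make_sample(roi_id="p1", location_class="polar",
                        mean_signal=30 + 240 * 0.9),
            make_sample(roi_id="a1", location_class="aligned",
                        mean_signal=30 + 240 * 0.9),
        ]
        assert polar_vs_aligned_ratio(samples) == pytest.approx(1.0)

    def test_missing_class_skips_cell(self):
        samples = [make_sample(roi_id="p1", location_class="polar")]
        assert polar_vs_aligned_ratio(samples) is None

    def test_identical_distributions_give_unit_ratio_in_expectation(self):
        """Over 200 simulated cells with polar and aligned values drawn from
        the same distribution, the mean ratio is 1 within 0.05."""
        rng = np.random.default_rng(77)
        ratios = []
        for _ in range(200):
            cells = []
            for cls, n in (("polar", 3), ("aligned", 5)):
                for i in range(n):
                    v = rng.normal(1.0, 0.1)
                    cells.append(make_sample(
                        roi_id=f"{cls}{i}", location_class=cls,
                        mean_signal=30 + 240 * max(v, 0.1)))
            ratios.append(polar_vs_aligned_ratio(cells))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)


class TestGradientRegression:
    def _line_samples(self, pairs):
        return [make_sample(roi_id=f"g{i}", dist_to_nearest_pole=d,
                            mean_signal=30 + 240 * v)
                for i, (d, v) in enumerate(pairs)]

    def test_exact_line(self, cfg):
        fit = gradient_regression(
            self._line_samples([(1.5, 9), (2.5, 8), (3.5, 7)]), cfg)
        assert fit.slope == pytest.approx(-1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_intensity(self, cfg):
        fit = gradient_regression(
            self._line_samples([(1.5, 4), (2.5, 4), (3.5, 4)]), cfg)
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == 0.0

    def test_too_few_samples_after_filter(self, cfg):
        with pytest.raises(ValueError, match=">= 3"):
            gradient_regression(
                self._line_samples([(0.5, 9), (0.8, 8), (3.5, 7)]), cfg)

    def test_generator_gradient_negative_slope(self, cfg):
        """Kinetochore phospho-intensity decreases with pole distance in
        >= 95% of seeded CENP-E-inhibited runs."""
        preset = get_preset("cenpe_inhibited_2v2")
        neg = 0
        for seed in range(100):
            cell, _ = simulate_cell(preset, 20_000 + seed)
            samples = simulate_intensities(preset, cell, 20_000 + seed)
            fit = gradient_regression(samples, cfg)
            neg += fit.slope < 0
        assert neg >= 95
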