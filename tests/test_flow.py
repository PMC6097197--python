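"""Flow quantification: geometry, profile caliper, conversion,
per-vessel flow and aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import retperf as rp
from retperf.errors import (
    AmbiguousProfileError,
    EmptyAccountingError,
    InvalidParameterError,
    NoVesselError,
    OutOfBoundsError,
)

from conftest import gaussian_dip_profile


def brute_force_intersections(centerline, radius=1.25, n_dense=20000):
    """Independent crossing oracle: dense resampling of the polyline and
    sign changes of (r - radius)."""
    pts = np.asarray(centerline, float)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0], np.cumsum(seg_len)])
    dense_s = np.linspace(0, s[-1], n_dense)
    xs = np.interp(dense_s, s, pts[:, 0])
    ys = np.interp(dense_s, s, pts[:, 1])
    r = np.hypot(xs, ys) - radius
    idx = np.flatnonzero(np.sign(r[:-1]) * np.sign(r[1:]) < 0)
    crossings = []
    for i in idx:
        t = r[i] / (r[i] - r[i + 1])
        crossings.append(dense_s[i] + t * (dense_s[i + 1] - dense_s[i]))
    return crossings


class TestCircleCrossings:
    def test_radial_vessel_crosses_once_with_inward_tangent(self):
        v = rp.VesselSegment("a", "arteriole",
                             [(2.0, 0.0), (0.5, 0.0)], -3.0)
        (c,) = rp.detect_circle_crossings([v])
        assert c.point_mm == pytest.approx((1.25, 0.0))
        assert c.tangent == pytest.approx((-1.0, 0.0))
        assert c.n_intersections == 1

    def test_chord_vessel_two_intersections_one_retained(self):
        v = rp.VesselSegment("c", "venule", [(-2.0, 1.0), (2.0, 1.0)], 2.0)
        hits = rp.polyline_circle_intersections(v.centerline)
        assert len(hits) == 2
        x = math.sqrt(1.25 ** 2 - 1.0)
        assert sorted(h[1][0] for h in hits) == pytest.approx([-x, x])
        crossings = rp.detect_circle_crossings([v])
        assert len(crossings) == 1
        assert crossings[0].n_intersections == 2

    def test_vessel_wholly_inside_has_no_crossing(self):
        v = rp.VesselSegment("i", "venule", [(0.2, 0.2), (0.6, -0.3)], 2.0)
        assert rp.detect_circle_crossings([v]) == []

    def test_empty_vessel_list_gives_empty_result(self):
        assert rp.detect_circle_crossings([]) == []

    def test_outermost_crossing_retained_for_reversed_polyline(self):
        # same chord traversed both ways: the retained crossing must sit
        # nearest the endpoint farther from the fovea
        pts = [(-2.0, 1.0), (2.0, 1.1)]
        fwd = rp.VesselSegment("f", "venule", pts, 2.0)
        rev = rp.VesselSegment("r", "venule", pts[::-1], 2.0)
        (cf,) = rp.detect_circle_crossings([fwd])
        (cr,) = rp.detect_circle_crossings([rev])
        assert np.hypot(*cf.point_mm) == pytest.approx(1.25, abs=1e-9)
        assert np.hypot(*cr.point_mm) == pytest.approx(1.25, abs=1e-9)

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            net = rp.generate_vessel_network(
                3, 3, seed=int(rng.integers(2 ** 31))
            )
            for v in net:
                exact = rp.polyline_circle_intersections(v.centerline)
                brute = brute_force_intersections(v.centerline)
                assert len(exact) == len(brute)
                for (s_e, _, _), s_b in zip(exact, brute):
                    assert s_e == pytest.approx(s_b, abs=1e-3)

    def test_nonpositive_circle_rejected(self):
        with pytest.raises(InvalidParameterError):
            rp.detect_circle_crossings([], circle_diameter_mm=0)


class TestExtractProfile:
    def _image(self, pixels):
        n = pixels.shape[0]
        return rp.FundusImage(pixels, 4.3 / n,
                              ((n - 1) / 2, (n - 1) / 2), 20)

    def test_constant_image_gives_constant_profile(self):
        img = self._image(np.full((512, 512), 0.7))
        pos, prof = rp.extract_profile(img, (0.3, -0.2), (0.0, 1.0))
        assert np.allclose(prof, 0.7)
        assert pos[len(pos) // 2] == 0.0
        assert np.allclose(np.diff(pos), img.mm_per_px * 1000)

    def test_vertical_vessel_gives_symmetric_centered_dip(self):
        n = 512
        mm = 4.3 / n
        cols = np.arange(n)
        x_mm = (cols - (n - 1) / 2) * mm
        sigma = 0.06 / rp.FWHM_PER_SIGMA
        row = 1.0 - 0.5 * np.exp(-x_mm ** 2 / (2 * sigma ** 2))
        img = self._image(np.tile(row, (n, 1)))
        pos, prof = rp.extract_profile(img, (0.0, 0.0), (0.0, 1.0))
        assert prof[np.argmin(np.abs(pos))] == pytest.approx(prof.min())
        assert np.allclose(prof, prof[::-1], atol=1e-9)

    def test_rendered_vessel_profile_depth_matches_contrast(self):
        v = rp.VesselGroundTruth(
            "a", "arteriole", [(2.0, 0.0), (0.5, 0.0)], -3.0,
            true_diameter_um=60.0, contrast=0.55,
        )
        img = rp.render_fundus([v], 20, 1024, 0.0)
        pos, prof = rp.extract_profile(img, (1.25, 0.0), (-1.0, 0.0))
        depth = prof.max() - prof.min()
        assert depth == pytest.approx(
            0.55 * rp.synth.BACKGROUND_INTENSITY, rel=0.02
        )

    def test_window_leaving_image_raises(self):
        img = self._image(np.full((512, 512), 0.7))
        with pytest.raises(OutOfBoundsError):
            rp.extract_profile(img, (2.1, 0.0), (0.0, 1.0),
                               half_length_um=300)


class TestFwhmDiameter:
    def test_gaussian_dip_closed_form(self):
        # sigma = 12.74 um -> FWHM = 2*sqrt(2 ln 2)*sigma = 30.0 um
        sigma = 30.0 / rp.FWHM_PER_SIGMA
        assert sigma == pytest.approx(12.739, abs=1e-3)
        pos, prof = gaussian_dip_profile(30.0, 3.0)
        assert rp.fwhm_diameter(pos, prof) == pytest.approx(30.0, abs=0.15)

    def test_top_hat_width_preserved(self):
        pitch = 5.0
        pos = np.arange(-30, 31) * pitch
        prof = np.ones_like(pos, dtype=float)
        prof[(pos >= -20) & (pos < 20)] = 0.4  # 8 samples wide
        est = rp.fwhm_diameter(pos, prof)
        assert abs(est - 40.0) <= pitch

    def test_flat_profile_raises_no_vessel(self):
        pos = np.arange(-30, 31) * 5.0
        with pytest.raises(NoVesselError):
            rp.fwhm_diameter(pos, np.ones_like(pos, dtype=float))

    def test_dip_below_noise_threshold_raises(self):
        rng = np.random.default_rng(0)
        pos = np.arange(-40, 41) * 5.0
        prof = 1.0 + rng.normal(0, 0.05, pos.size)
        prof[40] -= 0.08  # dip shallower than 3x noise SD
        with pytest.raises(NoVesselError):
            rp.fwhm_diameter(pos, prof)

    def test_two_substantial_dips_raise_ambiguous(self):
        pos, prof = gaussian_dip_profile(40.0, 4.0)
        sigma = 40.0 / rp.FWHM_PER_SIGMA
        prof -= 0.45 * np.exp(-(pos - 120) ** 2 / (2 * sigma ** 2))
        with pytest.raises(AmbiguousProfileError):
            rp.fwhm_diameter(pos, prof)

    def test_pixel_count_mode_within_one_sample(self):
        pos, prof = gaussian_dip_profile(60.0, 5.0)
        est = rp.fwhm_diameter(pos, prof, mode="pixel_count")
        assert abs(est - 60.0) <= 5.0

    @pytest.mark.parametrize("diameter", [20.0, 60.0, 120.0])
    @pytest.mark.parametrize("scale", [3.0, 8.0, 15.0])
    def test_unbiased_across_diameters_and_scales(self, diameter, scale):
        pos, prof = gaussian_dip_profile(diameter, scale)
        est = rp.fwhm_diameter(pos, prof)
        assert abs(est - diameter) < 0.5 * scale


class TestConvertFov:
    @pytest.mark.parametrize("v,kind,setting,expected", [
        (-2.0, "arteriole", 35, -1.90),
        (1.0, "venule", 35, 0.92),
        (1.0, "venule", 20, 1.0),
        (-3.0, "arteriole", 20, -3.0),
    ])
    def test_conversion_factors(self, v, kind, setting, expected):
        assert rp.convert_fov(v, kind, setting) == pytest.approx(expected)

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidParameterError):
            rp.convert_fov(1.0, "capillary", 35)

    def test_identity_setting_is_idempotent(self):
        v = rp.convert_fov(-2.0, "arteriole", 35)
        assert rp.convert_fov(v, "arteriole", 20) == v


class TestVesselFlow:
    def test_closed_form_cylinder_flux(self):
        # pi * 0.05^2 mm^2 * 1 mm/s * 1000 = 7.854 nl/s
        assert rp.vessel_flow(1.0, 100.0) == pytest.approx(7.854, abs=5e-4)

    def test_zero_velocity_gives_zero_flow(self):
        assert rp.vessel_flow(0.0, 80.0) == 0.0

    def test_doubling_diameter_quadruples_flow(self):
        assert rp.vessel_flow(2.0, 80.0) == pytest.approx(
            4 * rp.vessel_flow(2.0, 40.0)
        )

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            rp.vessel_flow(1.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(v=st.floats(-10, 10, allow_nan=False),
           d=st.floats(10, 200))
    def test_flow_invariant_to_velocity_sign(self, v, d):
        assert rp.vessel_flow(v, d) == rp.vessel_flow(-v, d)
        assert rp.vessel_flow(v, d) >= 0

    def test_profile_correction_scales_linearly(self):
        assert rp.vessel_flow(1.0, 100.0, profile_correction=0.5) \
            == pytest.approx(rp.vessel_flow(1.0, 100.0) / 2)


def _cm(vid, kind, flow):
    return rp.CrossingMeasurement(vid, kind, (1.25, 0.0), (1.0, 0.0),
                                  60.0, 2.0, flow)


class TestAggregateMacularFlow:
    def test_macular_flow_is_mean_of_side_totals(self):
        res = rp.aggregate_macular_flow([
            _cm("a1", "arteriole", 1.5), _cm("a2", "arteriole", 2.5),
            _cm("v1", "venule", 4.2),
        ])
        assert res.arteriolar_total_nl_s == pytest.approx(4.0)
        assert res.venular_total_nl_s == pytest.approx(4.2)
        assert res.macular_flow_nl_s == pytest.approx(4.1)
        assert not res.one_sided

    def test_balanced_sides_have_zero_imbalance(self):
        res = rp.aggregate_macular_flow([
            _cm("a", "arteriole", 3.0), _cm("v", "venule", 3.0),
        ])
        assert res.macular_flow_nl_s == pytest.approx(3.0)
        assert res.imbalance == pytest.approx(0.0)

    def test_no_crossings_raises_empty_accounting(self):
        with pytest.raises(EmptyAccountingError):
            rp.aggregate_macular_flow([])

    def test_one_sided_accounting_warns_and_falls_back(self):
        with pytest.warns(UserWarning, match="one-sided"):
            res = rp.aggregate_macular_flow([_cm("a", "arteriole", 3.3)])
        assert res.one_sided
        assert res.macular_flow_nl_s == pytest.approx(3.3)

    def test_flow_monotone_in_velocity_and_diameter(self, noiseless_scene):
        # raising any one vessel's |velocity| cannot lower macular flow
        scene = noiseless_scene
        base = rp.measure_macular_flow(scene.image, scene.vessels)
        import dataclasses
        boosted = [dataclasses.replace(
            v, velocity_mm_s=v.velocity_mm_s * (1.5 if i == 0 else 1.0),
            centerline=v.centerline.copy())
            for i, v in enumerate(scene.vessels)]
        res = rp.measure_macular_flow(scene.image, boosted)
        assert res.macular_flow_nl_s >= base.macular_flow_nl_s
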