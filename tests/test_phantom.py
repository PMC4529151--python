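import math

import numpy as np
import pandas as pd
import pytest

import rpcsvoct as r
from rpcsvoct.phantom import (REGION_ANGLES, SpeckleParams, max_capillaries,
                              generate_study_table)


def perpendicular_offsets(network):
    """Project capillary line centers onto the perpendicular axis."""
    a = math.radians(network.dominant_angle)
    p = np.array([-math.sin(a), math.cos(a)])
    offs = [float(c[:, :2].mean(axis=0) @ p) for c in network.capillaries]
    return np.sort(np.asarray(offs))


def segment_line_crossings(network, center, angle_deg, length_um):
    """Brute-force count of capillary polylines intersecting a segment."""
    a = math.radians(angle_deg)
    u = np.array([math.cos(a), math.sin(a)])
    q0 = np.asarray(center) - u * length_um / 2
    q1 = np.asarray(center) + u * length_um / 2
    def _seg_intersect(p0, p1):
        d1, d2 = p1 - p0, q1 - q0
        denom = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(denom) < 1e-12:
            return False
        dp = q0 - p0
        t = (dp[0] * d2[1] - dp[1] * d2[0]) / denom
        s = (dp[0] * d1[1] - dp[1] * d1[0]) / denom
        return 0 <= t <= 1 and 0 <= s <= 1
    count = 0
    for c in network.capillaries:
        pts = c[:, :2]
        if any(_seg_intersect(pts[j], pts[j + 1])
               for j in range(len(pts) - 1)):
            count += 1
    return count


class TestGenerateNetwork:
    def test_parallel_spacing_recovered(self):
        net = r.generate_network("Temp", 35.0, 5.0, 18, 0.0, seed=1,
                                 fov_um=700.0)
        assert len(net.capillaries) == 18
        gaps = np.diff(perpendicular_offsets(net))
        assert gaps.mean() == pytest.approx(35.0, abs=0.7)
        assert np.allclose(gaps, 35.0, atol=1e-6)

    def test_deterministic_per_seed(self):
        a = r.generate_network("Temp", 35.0, 5.0, 12, 0.3, seed=1)
        b = r.generate_network("Temp", 35.0, 5.0, 12, 0.3, seed=1)
        for ca, cb in zip(a.capillaries, b.capillaries):
            assert np.array_equal(ca, cb)
        c = r.generate_network("Temp", 35.0, 5.0, 12, 0.3, seed=2)
        assert not all(np.array_equal(x, y)
                       for x, y in zip(a.capillaries, c.capillaries))

    def test_denser_spacing_gives_more_crossings(self):
        # brute-force segment-line intersection oracle on a fixed
        # perpendicular line through the FOV center
        st = r.generate_network("ST", 30.0, 5.0,
                                max_capillaries("ST", 30.0), 0.0, seed=3)
        sup = r.generate_network("Sup", 40.0, 5.0,
                                 max_capillaries("Sup", 40.0), 0.0, seed=3)
        length = 500.0
        n_st = segment_line_crossings(
            st, (318.25, 318.25), REGION_ANGLES["ST"] + 90.0, length)
        n_sup = segment_line_crossings(
            sup, (318.25, 318.25), REGION_ANGLES["Sup"] + 90.0, length)
        assert n_st > n_sup

    def test_overfull_fov_raises_with_max_count(self):
        with pytest.raises(ValueError, match=r"at most \d+"):
            r.generate_network("Temp", 60.0, 5.0, 40, 0.0, seed=0)

    def test_points_inside_fov_and_angle_exact(self):
        for region in ("Temp", "ST", "Sup", "IT"):
            net = r.generate_network(region, 35.0, 5.0, 10, 0.0, seed=5)
            for c in net.capillaries:
                assert np.all(c[:, :2] >= 0) and np.all(c[:, :2] <= net.fov_um)
            assert net.measured_dominant_angle() == pytest.approx(
                REGION_ANGLES[region] % 180.0, abs=1e-6)

    def test_wavy_network_angle_near_nominal(self):
        net = r.generate_network("ST", 35.0, 5.0, 12, 0.2, seed=7)
        assert net.measured_dominant_angle() == pytest.approx(45.0, abs=5.0)

    def test_requires_spacing_above_diameter(self):
        with pytest.raises(ValueError):
            r.generate_network("Temp", 4.0, 5.0, 3, 0.0, seed=0)


class TestRenderHistology:
    def test_single_bar_width(self):
        net = r.generate_network("Temp", 40.0, 5.0, 1, 0.0, seed=0)
        img = r.render_histology(net, pixel_um=1.0, psf_fwhm_um=0.0)
        mask = img.pixels >= 0.5
        widths = mask.sum(axis=0)
        mid = widths[widths > 0]
        assert np.median(mid) == pytest.approx(5.0, abs=1.0)

    def test_area_matches_analytic_tubes(self):
        net = r.generate_network("ST", 35.0, 5.0, 12, 0.0, seed=2)
        img = r.render_histology(net, pixel_um=1.0, psf_fwhm_um=0.0)
        analytic = sum(
            d * np.hypot(*np.diff(c[:, :2], axis=0).T).sum()
            for c, d in zip(net.capillaries, net.diameters))
        assert img.pixels.sum() == pytest.approx(analytic, rel=0.03)

    def test_render_is_deterministic(self):
        net = r.generate_network("IT", 35.0, 5.0, 10, 0.3, seed=4)
        a = r.render_histology(net, 1.0, 0.5)
        b = r.render_histology(net, 1.0, 0.5)
        assert np.array_equal(a.pixels, b.pixels)


class TestRenderOCTVolume:
    def test_no_flow_no_noise_gives_zero_variance(self, st_network,
                                                  flat_layers,
                                                  small_geometry):
        params = SpeckleParams(seed=1, flow_decorrelation=0.0,
                               noise_floor=0.0)
        vol, _ = r.render_oct_volume(st_network, flat_layers,
                                     small_geometry, params)
        assert np.array_equal(vol.intensity[0], vol.intensity[1])
        sv = r.speckle_variance(vol)
        assert np.all(sv.sv == 0.0)

    def test_flow_contrast_exceeds_static_over_seeds(self):
        # Monte-Carlo over 10 seeds on a reduced grid
        geom = r.ScanGeometry(n_fast=80, n_slow=80, fov_um=370.0,
                              n_depth=80, depth_pixel_um=2.0)
        layers = r.generate_layers(geom, ilm_um=40.0, rnfl_um=60.0,
                                   rpe_um=130.0)
        net = r.generate_network("ST", 35.0, 5.0, 8, 0.0, seed=0,
                                 fov_um=370.0)
        ratios = []
        for seed in range(10):
            vol, truth = r.render_oct_volume(net, layers, geom,
                                             SpeckleParams(seed=seed))
            sv = r.speckle_variance(vol)
            flow = truth["flow_mask"]
            ratios.append(sv.sv[flow].mean() / sv.sv[~flow].mean())
        assert np.mean(ratios) > 5.0

    def test_flow_volume_conservation(self, st_network, flat_layers,
                                      small_geometry, default_render):
        _, truth = default_render
        vox = (small_geometry.pixel_slow_um * small_geometry.depth_pixel_um
               * small_geometry.pixel_um)
        analytic = sum(
            math.pi * (d / 2) ** 2
            * np.hypot(*np.diff(c[:, :2], axis=0).T).sum()
            for c, d in zip(st_network.capillaries, st_network.diameters))
        rasterized = truth["flow_fraction"].sum() * vox
        assert rasterized == pytest.approx(analytic, rel=0.03)

    def test_variance_monotone_in_decorrelation(self):
        geom = r.ScanGeometry(n_fast=60, n_slow=60, fov_um=280.0,
                              n_depth=70, depth_pixel_um=2.0)
        layers = r.generate_layers(geom, ilm_um=40.0, rnfl_um=60.0,
                                   rpe_um=120.0)
        net = r.generate_network("ST", 35.0, 5.0, 6, 0.0, seed=0,
                                 fov_um=280.0)
        grid = [0.1, 0.3, 0.5, 0.7, 0.9]
        means = []
        for fd in grid:
            vals = []
            for seed in range(5):
                params = SpeckleParams(seed=seed, flow_decorrelation=fd,
                                       noise_floor=0.0)
                vol, truth = r.render_oct_volume(net, layers, geom, params)
                sv = r.speckle_variance(vol)
                vals.append(sv.sv[truth["flow_mask"]].mean())
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)

    def test_bit_identical_per_seed(self, st_network, flat_layers,
                                    small_geometry, default_render):
        vol1, _ = default_render
        vol2, _ = r.render_oct_volume(st_network, flat_layers,
                                      small_geometry, SpeckleParams(seed=0))
        assert np.array_equal(vol1.intensity, vol2.intensity)

    def test_fov_and_depth_validation(self, flat_layers, small_geometry):
        big = r.generate_network("ST", 35.0, 5.0, 5, 0.0, seed=0,
                                 fov_um=900.0)
        with pytest.raises(ValueError, match="FOV"):
            r.render_oct_volume(big, flat_layers, small_geometry,
                                SpeckleParams(seed=0))
        shallow = r.ScanGeometry(n_fast=150, n_slow=150, fov_um=700.0,
                                 n_depth=50, depth_pixel_um=2.0)
        net = r.generate_network("ST", 35.0, 5.0, 5, 0.0, seed=0,
                                 fov_um=700.0)
        with pytest.raises(ValueError, match="depth"):
            r.render_oct_volume(net, flat_layers, shallow,
                                SpeckleParams(seed=0))

    def test_speckle_params_validation(self):
        with pytest.raises(ValueError):
            SpeckleParams(n_repeats=1)
        with pytest.raises(ValueError):
            SpeckleParams(flow_decorrelation=1.5)


class TestStudyTable:
    def test_pure_region_means_when_noise_free(self):
        tab = generate_study_table(n_subjects=4, rnfl_slope=0.0,
                                   noise_sd=0.0, random_intercept_sd=0.0,
                                   seed=0)
        means = {"Sup": 38.0, "ST": 31.0, "Temp": 36.0, "IT": 32.0,
                 "Inf": 38.0, "N": 35.0}
        for region, sub in tab.groupby("region"):
            assert np.allclose(sub["icd_um"], means[region])

    def test_ols_recovers_slope_exactly_without_noise(self):
        import statsmodels.formula.api as smf
        tab = generate_study_table(n_subjects=5, rnfl_slope=-0.065,
                                   noise_sd=0.0, random_intercept_sd=0.0,
                                   seed=1)
        fit = smf.ols("icd_um ~ rnfl_um + C(region)", tab).fit()
        assert fit.params["rnfl_um"] == pytest.approx(-0.065, abs=1e-10)

    def test_deterministic_and_shaped(self):
        a = generate_study_table(seed=5)
        b = generate_study_table(seed=5)
        pd.testing.assert_frame_equal(a, b)
        # default: 9 subjects, 16 eyes, 6 regions
        assert len(a) == 16 * 6
        assert a["subject"].nunique() == 9

    def test_histology_offset_applied(self):
        tab = generate_study_table(
            n_subjects=4, noise_sd=0.0, random_intercept_sd=0.0,
            rnfl_slope=0.0, seed=2, techniques=("svOCT", "histology"),
            technique_icd_offsets={"N": -4.0})
        piv = tab.pivot_table(index=["subject", "eye", "region"],
                              columns="technique", values="icd_um")
        diff = (piv["histology"] - piv["svOCT"]).groupby("region").mean()
        assert diff["N"] == pytest.approx(-4.0, abs=1e-9)
        assert abs(diff.drop("N")).max() < 1e-9
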