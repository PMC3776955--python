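"""Virtual penetrations: geometry oracles, fits, significance, summaries."""

import numpy as np
import pandas as pd
import pytest

from tonodepth.penetration import (
    Penetration,
    PenetrationConfig,
    alpha_from_p,
    area_summary,
    blur_control,
    bootstrap_slope_p,
    build_penetration,
    fit_depth_gradient,
    map_gradients,
    mean_gradient_direction,
    summarize_gradients,
)
from tonodepth.phantom import (
    LABEL_REVERSED,
    make_phantom_mask,
    plant_frequency_field,
    simulate_session,
)
from tonodepth.response import BootstrapConfig, extract_amplitudes, resample_to_mask
from tonodepth.surface import compute_depth_map, curvature_and_region, extract_surface

F_OCT = np.array([-2.0, -0.75, 0.5, 1.75, 3.0])


def _pen_from_arrays(depths):
    return Penetration(
        vertex_id=0,
        origin=np.zeros(3),
        direction=np.array([0, 0, -1.0]),
        voxel_rows=np.arange(len(depths)),
        depths_mm=np.asarray(depths, float),
    )


class TestBuildPenetration:
    def test_slab_cylinder_equals_brute_force(self, default_spec):
        spec = default_spec.replace(colliculus_radii_mm=((0, 0, 0), (0, 0, 0)))
        tm = make_phantom_mask(spec)
        surf = extract_surface(tm.mask, tm.voxel_size_mm, smoothing_iters=10)
        dm = compute_depth_map(tm.mask, surf, tm.voxel_size_mm)
        cfg = PenetrationConfig()
        # a vertex near the middle of the flat top face
        center = np.array([tm.geometry.slab_max[0] / 2 + 3.0, 12.0,
                           tm.geometry.z_top])
        vid = int(np.argmin(np.linalg.norm(surf.vertices - center, axis=1)))
        pen = build_penetration(surf, dm, vid, cfg)
        assert pen.usable
        o, n = pen.origin, pen.direction
        rel = dm.voxel_centers_mm - o
        t = rel @ n
        perp = np.linalg.norm(rel - t[:, None] * n, axis=1)
        brute = np.flatnonzero(
            (perp <= cfg.radius_mm + 1e-9)
            & (t >= cfg.depth_range_mm[0] - 1e-9)
            & (t <= cfg.depth_range_mm[1] + 1e-9)
        )
        assert set(pen.voxel_rows) == set(brute)

    def test_sphere_direction_antiparallel_to_radius(self, sphere_surface):
        surf, c, r = sphere_surface
        vs = 0.5
        n = 46
        ax = (np.arange(n) + 0.5) * vs
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= r * r
        dm = compute_depth_map(mask, surf, vs)
        rng = np.random.default_rng(0)
        angles = []
        for vid in rng.choice(surf.n_vertices, 200, replace=False):
            pen = build_penetration(surf, dm, int(vid), PenetrationConfig())
            radial = (surf.vertices[vid] - c)
            radial /= np.linalg.norm(radial)
            angles.append(
                np.degrees(np.arccos(np.clip(-pen.direction @ radial, -1, 1)))
            )
        # patch-mean normals on a digitized sphere: typically a few degrees
        # from the analytic radial direction
        assert np.median(angles) < 5.0
        assert np.percentile(angles, 90) < 10.0

    def test_zero_radius_keeps_only_axis_voxels(self, phantom_surface):
        surf, dm = phantom_surface
        vid = int(np.flatnonzero(surf.region_mask)[0])
        pen = build_penetration(surf, dm, vid,
                                PenetrationConfig(radius_mm=0.0))
        if pen.n_voxels:
            rel = dm.voxel_centers_mm[pen.voxel_rows] - pen.origin
            t = rel @ pen.direction
            perp = np.linalg.norm(rel - t[:, None] * pen.direction, axis=1)
            assert np.all(perp < 1e-6)


class TestFitDepthGradient:
    def test_exact_line_recovered(self):
        depths = np.linspace(0.2, 4.5, 12)
        vals = 0.3 + 0.52 * depths
        fit = fit_depth_gradient(_pen_from_arrays(depths), vals)
        assert fit.g == pytest.approx(0.52)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.usable

    def test_flat_rind_then_line_trims_rind(self):
        depths = np.concatenate([np.linspace(0.1, 0.95, 6), np.linspace(1.05, 4.5, 12)])
        vals = np.where(depths < 1.0, 0.0, 0.5 * (depths - 1.0))
        fit = fit_depth_gradient(_pen_from_arrays(depths), vals)
        assert 0.9 <= fit.d0 <= 1.1
        assert fit.g == pytest.approx(0.5, abs=1e-6)

    def test_pure_noise_sign_is_random(self):
        rng = np.random.default_rng(0)
        depths = np.linspace(0.2, 4.5, 14)
        signs = []
        for _ in range(40):
            fit = fit_depth_gradient(_pen_from_arrays(depths), rng.normal(size=14))
            signs.append(fit.g > 0)
        assert 0.2 < np.mean(signs) < 0.8

    def test_too_few_points_unusable(self):
        fit = fit_depth_gradient(_pen_from_arrays([2.0, 2.5]), np.array([1.0, 2.0]))
        assert not fit.usable

    def test_d0_tie_breaks_toward_smaller(self):
        # perfectly linear data: every d0 fits exactly; keep d0 = 0
        depths = np.linspace(0.0, 4.0, 20)
        fit = fit_depth_gradient(_pen_from_arrays(depths), 1.0 + 2.0 * depths)
        assert fit.d0 == pytest.approx(0.0)


class TestBootstrapSlopeP:
    def test_noiseless_monotone_profile_floors_p(self):
        depths = np.linspace(0.5, 4.5, 10)
        pen = _pen_from_arrays(depths)
        # per-presentation samples: every resample reproduces a rising profile
        pref = -1.0 + 0.5 * depths
        A = np.exp(-((F_OCT[:, None] - pref[None, :]) ** 2) / 2.0)
        samples = np.repeat(A[:, None, :], 20, axis=1)  # (5, 20 reps, 10 vox)
        fit = fit_depth_gradient(pen, np.array(
            [np.dot(F_OCT, a - a.min()) / (a - a.min()).sum() for a in A.T]))
        bcfg = BootstrapConfig(B=500, seed=0)
        p = bootstrap_slope_p(pen, samples, F_OCT, fit, PenetrationConfig(), bcfg)
        assert p == pytest.approx(1 / (bcfg.B + 1))


class TestMapGradients:
    def test_deterministic_given_seed(self, phantom_surface, phantom_responses):
        surf, dm = phantom_surface
        cfg = PenetrationConfig()
        bcfg = BootstrapConfig(B=150, seed=9)
        t1 = map_gradients(surf, dm, phantom_responses, cfg, bcfg)
        t2 = map_gradients(surf, dm, phantom_responses, cfg, bcfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_reversed_patches_give_negative_slopes(self, default_spec):
        spec = default_spec.replace(reversed_patch_fraction=1.0, seed=21)
        func = make_phantom_mask(spec)
        struct = make_phantom_mask(spec, voxel_size_mm=spec.surface_voxel_size_mm)
        gt = plant_frequency_field(func, spec)
        surf = extract_surface(struct.mask, struct.voxel_size_mm, 20)
        curvature_and_region(surf)
        dm = compute_depth_map(struct.mask, surf, struct.voxel_size_mm)
        resp = extract_amplitudes(resample_to_mask(simulate_session(gt, spec), struct))
        table = map_gradients(surf, dm, resp, PenetrationConfig(),
                              BootstrapConfig(B=300, seed=5))
        vids = table.index.values
        rev = gt.column_label_at(surf.vertices[vids]) == LABEL_REVERSED
        g = table["g"].values
        p = table["p"].values
        ok = rev & table["usable"].values
        assert np.nanmean(g[ok]) < -0.1
        # mirrored one-sided test: fraction of resampled slopes >= 0 is small,
        # i.e. the positive-gradient p is near 1
        assert np.nanmedian(p[ok]) > 0.9


class TestSummaries:
    def test_area_summary_nested_and_bounds(self, phantom_surface):
        surf, _ = phantom_surface
        vids = np.flatnonzero(surf.region_mask)
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, len(vids))
        areas = area_summary(surf, vids, p, thresholds=(0.0, 0.05, 0.16, 1.0))
        assert areas[0.0] == 0.0
        assert areas[0.05] <= areas[0.16] <= areas[1.0]
        assert areas[1.0] == pytest.approx(surf.vertex_area[vids].sum())

    def test_single_penetration_direction(self):
        n = np.array([[0.0, 0.6, -0.8]])
        out = mean_gradient_direction(n, np.array([0.7]), np.array([0.01]))
        vec, sag, axi = out
        assert np.allclose(vec, n[0])

    def test_weighted_direction_hand_example(self):
        # weights 3:1 on orthogonal y/z unit vectors -> sagittal atan2(1,3)
        dirs = np.array([[0, 1.0, 0], [0, 0, 1.0]])
        g = np.array([3.0, 1.0])
        p = np.array([0.001, 0.001])
        vec, sag, axi = mean_gradient_direction(dirs, g, p)
        assert sag == pytest.approx(np.degrees(np.arctan2(1, 3)), abs=1e-6)
        assert axi == pytest.approx(0.0, abs=1e-9)

    def test_mirror_symmetric_directions_average_onto_plane(self):
        dirs = np.array([[0.5, 0.7, 0.2], [-0.5, 0.7, 0.2]])
        g = np.array([0.4, 0.4])
        p = np.array([0.01, 0.01])
        vec, sag, axi = mean_gradient_direction(dirs, g, p)
        assert vec[0] == pytest.approx(0.0, abs=1e-12)
        assert axi == pytest.approx(0.0, abs=1e-9)

    def test_none_significant_reported_as_such(self):
        out = mean_gradient_direction(np.array([[0, 1, 0.0]]), np.array([0.5]),
                                      np.array([0.4]))
        assert out is None

    def test_summarize_respects_area_nesting(self, phantom_surface, phantom_responses):
        surf, dm = phantom_surface
        table = map_gradients(surf, dm, phantom_responses, PenetrationConfig(),
                              BootstrapConfig(B=150, seed=3))
        s = summarize_gradients(surf, table)
        assert s.sig_area_mm2 <= s.trend_area_mm2 <= s.total_area_mm2
        assert s.n_significant <= s.n_penetrations


class TestBlurControl:
    def test_constant_volume_unchanged(self):
        vol = np.full((20, 20, 20), 7.0)
        out = blur_control(vol, fwhm_mm=2.0, voxel_size_mm=1.2)
        assert np.allclose(out, 7.0)

    def test_white_noise_sd_follows_kernel_energy(self):
        # noise-sd ratio of Gaussian smoothing equals sqrt(sum k^2) of the
        # discrete kernel
        rng = np.random.default_rng(0)
        vol = rng.normal(0, 1.0, (64, 64, 64))
        out = blur_control(vol, fwhm_mm=2.0, voxel_size_mm=1.2)
        sigma = 2.0 / (2 * np.sqrt(2 * np.log(2))) / 1.2
        x = np.arange(-8, 9)
        k = np.exp(-x**2 / (2 * sigma**2))
        k /= k.sum()
        pred = np.sqrt((k**2).sum()) ** 3
        assert out.std() / vol.std() == pytest.approx(pred, rel=0.05)

    def test_fwhm_below_voxel_rejected(self):
        with pytest.raises(ValueError):
            blur_control(np.zeros((5, 5, 5)), fwhm_mm=0.5, voxel_size_mm=1.2)

    def test_blurred_reanalysis_preserves_significant_layout(
        self, phantom, phantom_surface, default_spec
    ):
        # repeating the depth analysis on 2-mm-FWHM-blurred volumes keeps the
        # significant-gradient layout (almost every significant vertex stays
        # significant; blur raises power so the set can only grow) while
        # reducing fitted slope magnitudes
        from tonodepth.phantom import SessionData, simulate_session

        func, struct, gt = phantom
        surf, dm = phantom_surface
        data = simulate_session(gt, default_spec)

        def analyze(d):
            resp = extract_amplitudes(resample_to_mask(d, struct))
            return map_gradients(surf, dm, resp, PenetrationConfig(),
                                 BootstrapConfig(B=300, seed=3))

        plain = analyze(data)
        blurred_vols = blur_control(data.to_volumes(), 2.0,
                                    default_spec.voxel_size_mm)
        blurred = analyze(
            SessionData.from_volumes(blurred_vols, func, data.design)
        )
        sig_a = (plain["p"] < 0.05).values
        sig_b = (blurred["p"] < 0.05).values
        containment = (sig_a & sig_b).sum() / max(sig_a.sum(), 1)
        assert containment > 0.6
        assert blurred["g"][sig_b].mean() < plain["g"][sig_a].mean()


class TestAlphaFromP:
    @pytest.mark.parametrize(
        "p,alpha",
        [(0.01, 1.0), (0.05, 1.0), (0.5, 0.0), (0.9, 0.0),
         (np.sqrt(0.05 * 0.5), 0.5)],
    )
    def test_mapping_examples(self, p, alpha):
        assert alpha_from_p(p) == pytest.approx(alpha, abs=1e-9)

    def test_monotone_in_p(self):
        p = np.linspace(0.01, 0.99, 50)
        a = alpha_from_p(p)
        assert np.all(np.diff(a) <= 1e-12)
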