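"""SHG collagen analytics: thickness, anisotropy, Voronoi context."""

import numpy as np
import pytest

from mmkidney import collagen as col
from mmkidney import phantoms
from mmkidney.phantoms import PhantomSpec


def _grating(phi_deg, shape=(80, 80), freq=0.137):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    t = np.radians(phi_deg)
    return np.sin(2 * np.pi * freq * (-xx * np.sin(t) + yy * np.cos(t)))


class TestBackgroundSubtract:
    def test_constant_image_maps_to_zero(self):
        out = col.background_subtract(np.full((64, 64), 3.0), disk_radius_px=10)
        assert out.max() < 1e-6

    def test_gradient_removed_fiber_preserved(self):
        spec = PhantomSpec(kind="fiber_field", shape=(128, 128), seed=0)
        fiber, _ = phantoms.make_fiber_phantom(spec, [4], [0.0])
        gradient = np.tile(np.linspace(0.0, 0.8, 128), (128, 1))
        out = col.background_subtract(fiber + gradient, disk_radius_px=10)
        ref = col.background_subtract(fiber, disk_radius_px=10)
        fg = fiber > 0.5
        assert abs(out[fg].mean() - ref[fg].mean()) / ref[fg].mean() < 0.1
        assert out.min() >= 0.0

    def test_zero_radius_passthrough_warns(self):
        img = np.random.default_rng(0).random((16, 16))
        with pytest.warns(UserWarning):
            out = col.background_subtract(img, disk_radius_px=0)
        assert np.array_equal(out, img)


class TestFiberThickness:
    @pytest.mark.parametrize("width", [2, 4, 6, 8, 12])
    def test_even_widths_exact(self, width):
        spec = PhantomSpec(kind="fiber_field", shape=(128, 128), seed=0)
        img, _ = phantoms.make_fiber_phantom(spec, [width], [0.0])
        samples = col.fiber_thickness(img > 0.5)
        assert len(samples) >= 1
        assert (samples.thickness_px == width).all()

    @pytest.mark.parametrize("width", [3, 5, 7])
    def test_odd_widths_within_plus_one(self, width):
        spec = PhantomSpec(kind="fiber_field", shape=(128, 128), seed=0)
        img, _ = phantoms.make_fiber_phantom(spec, [width], [0.0])
        samples = col.fiber_thickness(img > 0.5)
        assert (samples.thickness_px >= width).all()
        assert (samples.thickness_px <= width + 1).all()

    @pytest.mark.parametrize("angle", [30.0, 45.0, 60.0])
    def test_rotated_ribbon_within_one_pixel(self, angle):
        spec = PhantomSpec(kind="fiber_field", shape=(160, 160), seed=0)
        img, _ = phantoms.make_fiber_phantom(spec, [12], [angle])
        samples = col.fiber_thickness(img > 0.5)
        assert abs(np.median(samples.thickness_px) - 12) <= 1.0

    def test_two_parallel_ribbons_two_populations(self):
        spec = PhantomSpec(kind="fiber_field", shape=(160, 160), seed=0)
        img, _ = phantoms.make_fiber_phantom(
            spec, [4, 8], [0.0, 0.0], anchors=[(40.0, 80.0), (120.0, 80.0)]
        )
        samples = col.fiber_thickness(img > 0.5)
        thick = np.sort(samples.thickness_px.unique())
        assert any(abs(t - 4) <= 1 for t in thick)
        assert any(abs(t - 8) <= 1 for t in thick)

    def test_translation_invariance(self):
        spec = PhantomSpec(kind="fiber_field", shape=(128, 128), seed=0)
        a, _ = phantoms.make_fiber_phantom(spec, [6], [0.0], anchors=[(40.0, 64.0)])
        b, _ = phantoms.make_fiber_phantom(spec, [6], [0.0], anchors=[(80.0, 64.0)])
        sa = col.fiber_thickness(a > 0.5)
        sb = col.fiber_thickness(b > 0.5)
        assert np.array_equal(
            np.sort(sa.thickness_px.values), np.sort(sb.thickness_px.values)
        )

    def test_empty_mask_empty_table(self):
        samples = col.fiber_thickness(np.zeros((16, 16), bool))
        assert samples.empty

    def test_micron_conversion(self):
        spec = PhantomSpec(kind="fiber_field", shape=(64, 64), seed=0)
        img, _ = phantoms.make_fiber_phantom(spec, [4], [0.0])
        samples = col.fiber_thickness(img > 0.5, pixel_size_um=0.5)
        assert (samples.thickness_um == samples.thickness_px * 0.5).all()


class TestAnisotropy:
    @pytest.mark.parametrize("phi", [0, 30, 60, 90, 120, 150])
    def test_grating_orientation_recovered(self, phi):
        theta, aniso = col.bin_orientation(_grating(phi))
        err = min(abs(theta - phi), 180 - abs(theta - phi))
        assert err <= 2.0
        assert aniso > 0.8

    def test_rotation_equivariance(self):
        base, _ = col.bin_orientation(_grating(20))
        rot, _ = col.bin_orientation(_grating(65))
        shift = (rot - base) % 180
        assert abs(shift - 45) <= 2.0

    def test_intensity_scale_invariance(self):
        t1 = col.bin_orientation(_grating(40))
        t2 = col.bin_orientation(17.0 * _grating(40))
        assert t1[0] == pytest.approx(t2[0], abs=1e-9)
        assert t1[1] == pytest.approx(t2[1], abs=1e-9)

    def test_isotropic_noise_low_anisotropy(self):
        rng = np.random.default_rng(0)
        _, aniso = col.bin_orientation(rng.normal(0, 1, (80, 80)))
        assert aniso < 0.1

    def test_flat_bin_flagged(self):
        theta, aniso = col.bin_orientation(np.full((32, 32), 2.0))
        assert np.isnan(theta)
        assert aniso == 0.0

    def test_periodic_smooth_reconstruction(self):
        rng = np.random.default_rng(3)
        u = rng.random((40, 56))
        p, s = col.periodic_smooth_decompose(u)
        np.testing.assert_allclose(p + s, u, atol=1e-10)
        # periodic component wraps more continuously than the original
        jump_u = np.abs(u[0] - u[-1]).mean() + np.abs(u[:, 0] - u[:, -1]).mean()
        jump_p = np.abs(p[0] - p[-1]).mean() + np.abs(p[:, 0] - p[:, -1]).mean()
        assert jump_p < jump_u

    def test_edge_artifact_energy_reduced(self):
        u = _grating(30)
        u = u - u.mean()
        p, _ = col.periodic_smooth_decompose(u)
        ratio = col.axis_artifact_energy(u) / col.axis_artifact_energy(p)
        assert ratio >= 10.0

    def test_bins_tile_and_flag(self):
        spec = PhantomSpec(kind="fiber_field", shape=(128, 128), seed=2)
        img, _ = phantoms.make_fiber_phantom(spec, [4, 4], [0.0, 90.0])
        bins = col.anisotropy_bins(img, bin_um=64, pixel_size_um=1.0)
        assert len(bins) == 4
        flat = [b for b in bins if b.flat]
        oriented = [b for b in bins if not b.flat and b.anisotropy > 0.8]
        assert len(oriented) >= 2

    def test_bin_too_small_rejected(self):
        with pytest.raises(ValueError):
            col.anisotropy_bins(np.zeros((64, 64)), bin_um=8, pixel_size_um=1.0)


class TestVoronoi:
    def test_single_center_one_label(self):
        part = col.voronoi_partition([(10.0, 10.0)], (32, 32))
        assert (part.labels == 0).all()

    def test_two_centers_perpendicular_bisector(self):
        part = col.voronoi_partition([(16.0, 8.0), (16.0, 24.0)], (32, 32))
        # boundary is the vertical line x = 16
        assert (part.labels[:, :16] == 0).all()
        assert (part.labels[:, 17:] == 1).all()

    def test_seed_pixels_carry_own_id(self):
        seeds = [(5.0, 5.0), (20.0, 25.0), (28.0, 3.0)]
        part = col.voronoi_partition(seeds, (32, 32))
        for i, (sy, sx) in enumerate(seeds):
            assert part.labels[int(sy), int(sx)] == i

    def test_no_centers_rejected(self):
        with pytest.raises(ValueError):
            col.voronoi_partition([], (16, 16))


class TestThicknessVsDistance:
    def test_samples_at_seed_have_zero_distance(self):
        import pandas as pd

        samples = pd.DataFrame(
            {"y": [10.0], "x": [10.0], "thickness_px": [4.0], "thickness_um": [4.0]}
        )
        part = col.voronoi_partition([(10.0, 10.0)], (32, 32))
        table, *_ = col.thickness_vs_distance(samples, part)
        assert table.distance_um.iloc[0] == pytest.approx(0.0)

    def test_ring_of_samples_at_known_distance(self):
        import pandas as pd

        angles = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        ys = 100 + 50 * np.sin(angles)
        xs = 100 + 50 * np.cos(angles)
        samples = pd.DataFrame(
            {"y": ys, "x": xs, "thickness_px": 4.0, "thickness_um": 8.0}
        )
        part = col.voronoi_partition([(100.0, 100.0)], (200, 200), pixel_size_um=2.0)
        table, *_ = col.thickness_vs_distance(samples, part)
        np.testing.assert_allclose(table.distance_um, 100.0, atol=2.0)

    def test_sample_count_conserved_with_exclusion(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        n = 50
        samples = pd.DataFrame(
            {
                "y": rng.uniform(0, 99, n),
                "x": rng.uniform(0, 99, n),
                "thickness_px": rng.uniform(2, 10, n),
                "thickness_um": rng.uniform(2, 10, n),
            }
        )
        part = col.voronoi_partition([(50.0, 50.0)], (100, 100))
        excl = np.zeros((100, 100), bool)
        excl[:, 50:] = True
        table, *_ = col.thickness_vs_distance(samples, part, exclusion_mask=excl)
        n_excluded = (np.round(samples.x).clip(0, 99) >= 50).sum()
        assert len(table) == n - n_excluded

    def test_thick_near_thin_far_trend(self):
        import pandas as pd

        dist = np.linspace(5, 95, 40)
        thick = 12.0 - 0.08 * dist
        samples = pd.DataFrame(
            {"y": 100.0, "x": 100.0 + dist, "thickness_px": thick,
             "thickness_um": thick}
        )
        part = col.voronoi_partition([(100.0, 100.0)], (220, 220))
        table, density, d_edges, t_edges = col.thickness_vs_distance(
            samples, part, distance_bins=5, thickness_bins=5
        )
        d_centers = 0.5 * (d_edges[:-1] + d_edges[1:])
        t_centers = 0.5 * (t_edges[:-1] + t_edges[1:])
        mean_thickness = (density * t_centers[None, :]).sum(axis=1) / density.sum(axis=1)
        assert (np.diff(mean_thickness) < 0).all()


def test_high_anisotropy_mask_flags_oriented_bins():
    spec = PhantomSpec(kind="fiber_field", shape=(128, 128), seed=2)
    img, _ = phantoms.make_fiber_phantom(spec, [4], [0.0], anchors=[(32.0, 64.0)])
    rng = np.random.default_rng(5)
    img[64:, :] += rng.normal(0, 0.2, (64, 128)).clip(0, None)
    bins = col.anisotropy_bins(img, bin_um=64, pixel_size_um=1.0)
    mask = col.high_anisotropy_mask(bins, img.shape, quantile=0.5)
    assert mask[32, 64]  # the oriented fiber bin is flagged
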