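"""Glomerulus segmentation, z-tracking, and Vv(Mes/Glom) estimation."""

import numpy as np
import pytest

from mmkidney import glomerulus as glom
from mmkidney import phantoms
from mmkidney.datatypes import MultimodalVolume


def _tracked_record(glom_volume, **kwargs):
    volume, truth = glom_volume
    cz = int(round(truth.center_um[0] / volume.z_spacing_um))
    cy = truth.center_um[1] / volume.pixel_size_um
    cx = truth.center_um[2] / volume.pixel_size_um
    return glom.track_glomerulus(volume, seed_yx=(cy, cx), seed_plane=cz, **kwargs)


class TestOpenCloseSegmentation:
    def test_sphere_cross_section_single_region_contains_centroid(self, glom_volume):
        volume, truth = glom_volume
        cz = int(round(truth.center_um[0] / volume.z_spacing_um))
        regions = glom.segment_glomeruli_openclose(
            volume["protein_2940"][cz], classes=3
        )
        assert regions.n_regions >= 1
        iy = int(round(truth.center_um[1] / volume.pixel_size_um))
        ix = int(round(truth.center_um[2] / volume.pixel_size_um))
        assert regions.labels[iy, ix] > 0

    def test_circularity_filter_removes_elongated_bar(self):
        img = np.zeros((64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        disk_mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= 100  # ~314 px circle
        img[disk_mask] = 1.0
        img[50:55, 1:64] = 1.0  # bar of comparable area (315 px)
        regions = glom.segment_glomeruli_openclose(
            img, r_open=0, r_close=0, circularity_min=0.6
        )
        assert regions.n_regions == 1
        assert regions.labels[20, 20] > 0
        assert regions.labels[52, 30] == 0

    def test_zero_radii_plain_otsu_components(self):
        img = np.zeros((32, 32))
        img[5:10, 5:10] = 1.0
        img[20:28, 20:28] = 1.0
        regions = glom.segment_glomeruli_openclose(img, r_open=0, r_close=0)
        assert regions.n_regions == 2

    def test_blank_image_no_regions(self):
        regions = glom.segment_glomeruli_openclose(np.zeros((16, 16)))
        assert regions.n_regions == 0


@pytest.fixture(scope="module")
def ringed_image():
    rng = np.random.default_rng(1)
    img = np.zeros((300, 300))
    yy, xx = np.mgrid[0:300, 0:300]
    disks = []
    for cy, cx, r in [(90, 90, 50), (210, 200, 45)]:
        img[np.abs(np.hypot(yy - cy, xx - cx) - r) < 3] = 1.0
        disks.append(np.hypot(yy - cy, xx - cx) < r - 3)
    for _ in range(40):
        ay, ax_ = rng.integers(0, 300, 2)
        th = rng.uniform(0, np.pi)
        L = rng.uniform(10, 30)
        for t in np.linspace(-L / 2, L / 2, int(2 * L)):
            py, px = int(ay + t * np.sin(th)), int(ax_ + t * np.cos(th))
            if 0 <= py < 300 and 0 <= px < 300:
                img[py, px] = 0.8
    img = np.clip(img + rng.normal(0, 0.02, img.shape), 0, None)
    return img, disks


class TestSHGSegmentation:
    def test_two_ringed_disks_recovered(self, ringed_image):
        img, disks = ringed_image
        regions = glom.segment_glomeruli_shg(
            img, se_radius_px=8, area_range_um2=(2000, 20000)
        )
        assert regions.n_regions == 2
        jaccards = []
        for d in disks:
            best = max(
                ((regions.labels == i) & d).sum() / ((regions.labels == i) | d).sum()
                for i in range(1, regions.n_regions + 1)
            )
            jaccards.append(best)
        assert min(jaccards) >= 0.8

    def test_labels_mutually_exclusive(self, ringed_image):
        img, _ = ringed_image
        regions = glom.segment_glomeruli_shg(
            img, se_radius_px=8, area_range_um2=(2000, 20000)
        )
        # a label image is single-valued per pixel by construction; check
        # ids are contiguous 1..n
        ids = np.unique(regions.labels)
        assert set(ids) == set(range(regions.n_regions + 1))

    def test_blank_image_no_regions(self):
        regions = glom.segment_glomeruli_shg(np.zeros((64, 64)), se_radius_px=5)
        assert regions.n_regions == 0


class TestMesangium:
    def test_uniform_interior_is_all_mesangium(self):
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        protein = np.where(mask, 0.9, 0.0)
        mes = glom.segment_mesangium(mask, protein)
        assert np.array_equal(mes, mask)

    def test_zero_interior_empty(self):
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        mes = glom.segment_mesangium(mask, np.zeros((16, 16)))
        assert not mes.any()

    def test_phantom_tuft_fraction_recovered(self, glom_volume):
        volume, truth = glom_volume
        cz = int(round(truth.center_um[0] / volume.z_spacing_um))
        corp = truth.corpuscle_mask[cz]
        mes = glom.segment_mesangium(corp, volume["protein_2940"][cz])
        frac = mes.sum() / corp.sum()
        oracle = truth.tuft_mask[cz].sum() / corp.sum()
        assert frac == pytest.approx(oracle, abs=0.02)


class TestTracking:
    def test_max_plane_at_equator(self, glom_volume):
        volume, truth = glom_volume
        rec = _tracked_record(glom_volume)
        equator = int(round(truth.center_um[0] / volume.z_spacing_um))
        assert abs(rec.max_plane - equator) <= 1

    def test_area_profile_non_increasing_toward_vanish(self, glom_volume):
        rec = _tracked_record(glom_volume)
        zs = sorted(rec.plane_areas_px)
        areas = [rec.plane_areas_px[z] for z in zs]
        direction = 1 if rec.max_plane == zs[0] else -1
        ordered = areas[::direction]
        # allow 2 % jitter from noise at the segmentation boundary
        assert all(
            b <= a * 1.02 + 8 for a, b in zip(ordered, ordered[1:])
        )

    def test_mesangium_subset_of_corpuscle(self, glom_volume):
        rec = _tracked_record(glom_volume)
        for z in rec.plane_areas_px:
            assert rec.mes_areas_px[z] <= rec.plane_areas_px[z]

    def test_vv_estimates_in_unit_interval(self, glom_volume):
        rec = _tracked_record(glom_volume)
        for v in (rec.vv_3d, rec.vv_2d_single, rec.vv_2d_max):
            assert 0.0 <= v <= 1.0

    def test_clipped_at_border_flagged(self):
        spec = phantoms.PhantomSpec(
            kind="glomerulus_volume", shape=(40, 34, 34), pixel_size_um=2,
            z_spacing_um=2, noise_sigma=0.0, seed=0,
        )
        volume, truth = phantoms.make_glomerulus_volume_phantom(
            spec, radius_um=32, mes_fraction=0.6
        )
        cz = int(round(truth.center_um[0] / 2))
        rec = glom.track_glomerulus(
            volume, seed_yx=(16, 16), seed_plane=cz
        )
        assert rec.clipped


class TestRadiusAndHemisphere:
    def test_digitized_disk_radius(self):
        yy, xx = np.mgrid[0:128, 0:128]
        mask = (yy - 64) ** 2 + (xx - 64) ** 2 <= 50 ** 2
        r = glom.radius_from_mask(mask, pixel_size_um=2.0)
        assert r == pytest.approx(100.0, abs=2.0)

    def test_circle_boundary_distances_nearly_constant(self):
        from scipy import ndimage

        yy, xx = np.mgrid[0:128, 0:128]
        mask = (yy - 64) ** 2 + (xx - 64) ** 2 <= 50 ** 2
        boundary = mask & ~ndimage.binary_erosion(mask)
        cy, cx = ndimage.center_of_mass(mask)
        d = np.hypot(*(np.nonzero(boundary) - np.array([[cy], [cx]])))
        assert d.std() / d.mean() < 0.03

    def test_terminal_max_plane_defaults_to_100um(self):
        rec = glom.GlomerulusRecord(
            id=1, plane_areas_px={}, mes_areas_px={}, centroid_um=(0, 0, 0),
            max_plane=0, vanish_plane=None, thickness_um=50.0, radius_um=0.0,
            retained=False, clipped=False, vv_3d=0.5, vv_2d_single=0.5,
            vv_2d_max=0.5, n_volume_planes=40, pixel_size_um=2.0,
        )
        assert glom.estimate_radius(rec) == 100.0

    def test_hemisphere_rule_boundary_inclusive(self):
        base = dict(
            id=1, plane_areas_px={}, mes_areas_px={}, centroid_um=(0, 0, 0),
            max_plane=5, vanish_plane=10, radius_um=100.0, retained=False,
            clipped=False, vv_3d=0.5, vv_2d_single=0.5, vv_2d_max=0.5,
            n_volume_planes=40,
        )
        at_limit = glom.GlomerulusRecord(thickness_um=90.0, **base)
        below = glom.GlomerulusRecord(thickness_um=50.0, **base)
        assert glom.hemisphere_filter(at_limit) is True
        assert glom.hemisphere_filter(below) is False


class TestVvAggregation:
    def _record(self, i, vv3, vv2s, vv2m, retained=True, clipped=False):
        return glom.GlomerulusRecord(
            id=i, plane_areas_px={}, mes_areas_px={}, centroid_um=(0, 0, 0),
            max_plane=5, vanish_plane=10, thickness_um=100, radius_um=100,
            retained=retained, clipped=clipped, vv_3d=vv3, vv_2d_single=vv2s,
            vv_2d_max=vv2m, n_volume_planes=40,
        )

    def test_summary_se_formula(self):
        records = [self._record(i, 0.5 + 0.02 * i, 0.4, 0.6) for i in range(5)]
        _, summary = glom.vv_mes_glom(records, "3d_hemisphere")
        assert summary["se"] == pytest.approx(summary["sd"] / np.sqrt(5))
        assert summary["n"] == 5

    def test_no_retained_records_error_names_filter(self):
        records = [self._record(1, 0.5, 0.4, 0.6, retained=False)]
        with pytest.raises(ValueError, match="hemisphere"):
            glom.vv_mes_glom(records, "3d_hemisphere")

    def test_saturated_mesangium_gives_unit_vv(self):
        records = [self._record(i, 1.0, 1.0, 1.0) for i in range(3)]
        for method in ("3d_hemisphere", "2d_single_plane", "2d_max_plane"):
            vals, _ = glom.vv_mes_glom(records, method)
            assert (vals == 1.0).all()


class TestNucleiCounting:
    def test_exact_counts_by_region(self):
        spec = phantoms.PhantomSpec(
            kind="glomerulus_volume", shape=(60, 60, 60), pixel_size_um=2,
            z_spacing_um=2, seed=11,
        )
        volume, truth = phantoms.make_glomerulus_volume_phantom(
            spec, radius_um=50, mes_fraction=0.6,
            n_glomerular_nuclei=8, n_cortical_nuclei=15,
        )
        regions = glom.LabeledRegions(
            labels=truth.corpuscle_mask.astype(int), n_regions=1,
            provenance="manual",
        )
        counts = glom.count_nuclei_3d(volume["nuclei"], regions)
        assert counts[1] == 8
        assert counts[0] == 15

    def test_empty_channel_gives_zeros(self):
        regions = glom.LabeledRegions(
            labels=np.ones((4, 4, 4), int), n_regions=1, provenance="manual"
        )
        counts = glom.count_nuclei_3d(np.zeros((4, 4, 4)), regions)
        assert counts == {1: 0}

    def test_straddling_nucleus_counted_once_by_centroid(self):
        labels = np.zeros((4, 8, 8), int)
        labels[:, :, 4:] = 1
        nuclei = np.zeros((4, 8, 8))
        nuclei[1:3, 3:5, 3:6] = 1.0  # straddles the boundary, centroid at x=4
        regions = glom.LabeledRegions(labels=labels, n_regions=1, provenance="manual")
        counts = glom.count_nuclei_3d(nuclei, regions)
        assert sum(counts.values()) == 1
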