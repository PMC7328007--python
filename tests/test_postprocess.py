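"""Region extraction and mask clean-up, checked against brute-force oracles."""

import numpy as np
import pytest

from colonyquant.postprocess import (
    ColonyCrop,
    Region,
    center_crop_resize,
    clear_border,
    crop_colonies,
    filter_regions,
    label_regions,
    morphological_open,
    resize_mask_to_original,
)
from colonyquant.segmentation import PlateImage

from oracles import brute_components, brute_moments, random_blob_mask


# --- center crop / resize --------------------------------------------------

class TestCenterCropResize:
    def test_square_identity(self):
        img = np.random.default_rng(0).integers(0, 255, (96, 96, 3), dtype=np.uint8)
        out = center_crop_resize(PlateImage(img, "p"), 96)
        assert np.array_equal(out.pixels, img)

    def test_landscape_crops_centered_square(self):
        img = np.zeros((96, 160, 3), np.uint8)
        img[:, 32:128] = 200  # the centered 96-wide band
        out = center_crop_resize(PlateImage(img, "p"), 96)
        assert out.pixels.shape == (96, 96, 3)
        assert (out.pixels == 200).all()

    @pytest.mark.parametrize("target", [64, 96, 100])
    def test_output_always_square_of_target(self, target):
        img = np.random.default_rng(1).integers(0, 255, (120, 150, 3), dtype=np.uint8)
        out = center_crop_resize(PlateImage(img, "p"), target)
        assert out.pixels.shape == (target, target, 3)

    def test_nonpositive_target_raises(self):
        with pytest.raises(ValueError):
            center_crop_resize(np.zeros((64, 64, 3), np.uint8), 0)


class TestResizeMask:
    def test_same_dims_identity(self):
        mask = np.random.default_rng(0).uniform(size=(32, 32)) > 0.5
        assert np.array_equal(resize_mask_to_original(mask, (32, 32)), mask)

    def test_upscale_single_pixel_becomes_block(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 2] = True
        up = resize_mask_to_original(mask, (8, 8))
        assert up.sum() == 4
        assert up[2:4, 4:6].all()

    def test_round_trip_preserves_large_blob_count(self):
        rng = np.random.default_rng(3)
        rr, cc = np.mgrid[0:128, 0:128]
        mask = np.zeros((128, 128), bool)
        for cy, cx in [(30, 30), (90, 90), (30, 95)]:
            mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= 12**2
        down = resize_mask_to_original(mask, (64, 64))
        up = resize_mask_to_original(down, (128, 128))
        assert len(brute_components(up)) == 3


class TestClearBorder:
    def test_edge_touching_blob_removed(self):
        mask = np.zeros((16, 16), bool)
        mask[0:4, 5:9] = True
        assert not clear_border(mask).any()

    def test_interior_blob_untouched(self):
        mask = np.zeros((16, 16), bool)
        mask[6:10, 6:10] = True
        assert np.array_equal(clear_border(mask), mask)

    def test_full_frame_cleared(self):
        assert not clear_border(np.ones((8, 8), bool)).any()


class TestMorphologicalOpen:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((16, 16), bool)
        mask[8, 8] = True
        assert not morphological_open(mask, 1).any()

    def test_large_disk_nearly_preserved(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 20**2
        opened = morphological_open(disk, 2)
        change = abs(int(opened.sum()) - int(disk.sum())) / disk.sum()
        assert change < 0.05

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        mask = random_blob_mask(rng)
        once = morphological_open(mask, 2)
        assert np.array_equal(morphological_open(once, 2), once)

    def test_radius_zero_rejected(self):
        with pytest.raises(ValueError):
            morphological_open(np.zeros((4, 4), bool), 0)


class TestLabelRegions:
    def test_single_disk_round_and_conserved(self):
        rr, cc = np.mgrid[0:64, 0:64]
        disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 15**2
        regions = label_regions(disk)
        assert len(regions) == 1
        assert regions[0].eccentricity < 0.05
        assert regions[0].area == int(disk.sum())

    def test_two_disjoint_disks_conserve_area(self):
        rr, cc = np.mgrid[0:64, 0:64]
        m = ((rr - 16) ** 2 + (cc - 16) ** 2 <= 8**2) | (
            (rr - 48) ** 2 + (cc - 48) ** 2 <= 6**2
        )
        regions = label_regions(m)
        assert len(regions) == 2
        assert sum(r.area for r in regions) == int(m.sum())

    def test_elongated_ellipse_eccentricity(self):
        """Filled ellipse with semi-axes (2b, b) has eccentricity sqrt(3)/2."""
        rr, cc = np.mgrid[0:128, 0:128]
        ell = ((rr - 64) / 40) ** 2 + ((cc - 64) / 20) ** 2 <= 1
        (region,) = label_regions(ell)
        assert region.eccentricity == pytest.approx(np.sqrt(3) / 2, abs=0.01)

    def test_agrees_with_brute_force_moments(self):
        """Area/bbox/centroid/eccentricity match the pixel-set oracle."""
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(40):
            mask = random_blob_mask(rng, size=64, n_blobs=3)
            regions = label_regions(mask)
            comps = brute_components(mask)
            assert len(regions) == len(comps)
            by_bbox = {}
            for comp in comps:
                area, bbox, centroid, ecc = brute_moments(comp)
                by_bbox[bbox] = (area, centroid, ecc)
            for region in regions:
                area, centroid, ecc = by_bbox[region.bbox]
                assert region.area == area
                assert region.centroid == pytest.approx(centroid, rel=1e-6)
                assert region.eccentricity == pytest.approx(ecc, rel=1e-6, abs=1e-9)
                checked += 1
        assert checked >= 100

    def test_pixel_conservation(self):
        rng = np.random.default_rng(1)
        mask = random_blob_mask(rng, n_blobs=5)
        regions = label_regions(mask)
        assert sum(r.area for r in regions) == int(mask.sum())


class TestFilterRegions:
    @staticmethod
    def region(ecc, area):
        return Region(1, (0, 0, 10, 10), area, ecc, (5.0, 5.0), "p")

    @pytest.mark.parametrize(
        "ecc,area,kept",
        [
            (0.0, 1000, True),
            (0.61, 1000, False),
            (0.60, 400, True),
            (0.600001, 400, False),
            (0.5, 399, False),
            (0.5, 400, True),
        ],
    )
    def test_inclusive_thresholds(self, ecc, area, kept):
        k, r = filter_regions([self.region(ecc, area)])
        assert (len(k) == 1) is kept
        assert len(k) + len(r) == 1

    def test_partition_and_idempotence(self):
        rng = np.random.default_rng(2)
        regions = [self.region(rng.uniform(0, 1), rng.integers(1, 800)) for _ in range(50)]
        kept, rejected = filter_regions(regions)
        assert sorted(map(id, kept + rejected)) == sorted(map(id, regions))
        kept2, rejected2 = filter_regions(kept)
        assert kept2 == kept and rejected2 == []


class TestCropColonies:
    def _image(self):
        return PlateImage(
            np.random.default_rng(0).integers(0, 255, (64, 64, 3), dtype=np.uint8), "pl"
        )

    def test_zero_padding_crop_size(self):
        region = Region(3, (10, 10, 30, 30), 400, 0.1, (20, 20), "pl")
        (crop,) = crop_colonies(self._image(), [region], padding=0)
        assert crop.pixels.shape == (20, 20, 3)
        assert crop.name == "pl__3.jpg"

    def test_padding_clipped_at_corner(self):
        region = Region(1, (0, 0, 10, 10), 100, 0.1, (5, 5), "pl")
        (crop,) = crop_colonies(self._image(), [region], padding=5)
        assert crop.bbox == (0, 0, 15, 15)
        assert crop.pixels.shape == (15, 15, 3)

    def test_one_crop_per_region_with_provenance(self):
        regions = [
            Region(i, (i * 5, i * 5, i * 5 + 8, i * 5 + 8), 64, 0.1, (0, 0), "pl")
            for i in range(1, 5)
        ]
        crops = crop_colonies(self._image(), regions, padding=2)
        assert len(crops) == 4
        assert all(c.plate_id == "pl" for c in crops)
        assert len({c.name for c in crops}) == 4

    def test_empty_region_list_is_empty_output(self):
        assert crop_colonies(self._image(), []) == []


class TestEndToEndRegions:
    def test_well_separated_colonies_all_recovered(self):
        """k clean round colonies above both thresholds yield exactly k crops."""
        rr, cc = np.mgrid[0:256, 0:256]
        mask = np.zeros((256, 256), bool)
        centers = [(50, 50), (50, 200), (200, 50), (200, 200), (128, 128)]
        for cy, cx in centers:
            mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= 15**2
        mask = morphological_open(clear_border(mask), 1)
        regions = label_regions(mask)
        kept, rejected = filter_regions(regions, ecc_max=0.6, area_min=400)
        assert len(kept) == len(centers) and rejected == []
        img = PlateImage(np.zeros((256, 256, 3), np.uint8), "p")
        assert len(crop_colonies(img, kept)) == len(centers)
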