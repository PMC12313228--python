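"""Segmentation and measurement tests against rendered ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from organquant import imagequant as iq
from organquant import synthdata as sd


class TestSegmentation:
    def test_otsu_recovers_noise_free_geometry_exactly(self, mixed_island_image):
        image, _ = mixed_island_image
        mask, t = iq.segment_keratinocytes(image, "cytokeratin", "otsu")
        truth = image.channel("cytokeratin") == 1.0
        assert np.array_equal(mask, truth)
        assert 0.0 < t < 1.0

    def test_fixed_half_threshold_matches_otsu_on_binary_image(self, mixed_island_image):
        image, _ = mixed_island_image
        m1, _ = iq.segment_keratinocytes(image, "cytokeratin", "otsu")
        m2, t = iq.segment_keratinocytes(image, "cytokeratin", "fixed:0.5")
        assert np.array_equal(m1, m2)
        assert t == 0.5

    def test_noisy_mask_agreement_above_99_percent(self, mixed_island_spec):
        spec = dataclasses.replace(mixed_island_spec, noise_sd=0.05)
        image, _ = sd.generate_organ_image(spec)
        clean, _ = sd.generate_organ_image(mixed_island_spec)
        mask, _ = iq.segment_keratinocytes(image, "cytokeratin", "otsu")
        truth = clean.channel("cytokeratin") == 1.0
        assert (mask == truth).mean() >= 0.99

    def test_constant_channel_with_otsu_suggests_fixed(self):
        img = iq.OrganImage(channels={"cytokeratin": np.full((20, 20), 0.3)})
        with pytest.raises(ValueError, match="fixed"):
            iq.segment_keratinocytes(img, "cytokeratin", "otsu")

    def test_threshold_monotonicity(self, mixed_island_spec):
        spec = dataclasses.replace(mixed_island_spec, noise_sd=0.1)
        image, _ = sd.generate_organ_image(spec)
        areas = [
            iq.segment_keratinocytes(image, "cytokeratin", f"fixed:{t}")[0].sum()
            for t in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestIslandExtraction:
    def test_island_count_matches_ground_truth(self, mixed_island_image):
        image, gt = mixed_island_image
        mask, _ = iq.segment_keratinocytes(image)
        table, _, _ = iq.extract_islands(mask, image.um_per_px)
        assert (~table.is_sheet).sum() == len(gt.islands)
        assert table.is_sheet.sum() == 1

    def test_sheet_only_yields_no_island_rows(self, sheet_only_spec):
        image, _ = sd.generate_organ_image(sheet_only_spec)
        mask, _ = iq.segment_keratinocytes(image)
        table, _, _ = iq.extract_islands(mask, image.um_per_px)
        assert (~table.is_sheet).sum() == 0

    def test_one_pixel_bridge_merges_islands_under_8_connectivity(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[:5, :] = True  # sheet
        mask[20:30, 10:20] = True
        mask[30:40, 20:30] = True  # touches previous region only diagonally at (29/30, 19/20)
        table, _, _ = iq.extract_islands(mask, 1.0)
        assert (~table.is_sheet).sum() == 1

    def test_no_top_border_component_is_an_orientation_error(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[30:38, 5:35] = True
        with pytest.raises(ValueError, match="orientation"):
            iq.extract_islands(mask, 1.0)

    def test_min_island_area_filters_specks(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[:5, :] = True
        mask[20:22, 20:22] = True  # 4 px speck
        table, _, _ = iq.extract_islands(mask, 1.0, min_island_area=25)
        assert (~table.is_sheet).sum() == 0

    def test_calibration_equivariance(self, mixed_island_image):
        image, _ = mixed_island_image
        mask, _ = iq.segment_keratinocytes(image)
        t1, _, _ = iq.extract_islands(mask, 1.0)
        t2, _, _ = iq.extract_islands(mask, 2.0)
        i1, i2 = t1[~t1.is_sheet], t2[~t2.is_sheet]
        assert np.allclose(i2.depth_um, 2.0 * i1.depth_um)
        assert np.allclose(i2.area_um2, 4.0 * i1.area_um2)
        assert np.array_equal(i1.area_px2, i2.area_px2)


class TestNucleiCounting:
    @pytest.mark.parametrize("n_nuclei", [1, 14, 20])
    def test_exact_recovery_on_noise_free_islands(self, n_nuclei):
        spec = sd.OrganImageSpec(
            n_singular_islands=1 if n_nuclei < 15 else 0,
            n_clustered_islands=0 if n_nuclei < 15 else 1,
            nuclei_per_singular=n_nuclei if n_nuclei < 15 else 8,
            nuclei_per_clustered=n_nuclei if n_nuclei >= 15 else 20,
            island_depths_px=(150,),
            island_radii_px=(30,),
            seed=n_nuclei,
        )
        image, gt = sd.generate_organ_image(spec)
        q = iq.quantify_image(image)
        counts = q["island_table"].loc[~q["island_table"].is_sheet, "nuclei_count"]
        assert counts.tolist() == [n_nuclei]

    def test_island_without_dapi_counts_zero(self):
        img = iq.OrganImage(
            channels={"dapi": np.zeros((30, 30)), "cytokeratin": np.ones((30, 30))}
        )
        island = np.zeros((30, 30), dtype=bool)
        island[10:20, 10:20] = True
        assert iq.count_nuclei(img, island) == 0


class TestDepthAndIntensity:
    def test_depth_is_deepest_pixel_below_sheet_base(self):
        mask = np.zeros((300, 100), dtype=bool)
        mask[:50, :] = True
        mask[240:250, 40:60] = True  # deepest pixel at row 249; base row 49
        table, _, _ = iq.extract_islands(mask, 1.0)
        assert iq.invasion_depth(table) == pytest.approx(200.0)

    def test_no_islands_depth_zero(self, sheet_only_spec):
        image, _ = sd.generate_organ_image(sheet_only_spec)
        q = iq.quantify_image(image)
        assert q["depth_um"] == 0.0

    def test_mean_marker_intensity_examples(self):
        pdpn = np.zeros((10, 10))
        pdpn[:, :5] = 1.0
        img = iq.OrganImage(channels={"pdpn": pdpn, "flat": np.full((10, 10), 0.4)})
        full = np.ones((10, 10), dtype=bool)
        assert iq.mean_marker_intensity(img, full, "flat") == pytest.approx(0.4)
        assert iq.mean_marker_intensity(img, full, "pdpn") == pytest.approx(0.5)
        with pytest.raises(ValueError):
            iq.mean_marker_intensity(img, np.zeros((10, 10), bool), "pdpn")

    def test_pdpn_island_intensity_recovered_from_synthetic_render(self, mixed_island_image):
        image, _ = mixed_island_image
        q = iq.quantify_image(image)
        islands_mask = np.isin(
            q["labels"], q["island_table"].loc[~q["island_table"].is_sheet, "label"]
        )
        assert iq.mean_marker_intensity(image, islands_mask, "pdpn") == pytest.approx(0.8)
        assert iq.mean_marker_intensity(image, q["sheet_mask"], "pdpn") == pytest.approx(0.2)


class TestLwr:
    def test_rotation_invariance(self):
        masks, _ = sd.generate_cell_masks(1, 1.8, seed=4)
        shapes, _ = iq.measure_lwr(masks)
        rotated, _ = iq.measure_lwr([np.rot90(masks[0])])
        assert rotated[0].lwr == pytest.approx(shapes[0].lwr, rel=1e-9)

    def test_tiny_mask_rejected(self):
        with pytest.raises(ValueError, match="10 pixels"):
            iq.measure_lwr([np.ones((3, 3), dtype=bool)[:1]])

    def test_lwr_at_least_one(self, rng):
        ratios = rng.uniform(1.0, 3.0, size=10)
        masks, _ = sd.generate_cell_masks(10, ratios, seed=7)
        shapes, _ = iq.measure_lwr(masks)
        assert all(s.lwr >= 1.0 for s in shapes)
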