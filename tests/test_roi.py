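"""ROI placement protocols and measurement rules."""

import numpy as np
import pytest

from renalct import phantom, roi

SP = phantom.DEFAULT_SPACING


class TestDetection:
    def test_patches_found_vessel_excluded(self, structured_volume):
        _, vol = structured_volume
        regions, vessels = roi.detect_enhancement_regions(
            vol.phases["CMP"], vol.masks["tumor"], vol.spacing,
            return_excluded=True)
        assert len(regions) == 3
        assert len(vessels) >= 1
        # each true patch blob is recovered by exactly one detected region
        from scipy import ndimage
        labeled, n_true = ndimage.label(vol.masks["patches"])
        assert n_true == 3
        for lab in range(1, n_true + 1):
            blob = labeled == lab
            covering = [i for i, reg in enumerate(regions)
                        if (reg & blob).sum() / blob.sum() > 0.6]
            assert len(covering) == 1
        # the excluded elongated component overlaps the true vessel
        assert any((v & vol.masks["vessels"]).any() for v in vessels)

    def test_homogeneous_tumor_returns_empty(self, homogeneous_volume):
        _, vol = homogeneous_volume
        # add mild noise so the 90th-percentile threshold is not degenerate
        rng = np.random.default_rng(0)
        grid = vol.phases["CMP"] + rng.normal(0, 5, vol.shape)
        regions = roi.detect_enhancement_regions(
            grid, vol.masks["tumor"], vol.spacing)
        assert regions == []

    def test_excluded_mask_never_intersected(self):
        spec = phantom.LesionSpec(diameter_mm=32, n_patches=3,
                                  cyst_fraction=0.25, tumor_noise_sd=5.0)
        vol = phantom.simulate_lesion_volume(spec, seed=4)
        regions = roi.detect_enhancement_regions(
            vol.phases["CMP"], vol.masks["tumor"], vol.spacing,
            exclude_mask=vol.masks["cysts"])
        for reg in regions:
            assert not np.any(reg & vol.masks["cysts"])

    def test_empty_tumor_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi.detect_enhancement_regions(
                np.zeros((3, 10, 10)), np.zeros((3, 10, 10), bool), SP)


def _disc_mask(shape, radius_px, nz=3):
    m = np.zeros((nz,) + shape, bool)
    rr = (np.arange(shape[0])[:, None] - shape[0] // 2) ** 2
    cc = (np.arange(shape[1])[None, :] - shape[1] // 2) ** 2
    m[nz // 2] = rr + cc <= radius_px**2
    return m


class TestFixedAreaROI:
    def test_pixel_count_respects_area_range(self):
        region = _disc_mask((60, 60), 12)
        g = roi.place_fixed_area_roi(region, (10, 20), SP)
        count = g.pixel_mask((60, 60), SP).sum()
        assert 10 / 0.49 <= count <= 20 / 0.49  # 21..40 pixels at 0.7 mm

    def test_small_disc_is_covered_up_to_discretization(self):
        rpx = np.sqrt(20 / np.pi) / 0.7
        disc = _disc_mask((40, 40), rpx)
        g = roi.place_fixed_area_roi(disc, (10, 20), SP)
        m = g.pixel_mask((40, 40), SP)
        assert not np.any(m & ~disc[1])  # ROI inside the region
        assert 10 <= m.sum() * 0.49 <= 20

    def test_region_too_small_for_minimum_area(self):
        small = _disc_mask((40, 40), np.sqrt(30 / np.pi) / 0.7)
        with pytest.raises(roi.RegionTooSmallError):
            roi.place_fixed_area_roi(small, (50, 100), SP)

    def test_support_mask_lets_roi_exceed_region(self):
        region = _disc_mask((80, 80), 3)  # ~14 mm^2 bright patch
        support = _disc_mask((80, 80), 30)  # generous surrounding tumor
        g = roi.place_fixed_area_roi(region, (50, 100), SP,
                                     support_mask=support)
        assert 50 <= g.pixel_mask((80, 80), SP).sum() * 0.49 <= 100


class TestWholeTumorROI:
    def test_sphere_radius_minus_margin(self, homogeneous_volume):
        _, vol = homogeneous_volume  # radius 15 mm sphere
        g = roi.place_whole_tumor_roi(vol.masks["tumor"], 2.5, SP)
        assert g.radius_mm == pytest.approx(12.5, abs=0.7)

    def test_zero_margin_gives_inscribed_circle(self, homogeneous_volume):
        _, vol = homogeneous_volume
        g = roi.place_whole_tumor_roi(vol.masks["tumor"], 0.0, SP)
        assert g.radius_mm == pytest.approx(15.0, abs=0.7)

    def test_tiny_tumor_rejected(self):
        tiny = _disc_mask((20, 20), 2.0 / 0.7)
        with pytest.raises(roi.MarginTooLargeError):
            roi.place_whole_tumor_roi(tiny, 2.5, SP)


class TestMeasureROI:
    def test_uniform_grid(self):
        grid = np.full((3, 40, 40), 100.0)
        g = roi.ROIGeometry(1, 20, 20, 5.0)
        m = roi.measure_roi(grid, g, SP)
        assert m.mean_hu == 100.0 and m.sd_hu == 0.0
        assert m.area_mm2 == pytest.approx(m.pixel_count * 0.49)

    def test_two_point_distribution(self):
        grid = np.zeros((3, 40, 40))
        g = roi.ROIGeometry(1, 20, 20, 5.0)
        mask = g.pixel_mask((40, 40), SP)
        idx = np.argwhere(mask)
        half = len(idx) // 2
        for r, c in idx[:half]:
            grid[1, r, c] = 100.0
        m = roi.measure_roi(grid, g, SP)
        if len(idx) % 2 == 0:  # exact closed form for an even split
            assert m.mean_hu == pytest.approx(50.0)
            assert m.sd_hu == pytest.approx(50.0)

    def test_roi_outside_grid_rejected(self):
        grid = np.zeros((3, 20, 20))
        with pytest.raises(ValueError, match="outside"):
            roi.measure_roi(grid, roi.ROIGeometry(1, 19, 19, 5.0), SP)
        with pytest.raises(ValueError, match="slice"):
            roi.measure_roi(grid, roi.ROIGeometry(7, 10, 10, 2.0), SP)

    def test_patch_mean_recovered_within_3_se(self, structured_volume):
        spec, vol = structured_volume
        regions = roi.detect_enhancement_regions(
            vol.phases["CMP"], vol.masks["tumor"], vol.spacing)
        g = roi.place_fixed_area_roi(regions[0], (10, 20), vol.spacing,
                                     intensity=vol.phases["CMP"])
        m = roi.measure_roi(vol.phases["CMP"], g, vol.spacing)
        target = spec.phase_hu["CMP"] + spec.patch_contrast_hu
        sd = np.sqrt(spec.noise("CMP") ** 2 + spec.tumor_noise("CMP") ** 2)
        assert abs(m.mean_hu - target) < 3 * sd / np.sqrt(m.pixel_count)


class TestProtocol:
    def test_noise_free_homogeneous_phantom(self, homogeneous_volume,
                                            noise_free_protocol):
        spec, vol = homogeneous_volume
        res = roi.measure_lesion_protocol(vol, noise_free_protocol)
        for ph in phantom.PHASES:
            m = res.record.phases[ph]
            assert m.avt_roi1 == pytest.approx(spec.phase_hu[ph], abs=1e-9)
            assert m.avt_roi1 == m.avt_roi2 == m.avt_roi3
            assert m.hdt == 0.0
            assert m.avc == pytest.approx(spec.cortex_hu[ph], abs=1e-9)

    def test_roi3_geometry_propagated_across_phases(self, structured_volume,
                                                    noise_free_protocol):
        _, vol = structured_volume
        res = roi.measure_lesion_protocol(vol, noise_free_protocol)
        g = res.geometries["roi3"]
        # copying the EP geometry to a co-registered phase reproduces HDT
        m_ep = roi.measure_roi(vol.phases["EP"], g, vol.spacing)
        assert res.record.phases["EP"].hdt == pytest.approx(m_ep.sd_hu)

    def test_missing_phase_rejected(self, structured_volume):
        _, vol = structured_volume
        partial = phantom.FourPhaseVolume(
            phases={ph: g for ph, g in vol.phases.items() if ph != "EP"},
            spacing=vol.spacing, masks=vol.masks)
        with pytest.raises(roi.IncompleteFourPhaseError):
            roi.measure_lesion_protocol(partial)

    def test_translation_invariance(self, structured_volume):
        _, vol = structured_volume
        shift = (1, 3, -2)
        shifted = phantom.FourPhaseVolume(
            phases={ph: np.roll(g, shift, axis=(0, 1, 2))
                    for ph, g in vol.phases.items()},
            spacing=vol.spacing,
            masks={k: np.roll(m, shift, axis=(0, 1, 2))
                   for k, m in vol.masks.items()})
        cfg = roi.ProtocolConfig(observer_noise_sd=0.0, seed=0)
        a = roi.measure_lesion_protocol(vol, cfg).record
        b = roi.measure_lesion_protocol(shifted, cfg).record
        for ph in phantom.PHASES:
            for attr in ("avt_roi1", "avt_roi2", "avt_roi3", "avc",
                         "hdt", "hdp"):
                assert getattr(a.phases[ph], attr) == pytest.approx(
                    getattr(b.phases[ph], attr), abs=1e-9)

    def test_roi_variant_ordering_on_patchy_phantom(self, structured_volume,
                                                    noise_free_protocol):
        # patches are the intensity maxima: smaller ROIs read higher CMP HU
        _, vol = structured_volume
        m = roi.measure_lesion_protocol(
            vol, noise_free_protocol).record.phases["CMP"]
        assert m.avt_roi2 >= m.avt_roi1 >= m.avt_roi3
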