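"""Region selections and the derived area arithmetic."""

import numpy as np
import pytest

from rootcell import (CalibratedImage, PhantomSpec, PipelineParams,
                      RegionSelection, compute_areas, generate_phantom,
                      select_central_metaxylem, select_cortex, select_root,
                      select_stele)
from rootcell.segmentation import _make_selection


def _disk_mask(shape, center, radius):
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return np.hypot(rr, cc) <= radius


class TestSelectRoot:
    def test_phantom_root_area(self, clean_phantom, params):
        _, img, truth = clean_phantom
        root = select_root(img, params)
        assert root.area_px == pytest.approx(np.pi * 120 ** 2, rel=0.03)
        assert root.n_components == 1

    def test_debris_ignored(self, clean_phantom):
        # fixed threshold and min-max stretch isolate the
        # largest-component rule from histogram-dependent preprocessing
        params = PipelineParams(threshold_override=100, contrast_saturation=0.0)
        _, img, _ = clean_phantom
        base = select_root(img, params)
        px = img.pixels.copy()
        # debris blob: above threshold but below the image maximum, so the
        # min-max stretch is unaffected and only component choice matters
        px[20:70, 20:70][_disk_mask((50, 50), (25, 25), 24)] = 180
        noisy = CalibratedImage(px, img.modality, source_id="debris")
        root = select_root(noisy, params)
        assert np.array_equal(root.mask, base.mask)

    def test_blank_image_rejected(self, params):
        img = CalibratedImage(np.zeros((128, 128), dtype=np.uint8), source_id="blank")
        with pytest.raises(ValueError, match="no foreground"):
            select_root(img, params)

    def test_truncated_section_rejected(self, params):
        px = np.zeros((128, 128), dtype=np.uint8)
        px[_disk_mask((128, 128), (0, 0), 90)] = 220  # quarter disk in a corner
        img = CalibratedImage(px, source_id="cut")
        with pytest.raises(ValueError, match="borders"):
            select_root(img, params)


class TestSelectStele:
    @staticmethod
    def _root_from_mask(mask):
        return _make_selection("root", mask)

    @pytest.mark.parametrize("proportion", [4.0, 2.0])
    def test_area_proportion(self, proportion):
        root = self._root_from_mask(_disk_mask((400, 400), (200, 200), 150))
        stele = select_stele(root, proportion)
        assert stele.area_px == pytest.approx(root.area_px / proportion, rel=0.02)

    def test_elliptical_root_matched_moments(self):
        rr = np.arange(400)[:, None] - 200.0
        cc = np.arange(400)[None, :] - 200.0
        mask = (rr / 80) ** 2 + (cc / 160) ** 2 <= 1  # 2:1 axes along rows/cols
        root = self._root_from_mask(mask)
        stele = select_stele(root, 4.0)
        # moments oracle computed directly from the stele mask
        sr, sc = np.nonzero(stele.mask)
        assert np.mean(sr) == pytest.approx(200, abs=1.5)
        assert np.mean(sc) == pytest.approx(200, abs=1.5)
        ratio = np.std(sc) / np.std(sr)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_contained_in_root(self, clean_phantom, params):
        _, img, _ = clean_phantom
        root = select_root(img, params)
        stele = select_stele(root, 4.0)
        assert np.all(root.mask[stele.mask])

    def test_bad_proportion_rejected(self):
        root = self._root_from_mask(_disk_mask((200, 200), (100, 100), 80))
        with pytest.raises(ValueError):
            select_stele(root, 1.0)


class TestSelectCentralMetaxylem:
    def test_single_vessel(self, clean_phantom, params):
        _, img, truth = clean_phantom
        root = select_root(img, params)
        stele = select_stele(root, 4.0)
        cmx, ncm = select_central_metaxylem(img, stele, params)
        assert ncm == 1
        assert cmx.area_px == pytest.approx(truth.true_cma, rel=0.10)
        assert np.all(stele.mask[cmx.mask])

    def test_four_vessels(self, params):
        spec = PhantomSpec(noise_sigma=0.0, n_cmx=4, cmx_radius=11.0)
        img, truth = generate_phantom(spec)
        root = select_root(img, params)
        stele = select_stele(root, 4.0)
        _, ncm = select_central_metaxylem(img, stele, params)
        assert ncm == truth.true_ncm == 4

    def test_manual_override(self, clean_phantom, params):
        _, img, _ = clean_phantom
        root = select_root(img, params)
        stele = select_stele(root, 4.0)
        cmx, ncm = select_central_metaxylem(img, stele, params.replace(manual_ncm=2))
        assert ncm == 2
        assert cmx.area_px > 0  # automatic selection retained

    def test_no_vessels_warns(self, params):
        spec = PhantomSpec(noise_sigma=0.0, n_cmx=0, n_mx=0)
        img, _ = generate_phantom(spec)
        root = select_root(img, params)
        stele = select_stele(root, 4.0)
        cmx, ncm = select_central_metaxylem(img, stele, params)
        assert ncm == 0 and cmx.area_px == 0
        assert any("no central metaxylem" in w for w in cmx.warnings)


class TestSelectCortex:
    def test_phantom_cortex_area(self, clean_phantom, params):
        _, img, truth = clean_phantom
        root = select_root(img, params)
        stele = select_stele(root, 4.0)
        cortex = select_cortex(img, root, stele, params)
        assert cortex.area_px == pytest.approx(truth.true_cortex_area, rel=0.03)

    def test_containment_chain(self, noisy_phantom, params):
        _, img, _ = noisy_phantom
        root = select_root(img, params)
        stele = select_stele(root, 4.0)
        cortex = select_cortex(img, root, stele, params)
        assert np.all(cortex.mask[stele.mask])
        assert np.all(root.mask[cortex.mask])

    def test_missing_band_falls_back(self, params):
        # bright disk with no internal structure: no sclerenchyma band
        px = np.full((256, 256), 10, dtype=np.uint8)
        px[_disk_mask((256, 256), (128, 128), 100)] = 200
        img = CalibratedImage(px, source_id="flat")
        root = select_root(img, params)
        stele = select_stele(root, 4.0)
        cortex = select_cortex(img, root, stele, params)
        assert any("falling back" in w for w in cortex.warnings)
        assert np.all(root.mask[cortex.mask])


class TestComputeAreas:
    @staticmethod
    def _sel(label, area, shape=(64, 64)):
        mask = np.zeros(shape, dtype=bool)
        mask.ravel()[:area] = True
        return _make_selection(label, mask)

    def test_subtraction_identities(self):
        root = self._sel("root", 4000)
        cortex = self._sel("cortex", 3000)
        stele = self._sel("stele", 1000)
        cmx = self._sel("central_metaxylem", 100)
        areas = compute_areas(root, stele, cmx, cortex)
        assert areas.ela == 1000 and areas.ctxa == 2000
        assert areas.ela + areas.cortex_measured == areas.roota
        assert areas.ctxa + areas.stelea == areas.cortex_measured

    def test_calibration_scales_squared(self):
        root = self._sel("root", 4000)
        cortex = self._sel("cortex", 3000)
        stele = self._sel("stele", 1000)
        cmx = self._sel("central_metaxylem", 100)
        areas = compute_areas(root, stele, cmx, cortex, calibration=0.5)
        assert areas.roota == 4000 * 0.25 and areas.cma == 100 * 0.25

    def test_zero_cortex_minus_stele_accepted(self):
        root = self._sel("root", 4000)
        cortex = self._sel("cortex", 1000)
        stele = self._sel("stele", 1000)
        cmx = self._sel("central_metaxylem", 100)
        assert compute_areas(root, stele, cmx, cortex).ctxa == 0

    def test_ordering_violation_named(self):
        root = self._sel("root", 4000)
        cortex = self._sel("cortex", 900)
        stele = self._sel("stele", 1000)
        cmx = self._sel("central_metaxylem", 100)
        with pytest.raises(ValueError, match="cortex_measured >= stelea"):
            compute_areas(root, stele, cmx, cortex)


class TestRegionSelection:
    def test_area_must_match_mask(self):
        with pytest.raises(ValueError):
            RegionSelection("root", np.ones((8, 8), dtype=bool), [], area_px=3)

    def test_label_validated(self):
        with pytest.raises(ValueError):
            RegionSelection("blob", np.ones((8, 8), dtype=bool), [], area_px=64)
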