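import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from synapdyn import colocalization as coloc
from synapdyn import structure_detection as det
from synapdyn import synthetic_data as sd
from synapdyn.colocalization import (
    ColocalizationError,
    CompartmentMasks,
    MaskPair,
)
from synapdyn.structure_detection import DetectionParams

bool_masks = hnp.arrays(dtype=bool, shape=(16, 16))


class TestOverlapMask:
    def test_identical_masks_idempotent(self, rng):
        m = rng.random((32, 32)) > 0.5
        assert np.array_equal(coloc.overlap_mask(MaskPair(m, m)), m)

    def test_disjoint_masks_empty(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[:4] = True
        b[4:] = True
        assert not coloc.overlap_mask(MaskPair(a, b)).any()

    def test_random_masks_equal_pixelwise_and(self):
        rng = np.random.default_rng(3)
        a = rng.random((32, 32)) > 0.5
        b = rng.random((32, 32)) > 0.5
        assert np.array_equal(coloc.overlap_mask(MaskPair(a, b)), a & b)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(bool_masks, bool_masks)
    def test_subtraction_construction_equals_and(self, a, b):
        assert np.array_equal(coloc.overlap_mask(MaskPair(a, b)), a & b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ColocalizationError, match="shapes differ"):
            MaskPair(np.ones((4, 4), bool), np.ones((5, 5), bool))


class TestPercentStructuresOverlapping:
    def _detect(self, stack, truth, channel):
        params = DetectionParams(
            threshold_mode="manual",
            threshold_value=truth.params["suggested_threshold"],
        )
        mask = det.binarize(stack, channel, params)
        return det.detect_structures(mask, params), mask

    def test_all_true_mask_gives_100(self):
        stack, truth = sd.make_cluster_scene(8, 0, 0.0, seed=1)
        ss, _ = self._detect(stack, truth, 0)
        assert coloc.percent_structures_overlapping(ss, np.ones(stack.frame_shape, bool)) == 100.0

    def test_empty_mask_gives_0(self):
        stack, truth = sd.make_cluster_scene(8, 0, 0.0, seed=1)
        ss, _ = self._detect(stack, truth, 0)
        assert coloc.percent_structures_overlapping(ss, np.zeros(stack.frame_shape, bool)) == 0.0

    def test_planted_half_overlap_recovered_exactly(self):
        stack, truth = sd.make_cluster_scene(20, 20, 0.5, seed=7)
        ss_a, _ = self._detect(stack, truth, 0)
        _, mask_b = self._detect(stack, truth, 1)
        assert coloc.percent_structures_overlapping(ss_a, mask_b[0, 0]) == 50.0

    def test_empty_structures_undefined(self):
        stack, truth = sd.make_cluster_scene(5, 0, 0.0, seed=1)
        params = DetectionParams(threshold_mode="manual", threshold_value=1e6)
        ss = det.detect_structures(det.binarize(stack, 0, params), params)
        with pytest.raises(ColocalizationError, match="undefined"):
            coloc.percent_structures_overlapping(ss, np.ones(stack.frame_shape, bool))

    def test_monotone_in_mask_b(self, rng):
        stack, truth = sd.make_cluster_scene(12, 12, 0.5, seed=9)
        ss_a, _ = self._detect(stack, truth, 0)
        _, mask_b = self._detect(stack, truth, 1)
        base = mask_b[0, 0]
        pct = coloc.percent_structures_overlapping(ss_a, base)
        grown = base.copy()
        grown[rng.random(base.shape) > 0.6] = True
        assert coloc.percent_structures_overlapping(ss_a, grown) >= pct

    def test_min_overlap_criterion(self):
        # one 3x3 structure sharing exactly 2 px with mask B
        mask_a = np.zeros((8, 8), dtype=bool)
        mask_a[2:5, 2:5] = True
        mask_b = np.zeros((8, 8), dtype=bool)
        mask_b[2, 2:4] = True
        ss = det.detect_structures(mask_a, DetectionParams(min_size_px=1))
        assert coloc.percent_structures_overlapping(ss, mask_b, min_overlap_px=2) == 100.0
        assert coloc.percent_structures_overlapping(ss, mask_b, min_overlap_px=3) == 0.0


class TestCompartments:
    def test_cytosol_is_complement_within_cell(self):
        img = np.zeros((10, 10))
        img[:, :5] = 100.0
        cell = np.ones((10, 10), bool)
        comp = coloc.build_compartments(img, 50.0, cell)
        assert np.array_equal(comp.cluster, img > 50)
        assert np.array_equal(comp.cytosol, ~(img > 50))

    def test_without_cell_mask_cytosol_is_field_remainder(self):
        img = np.zeros((6, 6))
        img[0, 0] = 10
        comp = coloc.build_compartments(img, 5.0)
        assert comp.cluster.sum() == 1
        assert comp.cytosol.sum() == 35

    def test_degenerate_threshold_rejected(self):
        img = np.full((5, 5), 10.0)
        with pytest.raises(ColocalizationError, match="cluster"):
            coloc.build_compartments(img, 100.0)
        with pytest.raises(ColocalizationError, match="cytosol"):
            coloc.build_compartments(img, 1.0)

    def test_overlapping_compartments_rejected(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(ColocalizationError, match="overlap"):
            CompartmentMasks(cluster=m, cytosol=m)


class TestIntensityFoldChange:
    def _planted(self, ratio, noise=None, seed=0):
        mask = sd.default_cluster_mask(seed=seed)
        cluster_img = 10.0 + 150.0 * mask
        measure = np.where(mask, 50.0 * ratio, 50.0)
        if noise is not None:
            rng = np.random.default_rng(seed)
            measure = sd._apply_noise(measure, noise, rng)
        comp = coloc.build_compartments(cluster_img, 85.0)
        return measure, comp

    def test_uniform_image_fold_is_one(self):
        measure, comp = self._planted(1.0)
        assert coloc.intensity_fold_change(measure, comp) == pytest.approx(1.0)

    @pytest.mark.parametrize("ratio", [2.0, 3.0, 5.0])
    def test_planted_ratio_recovered(self, ratio):
        measure, comp = self._planted(ratio)
        assert coloc.intensity_fold_change(measure, comp) == pytest.approx(ratio, rel=1e-9)

    def test_scale_invariance(self):
        measure, comp = self._planted(3.0)
        f1 = coloc.intensity_fold_change(measure, comp)
        f2 = coloc.intensity_fold_change(measure * 17.3, comp)
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_zero_cytosol_mean_rejected(self):
        _, comp = self._planted(2.0)
        with pytest.raises(ColocalizationError, match="cytosol"):
            coloc.intensity_fold_change(np.zeros(comp.cluster.shape), comp)


class TestNuclearRatio:
    def _masks(self):
        cell = np.zeros((20, 20), bool)
        cell[2:18, 2:18] = True  # 256 px
        nuc = np.zeros((20, 20), bool)
        nuc[5:13, 5:13] = True  # 64 px = 25% of cell
        return nuc, cell

    def test_all_signal_in_nucleus_gives_one(self):
        nuc, cell = self._masks()
        img = np.where(nuc, 40.0, 0.0)
        assert coloc.nuclear_intensity_ratio(img, nuc, cell) == pytest.approx(1.0)

    def test_uniform_signal_proportional_to_area(self):
        nuc, cell = self._masks()
        img = np.full((20, 20), 9.0)
        assert coloc.nuclear_intensity_ratio(img, nuc, cell) == pytest.approx(0.25)

    def test_planted_four_to_one_closed_form(self):
        nuc, cell = self._masks()
        img = np.where(nuc, 4.0, 1.0) * cell
        # nucleus 64 px at 4, cytoplasm 192 px at 1
        expected_cell = 64 * 4 / (64 * 4 + 192 * 1)
        expected_cyt = 64 * 4 / (192 * 1)
        assert coloc.nuclear_intensity_ratio(img, nuc, cell) == pytest.approx(expected_cell)
        assert coloc.nuclear_intensity_ratio(
            img, nuc, cell, denominator="cytoplasm"
        ) == pytest.approx(expected_cyt)

    def test_empty_nucleus_rejected(self):
        _, cell = self._masks()
        with pytest.raises(ColocalizationError, match="nucleus"):
            coloc.nuclear_intensity_ratio(np.ones((20, 20)), np.zeros((20, 20), bool), cell)
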