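"""Nucleus↔cell matching, cytoplasm derivation, and N/C ratio computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers_oracles import brute_force_ki67, brute_force_matches, crop_to_labels
from spheroquant import subcellular as sub
from spheroquant.volumes import IntensityVolume, LabeledVolume

SP1 = (1.0, 1.0, 1.0)


def lv(data):
    return LabeledVolume(np.asarray(data, dtype=np.int32), SP1)


def small_cell_pair():
    """27-voxel cubic cell with an 8-voxel nucleus fully inside."""
    cell = np.zeros((5, 5, 5), dtype=np.int32)
    cell[1:4, 1:4, 1:4] = 5
    nuc = np.zeros((5, 5, 5), dtype=np.int32)
    nuc[1:3, 1:3, 1:3] = 5
    return lv(nuc), lv(cell)


class TestMatching:
    def test_identical_masks_score_one(self):
        nuc, _ = small_cell_pair()
        for metric in ("iou", "nucleus_coverage"):
            (m,) = sub.match_nuclei_to_cells(nuc, nuc, metric=metric)
            assert m.overlap_score == 1.0

    def test_contained_nucleus_metric_difference(self):
        nuc, cell = small_cell_pair()
        assert sub.match_nuclei_to_cells(nuc, cell, metric="iou") == []
        (m,) = sub.match_nuclei_to_cells(nuc, cell, metric="nucleus_coverage")
        assert m.overlap_score == 1.0
        # the strict-Jaccard score of this pair is 8/27
        (m_iou,) = sub.match_nuclei_to_cells(nuc, cell, threshold=0.2, metric="iou")
        assert m_iou.overlap_score == pytest.approx(8 / 27)

    @pytest.mark.parametrize("metric", ["iou", "nucleus_coverage"])
    def test_matches_brute_force_all_pairs(self, clean_spheroid, metric):
        nuc, cell = crop_to_labels(
            clean_spheroid.cell_labels.data, clean_spheroid.nucleus_labels.data
        )[::-1]
        got = sub.match_nuclei_to_cells(
            lv(nuc), lv(cell), threshold=0.3, metric=metric
        )
        oracle = brute_force_matches(nuc, cell, threshold=0.3, metric=metric)
        assert [(m.cell_id, m.nucleus_id) for m in got] == [
            (c, n) for c, n, _ in oracle
        ]
        for m, (_, _, s) in zip(got, oracle):
            assert m.overlap_score == pytest.approx(s, rel=1e-12)

    def test_grid_mismatch_errors(self):
        nuc, _ = small_cell_pair()
        other = lv(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            sub.match_nuclei_to_cells(nuc, other)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_iou_never_exceeds_coverage(self, seed):
        rng = np.random.default_rng(seed)
        nuc = lv(rng.integers(0, 4, (6, 6, 6)))
        cell = lv(rng.integers(0, 4, (6, 6, 6)))
        ious = sub.match_nuclei_to_cells(nuc, cell, threshold=0.0, metric="iou")
        covs = sub.match_nuclei_to_cells(
            nuc, cell, threshold=0.0, metric="nucleus_coverage"
        )
        iou_by_pair = {(m.cell_id, m.nucleus_id): m.overlap_score for m in ious}
        cov_by_pair = {(m.cell_id, m.nucleus_id): m.overlap_score for m in covs}
        for pair in iou_by_pair.keys() & cov_by_pair.keys():
            assert 0.0 <= iou_by_pair[pair] <= cov_by_pair[pair] <= 1.0


class TestCytoplasm:
    def test_cube_minus_nucleus(self):
        nuc, cell = small_cell_pair()
        matches = sub.match_nuclei_to_cells(nuc, cell)
        cyto = sub.derive_cytoplasm(cell, nuc, matches)
        assert (cyto.data == 5).sum() == 19
        assert not ((cyto.data > 0) & (nuc.data > 0)).any()

    def test_nucleus_equals_cell_gives_empty_cytoplasm(self):
        nuc, _ = small_cell_pair()
        matches = sub.match_nuclei_to_cells(nuc, nuc)
        cyto = sub.derive_cytoplasm(nuc, nuc, matches)
        assert not cyto.data.any()
        img = IntensityVolume(np.ones(nuc.shape), SP1)
        records, qc = sub.compartment_means_and_ratio(img, nuc, cyto, matches, 0.0)
        assert records == []
        assert qc["empty_cytoplasm"] == 1

    def test_partition_of_cell_voxels(self, clean_spheroid):
        cell = clean_spheroid.cell_labels
        nuc = clean_spheroid.nucleus_labels
        matches = sub.match_nuclei_to_cells(nuc, cell)
        cyto = sub.derive_cytoplasm(cell, nuc, matches)
        # voxelwise: cytoplasm ∩ nucleus = ∅ and cytoplasm ∪ nucleus = cell
        assert not ((cyto.data > 0) & (nuc.data > 0)).any()
        matched = {m.cell_id for m in matches}
        for i in list(matched)[:10]:
            cm = cell.data == i
            assert np.array_equal(cm, (cyto.data == i) | (nuc.data == i))


class TestBackgroundAndRatio:
    def test_constant_background(self):
        nuc, cell = small_cell_pair()
        img = IntensityVolume(np.full(cell.shape, 7.0), SP1)
        assert sub.background_level(img, cell) == 7.0

    def test_forced_background_mean(self):
        cell = np.ones((1, 1, 20), dtype=np.int32)
        cell[0, 0, :10] = 0
        img = np.zeros((1, 1, 20))
        img[0, 0, :10] = np.arange(1, 11)
        assert sub.background_level(
            IntensityVolume(img, SP1), lv(cell)
        ) == pytest.approx(5.5)

    def test_no_background_voxels_errors(self):
        cell = lv(np.ones((3, 3, 3)))
        img = IntensityVolume(np.ones((3, 3, 3)), SP1)
        with pytest.raises(ValueError):
            sub.background_level(img, cell)

    def test_forced_ratio_arithmetic(self):
        nuc, cell = small_cell_pair()
        img = np.full(cell.shape, 20.0)
        img[(cell.data > 0) & (nuc.data == 0)] = 70.0
        img[nuc.data > 0] = 120.0
        matches = sub.match_nuclei_to_cells(nuc, cell)
        cyto = sub.derive_cytoplasm(cell, nuc, matches)
        records, _ = sub.compartment_means_and_ratio(
            IntensityVolume(img, SP1), nuc, cyto, matches, background=20.0
        )
        assert records[0].nc_ratio == pytest.approx(2.0, rel=1e-12)

    def test_uniform_signal_gives_unit_ratio(self, clean_spheroid):
        cell = clean_spheroid.cell_labels
        nuc = clean_spheroid.nucleus_labels
        matches = sub.match_nuclei_to_cells(nuc, cell)
        cyto = sub.derive_cytoplasm(cell, nuc, matches)
        img = IntensityVolume(np.full(cell.shape, 42.0), cell.spacing_um)
        records, _ = sub.compartment_means_and_ratio(img, nuc, cyto, matches, 0.0)
        assert all(r.nc_ratio == pytest.approx(1.0, rel=1e-12) for r in records)

    def test_programmed_ratios_recovered_exactly(self, clean_spheroid):
        """No blur/noise: recovered N/C equals programmed truth to 1e-9."""
        cell = clean_spheroid.cell_labels
        nuc = clean_spheroid.nucleus_labels
        matches = sub.match_nuclei_to_cells(nuc, cell)
        cyto = sub.derive_cytoplasm(cell, nuc, matches)
        bg = sub.background_level(clean_spheroid.channels["yap"], cell)
        records, _ = sub.compartment_means_and_ratio(
            clean_spheroid.channels["yap"], nuc, cyto, matches, bg
        )
        truth = clean_spheroid.truth.set_index("id").true_nc_ratio
        assert len(records) == len(truth)
        for r in records:
            assert r.nc_ratio == pytest.approx(truth[r.cell_id], rel=1e-9)

    @settings(deadline=None, max_examples=20)
    @given(st.floats(-30.0, 80.0))
    def test_background_offset_invariance(self, c):
        """Adding a constant to the volume leaves every N/C ratio unchanged."""
        nuc, cell = small_cell_pair()
        img = np.full(cell.shape, 20.0)
        img[(cell.data > 0) & (nuc.data == 0)] = 70.0
        img[nuc.data > 0] = 120.0
        matches = sub.match_nuclei_to_cells(nuc, cell)
        cyto = sub.derive_cytoplasm(cell, nuc, matches)

        def ratio(arr):
            vol = IntensityVolume(arr, SP1)
            bg = sub.background_level(vol, cell)
            recs, _ = sub.compartment_means_and_ratio(vol, nuc, cyto, matches, bg)
            return recs[0].nc_ratio

        assert ratio(img + c) == pytest.approx(ratio(img), rel=1e-9)

    @settings(deadline=None, max_examples=20)
    @given(st.floats(0.01, 100.0))
    def test_gain_invariance_at_zero_background(self, k):
        nuc, cell = small_cell_pair()
        img = np.zeros(cell.shape)
        img[(cell.data > 0) & (nuc.data == 0)] = 50.0
        img[nuc.data > 0] = 100.0
        matches = sub.match_nuclei_to_cells(nuc, cell)
        cyto = sub.derive_cytoplasm(cell, nuc, matches)
        recs, _ = sub.compartment_means_and_ratio(
            IntensityVolume(img * k, SP1), nuc, cyto, matches, 0.0
        )
        assert recs[0].nc_ratio == pytest.approx(2.0, rel=1e-9)


class TestKi67Assignment:
    def test_object_inside_cell(self):
        nuc, cell = small_cell_pair()
        assert sub.assign_ki67(nuc, cell) == {5}

    def test_no_objects(self):
        _, cell = small_cell_pair()
        empty = lv(np.zeros(cell.shape))
        assert sub.assign_ki67(empty, cell) == set()

    def test_straddling_objects_match_brute_force(self):
        rng = np.random.default_rng(5)
        cell = lv(rng.integers(0, 5, (10, 10, 10)))
        ki = lv(rng.integers(0, 3, (10, 10, 10)))
        got = sub.assign_ki67(ki, cell, min_object_fraction=0.4)
        assert got == brute_force_ki67(ki.data, cell.data, 0.4)

    def test_generator_truth(self, clean_spheroid):
        got = sub.assign_ki67(
            clean_spheroid.ki67_labels, clean_spheroid.cell_labels
        )
        truth = set(
            clean_spheroid.truth.loc[clean_spheroid.truth.ki67_status, "id"]
        )
        assert got == truth
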