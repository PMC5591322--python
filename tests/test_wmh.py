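"""MRI arm: lesion filling, segmentation, WMH extraction, classification,
quadrant partition and region volumetry against phantom ground truth."""

import numpy as np
import pandas as pd
import pytest

from fusionwmh import (
    LabelMap,
    PartitionPlanes,
    SegmentationError,
    ValidationError,
    Volume3D,
    WMHThresholdParams,
    classify_pvh_dwmh,
    compute_region_volumes,
    extract_ventricles,
    extract_wmh,
    fill_lesions,
    partition_quadrants,
    segment_tissues,
)
from fusionwmh.phantom import MriPhantomSpec, make_mri_phantom
from fusionwmh.pipeline import run_mri
from fusionwmh.wmh import CSF, GM, WM, robust_wm_stats

from conftest import full_mask, uniform_volume


def _wm_block(shape=(24, 24, 24), mean=100.0, sd=2.0, seed=0):
    rng = np.random.default_rng(seed)
    vox = rng.normal(mean, sd, shape)
    aff = np.eye(4)
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0
    return Volume3D(vox, aff)


class TestFillLesions:
    def test_empty_prior_is_noop(self):
        t1 = _wm_block()
        empty = LabelMap(np.zeros(t1.shape, dtype=np.int16), t1.affine)
        out = fill_lesions(t1, empty, seed=0)
        np.testing.assert_array_equal(out.voxels, t1.voxels)

    def test_filled_mean_matches_ring_statistics(self):
        t1 = _wm_block(mean=100.0, sd=2.0, seed=1)
        lesion = np.zeros(t1.shape, dtype=bool)
        lesion[10:14, 10:14, 10:14] = True
        vox = np.array(t1.voxels)
        vox[lesion] = 40.0  # hypointense lesion
        t1 = t1.like(vox)
        out = fill_lesions(t1, LabelMap.from_mask(lesion, t1.affine), seed=2)
        n = lesion.sum()
        # filled values drawn from ring Normal(~100, ~2): mean of n draws
        # should sit within 3 standard errors
        assert abs(out.voxels[lesion].mean() - 100.0) < 3 * 2.0 / np.sqrt(n) + 0.2
        np.testing.assert_array_equal(out.voxels[~lesion], t1.voxels[~lesion])

    def test_deterministic_given_seed(self):
        t1 = _wm_block(seed=3)
        lesion = np.zeros(t1.shape, dtype=bool)
        lesion[5:8, 5:8, 5:8] = True
        prior = LabelMap.from_mask(lesion, t1.affine)
        a = fill_lesions(t1, prior, seed=7)
        b = fill_lesions(t1, prior, seed=7)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_lesion_covering_everything_fails(self):
        t1 = _wm_block()
        allmask = LabelMap.from_mask(np.ones(t1.shape, bool), t1.affine)
        with pytest.raises(ValidationError):
            fill_lesions(t1, allmask, seed=0)


class TestSegmentTissues:
    def test_three_class_phantom_misclassification_below_1pct(self):
        rng = np.random.default_rng(4)
        shape = (30, 30, 30)
        truth = rng.integers(1, 4, size=shape)
        means = {1: 30.0, 2: 70.0, 3: 110.0}
        vox = np.zeros(shape)
        for c, m in means.items():
            sel = truth == c
            vox[sel] = rng.normal(m, 5.0, sel.sum())
        vol = Volume3D(vox, np.eye(4))
        tm = segment_tissues(vol, full_mask(vol), seed=0)
        err = (tm.labels.labels != truth).mean()
        assert err < 0.01

    def test_constant_intensity_raises(self):
        vol = uniform_volume(50.0, (8, 8, 8))
        with pytest.raises((SegmentationError, ValidationError)):
            segment_tissues(vol, full_mask(vol), seed=0)

    def test_class_means_ordered_regardless_of_structure(self):
        rng = np.random.default_rng(5)
        vox = np.concatenate([rng.normal(m, 4.0, 2000)
                              for m in (110.0, 30.0, 70.0)])
        rng.shuffle(vox)
        vol = Volume3D(vox.reshape(20, 30, 10), np.eye(4))
        tm = segment_tissues(vol, full_mask(vol), seed=0)
        assert tm.class_means[CSF] < tm.class_means[GM] < tm.class_means[WM]


class TestExtractVentricles:
    def test_central_cavity_kept_surface_rim_rejected(self, small_mri_phantom):
        _, t1, flair, truth = small_mri_phantom
        tm = segment_tissues(
            fill_lesions(t1, truth["lesions"], seed=0,
                         wm_mask=truth["tissue"].labels == WM),
            truth["brain_mask"], seed=0)
        from fusionwmh.wmh import TissueMap  # noqa: F401
        vent = extract_ventricles(tm, truth["brain_mask"])
        got = vent.mask()
        want = truth["ventricles"].mask()
        dice = 2 * (got & want).sum() / max(1, got.sum() + want.sum())
        assert dice > 0.95
        # no surface CSF in the result: everything inside the WM core
        assert got.sum() < 1.5 * want.sum()

    def test_no_csf_gives_empty_mask(self):
        from fusionwmh.wmh import TissueMap
        labels = np.full((10, 10, 10), WM, dtype=np.int16)
        lm = LabelMap(labels, np.eye(4), {1: "CSF", 2: "GM", 3: "WM"})
        tm = TissueMap(lm, {CSF: 10.0, GM: 50.0, WM: 90.0})
        brain = LabelMap.from_mask(np.ones((10, 10, 10), bool), np.eye(4))
        vent = extract_ventricles(tm, brain)
        assert not vent.mask().any()

    def test_two_disjoint_cavities_both_returned(self):
        from scipy import ndimage

        from fusionwmh.wmh import TissueMap
        shape = (24, 24, 24)
        labels = np.full(shape, WM, dtype=np.int16)
        labels[8:11, 8:11, 10:14] = CSF
        labels[14:17, 14:17, 10:14] = CSF
        lm = LabelMap(labels, np.eye(4), {1: "CSF", 2: "GM", 3: "WM"})
        tm = TissueMap(lm, {CSF: 10.0, GM: 50.0, WM: 90.0})
        brain = LabelMap.from_mask(np.ones(shape, bool), np.eye(4))
        vent = extract_ventricles(tm, brain)
        _, n = ndimage.label(vent.mask())
        assert n == 2


class TestExtractWMH:
    def test_uniform_wm_yields_no_lesions(self):
        flair = _wm_block(seed=6)
        les = extract_wmh(flair, full_mask(flair), WMHThresholdParams())
        assert les.n_components == 0

    def test_recovers_exact_voxel_set_at_six_sigma(self):
        # two spheres at nominal WM mean + 6 sd in noise-free WM: the
        # threshold at mean + 3 sd must recover exactly the truth set
        shape = (40, 40, 40)
        vox = np.full(shape, 100.0)
        ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape),
                                 indexing="ij")
        truth = ((ii - 12) ** 2 + (jj - 12) ** 2 + (kk - 20) ** 2 <= 16) | \
                ((ii - 28) ** 2 + (jj - 28) ** 2 + (kk - 20) ** 2 <= 25)
        vox[truth] = 100.0 + 6 * 2.0
        flair = Volume3D(vox, np.eye(4))
        les = extract_wmh(flair, full_mask(flair),
                          WMHThresholdParams(k_sigma=3.0))
        np.testing.assert_array_equal(les.mask(), truth)
        assert les.n_components == 2

    def test_noisy_phantom_recovery_superset_with_few_extras(
            self, small_mri_phantom):
        _, _, flair, truth = small_mri_phantom
        wm = (truth["tissue"].labels == WM) | truth["lesions"].mask()
        les = extract_wmh(flair, LabelMap.from_mask(wm, flair.affine),
                          WMHThresholdParams(k_sigma=3.0))
        tru = truth["lesions"].mask()
        got = les.mask()
        assert not (tru & ~got).any()          # nothing missed
        assert (got & ~tru).sum() <= 0.005 * tru.sum()  # rare noise voxels

    def test_small_speck_removed_by_size_filter(self):
        flair = _wm_block(seed=7)
        vox = np.array(flair.voxels)
        vox[5, 5, 5:8] = 200.0  # 3-voxel speck
        flair = flair.like(vox)
        les = extract_wmh(flair, full_mask(flair),
                          WMHThresholdParams(min_component_voxels=5))
        assert les.n_components == 0
        les2 = extract_wmh(flair, full_mask(flair),
                           WMHThresholdParams(min_component_voxels=3))
        assert les2.n_components == 1

    def test_empty_wm_mask_rejected(self):
        flair = _wm_block()
        empty = LabelMap(np.zeros(flair.shape, np.int16), flair.affine)
        with pytest.raises(ValidationError):
            extract_wmh(flair, empty, WMHThresholdParams())

    def test_threshold_monotone_in_k_sigma(self, small_mri_phantom):
        _, _, flair, truth = small_mri_phantom
        wm = (truth["tissue"].labels == WM) | truth["lesions"].mask()
        wm_mask = LabelMap.from_mask(wm, flair.affine)
        sets = []
        for k in (4.0, 3.0, 2.0):
            les = extract_wmh(flair, wm_mask,
                              WMHThresholdParams(k_sigma=k,
                                                 min_component_voxels=1))
            sets.append(les.mask())
        # decreasing k_sigma never shrinks the voxel set
        assert np.all(sets[0] <= sets[1])
        assert np.all(sets[1] <= sets[2])


def _single_lesion_map(offset_vox, affine, shape=(40, 40, 40)):
    labels = np.zeros(shape, dtype=np.int32)
    labels[offset_vox] = 1
    table = pd.DataFrame({"component": [1], "n_voxels": [1],
                          "volume_cc": [0.001],
                          "class": pd.Series([None], dtype=object),
                          "quadrant": pd.Series([None], dtype=object)})
    from fusionwmh.wmh import LesionComponentMap
    return LesionComponentMap(labels, affine, table)


class TestClassifyPvhDwmh:
    def _vent(self, shape=(40, 40, 40)):
        v = np.zeros(shape, dtype=bool)
        v[18:22, 15:25, 15:25] = True
        return LabelMap.from_mask(v, np.eye(4), "ventricles")

    def test_face_adjacent_component_is_pvh(self):
        vent = self._vent()
        les = _single_lesion_map((22, 20, 20), np.eye(4))  # face neighbour
        out = classify_pvh_dwmh(les, vent, d_mm=3.0)
        assert out.components["class"].iloc[0] == "PVH"

    def test_component_10mm_away_is_dwmh_at_3mm(self):
        vent = self._vent()
        les = _single_lesion_map((31, 20, 20), np.eye(4))  # 10 mm from x=21
        out = classify_pvh_dwmh(les, vent, d_mm=3.0)
        assert out.components["class"].iloc[0] == "DWMH"
        assert out.components["ventricle_distance_mm"].iloc[0] == pytest.approx(10.0)

    def test_distance_exactly_d_is_pvh_inclusive(self):
        vent = self._vent()
        les = _single_lesion_map((24, 20, 20), np.eye(4))  # exactly 3 mm
        out = classify_pvh_dwmh(les, vent, d_mm=3.0)
        assert out.components["ventricle_distance_mm"].iloc[0] == pytest.approx(3.0)
        assert out.components["class"].iloc[0] == "PVH"

    def test_empty_ventricles_all_dwmh_with_warning(self):
        les = _single_lesion_map((24, 20, 20), np.eye(4))
        empty = LabelMap(np.zeros((40, 40, 40), np.int16), np.eye(4))
        with pytest.warns(UserWarning):
            out = classify_pvh_dwmh(les, empty, d_mm=3.0)
        assert (out.components["class"] == "DWMH").all()


class TestPartitionQuadrants:
    def test_sign_conventions(self):
        grid = uniform_volume(0.0, (21, 21, 5))
        q = partition_quadrants(grid, PartitionPlanes(0.0, 0.0))
        x, y, _ = grid.world_coordinates()
        # voxel at world (+10, +10): right anterior
        sel = (x == 10) & (y == 10)
        assert set(np.unique(q.labels[sel])) == {1}  # RA
        assert q.lookup[1] == "RA"
        # boundary voxels (x=0 or y=0) assigned right/anterior
        assert set(np.unique(q.labels[(x == 0) & (y == 0)])) == {1}
        assert set(np.unique(q.labels[(x == -10) & (y == -10)])) == {4}  # LP

    def test_quadrants_partition_every_voxel(self):
        grid = uniform_volume(0.0, (12, 13, 7))
        q = partition_quadrants(grid, PartitionPlanes(1.3, -2.1))
        counts = np.bincount(q.labels.ravel(), minlength=5)
        assert counts[0] == 0
        assert counts[1:].sum() == np.prod(grid.shape)

    def test_shifting_central_plane_moves_exact_slab(self):
        grid = uniform_volume(0.0, (20, 30, 10))
        q0 = partition_quadrants(grid, PartitionPlanes(0.0, 0.0))
        q1 = partition_quadrants(grid, PartitionPlanes(0.0, 20.0))
        _, y, _ = grid.world_coordinates()
        ant0 = np.isin(q0.labels, (1, 3))
        ant1 = np.isin(q1.labels, (1, 3))
        moved = ant0 & ~ant1
        expect = (y >= 0.0) & (y < 20.0)
        np.testing.assert_array_equal(moved, expect)


class TestRegionVolumes:
    def test_unit_conversion_1000_voxels_is_1cc(self):
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        labels[10:20, 10:20, 0:10] = 1  # 1000 voxels, x,y >= 0 at 1mm iso
        aff = np.eye(4)
        aff[:3, 3] = (-9.5, -9.5, -9.5)
        table = pd.DataFrame({"component": [1], "n_voxels": [1000],
                              "volume_cc": [1.0], "class": ["PVH"],
                              "quadrant": [None]})
        from fusionwmh.wmh import LesionComponentMap
        les = LesionComponentMap(labels, aff, table)
        grid = Volume3D(np.zeros((20, 20, 20)), aff)
        q = partition_quadrants(grid, PartitionPlanes(0.0, 0.0))
        rv = compute_region_volumes(les, q)
        assert rv.pvh_ra == pytest.approx(1.0)
        assert rv.total == pytest.approx(1.0)
        assert sum(getattr(rv, c) for c in rv._CELLS if c != "pvh_ra") == 0.0

    def test_total_is_exact_sum_of_cells(self, small_mri_phantom):
        _, t1, flair, truth = small_mri_phantom
        res = run_mri(t1, flair, truth["planes"], seed=0)
        rv = res.volumes
        assert rv.total == pytest.approx(
            sum(getattr(rv, c) for c in rv._CELLS), abs=1e-12)

    def test_unclassified_lesions_rejected(self):
        les = _single_lesion_map((5, 5, 5), np.eye(4), (10, 10, 10))
        grid = Volume3D(np.zeros((10, 10, 10)), np.eye(4))
        q = partition_quadrants(grid, PartitionPlanes(0.0, 0.0))
        with pytest.raises(ValidationError):
            compute_region_volumes(les, q)


class TestPipelineRecovery:
    def test_region_volumes_within_5pct_and_classes_exact(self, mri_phantom_fine):
        _, t1, flair, truth = mri_phantom_fine
        res = run_mri(t1, flair, truth["planes"], seed=0)
        got = res.volumes.to_series()
        for cell, v in truth["region_volumes_cc"].items():
            assert got[cell] == pytest.approx(v, rel=0.05), cell
        # one recovered component per phantom lesion, each correctly classed
        comp = res.lesions.components
        assert len(comp) == len(truth["lesion_table"])
        merged = comp.sort_values("n_voxels").reset_index(drop=True)
        want = truth["lesion_table"].sort_values("n_voxels").reset_index(drop=True)
        assert list(merged["class"]) == list(want["class"])

    def test_mirror_symmetry_swaps_left_right(self, small_mri_phantom):
        spec, t1, flair, truth = small_mri_phantom
        res = run_mri(t1, flair, truth["planes"], seed=0)
        # reflect the phantom across the midsagittal plane: same affine,
        # data reversed along x (the x lattice is symmetric about 0)
        t1f = Volume3D(t1.voxels[::-1], t1.affine, t1.units)
        flairf = Volume3D(flair.voxels[::-1], flair.affine, flair.units)
        resf = run_mri(t1f, flairf, truth["planes"], seed=0)
        a, b = res.volumes, resf.volumes
        for cls in ("pvh", "dwmh"):
            for ap in ("a", "p"):
                assert getattr(a, f"{cls}_r{ap}") == pytest.approx(
                    getattr(b, f"{cls}_l{ap}"), abs=1e-9)
                assert getattr(a, f"{cls}_l{ap}") == pytest.approx(
                    getattr(b, f"{cls}_r{ap}"), abs=1e-9)

    def test_robust_wm_stats_ignore_hyperintense_tail(self):
        rng = np.random.default_rng(8)
        x = rng.normal(100.0, 2.0, 20000)
        x[:500] = 130.0  # lesion contamination
        vol = Volume3D(x.reshape(20, 50, 20), np.eye(4))
        mu, sd = robust_wm_stats(vol, np.ones(vol.shape, bool), k_sigma=3.0)
        assert abs(mu - 100.0) < 0.5
        assert abs(sd - 2.0) < 0.5
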