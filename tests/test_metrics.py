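"""Morphometrics: volume, CSSA, circularity, length, shape difference."""

import dataclasses

import numpy as np
import pytest

from limbcast import anatomy
from limbcast.anatomy import build_regions, standardise
from limbcast.metrics import (DIFF_LEGEND, circularity, cssa_mm2, limb_length_mm,
                              sample_slices, shape_difference, volume_mm3)
from limbcast.volume import BinaryMask


def make_mask(data, spacing=0.6):
    return BinaryMask(data=np.asarray(data, np.uint8), spacing_mm=spacing)


@pytest.fixture(scope="module")
def std_limb_and_partition(phantom96):
    _, truth = phantom96
    fr = truth["frame"]
    limb = standardise(truth["limb_mask"], fr)
    part = build_regions(fr, 40.0, tip_z_mm=anatomy.distal_tip_z_mm(limb))
    return limb, part


class TestVolume:
    def test_filled_cube_at_0p6mm(self):
        data = np.zeros((12, 12, 12))
        data[1:11, 1:11, 1:11] = 1
        assert volume_mm3(make_mask(data)) == pytest.approx(1000 * 0.216)

    def test_empty_mask_is_zero(self):
        assert volume_mm3(make_mask(np.zeros((4, 4, 4)))) == 0.0

    def test_quadrant_volumes_sum_exactly(self, std_limb_and_partition):
        limb, part = std_limb_and_partition
        vols = part.region_volumes(limb)
        assert sum(vols[q] for q in ("AL", "AM", "PL", "PM")) == \
            pytest.approx(volume_mm3(limb), abs=1e-9)


class TestCSSA:
    def test_100_pixels_at_0p6mm(self):
        data = np.zeros((3, 20, 20))
        data[1, 5:15, 5:15] = 1
        assert cssa_mm2(make_mask(data), 1) == pytest.approx(36.0)

    def test_rasterised_disc_area_within_1pct(self):
        yy, xx = np.mgrid[:64, :64]
        disc = ((yy - 31.5) ** 2 + (xx - 31.5) ** 2 <= 25 ** 2)
        m = make_mask(disc[None])
        assert cssa_mm2(m, 0) == pytest.approx(np.pi * 25 ** 2 * 0.36, rel=0.01)

    def test_taper_makes_proximal_slices_larger(self, phantom96):
        _, truth = phantom96
        limb = truth["limb_mask"]
        # above the distal cap the taper is monotone
        slices = range(30, 75, 10)
        areas = [cssa_mm2(limb, i) for i in slices]
        assert all(a < b for a, b in zip(areas, areas[1:]))

    def test_empty_slice_is_zero(self, phantom96):
        _, truth = phantom96
        assert cssa_mm2(truth["limb_mask"], 0) == 0.0


class TestCircularity:
    def test_rasterised_disc_is_one(self):
        yy, xx = np.mgrid[:64, :64]
        disc = ((yy - 31.5) ** 2 + (xx - 31.5) ** 2 <= 25 ** 2)
        assert circularity(make_mask(disc[None]), 0) == pytest.approx(1.0, abs=0.02)

    def test_square_approaches_continuous_limit(self):
        n = 220
        sq = np.zeros((n, n), bool)
        sq[10:210, 10:210] = True
        # analytic square: P^2/(4 pi A) = 16/(4 pi) = 1.2732
        assert circularity(make_mask(sq[None]), 0) == pytest.approx(16 / (4 * np.pi), abs=0.02)

    def test_literal_unnormalised_ratio_for_circle_is_4pi(self):
        yy, xx = np.mgrid[:64, :64]
        disc = ((yy - 31.5) ** 2 + (xx - 31.5) ** 2 <= 25 ** 2)
        lit = circularity(make_mask(disc[None]), 0, normalised=False)
        assert lit == pytest.approx(4 * np.pi, rel=0.02)

    def test_phantom_slices_in_reported_regime(self, phantom96):
        _, truth = phantom96
        vals = [circularity(truth["limb_mask"], i) for i in range(25, 70, 5)]
        assert all(1.1 <= v <= 1.4 for v in vals)

    def test_empty_slice_is_nan_not_zero(self, phantom96):
        _, truth = phantom96
        assert np.isnan(circularity(truth["limb_mask"], 0))

    def test_stray_pixels_ignored_via_largest_region(self):
        yy, xx = np.mgrid[:64, :64]
        disc = ((yy - 31.5) ** 2 + (xx - 31.5) ** 2 <= 20 ** 2)
        disc[2, 2] = disc[60, 3] = True  # isolated specks
        assert circularity(make_mask(disc[None]), 0) == pytest.approx(1.0, abs=0.02)


class TestLength:
    def test_slice_count_times_0p6(self):
        data = np.zeros((300, 4, 4))
        data[10:270, 1, 1] = 1  # 260 slices occupied
        assert limb_length_mm(make_mask(data)) == pytest.approx(156.0)

    def test_single_slice(self):
        data = np.zeros((5, 4, 4))
        data[2, 1, 1] = 1
        assert limb_length_mm(make_mask(data)) == pytest.approx(0.6)

    def test_phantom_length_within_one_slice(self, spec96, phantom96):
        _, truth = phantom96
        assert limb_length_mm(truth["limb_mask"]) == \
            pytest.approx(spec96.limb_length_mm, abs=0.6 + 1e-9)

    def test_empty_mask_is_zero(self):
        assert limb_length_mm(make_mask(np.zeros((4, 4, 4)))) == 0.0


class TestShapeDifference:
    def test_identical_masks_give_zero(self, phantom96):
        _, truth = phantom96
        sd = shape_difference(truth["limb_mask"], truth["limb_mask"])
        assert sd.total_mm3 == 0.0
        assert set(np.unique(sd.label_volume)) <= {0, 1}

    def test_fifty_extra_voxels(self, phantom96):
        _, truth = phantom96
        a = truth["limb_mask"]
        data = a.data.copy()
        # grow 50 background voxels adjacent to nothing in particular
        free = np.argwhere(data == 0)[:50]
        data[tuple(free.T)] = 1
        b = dataclasses.replace(a, data=data)
        sd = shape_difference(a, b)
        assert sd.total_mm3 == pytest.approx(50 * 0.216)
        assert sd.only_b_mm3 == pytest.approx(50 * 0.216)
        assert sd.only_a_mm3 == 0.0

    def test_symmetry_and_partition_consistency(self, std_limb_and_partition, rng):
        limb, part = std_limb_and_partition
        data = limb.data.copy()
        flip = rng.choice(np.prod(data.shape), 500, replace=False)
        data.ravel()[flip] ^= 1
        other = dataclasses.replace(limb, data=data)
        ab = shape_difference(limb, other, partition=part)
        ba = shape_difference(other, limb, partition=part)
        assert ab.total_mm3 == ba.total_mm3
        assert ab.total_mm3 == ab.only_a_mm3 + ab.only_b_mm3
        quads = sum(ab.per_region[q] for q in ("AL", "AM", "PL", "PM"))
        bands = sum(ab.per_region[b] for b in ("distal", "middle", "proximal"))
        assert quads == pytest.approx(ab.total_mm3, abs=1e-9)
        assert bands == pytest.approx(ab.total_mm3, abs=1e-9)

    def test_triangle_inequality_on_random_masks(self, rng):
        # XOR volume is a metric: fuzz the triangle bound
        for _ in range(20):
            a, b, c = (rng.random((10, 10, 10)) < 0.4 for _ in range(3))
            ma, mb, mc = (make_mask(x) for x in (a, b, c))
            d = lambda u, v: shape_difference(u, v, keep_labels=False).total_mm3
            assert d(ma, mc) <= d(ma, mb) + d(mb, mc) + 1e-12

    def test_volume_difference_lower_bound(self, rng):
        for _ in range(10):
            a, b = (rng.random((12, 12, 12)) < 0.5 for _ in range(2))
            ma, mb = make_mask(a), make_mask(b)
            sd = shape_difference(ma, mb, keep_labels=False)
            assert abs(volume_mm3(ma) - volume_mm3(mb)) <= sd.total_mm3 + 1e-12

    def test_grid_mismatch_rejected(self, phantom96, phantom64):
        with pytest.raises(ValueError):
            shape_difference(phantom96[1]["limb_mask"], phantom64[1]["limb_mask"])

    def test_label_volume_legend_codes(self, phantom96):
        _, truth = phantom96
        a = truth["limb_mask"]
        b = dataclasses.replace(a, data=np.roll(a.data, 2, axis=1))
        sd = shape_difference(a, b)
        assert set(np.unique(sd.label_volume)) <= set(DIFF_LEGEND)


class TestSampleSlices:
    def test_deterministic_given_seed(self, std_limb_and_partition):
        limb, part = std_limb_and_partition
        s1 = sample_slices(limb, part, per_region=3, seed=9)
        s2 = sample_slices(limb, part, per_region=3, seed=9)
        assert s1 == s2

    def test_three_per_band_gives_nine_total(self, std_limb_and_partition):
        limb, part = std_limb_and_partition
        sel = sample_slices(limb, part, per_region=3, seed=0)
        assert sorted(sel) == ["distal", "middle", "proximal"]
        assert sum(len(v) for v in sel.values()) == 9
        # indices fall in their own band
        for band, idxs in sel.items():
            z = np.asarray(idxs) * limb.spacing_mm[0]
            if band == "distal":
                assert (z < part.cut_z_mm[0]).all()
            elif band == "middle":
                assert ((z >= part.cut_z_mm[0]) & (z < part.cut_z_mm[1])).all()
            else:
                assert (z >= part.cut_z_mm[1]).all()

    def test_small_band_uses_all_slices_with_warning(self, std_limb_and_partition):
        limb, part = std_limb_and_partition
        nz = np.nonzero(limb.data.any(axis=(1, 2)))[0]
        distal = [i for i in nz if i * 0.6 < part.cut_z_mm[0]][:2]
        keep = [i for i in nz if i * 0.6 >= part.cut_z_mm[0]] + distal
        with pytest.warns(UserWarning, match="distal"):
            sel = sample_slices(limb, part, per_region=3, seed=1,
                                restrict_to=np.asarray(keep))
        assert sel["distal"] == sorted(distal)
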