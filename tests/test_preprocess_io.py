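"""NIfTI round-trips, resampling geometry, fingerprints, normalization,
the low-resolution halving rule, and the shipped plan presets."""

import numpy as np
import pytest

from ctseg.plans import Plan, plan_for_task
from ctseg.preprocess import (DatasetFingerprint, compute_fingerprint,
                              lowres_spacing, normalize, resample,
                              resampled_shape)
from ctseg.volume import (LabelMask, Volume, read_case, write_mask,
                          write_volume)


def _fp(**kw):
    base = dict(median_spacing=(1, 1, 1), median_shape=(32, 32, 32),
                fg_p005=-50.0, fg_p995=150.0, fg_mean=50.0, fg_std=20.0)
    base.update(kw)
    return DatasetFingerprint(**base)


class TestNiftiIO:
    def test_round_trip_preserves_data_and_geometry(self, tmp_path, rng):
        data = rng.normal(size=(10, 12, 8)).astype(np.float32)
        vol = Volume(data, (1.0, 1.25, 2.5))
        write_volume(vol, tmp_path / "img.nii.gz")
        back, _ = read_case(tmp_path / "img.nii.gz")
        assert np.array_equal(back.data, data)
        assert back.spacing == vol.spacing
        assert np.array_equal(back.affine, vol.affine)

    def test_mask_round_trip_and_pairing(self, tmp_path, rng):
        labels = (rng.random((10, 12, 8)) * 3).astype(np.int16)
        write_volume(Volume(np.zeros((10, 12, 8), np.float32), (1, 1, 1)),
                     tmp_path / "img.nii.gz")
        write_mask(LabelMask(labels, (1, 1, 1)), tmp_path / "mask.nii.gz")
        vol, mask = read_case(tmp_path / "img.nii.gz",
                              tmp_path / "mask.nii.gz")
        assert np.array_equal(mask.labels, labels)

    def test_shape_mismatch_rejected(self, tmp_path):
        write_volume(Volume(np.zeros((8, 8, 8), np.float32), (1, 1, 1)),
                     tmp_path / "img.nii.gz")
        write_mask(LabelMask(np.zeros((4, 4, 4), np.int16), (1, 1, 1)),
                   tmp_path / "mask.nii.gz")
        with pytest.raises(ValueError, match="does not match"):
            read_case(tmp_path / "img.nii.gz", tmp_path / "mask.nii.gz")


class TestResample:
    def test_shape_follows_spacing_formula(self, rng):
        vol = Volume(rng.normal(size=(32, 32, 16)).astype(np.float32),
                     (1.0, 1.0, 2.0))
        out = resample(vol, (1.0, 1.0, 1.0), "image")
        assert out.shape == (32, 32, 32)
        assert out.spacing == (1.0, 1.0, 1.0)

    def test_identity_when_spacing_unchanged(self, rng):
        data = rng.normal(size=(9, 9, 9)).astype(np.float32)
        out = resample(Volume(data, (1, 1, 1)), (1, 1, 1), "image")
        assert np.array_equal(out.data, data)

    def test_nearest_neighbour_preserves_value_set(self, rng):
        labels = (rng.random((16, 16, 8)) > 0.7).astype(np.int16)
        out = resample(LabelMask(labels, (1, 1, 2), class_set=(0, 1)),
                       (1, 1, 1), "mask")
        assert set(np.unique(out.labels)) <= {0, 1}
        assert out.shape == (16, 16, 16)

    def test_round_trip_shape_restored(self, rng):
        # factor-2 down and back up is shape-invertible
        vol = Volume(rng.normal(size=(24, 32, 40)).astype(np.float32),
                     (1.0, 1.0, 1.0))
        down = resample(vol, (2.0, 2.0, 2.0), "image")
        back = resample(down, (1.0, 1.0, 1.0), "image")
        assert back.shape == vol.shape

    def test_nonpositive_spacing_rejected(self, rng):
        vol = Volume(np.zeros((4, 4, 4), np.float32), (1, 1, 1))
        with pytest.raises(ValueError):
            resample(vol, (0.0, 1.0, 1.0), "image")


class TestFingerprint:
    def test_single_case_medians(self, rng):
        data = rng.normal(50, 10, size=(12, 10, 8)).astype(np.float32)
        labels = np.zeros((12, 10, 8), np.int16)
        labels[4:8, 4:8, 2:6] = 1
        fp = compute_fingerprint([(Volume(data, (1.5, 1.0, 2.0)),
                                   LabelMask(labels, (1.5, 1.0, 2.0)))])
        assert fp.median_spacing == (1.5, 1.0, 2.0)
        assert fp.median_shape == (12, 10, 8)

    def test_mean_and_sd_are_population_statistics(self):
        data = np.concatenate([np.full(1000, 10.0), np.full(1000, 20.0)])
        vol = Volume(data.reshape(20, 10, 10).astype(np.float32), (1, 1, 1))
        mask = LabelMask(np.ones((20, 10, 10), np.int16), (1, 1, 1))
        fp = compute_fingerprint([(vol, mask)])
        assert fp.fg_mean == pytest.approx(15.0)
        assert fp.fg_std == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_percentiles_match_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 100, size=(10, 10, 10)).astype(np.float32)
        labels = (rng.random((10, 10, 10)) > 0.5).astype(np.int16)
        fp = compute_fingerprint([(Volume(data, (1, 1, 1)),
                                   LabelMask(labels, (1, 1, 1),
                                             class_set=(0, 1)))])
        fg = np.sort(data[labels > 0].astype(np.float64))
        lo, hi = np.percentile(fg, [0.5, 99.5])  # linear interpolation
        assert fp.fg_p005 == pytest.approx(lo)
        assert fp.fg_p995 == pytest.approx(hi)
        assert fg[0] <= fp.fg_p005 <= fp.fg_p995 <= fg[-1]

    def test_no_foreground_rejected(self):
        vol = Volume(np.zeros((4, 4, 4), np.float32), (1, 1, 1))
        mask = LabelMask(np.zeros((4, 4, 4), np.int16), (1, 1, 1))
        with pytest.raises(ValueError, match="foreground"):
            compute_fingerprint([(vol, mask)])


class TestNormalize:
    def test_values_above_p995_clip_to_fixed_point(self):
        fp = _fp()
        vol = Volume(np.full((4, 4, 4), 1e4, np.float32), (1, 1, 1))
        out = normalize(vol, fp)
        expected = (fp.fg_p995 - fp.fg_mean) / fp.fg_std
        assert np.allclose(out.data, expected)

    def test_foreground_standardized_when_clipping_inactive(self, rng):
        data = rng.normal(100, 30, size=(16, 16, 16)).astype(np.float32)
        labels = np.ones((16, 16, 16), np.int16)
        vol = Volume(data, (1, 1, 1))
        fp = compute_fingerprint([(vol, LabelMask(labels, (1, 1, 1),
                                                  class_set=(0, 1)))])
        out = normalize(vol, fp)
        inside = out.data[(data > fp.fg_p005) & (data < fp.fg_p995)]
        assert abs(inside.mean()) < 0.05
        assert abs(inside.std() - 1.0) < 0.05

    def test_zero_variance_rejected(self):
        fp = _fp(fg_std=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            normalize(Volume(np.zeros((2, 2, 2), np.float32), (1, 1, 1)), fp)


class TestLowresRule:
    def test_single_halving_case(self):
        fp = _fp(median_spacing=(0.78, 0.78, 3.0),
                 median_shape=(511, 511, 136))
        spacing = lowres_spacing(fp, (128, 128, 128))
        # 35.5M voxels >= 4 * 2.1M, one halving brings it below
        assert spacing == tuple(2 * s for s in fp.median_spacing)

    def test_no_halving_when_already_small(self):
        fp = _fp(median_shape=(100, 100, 50))
        assert lowres_spacing(fp, (64, 64, 64)) == fp.median_spacing

    @pytest.mark.parametrize("seed", range(20))
    def test_k_is_minimal_and_satisfies_inequality(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(int(v) for v in rng.integers(40, 600, 3))
        patch = tuple(int(v) for v in rng.integers(16, 160, 3))
        fp = _fp(median_shape=shape)
        spacing = lowres_spacing(fp, patch)
        k = int(np.round(np.log2(spacing[0] / fp.median_spacing[0])))
        target = 4 * np.prod(patch)
        assert np.prod(np.asarray(shape) / 2 ** k) < target
        # minimality against exhaustive search
        best = next(j for j in range(11)
                    if np.prod(np.asarray(shape) / 2 ** j) < target)
        assert k == best


class TestPlans:
    @pytest.mark.parametrize("task,res,patch,levels,batch", [
        ("kidney", "full", (160, 160, 48), (5, 5, 3), 2),
        ("kidney", "low", (128, 128, 80), (5, 5, 4), 2),
        ("liver", "full", (96, 128, 128), (5, 5, 5), 2),
        ("pancreas", "full", (40, 192, 160), (3, 5, 5), 2),
        ("pancreas", "low", (64, 128, 128), (3, 5, 5), 2),
    ])
    def test_shipped_presets(self, task, res, patch, levels, batch):
        p = plan_for_task(task, res)
        assert p.patch_size == patch
        assert p.levels_per_axis == levels
        assert p.batch_size == batch

    def test_unknown_preset_lists_available(self):
        with pytest.raises(KeyError, match="kidney/full"):
            plan_for_task("spleen", "full")

    def test_patch_divisibility_enforced(self):
        with pytest.raises(ValueError, match="not divisible"):
            Plan("x", "full", (100, 128, 128), (5, 5, 5))

    def test_json_round_trip(self, tmp_path):
        p = plan_for_task("liver", "low")
        p.to_json(tmp_path / "plan.json")
        q = Plan.from_json(tmp_path / "plan.json")
        assert q == p
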