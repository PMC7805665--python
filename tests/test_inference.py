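"""Sliding-window inference: Gaussian weights, tiling coverage,
stitching conservation, mirror TTA, resolution ensembling, and
activation-map export."""

import itertools

import numpy as np
import pytest

from ctseg.inference import (SoftmaxVolume, argmax_mask, assemble,
                             export_activation_maps, gaussian_weights,
                             predict_volume, tile_positions)
from ctseg.network import NetworkSpec, build_network
from ctseg.volume import Volume


class ConstantStub:
    """Emits the same class probabilities everywhere (mirror-equivariant)."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, np.float64)

    def predict_proba(self, patch):
        c = len(self.probs)
        out = np.empty((c,) + patch.shape)
        out[:] = self.probs.reshape(c, 1, 1, 1)
        return out


class CornerKeyedStub:
    """Returns probabilities that depend on the patch content mean,
    breaking mirror equivariance and tile uniformity."""

    def predict_proba(self, patch):
        p1 = 1.0 / (1.0 + np.exp(-patch))
        return np.stack([1.0 - p1, p1])


class TestGaussianWeights:
    def test_center_peak_and_closed_form_profile(self):
        w = gaussian_weights((9, 9, 9)).weights
        assert w[4, 4, 4] == pytest.approx(1.0)
        sigma = 9 / 8.0
        for i in range(9):
            expected = max(np.exp(-((i - 4) ** 2) / (2 * sigma ** 2)), 1e-6)
            assert w[i, 4, 4] == pytest.approx(expected, rel=1e-12)

    def test_mirror_symmetric_and_floored(self):
        w = gaussian_weights((8, 10, 6)).weights
        for axis in range(3):
            assert np.allclose(w, np.flip(w, axis))
        assert w.min() >= 1e-6
        assert w.max() == 1.0


class TestTiling:
    def test_volume_equal_to_patch_gives_single_tile(self):
        assert tile_positions((16, 16, 16), (16, 16, 16)) == [(0, 0, 0)]

    def test_half_overlap_with_clamped_tail(self):
        starts = tile_positions((256, 128, 128), (128, 128, 128))
        assert sorted({s[0] for s in starts}) == [0, 64, 128]

    @pytest.mark.parametrize("seed", range(50))
    def test_every_voxel_covered(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(int(v) for v in rng.integers(8, 40, 3))
        patch = tuple(int(rng.integers(4, s + 1)) for s in shape)
        covered = np.zeros(shape, bool)
        for corner in tile_positions(shape, patch):
            sl = tuple(slice(c, c + p) for c, p in zip(corner, patch))
            covered[sl] = True
        assert covered.all()


class TestStitching:
    def test_constant_dyadic_probabilities_reproduced_bit_exactly(self):
        stub = ConstantStub([0.25, 0.25, 0.5])
        vol = Volume(np.zeros((20, 14, 9), np.float32), (1, 1, 1))
        sv = predict_volume(stub, vol, (8, 8, 8), tta=False)
        assert (sv.probs[0] == 0.25).all()
        assert (sv.probs[2] == 0.5).all()

    @pytest.mark.parametrize("seed", range(50))
    def test_constant_field_conserved_over_random_geometries(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(int(v) for v in rng.integers(6, 28, 3))
        patch = tuple(int(v) for v in rng.integers(4, 12, 3))
        p = rng.dirichlet(np.ones(3))
        sv = predict_volume(ConstantStub(p),
                            Volume(np.zeros(shape, np.float32), (1, 1, 1)),
                            patch, tta=False)
        for c in range(3):
            assert np.abs(sv.probs[c] - p[c]).max() < 1e-12
        assert np.allclose(sv.probs.sum(axis=0), 1.0, atol=1e-12)

    def test_tta_equals_plain_for_mirror_equivariant_network(self):
        stub = ConstantStub([0.25, 0.25, 0.5])
        vol = Volume(np.zeros((12, 12, 12), np.float32), (1, 1, 1))
        with_tta = predict_volume(stub, vol, (8, 8, 8), tta=True)
        without = predict_volume(stub, vol, (8, 8, 8), tta=False)
        assert np.array_equal(with_tta.probs, without.probs)

    def test_two_tile_hand_computed_average(self):
        # 1D-style toy: two overlapping tiles along axis 0
        stub = CornerKeyedStub()
        data = np.linspace(-1, 1, 8 * 4 * 4).reshape(8, 4, 4).astype(
            np.float32)
        vol = Volume(data, (1, 1, 1))
        sv = predict_volume(stub, vol, (4, 4, 4), tta=False)
        # oracle: explicit accumulation over the tile corners
        w = gaussian_weights((4, 4, 4)).weights
        num = np.zeros((2, 8, 4, 4))
        den = np.zeros((8, 4, 4))
        for c0 in (0, 2, 4):
            patch = data[c0:c0 + 4]
            probs = stub.predict_proba(patch)
            num[:, c0:c0 + 4] += w * probs
            den[c0:c0 + 4] += w
        assert np.allclose(sv.probs, num / den, atol=1e-12)

    def test_probability_simplex_preserved_with_tta(self, rng):
        stub = CornerKeyedStub()
        vol = Volume(rng.normal(size=(10, 6, 6)).astype(np.float32),
                     (1, 1, 1))
        sv = predict_volume(stub, vol, (4, 4, 4), tta=True)
        assert np.allclose(sv.probs.sum(axis=0), 1.0, atol=1e-10)
        assert sv.probs.min() >= 0


class TestAssembly:
    def test_identical_inputs_reduce_to_argmax(self, rng):
        probs = rng.dirichlet(np.ones(3), size=8).T.reshape(3, 2, 2, 2)
        sv = SoftmaxVolume(probs, (1, 1, 1))
        mask = assemble(sv, sv)
        assert np.array_equal(mask.labels, np.argmax(probs, axis=0))

    def test_ensemble_can_flip_the_decision(self):
        full = SoftmaxVolume(np.array([0.6, 0.4]).reshape(2, 1, 1, 1),
                             (1, 1, 1))
        low = SoftmaxVolume(np.array([0.1, 0.9]).reshape(2, 1, 1, 1),
                            (1, 1, 1))
        mask = assemble(full, low, class_set=(0, 1))
        assert mask.labels[0, 0, 0] == 1     # mean (0.35, 0.65)

    def test_low_resolution_map_resampled_and_renormalized(self, rng):
        full = SoftmaxVolume(rng.dirichlet(np.ones(3), size=64).T.reshape(
            3, 4, 4, 4), (1, 1, 1))
        low = SoftmaxVolume(rng.dirichlet(np.ones(3), size=8).T.reshape(
            3, 2, 2, 2), (2, 2, 2))
        mask = assemble(full, low)
        assert mask.labels.shape == (4, 4, 4)

    def test_argmax_tie_breaks_to_lowest_class(self):
        probs = np.full((3, 2, 2, 2), 1.0 / 3.0)
        mask = argmax_mask(SoftmaxVolume(probs, (1, 1, 1)))
        assert (mask.labels == 0).all()


class TestActivationExport:
    def test_map_count_and_alpha_range(self, rng, tmp_path):
        spec = NetworkSpec(variant="vnet", base_features=2,
                           levels_per_axis=(2, 2, 2), ag_levels=2,
                           dsv_levels=2)
        net = build_network(spec, seed=0)
        vol = Volume(rng.normal(size=(8, 8, 8)).astype(np.float32),
                     (1, 1, 1))
        maps = export_activation_maps(net, vol, (8, 8, 8),
                                      out_dir=tmp_path)
        attention = [k for k in maps if k.startswith("attention")]
        assert len(attention) == spec.ag_levels
        for k in attention:
            assert maps[k].min() >= 0.0 and maps[k].max() <= 1.0
            assert maps[k].shape == (8, 8, 8)
        secondary = [k for k in maps if k.startswith("secondary")]
        assert len(secondary) == spec.dsv_levels * spec.num_classes
        assert len(list(tmp_path.glob("*.nii.gz"))) == len(maps)

    def test_plain_network_warns_and_exports_nothing(self, rng):
        spec = NetworkSpec(variant="vnet", base_features=2,
                           levels_per_axis=(2, 2, 2), ag_levels=0,
                           dsv_levels=0)
        net = build_network(spec, seed=0)
        vol = Volume(np.zeros((8, 8, 8), np.float32), (1, 1, 1))
        with pytest.warns(UserWarning, match="nothing to export"):
            maps = export_activation_maps(net, vol, (8, 8, 8))
        assert maps == {}
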