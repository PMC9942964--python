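import dataclasses

import numpy as np
import pytest

from tagprobe import feature_discovery as fd
from tagprobe import multiscale_generator as mg
from tagprobe import scene_synth as ss


@pytest.fixture(scope="module")
def rated_codes(cfg):
    codes, factors = mg.sample_codes(90, cfg, seed=400)
    ratings = np.array([f.tau for f in factors])
    return codes, ratings


class TestBuildHighTranslucencySet:
    def test_full_scale_pair_count(self, rated_codes, cfg):
        codes, ratings = rated_codes
        images = fd.build_high_translucency_set(
            codes, ratings, n_targets=40, n_extra_sources=40, cfg=cfg,
            resolution=32,
        )
        assert len(images) == 3160

    def test_single_pair(self, rated_codes, cfg):
        codes, ratings = rated_codes
        images = fd.build_high_translucency_set(
            codes, ratings, n_targets=1, n_extra_sources=1, cfg=cfg,
            resolution=32,
        )
        assert len(images) == 1

    def test_count_law(self, rated_codes, cfg):
        codes, ratings = rated_codes
        for nt, ne in ((3, 5), (4, 0), (2, 7)):
            images = fd.build_high_translucency_set(
                codes, ratings, n_targets=nt, n_extra_sources=ne, cfg=cfg,
                resolution=32,
            )
            assert len(images) == (nt + ne) * nt - nt

    def test_targets_exceeding_pool_rejected(self, cfg):
        codes, factors = mg.sample_codes(10, cfg, seed=401)
        ratings = [f.tau for f in factors]
        with pytest.raises(ValueError, match="rated codes"):
            fd.build_high_translucency_set(
                codes, ratings, n_targets=8, n_extra_sources=8, cfg=cfg
            )

    def test_swap_is_middle_layer_only(self, rated_codes, cfg):
        codes, ratings = rated_codes
        order = np.argsort(-ratings)
        target, source = codes[order[0]], codes[order[1]]
        from tagprobe.latent_morphing import morph

        swapped = morph(source, target, cfg.groups.middle, 1.0)
        mid = np.array(cfg.groups.middle) - 1
        assert np.array_equal(swapped.layers[mid], target.layers[mid])
        rest = [i for i in range(cfg.L) if i + 1 not in cfg.groups.middle]
        assert np.array_equal(swapped.layers[rest], source.layers[rest])


class TestSamplePatches:
    def test_patch_count_is_product(self):
        imgs = [np.random.default_rng(i).random((32, 32, 3)) for i in range(5)]
        patches = fd.sample_patches(imgs, resize_to=64, patch=12, per_image=10, seed=0)
        assert patches.shape == (50, 12, 12, 3)

    def test_patch_values_verbatim_without_resize(self):
        img = np.random.default_rng(3).random((64, 64, 3))
        patches = fd.sample_patches([img], resize_to=64, patch=8, per_image=6, seed=1)
        for p in patches:
            found = False
            for r in range(57):
                for c in range(57):
                    if np.array_equal(img[r : r + 8, c : c + 8], p):
                        found = True
                        break
                if found:
                    break
            assert found

    def test_same_seed_same_offsets(self):
        imgs = [np.random.default_rng(4).random((32, 32, 3))]
        a = fd.sample_patches(imgs, 32, 8, 5, seed=9)
        b = fd.sample_patches(imgs, 32, 8, 5, seed=9)
        assert np.array_equal(a, b)

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError, match="patch"):
            fd.sample_patches([np.zeros((16, 16, 3))], 16, 24, 1, seed=0)


def _sparse_source_patches(n=6000, p=6, k=8, seed=0):
    """Random sparse (Laplacian) sources mixed into patch space."""
    rng = np.random.default_rng(seed)
    dim = p * p * 3
    mixing = rng.normal(size=(dim, k))
    sources = rng.laplace(size=(n, k))
    return (sources @ mixing.T).reshape(n, p, p, 3), mixing


class TestLearnIcaKernels:
    def test_bank_shape_at_reference_scale(self):
        rng = np.random.default_rng(5)
        patches = rng.laplace(size=(1000, 24, 24, 3)) * rng.random(24 * 24 * 3).reshape(
            24, 24, 3
        )
        bank = fd.learn_ica_kernels(patches, K=64, seed=0)
        assert bank.kernels.shape == (64, 24, 24, 3)
        np.testing.assert_allclose(
            np.linalg.norm(bank.kernels.reshape(64, -1), axis=1), 1.0, atol=1e-9
        )

    def test_source_recovery_oracle(self):
        patches, mixing = _sparse_source_patches()
        bank = fd.learn_ica_kernels(patches, K=8, seed=1)
        true = mixing / np.linalg.norm(mixing, axis=0)
        got = bank.kernels.reshape(8, -1)
        # best |correlation| match per true source, up to permutation/sign
        corr = np.abs(got @ true)
        best = corr.max(axis=0)
        assert (best >= 0.9).all(), best

    def test_component_responses_uncorrelated(self):
        patches, _ = _sparse_source_patches(seed=2)
        X = patches.reshape(len(patches), -1)
        from sklearn.decomposition import FastICA

        bank = fd.learn_ica_kernels(patches, K=8, seed=3)
        # recompute source activations against the learned bank by
        # least squares and check decorrelation
        k = bank.kernels.reshape(8, -1)
        acts, *_ = np.linalg.lstsq(k.T, (X - X.mean(axis=0)).T, rcond=None)
        c = np.corrcoef(acts)
        off = c[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_insufficient_patches_rejected(self):
        patches = np.random.default_rng(6).random((50, 6, 6, 3))
        with pytest.raises(ValueError, match="patches"):
            fd.learn_ica_kernels(patches, K=8, seed=0)

    def test_rank_deficiency_rejected(self):
        # rank-1 patch matrix cannot support 4 components
        base = np.random.default_rng(7).random((1, 6, 6, 3))
        patches = np.concatenate([base * s for s in np.linspace(0.1, 1, 60)])
        with pytest.raises(ValueError, match="rank"):
            fd.learn_ica_kernels(patches, K=4, seed=0)

    def test_fixed_seed_bitwise_reproducible(self):
        patches, _ = _sparse_source_patches(n=2000, seed=8)
        a = fd.learn_ica_kernels(patches, K=8, seed=11)
        b = fd.learn_ica_kernels(patches, K=8, seed=11)
        assert np.array_equal(a.kernels, b.kernels)

    def test_sign_convention(self):
        patches, _ = _sparse_source_patches(n=2000, seed=9)
        bank = fd.learn_ica_kernels(patches, K=8, seed=12)
        for k in bank.kernels:
            flat = k.ravel()
            assert flat[np.argmax(np.abs(flat))] > 0


def _gabor(p, theta, freq=3.0):
    ax = np.linspace(-1, 1, p)
    X, Y = np.meshgrid(ax, ax)
    u = X * np.cos(theta) + Y * np.sin(theta)
    env = np.exp(-(X**2 + Y**2) / 0.3)
    return np.cos(2 * np.pi * freq * u) * env


class TestClassifyKernels:
    def _bank(self, kernels):
        arr = np.stack(kernels)
        arr = arr / np.linalg.norm(arr.reshape(len(arr), -1), axis=1)[:, None, None, None]
        return fd.KernelBank(kernels=arr, nongaussianity=np.zeros(len(arr)))

    def test_equal_channels_achromatic(self):
        g = _gabor(16, 0.7)
        bank = self._bank([np.stack([g, g, g], axis=2)])
        fd.classify_kernels(bank)
        assert bank.chromaticity[0] == "achromatic"

    def test_opponent_gabor_chromatic_and_oriented(self):
        theta = np.deg2rad(40.0)
        g = _gabor(24, theta)
        kernel = np.stack([g, -g, np.zeros_like(g)], axis=2)
        bank = self._bank([kernel])
        fd.classify_kernels(bank)
        assert bank.chromaticity[0] == "chromatic"
        assert bank.orientation[0] is not None
        err = abs(bank.orientation[0] - theta) % np.pi
        err = min(err, np.pi - err)
        assert np.rad2deg(err) < 10.0

    def test_center_surround_orientation_free(self):
        ax = np.linspace(-1, 1, 17)
        X, Y = np.meshgrid(ax, ax)
        r2 = X**2 + Y**2
        dog = np.exp(-r2 / 0.1) - 0.5 * np.exp(-r2 / 0.4)
        bank = self._bank([np.stack([dog, dog, dog], axis=2)])
        fd.classify_kernels(bank)
        assert bank.orientation[0] is None
        assert bank.annotations().oriented.tolist() == [False]


class TestFilterImage:
    def test_zero_mean_kernel_constant_image(self):
        kernel = np.random.default_rng(0).normal(size=(7, 7, 3))
        kernel -= kernel.mean(axis=(0, 1))
        img = np.full((32, 32, 3), 0.6)
        resp = fd.filter_image(img, kernel)
        assert np.abs(resp).max() < 1e-10
        assert resp.shape == (32, 32)

    def test_delta_kernel_extracts_channel(self):
        kernel = np.zeros((5, 5, 3))
        kernel[2, 2, 0] = 1.0
        img = np.random.default_rng(1).random((20, 20, 3))
        resp = fd.filter_image(img, kernel)
        np.testing.assert_allclose(resp, img[:, :, 0], atol=1e-12)

    def test_linearity(self):
        kernel = np.random.default_rng(2).normal(size=(5, 5, 3))
        x = np.random.default_rng(3).random((16, 16, 3))
        y = np.random.default_rng(4).random((16, 16, 3))
        lhs = fd.filter_image(2.0 * x + 3.0 * y, kernel)
        rhs = 2.0 * fd.filter_image(x, kernel) + 3.0 * fd.filter_image(y, kernel)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_undersized_image_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            fd.filter_image(np.zeros((4, 4, 3)), np.zeros((8, 8, 3)))


@pytest.fixture(scope="module")
def scene_bank_and_sets():
    """Kernels learned from material-scale high-tau renders plus paired
    high/low-tau evaluation sets (fixed seeds)."""
    hi, lo, masks = [], [], []
    for s in range(60):
        f = ss.sample_scene(s, "glycerin")
        f = dataclasses.replace(
            f, body_color=np.array([0.5, 0.5, 0.5]), texture_amp=0.0
        )
        hi.append(ss.render_scene(dataclasses.replace(f, tau=0.9), 128))
        lo.append(ss.render_scene(dataclasses.replace(f, tau=0.1), 128))
        masks.append(ss.object_mask(f, 128))
    patches = fd.sample_patches(hi, 128, 24, 12, seed=1)
    bank = fd.learn_ica_kernels(patches, K=64, seed=2)
    fd.classify_kernels(bank)
    return bank, hi, lo, masks


class TestTranslucencyResponseContrast:
    def test_identical_sets_zero(self, scene_bank_and_sets):
        bank, hi, lo, masks = scene_bank_and_sets
        c = fd.translucency_response_contrast(
            hi[:8], hi[:8], bank, masks[:8], masks[:8]
        )
        np.testing.assert_allclose(c, 0.0, atol=1e-12)

    def test_sign_flips_on_swap(self, scene_bank_and_sets):
        bank, hi, lo, masks = scene_bank_and_sets
        a = fd.translucency_response_contrast(
            hi[:10], lo[:10], bank, masks[:10], masks[:10]
        )
        b = fd.translucency_response_contrast(
            lo[:10], hi[:10], bank, masks[:10], masks[:10]
        )
        np.testing.assert_allclose(a, -b, atol=1e-9)

    def test_top_contrast_kernel_is_chromatic(self, scene_bank_and_sets):
        bank, hi, lo, masks = scene_bank_and_sets
        c = fd.translucency_response_contrast(
            hi[:15], lo[:15], bank, masks[:15], masks[:15]
        )
        top = int(np.argmax(c))
        assert bank.chromaticity[top] == "chromatic"

    def test_empty_sets_rejected(self, scene_bank_and_sets):
        bank, hi, lo, masks = scene_bank_and_sets
        with pytest.raises(ValueError, match="nonempty"):
            fd.translucency_response_contrast([], lo[:2], bank, [], masks[:2])

    def test_coarse_scale_kernels_less_diagnostic(self, scene_bank_and_sets):
        # kernels learned from shape-scale (16 px) renders at 4x patch size
        # carry less translucency contrast than mid-scale kernels
        bank, hi, lo, masks = scene_bank_and_sets
        coarse_imgs = []
        for s in range(60):
            f = ss.sample_scene(s, "glycerin")
            f = dataclasses.replace(
                f,
                body_color=np.array([0.5, 0.5, 0.5]),
                texture_amp=0.0,
                tau=0.9,
            )
            coarse_imgs.append(ss.render_scene(f, 16))
        patches = fd.sample_patches(coarse_imgs, 128, 48, 6, seed=3)
        coarse_bank = fd.learn_ica_kernels(patches, K=16, seed=4)
        fd.classify_kernels(coarse_bank)
        mid = fd.translucency_response_contrast(
            hi[:12], lo[:12], bank, masks[:12], masks[:12]
        )
        coarse = fd.translucency_response_contrast(
            hi[:12], lo[:12], coarse_bank, masks[:12], masks[:12]
        )
        assert np.nanmax(mid) > np.nanmax(coarse)
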